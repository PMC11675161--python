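"""Desk-scale planted-effect validation of the full pipeline.

One validation trial generates a synthetic cohort of 12 controls and 12
patients on the 30-region parcellation with a pure interhemispheric
attenuation planted at strength 0.5 per unit normalised severity, sweeps
every subject over the 8 x 6 desk grid (120 s runs), and applies the
behavioral network-based model fitting in the directions the disease is
expected to push the simulated networks: patient modularity above controls,
patient efficiency below controls, severity correlating positively with
modularity and negatively with efficiency.  Cross-validation repeats the
efficiency fit on stratified training folds and scores held-out patients.

A directional fit succeeds only when some grid point passes both the
(sign-restricted) significance mask and the intersubject-variability mask;
``None`` records that no such point exists for that trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import aggregate_cohort, desk_preset, desk_z_threshold, sweep_cohort
from .progression import stratified_cv_fit
from .statmap import BehavioralFit, NoFitError
from .synthetic import CohortSpec, generate_cohort

__all__ = ["desk_cohort_spec", "planted_recovery_trial", "RecoveryTrial"]


def desk_cohort_spec(master_seed: int) -> CohortSpec:
    """The validation cohort conditions: 12 + 12 subjects, 30 regions,
    interhemispheric attenuation 0.5, no intramodule effect."""
    return CohortSpec(
        n_controls=12,
        n_patients=12,
        atlas="desk30",
        geometry_seed=10 * master_seed + 1,
        clinical_seed=10 * master_seed + 2,
        effect_seed=10 * master_seed + 3,
        effect_interhemispheric=0.5,
        effect_intramodule=0.0,
    )


#: expected directions of the planted disease effect in the fitted maps:
#: (property, target) -> (mode, sign) of the directional fit
EXPECTED_DIRECTIONS = {
    ("modularity", "group"): ("min", "-"),   # patient modularity above controls
    ("efficiency", "group"): ("max", "+"),   # patient efficiency below controls
    ("modularity", "updrs3_on"): ("max", "+"),
    ("efficiency", "updrs3_on"): ("min", "-"),
}


@dataclass
class RecoveryTrial:
    master_seed: int
    clinical: pd.DataFrame
    grid: object
    stacks: dict                 # property -> (n_subjects, nc, nd)
    fits: dict                   # (property, target) -> optimum statistic or None
    maps: dict                   # (property, target) -> StatisticalMap
    cv: pd.DataFrame
    z_threshold: float

    @property
    def cv_negative_fraction(self) -> float:
        """Fraction of all CV fold evaluations with a negative held-out
        correlation (fit failures count against)."""
        return float((self.cv.test_r < 0).mean())


def planted_recovery_trial(
    master_seed: int,
    cv_iterations: int = 20,
    z_threshold: float | None = None,
    progress: bool = False,
) -> RecoveryTrial:
    """Run one full end-to-end validation trial."""
    if z_threshold is None:
        z_threshold = desk_z_threshold()
    cohort = generate_cohort(desk_cohort_spec(master_seed))
    cfg = desk_preset()
    results = sweep_cohort(cohort, cfg, master_seed=master_seed, progress=progress)
    stacks = {p: aggregate_cohort(results[p], cohort.clinical) for p in results}

    fits: dict = {}
    maps: dict = {}
    for (prop, target), (mode, sign) in EXPECTED_DIRECTIONS.items():
        model = BehavioralFit(stacks[prop], cfg.grid, cohort.clinical, target, prop)
        if target == "group":
            from .statmap import rosenthal_effect_map

            maps[(prop, target)] = rosenthal_effect_map(
                model.stack_hc, model.stack_pd, cfg.grid
            )
        else:
            from .statmap import correlation_map

            maps[(prop, target)] = correlation_map(model.stack, model.y, cfg.grid)
        try:
            fits[(prop, target)] = model.fit(
                mode=mode, sign=sign, z_threshold=z_threshold
            ).optimum.value
        except NoFitError:
            fits[(prop, target)] = None

    eff_model = BehavioralFit(
        stacks["efficiency"], cfg.grid, cohort.clinical, "updrs3_on", "efficiency"
    )
    cv = stratified_cv_fit(
        eff_model.stack, eff_model.y, cfg.grid,
        k=3, iterations=cv_iterations, seed=master_seed,
        mode="min", sign="-", z_threshold=z_threshold,
    )
    return RecoveryTrial(
        master_seed=master_seed,
        clinical=cohort.clinical,
        grid=cfg.grid,
        stacks=stacks,
        fits=fits,
        maps=maps,
        cv=cv,
        z_threshold=z_threshold,
    )
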