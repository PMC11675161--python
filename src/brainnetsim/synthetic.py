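"""Synthetic cohorts: connectome geometry, subject connectomes, clinical tables.

The study's MRI-derived connectomes are not publicly shareable, so this module
generates cohorts with the statistical structure the analysis pipeline
assumes: symmetric nonnegative streamline-count matrices over a
two-hemisphere parcellation with homotopic interhemispheric edges and
distance-dependent connection strength; path lengths proportional to
inter-centroid distance; and a clinical table whose dependency structure
mirrors a cross-sectional Parkinson's cohort (age = onset age + duration,
positively coupled UPDRS III On/Off scores, a medication gap Off - On that
grows with disease duration).

A disease effect is planted in the patients' structural connectomes and is
tunable in strength: interhemispheric streamline counts are attenuated and
intrahemispheric (within-module) counts strengthened in proportion to the
patient's motor-impairment severity, normalised to [0, 1] over the cohort.
Attenuating between-module edges raises structural (and downstream simulated
functional) modularity and lowers global efficiency with increasing severity,
which is the alteration pattern the fitting pipeline is designed to detect.

Everything is deterministic given the spec's three seeds (geometry, clinical,
effect); the generator makes no attempt to reproduce real tractography degree
distributions beyond these invariants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    Parcellation,
    StructuralConnectome,
    write_connectome,
    write_region_table,
    read_region_table,
    read_connectome,
)

__all__ = [
    "CohortSpec",
    "Cohort",
    "synthetic_parcellation",
    "generate_parcellation_geometry",
    "generate_subject_sc",
    "generate_clinical_table",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

# Table-1-style cohort statistics used as generator defaults
HC_AGE_MEAN, HC_AGE_SD = 55.02, 9.78
ONSET_MEAN, ONSET_SD = 53.22, 9.30
DURATION_MEAN, DURATION_SD = 8.65, 5.21
UPDRS_ON_LOG_MEDIAN = np.log(17.5)
# log-normal sigma from the On-score interquartile range (11-28)
UPDRS_ON_LOG_SD = (np.log(28.0) - np.log(11.0)) / (2 * 0.6745)
# medication gap Off - On = GAP_INTERCEPT + GAP_SLOPE * duration + noise
GAP_SLOPE = 0.7      # points per year; plants the positive duration correlation
GAP_INTERCEPT = 7.4  # centres the gap near its observed median of 13.5
GAP_NOISE_SD = 7.0


def synthetic_parcellation(atlas: str = "schaefer100+sub") -> Parcellation:
    """Shipped synthetic parcellation variants.

    ``"schaefer100+sub"`` has 100 cortical + 14 subcortical regions,
    ``"desikan+sub"`` 68 + 14; ``"desk30"`` is the small test profile with
    16 cortical + 14 subcortical regions.  Regions alternate by hemisphere
    within each tissue class so homotopic pairs are adjacent in index.
    """
    n_cortical = {"schaefer100+sub": 100, "desikan+sub": 68, "desk30": 16}.get(atlas)
    if n_cortical is None:
        raise ValueError(f"unknown synthetic atlas {atlas!r}")
    sub_names = ["thalamus", "caudate", "putamen", "pallidum", "hippocampus", "amygdala", "accumbens"]
    ids, names, hemi, subc = [], [], [], []
    for i in range(n_cortical // 2):
        for h in ("L", "R"):
            ids.append(f"ctx-{h.lower()}-{i:03d}")
            names.append(f"cortex_{i:03d}_{h}")
            hemi.append(h)
            subc.append(False)
    for name in sub_names:
        for h in ("L", "R"):
            ids.append(f"sub-{h.lower()}-{name}")
            names.append(f"{name}_{h}")
            hemi.append(h)
            subc.append(True)
    return Parcellation(tuple(ids), tuple(names), tuple(hemi), tuple(subc), atlas)


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the cohort the pipeline is designed for: 51 healthy
    controls and 60 patients on a 100+14-region parcellation.  The disease
    effect sizes are fractional changes of streamline counts per unit
    normalised severity: ``effect_interhemispheric`` attenuates
    interhemispheric edges, ``effect_intramodule`` strengthens
    intrahemispheric ones.
    """

    n_controls: int = 51
    n_patients: int = 60
    atlas: str = "schaefer100+sub"
    geometry_seed: int = 101
    clinical_seed: int = 202
    effect_seed: int = 303
    density: float = 0.4            # fraction of nonzero off-diagonal edges
    distance_decay: float = 0.025   # 1/mm decay of counts with distance
    count_scale: float = 500.0      # streamline counts at zero distance
    count_noise_sd: float = 0.1     # log-normal sigma of multiplicative count noise
    effect_interhemispheric: float = 0.5
    effect_intramodule: float = 0.2
    preserve_total_streamlines: bool = True

    def __post_init__(self):
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.effect_interhemispheric < 0 or self.effect_intramodule < 0:
            raise ValueError("effect sizes must be nonnegative")

    @property
    def parcellation(self) -> Parcellation:
        return synthetic_parcellation(self.atlas)


def generate_parcellation_geometry(parcellation: Parcellation, seed: int) -> np.ndarray:
    """Mirror-symmetric 3D region centroids in mm; shape (N, 3).

    Left/right homotopic partners are exact mirror images in x; cortical
    centroids sit 15-70 mm lateral of the midline, subcortical ones 5-25 mm.
    """
    hemi = parcellation.hemisphere_array()
    if len(set(hemi)) < 2:
        raise ValueError("geometry generation needs both hemispheres")
    rng = np.random.default_rng(seed)
    n = parcellation.n_regions
    centroids = np.zeros((n, 3))
    subc = np.asarray(parcellation.is_subcortical)
    left = np.where(hemi == "L")[0]
    for i in left:
        lo, hi = (5.0, 25.0) if subc[i] else (15.0, 70.0)
        x = rng.uniform(lo, hi)
        y = rng.uniform(-100.0, 70.0)
        z = rng.uniform(-40.0, 80.0)
        centroids[i] = (-x, y, z)
    # homotopic partner = same position in the opposite-hemisphere sequence
    right = np.where(hemi == "R")[0]
    subc_order = lambda idx: sorted(idx, key=lambda j: (subc[j], j))
    for li, ri in zip(subc_order(left), subc_order(right)):
        centroids[ri] = centroids[li] * np.array([-1.0, 1.0, 1.0])
    return centroids


def _homotopic_pairs(parcellation: Parcellation) -> list[tuple[int, int]]:
    hemi = parcellation.hemisphere_array()
    subc = np.asarray(parcellation.is_subcortical)
    left = [i for i in range(len(hemi)) if hemi[i] == "L"]
    right = [i for i in range(len(hemi)) if hemi[i] == "R"]
    key = lambda idx: sorted(idx, key=lambda j: (subc[j], j))
    return list(zip(key(left), key(right)))


def _edge_support(spec: CohortSpec, parcellation: Parcellation, centroids: np.ndarray):
    """Deterministic cohort-level edge support: the top-`density` fraction of
    edges by the distance profile, with homotopic edges always included."""
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    profile = np.exp(-spec.distance_decay * d)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = profile[iu]
    k = max(1, int(round(spec.density * len(vals))))
    thresh = np.sort(vals)[::-1][k - 1]
    support = np.zeros((n, n), dtype=bool)
    support[iu] = vals >= thresh
    for li, ri in _homotopic_pairs(parcellation):
        support[min(li, ri), max(li, ri)] = True
    support = support | support.T
    return d, profile, support


def generate_subject_sc(
    spec: CohortSpec,
    centroids: np.ndarray,
    seed: int,
    subject_id: str = "unknown",
    severity: float = 0.0,
) -> StructuralConnectome:
    """Draw one subject's structural connectome.

    ``severity`` is the cohort-normalised severity in [0, 1] (0 for healthy
    controls): interhemispheric counts are multiplied by
    ``1 - effect_interhemispheric * severity`` and intrahemispheric counts by
    ``1 + effect_intramodule * severity``; with
    ``preserve_total_streamlines`` the matrix is then rescaled to the
    pre-effect streamline total (counts are a partition of the fixed number
    of seeded streamlines) before integer rounding.  A severity-0 patient is
    identical to the no-effect draw under the same seed.
    """
    parc = spec.parcellation
    d, profile, support = _edge_support(spec, parc, centroids)
    rng = np.random.default_rng(seed)
    n = parc.n_regions
    iu = np.triu_indices(n, k=1)

    noise = np.exp(rng.normal(0.0, spec.count_noise_sd, size=len(iu[0])))
    base = np.zeros((n, n))
    base[iu] = spec.count_scale * profile[iu] * noise
    base = base + base.T
    base[~support] = 0.0

    hemi = parc.hemisphere_array()
    inter = hemi[:, None] != hemi[None, :]
    factor = np.where(
        inter,
        1.0 - spec.effect_interhemispheric * severity,
        1.0 + spec.effect_intramodule * severity,
    )
    effected = np.clip(base * factor, 0.0, None)
    if spec.preserve_total_streamlines and effected.sum() > 0:
        # tractography seeds a fixed streamline total; the effect redistributes
        # mass rather than destroying it
        effected *= base.sum() / effected.sum()
    counts = np.rint(effected)
    counts[support & (counts < 1)] = 1.0  # keep the cohort edge support intact

    jitter = 1.0 + rng.uniform(0.0, 0.1, size=len(iu[0]))
    lengths = np.zeros((n, n))
    lengths[iu] = d[iu] * jitter
    lengths = lengths + lengths.T
    lengths[counts == 0] = 0.0
    return StructuralConnectome(counts, lengths, parc, subject_id)


def generate_clinical_table(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Synthetic clinical/demographic table.

    Patients: onset age ~ N(53.22, 9.30^2) truncated at 30 y, duration ~
    N(8.65, 5.21^2) truncated at 0.5 y, age = onset + duration; UPDRS III On
    log-normal around median 17.5; Off = On + medication gap with a planted
    positive slope in duration.  Controls: age ~ N(55.02, 9.78^2), no motor
    scores.
    """
    if spec.n_patients < 3:
        raise ValueError("need at least 3 patients for the clinical correlation structure")
    rng = np.random.default_rng(spec.clinical_seed if seed is None else seed)
    rows = []
    for i in range(spec.n_controls):
        age = _trunc_normal(rng, HC_AGE_MEAN, HC_AGE_SD, low=35.0)
        rows.append(
            dict(subject_id=f"hc{i:03d}", group="HC", age=round(age, 1),
                 onset_age=np.nan, duration=np.nan, updrs3_on=np.nan, updrs3_off=np.nan)
        )
    for i in range(spec.n_patients):
        onset = round(_trunc_normal(rng, ONSET_MEAN, ONSET_SD, low=30.0), 1)
        duration = round(_trunc_normal(rng, DURATION_MEAN, DURATION_SD, low=0.5), 1)
        on = float(np.clip(np.rint(np.exp(rng.normal(UPDRS_ON_LOG_MEDIAN, UPDRS_ON_LOG_SD))), 1, 80))
        gap = max(0.0, GAP_INTERCEPT + GAP_SLOPE * duration + rng.normal(0.0, GAP_NOISE_SD))
        rows.append(
            dict(subject_id=f"pd{i:03d}", group="PD",
                 age=round(onset + duration, 1), onset_age=onset,
                 duration=duration, updrs3_on=on, updrs3_off=float(np.rint(on + gap)))
        )
    return pd.DataFrame(rows)


def _trunc_normal(rng, mean, sd, low):
    while True:
        x = rng.normal(mean, sd)
        if x >= low:
            return x


@dataclass
class Cohort:
    """A generated cohort: parcellation, centroids, clinical table, connectomes."""

    spec: CohortSpec
    centroids: np.ndarray
    clinical: pd.DataFrame
    connectomes: dict  # subject_id -> StructuralConnectome

    @property
    def parcellation(self) -> Parcellation:
        return self.spec.parcellation

    def severity(self, variable: str = "updrs3_on") -> pd.Series:
        pd_rows = self.clinical[self.clinical.group == "PD"]
        return pd_rows.set_index("subject_id")[variable]


def normalized_severity(clinical: pd.DataFrame, variable: str = "updrs3_on") -> pd.Series:
    """Min-max normalised severity over the patient group; 0 if degenerate."""
    pd_rows = clinical[clinical.group == "PD"]
    s = pd_rows.set_index("subject_id")[variable].astype(float)
    rng_ = s.max() - s.min()
    if rng_ <= 0:
        return s * 0.0
    return (s - s.min()) / rng_


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Full deterministic cohort draw from (spec, seeds)."""
    parc = spec.parcellation
    centroids = generate_parcellation_geometry(parc, spec.geometry_seed)
    clinical = generate_clinical_table(spec)
    sev = normalized_severity(clinical)
    subject_ss = np.random.SeedSequence(spec.effect_seed).spawn(len(clinical))
    connectomes = {}
    for (_, row), ss in zip(clinical.iterrows(), subject_ss):
        s = float(sev.get(row.subject_id, 0.0)) if row.group == "PD" else 0.0
        sc_seed = int(ss.generate_state(1)[0] % (2**31))
        connectomes[row.subject_id] = generate_subject_sc(
            spec, centroids, sc_seed, subject_id=row.subject_id, severity=s
        )
    return Cohort(spec, centroids, clinical, connectomes)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a cohort directory: per-subject matrices, region table, clinical
    table and a manifest recording every seed and spec value."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_region_table(cohort.parcellation, outdir / "regions.csv")
    cohort.clinical.to_csv(outdir / "cohort.csv", index=False)
    for sid, sc in cohort.connectomes.items():
        write_connectome(sc, outdir / f"{sid}_counts.csv", outdir / f"{sid}_lengths.csv")
    spec_dict = asdict(cohort.spec)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"spec": spec_dict}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_cohort(indir) -> Cohort:
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        spec = CohortSpec(**json.load(fh)["spec"])
    parc = read_region_table(indir / "regions.csv")
    clinical = pd.read_csv(indir / "cohort.csv")
    connectomes = {
        row.subject_id: read_connectome(
            indir / f"{row.subject_id}_counts.csv",
            indir / f"{row.subject_id}_lengths.csv",
            parc,
            row.subject_id,
        )
        for row in clinical.itertuples()
    }
    centroids = generate_parcellation_geometry(parc, spec.geometry_seed)
    return Cohort(spec, centroids, clinical, connectomes)
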