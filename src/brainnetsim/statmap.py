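"""Group-level statistical maps and behavioral network-based model fitting.

Per-subject landscapes are stacked across the cohort and, at every grid
point, reduced to a group statistic: the Rosenthal effect size
r = Z / sqrt(n) of the Wilcoxon rank-sum test between patients and controls
(positive for controls > patients), or Pearson's correlation across patients
between the simulated network property and a clinical score.  Two masks
restrict where optima may be selected:

* significance: |Z| above a fixed threshold (default 3.82, i.e. a
  multiple-test-corrected p < 0.05 on the full sweep grid);
* intersubject variability: grid points whose across-subject SD of the
  property exceeds the third quartile over all grid points.

The optimal parameter point is the masked arg-extremum of the statistic,
optionally restricted to a biologically plausible delay window.  The
``BehavioralFit`` model object packages this procedure: construct it from a
landscape stack plus the cohort table, call ``fit()`` and read the optimum,
maps and masks off the returned results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .landscape import ParameterGrid

__all__ = [
    "StatisticalMap",
    "MaskSet",
    "OptimalPoint",
    "rosenthal_effect_map",
    "correlation_map",
    "significance_mask",
    "variability_mask",
    "select_optimum",
    "edgewise_correlation_fdr",
    "bh_adjust",
    "BehavioralFit",
    "BehavioralFitResults",
]

#: fixed significance threshold for the full 64 x 43 sweep (corrected p < 0.05)
DEFAULT_Z_THRESHOLD = 3.82
#: biologically plausible global-delay window (s/m) for optimum selection
PLAUSIBLE_DELAYS = (0.06, 0.25)


class NoFitError(RuntimeError):
    """Raised when the masked parameter region is empty."""


@dataclass
class StatisticalMap:
    statistic_name: str  # "rosenthal_r" or "pearson_r"
    values: np.ndarray
    p_values: np.ndarray
    z_values: np.ndarray
    grid: ParameterGrid
    n: tuple | int


@dataclass
class MaskSet:
    significance: np.ndarray
    variability: np.ndarray
    plausible_delay: np.ndarray | None = None

    @property
    def intersection(self) -> np.ndarray:
        out = self.significance & self.variability
        if self.plausible_delay is not None:
            out = out & self.plausible_delay
        return out


@dataclass
class OptimalPoint:
    coupling: float
    delay: float
    coupling_index: int
    delay_index: int
    value: float
    mode: str


def _ranksum_exact_p(w: float, n1: int, n2: int) -> float:
    """Two-tailed p of the rank-sum statistic under the exact permutation
    null (no ties): full dynamic-programming enumeration of the rank-sum
    distribution of n1 ranks drawn from 1..n1+n2."""
    n = n1 + n2
    max_w = n1 * (2 * n - n1 + 1) // 2
    # counts[k][s] = number of k-subsets of ranks seen so far with sum s
    counts = np.zeros((n1 + 1, max_w + 1))
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            counts[k, rank:] += counts[k - 1, : max_w + 1 - rank]
    dist = counts[n1]
    total = dist.sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(w - mu)
    sums = np.arange(max_w + 1)
    p = dist[np.abs(sums - mu) >= dev - 1e-9].sum() / total
    return min(1.0, float(p))


def _ranksum_stats(x: np.ndarray, y: np.ndarray) -> tuple:
    """Wilcoxon rank-sum (Z, two-tailed p); positive Z when the first sample
    ranks higher.

    For groups of at most 10 without ties the p-value comes from the exact
    permutation null (full enumeration); otherwise from the normal
    approximation with tie correction and no continuity correction.  Z is
    the signed normal quantile of the two-tailed p in both branches, so the
    Rosenthal effect size r = Z / sqrt(n) shares one pathway.
    """
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if max(n1, n2) <= 10 and not has_ties:
        p = _ranksum_exact_p(w, n1, n2)
        z = stats.norm.isf(max(p / 2.0, 1e-300)) * np.sign(w - mu)
        return z, p
    tie = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    return z, 2.0 * stats.norm.sf(abs(z))


def rosenthal_effect_map(
    stack_hc: np.ndarray, stack_pd: np.ndarray, grid: ParameterGrid
) -> StatisticalMap:
    """Effect-size map r = Z / sqrt(n_HC + n_PD); positive for HC > PD."""
    if len(stack_hc) < 2 or len(stack_pd) < 2:
        raise ValueError("need at least 2 subjects per group")
    nc, nd = grid.shape
    z = np.full((nc, nd), np.nan)
    p = np.full((nc, nd), np.nan)
    for ci in range(nc):
        for di in range(nd):
            z[ci, di], p[ci, di] = _ranksum_stats(stack_hc[:, ci, di], stack_pd[:, ci, di])
    r = z / np.sqrt(len(stack_hc) + len(stack_pd))
    return StatisticalMap("rosenthal_r", r, p, z, grid, (len(stack_hc), len(stack_pd)))


def correlation_map(stack: np.ndarray, y: np.ndarray, grid: ParameterGrid) -> StatisticalMap:
    """Pearson correlation map across subjects, p from the t-distribution.

    ``z_values`` are signed normal quantiles of the two-tailed p so that the
    correlation and group-difference maps share one thresholding pathway.
    Zero-variance grid points become NaN (excluded from masks downstream).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects for a correlation map")
    if y.std() == 0:
        raise ValueError("clinical variable is constant: correlation undefined")
    if stack.shape[0] != n:
        raise ValueError("stack and clinical vector are misaligned")
    flat = stack.reshape(n, -1)
    sd = flat.std(axis=0)
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (flat - flat.mean(axis=0)).T @ yc / (n * sd * y.std())
    r[sd == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # signed normal quantile of the two-tailed p (clipped against p == 0)
    z = stats.norm.isf(np.maximum(p / 2.0, 1e-300)) * np.sign(r)
    shape = grid.shape
    return StatisticalMap(
        "pearson_r", r.reshape(shape), p.reshape(shape), z.reshape(shape), grid, n
    )


def significance_mask(
    smap: StatisticalMap, z_threshold: float = DEFAULT_Z_THRESHOLD, sign: str | None = None
) -> np.ndarray:
    """|Z| > threshold; ``sign`` ("+" or "-") restricts to one direction."""
    z = smap.z_values
    with np.errstate(invalid="ignore"):
        mask = np.abs(z) > z_threshold
    mask &= np.isfinite(z)
    if sign == "+":
        mask &= z > 0
    elif sign == "-":
        mask &= z < 0
    elif sign is not None:
        raise ValueError("sign must be '+', '-' or None")
    return mask


def variability_mask(stack: np.ndarray) -> np.ndarray:
    """Across-subject SD strictly above the 75th percentile of all grid-point SDs."""
    if len(stack) < 2:
        raise ValueError("need at least 2 subjects")
    sd = stack.std(axis=0, ddof=0)
    return sd > np.percentile(sd, 75)


def delay_window_mask(grid: ParameterGrid, window: tuple) -> np.ndarray:
    lo, hi = window
    d = np.asarray(grid.delays)
    col = (d >= lo) & (d <= hi)
    return np.broadcast_to(col, grid.shape).copy()


def select_optimum(
    smap: StatisticalMap,
    mask: np.ndarray,
    mode: str = "max",
    delay_window: tuple | None = None,
) -> OptimalPoint:
    """Masked arg-extremum of the statistic.

    Ties are broken by the first point in ascending (delay, coupling) scan
    order.  Raises ``NoFitError`` when the masked region is empty.
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    mask = mask & np.isfinite(smap.values)
    if delay_window is not None:
        mask = mask & delay_window_mask(smap.grid, delay_window)
    if not mask.any():
        raise NoFitError("no grid point satisfies all masks: nothing to fit")
    best = None
    nc, nd = smap.grid.shape
    for di in range(nd):
        for ci in range(nc):
            if not mask[ci, di]:
                continue
            v = smap.values[ci, di]
            if best is None or (v > best[0] if mode == "max" else v < best[0]):
                best = (v, ci, di)
    v, ci, di = best
    return OptimalPoint(
        float(smap.grid.couplings[ci]), float(smap.grid.delays[di]), ci, di, float(v), mode
    )


def bh_adjust(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    rej, p_adj, _, _ = multipletests(np.asarray(p_values, dtype=float), alpha=alpha, method="fdr_bh")
    return rej, p_adj


def edgewise_correlation_fdr(
    fc_stack: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Edge-wise Pearson correlation with Benjamini-Hochberg FDR control.

    ``fc_stack`` is (n_subjects, N, N); edges are the lower-triangle pairs.
    Degenerate (zero-variance) edges are excluded with a warning, reducing
    the number of tests m.  Returns a tidy frame with columns
    region_i, region_j, r, p, p_corrected, significant.
    """
    y = np.asarray(y, dtype=float)
    n_subj, n_reg, _ = fc_stack.shape
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    il, jl = np.tril_indices(n_reg, k=-1)
    edges = fc_stack[:, il, jl]
    sd = edges.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant edge series from FDR family")
    r = np.full(len(il), np.nan)
    p = np.full(len(il), np.nan)
    for k in np.where(keep)[0]:
        r[k], p[k] = stats.pearsonr(edges[:, k], y)
    p_corr = np.full(len(il), np.nan)
    sig = np.zeros(len(il), dtype=bool)
    if keep.any():
        rej, p_adj = bh_adjust(p[keep], alpha)
        p_corr[keep] = p_adj
        sig[keep] = rej
    return pd.DataFrame(
        {"region_i": il, "region_j": jl, "r": r, "p": p, "p_corrected": p_corr, "significant": sig}
    )


# ---------------------------------------------------------------------------
# model-style interface

class BehavioralFit:
    """Behavioral network-based model fitting on one landscape stack.

    Parameters
    ----------
    stack : ndarray (n_subjects, n_couplings, n_delays)
        Per-subject landscapes of one network property, aligned row-by-row
        with ``clinical``.
    grid : ParameterGrid
    clinical : DataFrame
        Cohort table with at least ``subject_id`` and ``group`` columns.
    target : str
        ``"group"`` for the patient/control effect-size map, otherwise a
        clinical column (e.g. ``"updrs3_on"``, ``"duration"``) correlated
        across patients.
    property_name : str, optional label carried into summaries.
    """

    def __init__(self, stack, grid, clinical, target="group", property_name="property"):
        stack = np.asarray(stack, dtype=float)
        if stack.shape[0] != len(clinical):
            raise ValueError("stack and clinical table are misaligned")
        if stack.shape[1:] != grid.shape:
            raise ValueError("stack shape does not match grid")
        self.grid = grid
        self.clinical = clinical.reset_index(drop=True)
        self.target = target
        self.property_name = property_name
        if target == "group":
            groups = self.clinical.group.to_numpy()
            self.stack_hc = stack[groups == "HC"]
            self.stack_pd = stack[groups == "PD"]
            self.stack = stack
        else:
            is_pd = (self.clinical.group == "PD").to_numpy()
            y = self.clinical[target].to_numpy(dtype=float)
            sel = is_pd & np.isfinite(y)
            if sel.sum() < 3:
                raise ValueError(f"need at least 3 patients with finite {target!r}")
            self.stack = stack[sel]
            self.y = y[sel]
            self.subject_ids = list(self.clinical.subject_id[sel])

    def fit(
        self,
        mode: str = "max",
        sign: str | None = None,
        z_threshold: float = DEFAULT_Z_THRESHOLD,
        delay_window: tuple | None = None,
    ) -> "BehavioralFitResults":
        if self.target == "group":
            smap = rosenthal_effect_map(self.stack_hc, self.stack_pd, self.grid)
        else:
            smap = correlation_map(self.stack, self.y, self.grid)
        masks = MaskSet(
            significance=significance_mask(smap, z_threshold, sign),
            variability=variability_mask(self.stack),
            plausible_delay=(
                delay_window_mask(self.grid, delay_window) if delay_window else None
            ),
        )
        optimum = select_optimum(smap, masks.intersection, mode=mode)
        return BehavioralFitResults(self, smap, masks, optimum, z_threshold)


@dataclass
class BehavioralFitResults:
    """Fit output: statistic map, masks, the optimal parameter point."""

    model: BehavioralFit
    map: StatisticalMap
    masks: MaskSet
    optimum: OptimalPoint
    z_threshold: float

    def values_at_optimum(self) -> np.ndarray:
        """Per-subject property values at the optimal grid point (fitting sample)."""
        return self.model.stack[:, self.optimum.coupling_index, self.optimum.delay_index]

    def summary(self) -> str:
        o = self.optimum
        m = self.map
        lines = [
            "Behavioral network-based model fitting",
            "=" * 46,
            f"property:        {self.model.property_name}",
            f"target:          {self.model.target}",
            f"statistic:       {m.statistic_name}  (n = {m.n})",
            f"z threshold:     {self.z_threshold}",
            f"masked points:   {int(self.masks.intersection.sum())} / {m.grid.n_points}",
            f"optimum:         C = {o.coupling:g}, tau = {o.delay:g} s/m ({o.mode})",
            f"statistic value: {o.value:+.4f}"
            f"  (p = {m.p_values[o.coupling_index, o.delay_index]:.3g})",
        ]
        return "\n".join(lines)
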