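"""Progression analyses linking two optimal model regimes to clinical course.

The behavioral fitting of simulated network efficiency against a clinical
score typically yields two optimal parameter points: a small-delay optimum
(negative correlation) and a large-delay optimum (positive correlation).
The analyses here quantify how a subject's simulated functional network
changes between those two regimes:

* edge-difference profiles — on the FC edges significantly (FDR-corrected)
  correlated with severity at the small-delay optimum, the per-subject
  difference FC(large delay) - FC(small delay) and its median, correlated
  with the clinical score across patients;
* efficiency contrasts — per-subject efficiency difference and ratio
  between the two optima, with normality/one-sample t tests for controls
  and Pearson/Spearman correlations against severity or duration for
  patients;
* the moving median (and IQR) of disease duration along patients ordered by
  their efficiency ratio, plus a five-interval binning of the ratio;
* stratified k-fold cross-validation of the whole fitting procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import ParameterGrid
from .statmap import (
    BehavioralFit,
    MaskSet,
    NoFitError,
    correlation_map,
    select_optimum,
    significance_mask,
    variability_mask,
)

__all__ = [
    "edge_difference_profiles",
    "efficiency_contrasts",
    "moving_median_duration",
    "stratified_cv_fit",
]

RATIO_BINS = ((0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0), (1.0, 1.25))


def edge_difference_profiles(
    fc_large: np.ndarray,
    fc_small: np.ndarray,
    selected_edges,
    y: np.ndarray,
    subject_ids=None,
):
    """Per-subject FC differences on selected edges and their medians.

    ``fc_large`` / ``fc_small`` are (n_subjects, N, N) FC stacks at the
    large- and small-delay optima; ``selected_edges`` is a sequence of
    (i, j) region pairs (the FDR-significant small-delay edges).  Returns a
    per-subject DataFrame and the Pearson (r, p) of the medians against the
    clinical score ``y`` — (nan, nan) when the medians are constant, which
    is reported rather than an error.
    """
    selected_edges = list(selected_edges)
    if not selected_edges:
        raise ValueError(
            "empty edge set: run the edge-wise FDR step first to select edges"
        )
    if fc_large.shape != fc_small.shape:
        raise ValueError("FC stacks at the two optima are misaligned")
    ii = np.array([e[0] for e in selected_edges])
    jj = np.array([e[1] for e in selected_edges])
    diffs = fc_large[:, ii, jj] - fc_small[:, ii, jj]
    medians = np.median(diffs, axis=1)
    y = np.asarray(y, dtype=float)
    if np.std(medians) == 0 or np.std(y) == 0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(medians, y)
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(len(medians))]
    table = pd.DataFrame(
        {"subject_id": subject_ids, "median_difference": medians, "clinical": y}
    )
    return table, diffs, (r, p)


def _normality_pvalue(x: np.ndarray) -> float:
    """Kolmogorov-Smirnov test of the standardised sample against N(0, 1)."""
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest((x - x.mean()) / sd, "norm").pvalue)


def efficiency_contrasts(
    stack: np.ndarray,
    point_small,
    point_large,
    clinical: pd.DataFrame,
    severity: str = "updrs3_on",
) -> dict:
    """Per-subject efficiency at the two optima plus group-level tests.

    ``stack`` is the efficiency landscape stack aligned with ``clinical``;
    ``point_small`` / ``point_large`` are (coupling_index, delay_index)
    pairs.  Controls: KS normality and one-sample two-tailed t test of the
    differences against zero (an exact-equality fast path reports p = 0 for
    a zero-variance nonzero sample).  Patients: Pearson correlations of
    difference and ratio with the severity column, plus Spearman for the
    ratio.  Subjects with zero small-delay efficiency have an undefined
    ratio and are excluded from ratio statistics with a warning.
    """
    (ci_s, di_s), (ci_l, di_l) = point_small, point_large
    e_small = stack[:, ci_s, di_s]
    e_large = stack[:, ci_l, di_l]
    diff = e_large - e_small
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(e_small > 0, e_large / np.where(e_small > 0, e_small, 1.0), np.nan)
    if np.any(e_small <= 0):
        warnings.warn("zero small-delay efficiency: ratio undefined for some subjects")
    table = clinical.reset_index(drop=True).copy()
    table["e_small"] = e_small
    table["e_large"] = e_large
    table["difference"] = diff
    table["ratio"] = ratio

    out = {"table": table}
    hc = table[table.group == "HC"]
    if len(hc) >= 3:
        d = hc.difference.to_numpy()
        if np.ptp(d) == 0:
            t_p = 0.0 if d[0] != 0 else 1.0  # exact-equality fast path
            t_stat = np.inf if d[0] != 0 else 0.0
        else:
            t_stat, t_p = stats.ttest_1samp(d, 0.0)
        out["hc_tests"] = {
            "ks_normality_p": _normality_pvalue(d),
            "t_stat": float(t_stat),
            "t_p": float(t_p),
            "mean_difference": float(d.mean()),
        }
    pdrows = table[(table.group == "PD") & np.isfinite(table[severity])]
    if len(pdrows) >= 3:
        sev = pdrows[severity].to_numpy(dtype=float)
        res = {}
        res["diff_pearson"] = tuple(map(float, stats.pearsonr(pdrows.difference, sev)))
        ok = np.isfinite(pdrows.ratio.to_numpy())
        if ok.sum() >= 3:
            ratios = pdrows.ratio.to_numpy()[ok]
            res["ratio_pearson"] = tuple(map(float, stats.pearsonr(ratios, sev[ok])))
            res["ratio_spearman"] = tuple(map(float, stats.spearmanr(ratios, sev[ok])))
        out["pd_tests"] = res
    return out


def moving_median_duration(
    ratios: np.ndarray, durations: np.ndarray, window: int = 15
) -> dict:
    """Moving median and IQR of duration along patients sorted by ratio.

    ``window`` must be odd and at most the number of patients (a window of 1
    reproduces the sorted durations).  Also returns the five-interval
    summary of the ratio over [0, 1.25].
    """
    ratios = np.asarray(ratios, dtype=float)
    durations = np.asarray(durations, dtype=float)
    n = len(ratios)
    if window > n:
        raise ValueError("window exceeds the number of patients")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and at least 1")
    order = np.argsort(ratios, kind="stable")
    r_sorted = ratios[order]
    d_sorted = durations[order]
    med, iqr = [], []
    for i in range(n - window + 1):
        w = d_sorted[i : i + window]
        med.append(np.median(w))
        q1, q3 = np.percentile(w, [25, 75])
        iqr.append(q3 - q1)
    bins = []
    for k, (lo, hi) in enumerate(RATIO_BINS):
        last = k == len(RATIO_BINS) - 1
        sel = (r_sorted >= lo) & ((r_sorted <= hi) if last else (r_sorted < hi))
        entry = {"lo": lo, "hi": hi, "n": int(sel.sum())}
        if sel.any():
            q1, q3 = np.percentile(r_sorted[sel], [25, 75])
            entry.update(
                ratio_median=float(np.median(r_sorted[sel])),
                ratio_iqr=float(q3 - q1),
                duration_median=float(np.median(d_sorted[sel])),
            )
        bins.append(entry)
    return {
        "ratio_sorted": r_sorted,
        "duration_sorted": d_sorted,
        "moving_median": np.array(med),
        "moving_iqr": np.array(iqr),
        "bins": pd.DataFrame(bins),
    }


def _tertile_labels(y: np.ndarray) -> np.ndarray:
    """Rank-based tertiles (0, 1, 2) with sizes differing by at most one."""
    n = len(y)
    order = np.argsort(y, kind="stable")
    labels = np.empty(n, dtype=int)
    bounds = [round(n / 3), round(2 * n / 3)]
    labels[order[: bounds[0]]] = 0
    labels[order[bounds[0] : bounds[1]]] = 1
    labels[order[bounds[1] :]] = 2
    return labels


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list:
    """Shuffled k-folds balanced over tertiles of the target score.

    Each fold's tertile composition differs from the global proportions by
    at most one subject per tertile.  Falls back to plain shuffling with a
    warning when ties collapse the tertiles.
    """
    n = len(y)
    labels = _tertile_labels(y)
    if len(np.unique(y)) < 3:
        warnings.warn("target ties collapse tertiles; falling back to plain shuffling")
        perm = rng.permutation(n)
        return [sorted(perm[i::k].tolist()) for i in range(k)]
    folds: list = [[] for _ in range(k)]
    counter = 0
    for tert in range(3):
        members = np.where(labels == tert)[0]
        members = members[rng.permutation(len(members))]
        for m in members:
            folds[counter % k].append(int(m))
            counter += 1
    return [sorted(f) for f in folds]


def stratified_cv_fit(
    stack_pd: np.ndarray,
    y: np.ndarray,
    grid: ParameterGrid,
    k: int = 3,
    iterations: int = 200,
    seed: int = 0,
    mode: str = "max",
    sign: str | None = None,
    z_threshold: float = 3.82,
    delay_window: tuple | None = None,
    reuse_masks: bool = False,
) -> pd.DataFrame:
    """Stratified k-fold cross-validation of the behavioral model fitting.

    Per iteration the patients are stratified into ``k`` folds balanced over
    target tertiles; each fold in turn is held out, the full fitting
    (correlation map, significance and variability masks, optimum selection)
    runs on the training patients, and the Pearson correlation between the
    held-out patients' property values at the training optimum and their
    scores is recorded.  ``reuse_masks=True`` estimates the masks once on
    the full patient sample instead of per training set.

    Returns a tidy frame: iteration, fold, coupling/delay (indices and
    values), train_r, test_r; folds where no grid point survives the masks
    appear with NaNs.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < 3 * k:
        raise ValueError("need at least 3k patients for stratified k-fold CV")
    rng = np.random.default_rng(seed)
    cohort_masks = None
    if reuse_masks:
        smap_all = correlation_map(stack_pd, y, grid)
        cohort_masks = MaskSet(
            significance=significance_mask(smap_all, z_threshold, sign),
            variability=variability_mask(stack_pd),
        )
    rows = []
    for it in range(iterations):
        folds = stratified_folds(y, k, rng)
        for fi, test_idx in enumerate(folds):
            train_idx = sorted(set(range(n)) - set(test_idx))
            row = {"iteration": it, "fold": fi}
            try:
                smap = correlation_map(stack_pd[train_idx], y[train_idx], grid)
                if reuse_masks:
                    mask = cohort_masks.intersection
                else:
                    mask = significance_mask(smap, z_threshold, sign) & variability_mask(
                        stack_pd[train_idx]
                    )
                opt = select_optimum(smap, mask, mode=mode, delay_window=delay_window)
                test_vals = stack_pd[test_idx, opt.coupling_index, opt.delay_index]
                yt = y[test_idx]
                if np.std(test_vals) == 0 or np.std(yt) == 0:
                    test_r = np.nan
                else:
                    test_r = stats.pearsonr(test_vals, yt)[0]
                row.update(
                    coupling_index=opt.coupling_index,
                    delay_index=opt.delay_index,
                    coupling=opt.coupling,
                    delay=opt.delay,
                    train_r=opt.value,
                    test_r=test_r,
                )
            except NoFitError:
                row.update(
                    coupling_index=np.nan, delay_index=np.nan, coupling=np.nan,
                    delay=np.nan, train_r=np.nan, test_r=np.nan,
                )
            rows.append(row)
    return pd.DataFrame(rows)
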