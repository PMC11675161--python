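"""Structural connectomes, parcellations and model coupling matrices.

A structural connectome (SC) holds, for one subject, the region-by-region
matrix of streamline counts ``w_nm`` and the matrix of mean streamline path
lengths ``L_nm`` (millimetres) obtained from whole-brain tractography.  Two
derived objects feed the rest of the pipeline:

* the model coupling matrix ``C_nm = w_nm / <W>``, where ``<W>`` is the mean
  streamline count of the connectome — the network backbone of the
  whole-brain model; inter-regional delays are ``tau_nm = tau * L_nm`` with
  the global delay ``tau`` in s/m;
* a max-normalised weight matrix (counts divided by the largest off-diagonal
  count) used for graph-theoretical properties of the empirical SC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "StructuralConnectome",
    "CouplingMatrix",
    "normalize_coupling",
    "compute_delay_matrix",
    "normalize_sc_for_metrics",
    "read_connectome",
    "write_connectome",
    "read_region_table",
    "write_region_table",
]


class ConnectomeError(ValueError):
    """Raised for structurally invalid or degenerate connectomes."""


@dataclass(frozen=True)
class Parcellation:
    """Brain parcellation: ordered regions with hemisphere and tissue-class labels.

    Parameters
    ----------
    region_ids : tuple of str
        Unique ordered region identifiers; the order defines matrix row order.
    region_names : tuple of str
        Human-readable labels, same order.
    hemisphere : tuple of str
        ``"L"`` or ``"R"`` per region.
    is_subcortical : tuple of bool
        True for subcortical regions (thalamus, caudate, putamen, pallidum,
        hippocampus, amygdala, accumbens per hemisphere in the shipped
        variants).
    atlas_name : str
        Free-form atlas label, e.g. ``"schaefer100+sub"``.
    """

    region_ids: tuple
    region_names: tuple
    hemisphere: tuple
    is_subcortical: tuple
    atlas_name: str = "custom"

    def __post_init__(self):
        n = len(self.region_ids)
        if n < 2:
            raise ConnectomeError("parcellation needs at least 2 regions")
        if len(set(self.region_ids)) != n:
            raise ConnectomeError("region ids must be unique")
        if not (len(self.region_names) == len(self.hemisphere) == len(self.is_subcortical) == n):
            raise ConnectomeError("parcellation field lengths disagree")
        bad = set(self.hemisphere) - {"L", "R"}
        if bad:
            raise ConnectomeError(f"hemisphere labels must be 'L' or 'R', got {bad}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_subcortical(self) -> int:
        return int(sum(self.is_subcortical))

    def hemisphere_array(self) -> np.ndarray:
        return np.asarray(self.hemisphere)


def _check_square(mat: np.ndarray, name: str, n: int | None = None) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ConnectomeError(f"{name} must be a square matrix, got shape {mat.shape}")
    if n is not None and mat.shape[0] != n:
        raise ConnectomeError(f"{name} has {mat.shape[0]} regions, parcellation has {n}")
    if not np.all(np.isfinite(mat)):
        raise ConnectomeError(f"{name} contains non-finite entries")
    if np.any(mat < 0):
        raise ConnectomeError(f"{name} contains negative entries")
    return mat


def _symmetrize(mat: np.ndarray, name: str) -> np.ndarray:
    # tractography connections are undirected; average any asymmetry away
    if not np.allclose(mat, mat.T, rtol=0, atol=1e-12):
        warnings.warn(f"{name} matrix is asymmetric; symmetrising by averaging", stacklevel=3)
        mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 0.0)
    return mat


@dataclass
class StructuralConnectome:
    """One subject's structural connectome: streamline counts and path lengths."""

    counts: np.ndarray
    lengths: np.ndarray
    parcellation: Parcellation
    subject_id: str = "unknown"

    def __post_init__(self):
        n = self.parcellation.n_regions
        counts = _symmetrize(_check_square(self.counts, "counts", n).copy(), "counts")
        lengths = _symmetrize(_check_square(self.lengths, "lengths", n).copy(), "lengths")
        if np.any((counts > 0) & (lengths <= 0)):
            raise ConnectomeError("every connected region pair needs a positive path length")
        self.counts = counts
        self.lengths = lengths

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions


@dataclass
class CouplingMatrix:
    """Dimensionless coupling strengths and (optional) inter-regional delays."""

    strengths: np.ndarray
    mean_streamlines: float
    delays_s: np.ndarray | None = None
    delay_steps: np.ndarray | None = None


def normalize_coupling(sc: StructuralConnectome, include_zeros: bool = True) -> CouplingMatrix:
    """Coupling strengths ``C_nm = w_nm / <W>``.

    ``<W>`` is the arithmetic mean streamline count over the N(N-1)
    off-diagonal cells; with ``include_zeros=False`` only cells with at least
    one streamline enter the mean.  The result is invariant under uniform
    rescaling of the counts.
    """
    w = sc.counts
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = w[off]
    if not np.any(vals > 0):
        raise ConnectomeError("all-zero connectome: coupling normalisation undefined")
    mean_w = float(vals.mean()) if include_zeros else float(vals[vals > 0].mean())
    strengths = w / mean_w
    np.fill_diagonal(strengths, 0.0)
    return CouplingMatrix(strengths=strengths, mean_streamlines=mean_w)


def compute_delay_matrix(
    sc: StructuralConnectome, global_delay: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-regional delays ``tau_nm = tau * L_nm`` in seconds and integer steps.

    Parameters
    ----------
    global_delay : float
        Global delay ``tau`` in s/m (path lengths are stored in mm).
    dt : float
        Integration step in seconds; step delays are rounded to the nearest
        integer so the per-edge discretisation error is at most ``dt / 2``.
    """
    if global_delay < 0:
        raise ValueError("global delay must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau_s = global_delay * (sc.lengths / 1000.0)  # mm -> m
    tau_s[sc.counts == 0] = 0.0
    np.fill_diagonal(tau_s, 0.0)
    steps = np.rint(tau_s / dt).astype(np.int64)
    return tau_s, steps


def normalize_sc_for_metrics(sc: StructuralConnectome) -> np.ndarray:
    """Counts divided by the maximal off-diagonal count; weights in [0, 1]."""
    w = sc.counts
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    max_w = w[off].max()
    if max_w <= 0:
        raise ConnectomeError("all-zero connectome: max-normalisation undefined")
    weights = w / max_w
    np.fill_diagonal(weights, 0.0)
    return weights


# ---------------------------------------------------------------------------
# delimited-text IO (counts / lengths matrices + region table)

def _read_matrix(path: Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")


def _is_whitespace(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return "," not in first


def read_connectome(
    counts_path, lengths_path, parcellation: Parcellation, subject_id: str = "unknown"
) -> StructuralConnectome:
    """Read counts/lengths square matrices (whitespace- or comma-delimited)."""
    counts = _read_matrix(Path(counts_path))
    lengths = _read_matrix(Path(lengths_path))
    return StructuralConnectome(counts, lengths, parcellation, subject_id)


def write_connectome(sc: StructuralConnectome, counts_path, lengths_path) -> None:
    np.savetxt(counts_path, sc.counts, fmt="%.6g", delimiter=",")
    np.savetxt(lengths_path, sc.lengths, fmt="%.6g", delimiter=",")


def read_region_table(path) -> Parcellation:
    """Region table columns: region_id, name, hemisphere, subcortical flag."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    return Parcellation(
        region_ids=tuple(df[cols["region_id"]].astype(str)),
        region_names=tuple(df[cols["name"]].astype(str)),
        hemisphere=tuple(df[cols["hemisphere"]].astype(str)),
        is_subcortical=tuple(df[cols["subcortical"]].astype(bool)),
        atlas_name=str(df[cols["atlas"]].iloc[0]) if "atlas" in cols else "custom",
    )


def write_region_table(parc: Parcellation, path) -> None:
    pd.DataFrame(
        {
            "region_id": parc.region_ids,
            "name": parc.region_names,
            "hemisphere": parc.hemisphere,
            "subcortical": parc.is_subcortical,
            "atlas": parc.atlas_name,
        }
    ).to_csv(path, index=False)
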