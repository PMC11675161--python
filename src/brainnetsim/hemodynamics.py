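"""Balloon-Windkessel hemodynamic forward model: PSP -> BOLD -> volumes.

The vasodilatory signal s, blood inflow f, venous volume v and
deoxyhemoglobin content q of each region follow

    ds/dt = u - kappa s - gamma (f - 1)
    df/dt = s
    tau_h dv/dt = f - v^(1/alpha)
    tau_h dq/dt = f (1 - (1 - rho)^(1/f)) / rho - v^(1/alpha) q / v

driven by the neural input u(t), with the BOLD output

    BOLD = V0 (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)),
    k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2.

The resting state (s, f, v, q) = (0, 1, 1, 1) is an exact fixed point of the
zero-input system.  Default constants are the widely used set
kappa = 0.65 /s, gamma = 0.41 /s, tau_h = 0.98 s, alpha = 0.32, rho = 0.34,
V0 = 0.02.  The default input policy z-scores each region's PSP over the
retained window and scales by 0.01, keeping the balloon in its sensitive
near-linear regime regardless of PSP units; integration shares the neural
stage's Euler clock (same dt, no interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from numba import njit

__all__ = [
    "HemodynamicParameters",
    "psp_to_bold",
    "resample_to_tr",
    "steady_state",
    "steady_state_bold",
]


class HemodynamicError(RuntimeError):
    pass


@dataclass
class HemodynamicParameters:
    kappa: float = 0.65   # 1/s signal decay
    gamma: float = 0.41   # 1/s flow-dependent elimination
    tau_h: float = 0.98   # s hemodynamic transit time
    alpha: float = 0.32   # Grubb stiffness exponent
    rho: float = 0.34     # resting oxygen extraction fraction
    V0: float = 0.02      # resting venous volume fraction
    tr: float = 2.21      # s output sampling interval
    input_scaling: str = "zscore"  # "zscore" (x input_scale) or "raw"
    input_scale: float = 0.01

    def __post_init__(self):
        if min(self.kappa, self.gamma, self.tau_h, self.tr) <= 0:
            raise ValueError("rate/time constants must be positive")
        if not (0 < self.alpha < 1 and 0 < self.rho < 1):
            raise ValueError("alpha and rho must lie in (0, 1)")
        if self.input_scaling not in ("zscore", "raw"):
            raise ValueError("input_scaling must be 'zscore' or 'raw'")

    def to_dict(self) -> dict:
        return asdict(self)


@njit(cache=True, fastmath=True)
def _balloon_kernel(u, dt, kappa, gamma, tau_h, alpha, rho, V0, bold):
    N, T = u.shape
    k1 = 7.0 * rho
    k2 = 2.0
    k3 = 2.0 * rho - 0.2
    inv_alpha = 1.0 / alpha
    for n in range(N):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            fv = v ** inv_alpha
            E = 1.0 - (1.0 - rho) ** (1.0 / f)
            ds = u[n, t] - kappa * s - gamma * (f - 1.0)
            df = s
            dv = (f - fv) / tau_h
            dq = (f * E / rho - fv * q / v) / tau_h
            s += dt * ds
            f += dt * df
            v += dt * dv
            q += dt * dq
            if f <= 0.0 or v <= 0.0 or q <= 0.0 or not (-1e12 < q < 1e12):
                return n, t
            bold[n, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return -1, -1


def psp_to_bold(psp: np.ndarray, dt: float, h: HemodynamicParameters | None = None) -> np.ndarray:
    """Integrate the balloon model region-wise; returns BOLD at the Euler rate."""
    h = h or HemodynamicParameters()
    psp = np.asarray(psp, dtype=float)
    if psp.ndim != 2:
        raise ValueError("psp must be regions x timepoints")
    if psp.shape[1] * dt < 10.0:
        raise ValueError("need at least 10 s of input signal")
    if not np.all(np.isfinite(psp)):
        raise ValueError("psp contains non-finite values")
    if h.input_scaling == "zscore":
        mu = psp.mean(axis=1, keepdims=True)
        sd = psp.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0  # constant region -> zero drive
        u = (psp - mu) / sd * h.input_scale
    else:
        u = psp
    bold = np.empty_like(u)
    bad_n, bad_t = _balloon_kernel(
        np.ascontiguousarray(u), dt, h.kappa, h.gamma, h.tau_h, h.alpha, h.rho, h.V0, bold
    )
    if bad_n >= 0:
        raise HemodynamicError(
            f"balloon state left its positivity domain at t = {bad_t * dt:.3f} s, region {bad_n}"
        )
    return bold


def resample_to_tr(bold: np.ndarray, dt: float, tr: float) -> np.ndarray:
    """Sample volumes at times k*tr (nearest grid point), k = 1..floor(T*dt/tr)."""
    if tr < dt:
        raise ValueError("tr must be at least dt")
    bold = np.asarray(bold)
    T = bold.shape[1]
    n_vol = int(np.floor(T * dt / tr + 1e-9))
    idx = np.rint(np.arange(1, n_vol + 1) * tr / dt).astype(int) - 1
    idx = np.minimum(idx, T - 1)
    return bold[:, idx]


def steady_state(u0: float, h: HemodynamicParameters | None = None) -> tuple:
    """Closed-form fixed point (s, f, v, q) under constant input u0."""
    h = h or HemodynamicParameters()
    f = 1.0 + u0 / h.gamma
    if f <= 0:
        raise ValueError("constant input drives flow nonpositive")
    v = f**h.alpha
    E = 1.0 - (1.0 - h.rho) ** (1.0 / f)
    q = f**h.alpha * E / h.rho
    return 0.0, f, v, q


def steady_state_bold(u0: float, h: HemodynamicParameters | None = None) -> float:
    h = h or HemodynamicParameters()
    _, f, v, q = steady_state(u0, h)
    k1, k2, k3 = 7.0 * h.rho, 2.0, 2.0 * h.rho - 0.2
    return h.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
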