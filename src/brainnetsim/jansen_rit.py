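"""Reduced Jansen-Rit neural mass model on a delay-coupled brain network.

Each brain region holds one excitatory and one inhibitory neural population.
The convolution form of the model turns presynaptic firing density into
postsynaptic potential (PSP) through a second-order kernel, giving per region
``n`` the state (y_e, y_i, z_e, z_i):

    dy_e/dt = z_e
    dy_i/dt = z_i
    dz_e/dt = P_e - 2 a R z_e - (a R)^2 y_e + eta_e
    dz_i/dt = P_i - 2 b R z_i - (b R)^2 y_i + eta_i

with inputs

    P_e[n] = A a R^2 ( sigma_e( (C/N) sum_{m != n} C_nm y_e[m](t - tau_nm) )
                       - C_ei y_i[n] )
    P_i[n] = B b R^2 sigma_i( C_ie y_e[n] )

and the sigmoid firing density sigma(v) = F / (1 + exp(r (v0 - v))).
Regions interact through the excitatory PSPs only, weighted by the
streamline-derived coupling matrix C_nm, scaled by the global coupling C and
lagged by tau_nm = tau * L_nm.  Integration is fixed-step stochastic Euler
with additive noise drawn i.i.d. uniform on [-eta_amplitude, eta_amplitude]
per region, population and step.

The stochastic term is added directly inside the Euler increment (the
convolution-model reading of eta as an input current); an optional
``sqrt_dt_noise`` switch rescales it by 1/sqrt(dt) to the Euler-Maruyama
convention instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
from numba import njit

from .connectome import StructuralConnectome, normalize_coupling, compute_delay_matrix

__all__ = ["ModelParameters", "sigmoid_firing", "simulate", "DivergenceError"]


class DivergenceError(RuntimeError):
    """The integration left the finite domain; reports time and region."""

    def __init__(self, t: float, region: int):
        super().__init__(f"simulation diverged at t = {t:.3f} s in region {region}")
        self.t = t
        self.region = region


#: Default noise half-range at dt = 2 ms.  The default operating regime is a
#: self-sustained ~10 Hz limit cycle (see DEFAULT_DRIVE); the noise is kept
#: weak so that it perturbs the oscillators' phases without drowning the
#: coupling: synchronisation then drifts on multi-second timescales, which is
#: what survives the hemodynamic low-pass and gives simulated BOLD FC its
#: parameter-dependent structure.  Much larger amplitudes bury the slow
#: synchronisation dynamics under white noise and flatten the landscapes.
DEFAULT_ETA = 354.0

#: Default background drive to the excitatory populations, the analogue of
#: the constant part of the Jansen-Rit background firing input p(t).
#: Together with C_ei = C_ie = 35 it places the local E-I loop above its
#: Hopf point: each uncoupled region sustains a ~10.5 Hz limit cycle of a
#: few tenths of a mV around y_e* ~ 0.2 mV, so that the delayed network
#: coupling acts on interacting oscillators (phase locking and metastable
#: synchronisation) rather than on quiescent noise-driven nodes.
DEFAULT_DRIVE = 1.4e4


@dataclass
class ModelParameters:
    """All constants of one simulation run.

    The local Jansen-Rit constants default to the canonical values that give
    the model its ~10 Hz intrinsic rhythm: kernel amplitudes A = 3.25 mV,
    B = 22 mV; reciprocal time constants a = 100 /s, b = 50 /s; sigmoid with
    half-maximum potential v0 = 6 mV, slope r = 0.56 /mV and maximal firing
    density F_e = F_i = 5 /s.  R scales the spectral power distribution of
    the PSPs; C and tau are the two global parameters swept during fitting.
    """

    A: float = 3.25       # mV, excitatory kernel amplitude
    B: float = 22.0       # mV, inhibitory kernel amplitude
    a: float = 100.0      # 1/s, reciprocal excitatory time constant
    b: float = 50.0       # 1/s, reciprocal inhibitory time constant
    R: float = 1.0        # dimensionless spectral-power scaler
    C: float = 0.0        # dimensionless global coupling
    tau: float = 0.0      # s/m global delay
    C_ei: float = 35.0    # inhibitory -> excitatory local balance
    C_ie: float = 35.0    # excitatory -> inhibitory local balance
    r: float = 0.56       # 1/mV sigmoid slope
    v0: float = 6.0       # mV sigmoid half-maximum potential
    F_e: float = 5.0      # 1/s maximal excitatory firing density
    F_i: float = 5.0      # 1/s maximal inhibitory firing density
    drive: float = DEFAULT_DRIVE  # background input to excitatory populations
    eta_amplitude: float = DEFAULT_ETA  # noise half-range
    dt: float = 0.002     # s integration step
    duration: float = 720.0
    transient: float = 57.0
    seed: int = 0
    sqrt_dt_noise: bool = False
    linearize_sigmoid: bool = False  # test hook: tangent at v0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("a, b, dt and duration must be positive")
        if not 0 <= self.transient < self.duration:
            raise ValueError("transient must lie in [0, duration)")
        if min(self.A, self.B, self.F_e, self.F_i, self.r) < 0:
            raise ValueError("A, B, F_e, F_i, r must be nonnegative")
        if min(self.C, self.tau, self.eta_amplitude) < 0 or self.R <= 0:
            raise ValueError("C, tau, eta_amplitude must be nonnegative and R positive")
        if self.drive < 0:
            raise ValueError("drive must be nonnegative")

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def sigmoid_firing(v, F: float, r: float, v0: float):
    """Sigmoid firing density F / (1 + exp(r (v0 - v))), overflow-safe."""
    x = r * (np.asarray(v, dtype=float) - v0)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = F / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = F * ex / (1.0 + ex)
    return out if out.ndim else float(out)


@njit(cache=True, fastmath=True)
def _sigma(v, F, r, v0, linear):
    if linear:
        return 0.5 * F + 0.25 * F * r * (v - v0)
    x = r * (v - v0)
    if x >= 0.0:
        e = np.exp(-x)
        return F / (1.0 + e)
    e = np.exp(x)
    return F * e / (1.0 + e)


@njit(cache=True, fastmath=True)
def _jr_kernel(
    indptr, indices, weights, dsteps,
    n_steps, dt,
    A, B, a, b, R, Cei, Cie, r, v0, Fe, Fi,
    drive, eta_e, eta_i, linear,
    y0, ye,
):
    """Euler-integrate the network; ``ye`` has shape (n_steps + 1, N).

    ``eta_e`` / ``eta_i`` are pre-drawn noise arrays of shape (n_steps, N)
    (empty arrays mean a noise-free run).  Returns (-1, -1) on success, else
    (step, region) of the first divergence.
    """
    N = ye.shape[1]
    yi = y0[1].copy()
    ze = y0[2].copy()
    zi = y0[3].copy()
    for n in range(N):
        ye[0, n] = y0[0, n]
    noisy = eta_e.shape[0] > 0
    aR = a * R
    bR = b * R
    aR2 = aR * aR
    bR2 = bR * bR
    AaR2 = A * a * R * R
    BbR2 = B * b * R * R
    net = np.zeros(N)
    for t in range(n_steps):
        for n in range(N):
            acc = 0.0
            for k in range(indptr[n], indptr[n + 1]):
                td = t - dsteps[k]
                if td >= 0:
                    acc += weights[k] * ye[td, indices[k]]
            net[n] = acc
        for n in range(N):
            ye_old = ye[t, n]
            Pe = AaR2 * (_sigma(net[n], Fe, r, v0, linear) - Cei * yi[n])
            Pi = BbR2 * _sigma(Cie * ye_old, Fi, r, v0, linear)
            ee = eta_e[t, n] if noisy else 0.0
            ei = eta_i[t, n] if noisy else 0.0
            ye_new = ye_old + dt * ze[n]
            if not (-1e12 < ye_new < 1e12):
                return t, n
            ye[t + 1, n] = ye_new
            yi_new = yi[n] + dt * zi[n]
            ze[n] = ze[n] + dt * (drive + Pe - 2.0 * aR * ze[n] - aR2 * ye_old + ee)
            zi[n] = zi[n] + dt * (Pi - 2.0 * bR * zi[n] - bR2 * yi[n] + ei)
            yi[n] = yi_new
    return -1, -1


def _coupling_csr(sc: StructuralConnectome, params: ModelParameters):
    """CSR arrays of the effective coupling (C/N) * C_nm with per-edge step delays."""
    cm = normalize_coupling(sc)
    n = sc.n_regions
    eff = (params.C / n) * cm.strengths
    _, dsteps = compute_delay_matrix(sc, params.tau, params.dt)
    indptr = np.zeros(n + 1, dtype=np.int64)
    idx_list, w_list, d_list = [], [], []
    for i in range(n):
        nz = np.nonzero(eff[i])[0]
        indptr[i + 1] = indptr[i] + len(nz)
        idx_list.append(nz)
        w_list.append(eff[i, nz])
        d_list.append(dsteps[i, nz])
    cat = lambda lst, dt_: (
        np.concatenate(lst).astype(dt_) if indptr[-1] else np.empty(0, dtype=dt_)
    )
    return indptr, cat(idx_list, np.int64), cat(w_list, np.float64), cat(d_list, np.int64)


def draw_noise(params: ModelParameters, n_regions: int, n_steps: int) -> np.ndarray:
    """Pre-draw the noise streams for one run: shape (2, n_steps, N).

    One PCG64 generator seeded with ``params.seed`` fills the excitatory
    block first, then the inhibitory one, each step-major in region order —
    the documented splitting scheme that makes every (region, population)
    stream reproducible from the single master seed.  Sharing one noise
    array across all grid points of a subject realises the "per-subject"
    seed policy of the parameter sweep.
    """
    rng = np.random.default_rng(params.seed)
    q = params.eta_amplitude
    eta = rng.uniform(-q, q, size=(2, n_steps, n_regions))
    if params.sqrt_dt_noise:
        eta /= np.sqrt(params.dt)
    return eta


def simulate(
    sc: StructuralConnectome,
    params: ModelParameters,
    initial_state: np.ndarray | None = None,
    return_transient: bool = False,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate the coupled model; returns excitatory PSPs (regions x time).

    Integrates ``duration/dt`` Euler steps from zero initial conditions
    (overridable via ``initial_state``, shape (4, N): y_e, y_i, z_e, z_i) and
    discards the first ``transient`` seconds.  ``noise`` may carry a
    pre-drawn ``draw_noise`` array to share streams across runs; otherwise
    the streams are drawn here.  Fully reproducible from (params, seed).
    """
    n = sc.n_regions
    n_steps = int(round(params.duration / params.dt))
    n_trans = int(round(params.transient / params.dt))
    if n_steps <= n_trans:
        raise ValueError("nothing retained: duration must exceed transient")
    indptr, indices, weights, dsteps = _coupling_csr(sc, params)
    y0 = np.zeros((4, n)) if initial_state is None else np.asarray(initial_state, dtype=float)
    if y0.shape != (4, n):
        raise ValueError(f"initial_state must have shape (4, {n})")
    if params.eta_amplitude > 0:
        eta = draw_noise(params, n, n_steps) if noise is None else noise
        eta_e, eta_i = np.ascontiguousarray(eta[0]), np.ascontiguousarray(eta[1])
    else:
        eta_e = eta_i = np.empty((0, n))
    ye = np.empty((n_steps + 1, n))
    bad_t, bad_n = _jr_kernel(
        indptr, indices, weights, dsteps,
        n_steps, params.dt,
        params.A, params.B, params.a, params.b, params.R,
        params.C_ei, params.C_ie, params.r, params.v0, params.F_e, params.F_i,
        params.drive, eta_e, eta_i, params.linearize_sigmoid,
        y0, ye,
    )
    if bad_t >= 0:
        raise DivergenceError(bad_t * params.dt, int(bad_n))
    start = 1 if return_transient else n_trans + 1
    return np.ascontiguousarray(ye[start:].T)
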