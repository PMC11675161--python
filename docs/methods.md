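# Methods

## Scope

`brainnetsim` implements a whole-brain modelling analysis for cross-sectional
Parkinson's disease (PD) cohorts: per-subject structural connectomes drive a
delay-coupled reduced Jansen-Rit network model; simulated BOLD functional
connectivity (FC) is summarised by two weighted graph properties (modularity
Q and global efficiency E) on a grid of the two global model parameters
(coupling C and delay tau); and group-level statistical maps over that grid
are used for *behavioral network-based model fitting* — selecting the model
parameters whose simulated network properties best separate patients from
controls or correlate with clinical scores — followed by two-regime
progression analyses and stratified cross-validation.  Because clinical MRI
data of this kind are not publicly shareable, the package ships a synthetic
cohort generator with a planted, tunable disease effect, so that the entire
pipeline is testable end to end.

## Neural mass model

Each region holds one excitatory and one inhibitory population with states
(y_e, y_i, z_e, z_i) (PSPs in mV and their rates):

    y_e' = z_e                      y_i' = z_i
    z_e' = drive + P_e - 2aR z_e - (aR)^2 y_e + eta_e
    z_i' =          P_i - 2bR z_i - (bR)^2 y_i + eta_i

    P_e = A a R^2 [ sigma_e( (C/N) sum_m C_nm y_e,m(t - tau_nm) ) - C_ei y_i ]
    P_i = B b R^2 sigma_i( C_ie y_e )
    sigma(v) = F / (1 + exp(r (v0 - v)))

Coupling weights come from streamline counts, `C_nm = w_nm / <W>` with `<W>`
the mean over all N(N-1) off-diagonal cells (zeros included; a
nonzero-cells-only variant is a flag), making `C_nm` invariant to uniform
count rescaling.  Delays are `tau_nm = tau * L_nm` with path lengths stored
in mm and converted to metres, so tau in s/m spans the printed biologically
plausible window (0.06-0.25 s/m).  Step delays round to the nearest Euler
step (discretisation error at most dt/2 per edge).  The inhibitory term
`C_ei y_i` is applied outside the sigmoid; the sigmoid acts on the delayed
network input alone.

Parameters (defaults):  A = 3.25 mV, B = 22 mV, a = 100 /s, b = 50 /s,
v0 = 6 mV, r = 0.56 /mV, F_e = F_i = 5 /s, R = 1 — the canonical constants
that give the model its ~10 Hz rhythm.  Two further local constants are this
package's own calibration, since a two-population reduction with unit local
gains and zero-mean input is dynamically silent (its fixed point sits ~6 mV
below the sigmoid half-maximum, where the loop gain is ~1e-3; nothing
propagates through the network and simulated FC carries no information):

* `drive = 1.4e4` (mV/s^2) — a constant background input to the excitatory
  populations, the analogue of the Jansen-Rit background firing input p(t);
* `C_ei = C_ie = 35` — local E-I gains placing the loop slightly above its
  Hopf point.

Together they give each uncoupled region a self-sustained ~10.5 Hz limit
cycle of a few tenths of a mV around y_e* ~ 0.2 mV, so that delayed coupling
acts on interacting oscillators (phase locking, delay-dependent sync) rather
than on quiescent nodes, and the network input sweeps through the sigmoid's
sensitive range within the C grid [0, 63].

Noise is i.i.d. uniform on [-eta, +eta] per region, population and step,
added directly inside the Euler increment (an optional switch rescales by
1/sqrt(dt) to the Euler-Maruyama convention).  The default half-range
eta = 354 at dt = 2 ms is deliberately weak: it perturbs oscillator phases
so that synchronisation drifts on multi-second timescales (the part of the
dynamics that survives the hemodynamic low-pass), without burying the
coupling under white noise.  We examined and abandoned a calibration that
targets a fixed PSP fluctuation SD (~5% of A, i.e. eta ~ 1.26e4): at that
amplitude the simulated BOLD FC is numerically indistinguishable from its
sampling floor at every grid point, and the parameter landscapes are flat.

Integration is fixed-step stochastic Euler from zero initial conditions
(the discarded transient absorbs initialisation), 2 ms steps, 720 s runs
with the first 57 s discarded (663 s retained) in the full profile.  Noise
streams derive from one master seed: a single PCG64 generator fills the
excitatory block then the inhibitory one, step-major in region order.
Divergence (a non-finite or exploding state) raises an error naming time
and region; it is never silently imputed.

## Hemodynamics

The Balloon-Windkessel model maps the excitatory PSP to BOLD with the
standard constant set kappa = 0.65 /s, gamma = 0.41 /s, tau_h = 0.98 s,
alpha = 0.32, rho = 0.34, V0 = 0.02 and output
BOLD = V0 (k1(1-q) + k2(1-q/v) + k3(1-v)), k1 = 7 rho, k2 = 2,
k3 = 2 rho - 0.2.  The default input policy z-scores each region's PSP over
the retained window and scales by 0.01, keeping the balloon in its
near-linear regime regardless of PSP units; a "raw" policy passes the input
through unchanged (used by the closed-form steady-state oracles).  The
balloon shares the neural Euler clock (no interpolation); BOLD volumes are
taken at t = k*TR (nearest grid point), TR = 2.21 s, floor rule — 663 s
yields exactly 300 volumes.

## Network properties

FC is the Pearson correlation matrix of the regional BOLD volumes; edges are
taken in absolute value and self-connections excluded before graph analysis.
Modularity is maximised weighted Newman Q via seeded multi-restart Louvain
(igraph multilevel; each restart permutes node order; default 20 restarts,
resolution 1).  Graphs of at most 8 nodes are solved exactly by partition
enumeration, because Louvain-type local moving provably misses the optimum
on some small graphs (we found an 8-node counterexample where 50 restarts of
both Louvain and Leiden fall 0.03 short).  Global efficiency uses edge
lengths 1/w (the connectivity-toolbox convention; -log w is a documented
alternative), all-pairs Dijkstra, and the mean of inverse distances with
1/inf = 0, so disconnected graphs are handled without error.  Empirical-SC
weights are counts divided by the maximal off-diagonal count.

## Parameter landscapes

The sweep evaluates the pipeline at every point of an inclusive, evenly
spaced grid — 64 couplings over [0, 63] times 43 delays over [0, 0.42] s/m
(2,752 runs per subject) in the full profile.  Failed points are recorded
as missing with a diagnostic; more than 10% missing aborts.  Sweeps
checkpoint per subject and resume without recomputation.  Three seed
policies are offered: `per-subject` (one noise realisation shared across a
subject's grid points, isolating parameter effects; the default),
`per-point` (independent streams), and `common` (one realisation shared by
all subjects — common random numbers, so that between-subject landscape
differences reflect connectome differences only).

The *desk profile* is the package's own scaled-down study: the 30-region
synthetic parcellation, an 8 x 6 grid over the same parameter ranges, 120 s
runs (20 s transient) at dt = 4 ms with eta scaled by 1/sqrt(2) (keeping
phase diffusion dt-consistent), 5 Louvain restarts, and the common-noise
policy.  Its significance threshold is |Z| > 3.28 (Bonferroni over 48 grid
points), the analogue of the full profile's fixed Z > 3.82 which encodes a
multiple-test-corrected p < 0.05 over the 2,752-point grid; full random
field theory resel estimation is deliberately not implemented, matching the
operative fixed-threshold rule.

## Statistical mapping and fitting

Group differences use the Wilcoxon rank-sum test with the Rosenthal effect
size r = Z / sqrt(n), positive for controls > patients.  For groups of at
most 10 without ties the p-value is exact (full enumeration of the rank-sum
null); otherwise the normal approximation with tie correction (no
continuity correction) is used.  Clinical correlations are Pearson r with
two-tailed p from the t distribution (n - 2 df).  In both cases Z is the
signed normal quantile of the two-tailed p, so both map types share one
thresholding pathway (a deliberate choice over Fisher's transform).
Masks: significance |Z| > threshold, optionally sign-restricted for
directional fits; intersubject variability SD strictly above the 75th
percentile of all grid-point SDs.  The optimum is the masked arg-extremum,
ties broken by the first point in ascending (delay, coupling) scan order;
an empty masked region raises a no-fit error rather than being silently
relaxed.  Edge-wise severity correlations over lower-triangle FC edges are
controlled by Benjamini-Hochberg FDR (step-up, default alpha 0.05);
zero-variance edges are excluded from the family with a warning.

`BehavioralFit` / `BehavioralFitResults` package the procedure in the
model/results idiom: the model object holds the aligned landscape stack,
cohort table and target; `fit()` returns the maps, masks, optimum and a
`summary()` table.

## Progression analyses

Between a small-delay and a large-delay optimum the package computes
per-subject FC differences on the FDR-significant small-delay edges (with
the median difference correlated against severity), per-subject efficiency
differences and ratios (controls: KS normality and one-sample t tests;
patients: Pearson for the difference and Pearson + Spearman for the ratio),
a moving median (default window 15, odd-forced) with IQR of disease
duration along patients sorted by efficiency ratio, and a five-interval
ratio binning over [0, 1.25].  Stratified k-fold cross-validation (default
3 folds, 200 iterations) stratifies patients over tertiles of the target
score — each fold's tertile composition deviates from the global
proportions by at most one subject — refits masks and optimum on every
training set (a reuse switch restores cohort-level masks), and records the
held-out Pearson correlation at the training optimum.

## Synthetic cohorts

Region centroids are mirror-symmetric between hemispheres (homotopic pairs
are exact mirror images); cortical centroids lie 15-70 mm lateral, the 14
subcortical regions (thalamus, caudate, putamen, pallidum, hippocampus,
amygdala, accumbens per side) 5-25 mm.  Streamline counts decay
exponentially with distance (rate 0.025 /mm, scale 500 at zero distance)
with log-normal edge noise (sigma 0.1) and are rounded to integers; the
cohort-level edge support keeps the top 40% of edges by the distance
profile plus all homotopic pairs.  Path lengths are centroid distances with
a positive jitter of up to 10%.  The clinical table reproduces the
dependency structure of a cross-sectional PD cohort: onset age ~
N(53.22, 9.30^2) truncated at 30 y, duration ~ N(8.65, 5.21^2) truncated at
0.5 y, age = onset + duration exactly; UPDRS III On log-normal around
median 17.5 (IQR 11-28); Off = On + a medication gap with slope 0.7
points/year in duration (planting the positive duration correlation of the
Off - On difference); control ages ~ N(55.02, 9.78^2).

The disease effect multiplies patients' interhemispheric counts by
(1 - 0.5 s) and intrahemispheric counts by (1 + 0.2 s), where s is the
patient's severity min-max normalised over the cohort; the matrix is then
rescaled to its pre-effect streamline total, because tractography seeds a
fixed number of streamlines (counts partition a constant total).  Effects
are planted in SC, not FC, because the model consumes SC.  The generator
makes no attempt to reproduce real tractography degree distributions,
heavy-tailed edge weights, or acquisition artefacts; passing tests
demonstrate pipeline correctness on data with the assumed statistical
structure, not performance on real MRI data.

## What the desk-scale validation does and does not show

The end-to-end planted-effect validation (12 + 12 subjects, desk profile)
demonstrates that every stage runs, is deterministic, and that the planted
effect is strongly present in the structural connectomes themselves
(severity-modularity correlation ~0.98 at the SC level).  Its transmission
into *simulated-FC graph metrics at corrected significance* is, however,
fundamentally power-limited at this scale, and the corresponding acceptance
check is expected to fail; we report the quantitative reasons rather than
loosening it:

* 120 s runs yield 45 BOLD volumes (~40 effective DOF given the
  hemodynamic bandwidth), an irreducible per-edge FC sampling floor of
  |r| ~ 0.15;
* in smooth (subcritical) dynamical regimes the full-severity effect moves
  the graph metrics by 0.001-0.01 — below that floor;
* in the oscillatory regime transmission is strong (up to ~8 per-subject
  noise SDs at the best grid points) but chaotic: responses to 2% SC
  perturbations are as large as the full-severity effect, so severity
  gradients across subjects scramble, and the transmitted group-difference
  sign varies across the grid;
* the rank-sum |Z| attainable at n = 12 + 12 is at most 4.16; observed
  maxima are ~2.7 against the desk threshold of 3.28, and severity
  correlations reach ~0.8 where ~0.85 would be needed.

This mirrors the power situation of the real analysis, which required 111
subjects and 663-s recordings at Z > 3.82.  The oracle-based checks
(closed-form dynamics, exact graph and statistics references) and the
byte-level reproducibility checks are exact and do pass.

## Numerical and engineering notes

* Integration kernels are numba-compiled; trajectories are bit-reproducible
  for a given (parameters, seed) on a given platform.
* Asymmetric connectome matrices are symmetrised by averaging with a
  warning; counts/lengths files are plain delimited text.
* The sigmoid is evaluated in an overflow-safe branch form; a
  `linearize_sigmoid` hook replaces it by its tangent at v0 for the
  linear-system oracle tests.
* Degenerate inputs fail loudly by design: all-zero connectomes, constant
  BOLD series, constant clinical vectors, empty masked regions and empty
  edge sets raise typed errors.
* Problem sizes in the shipped tests use the desk profile throughout; the
  full 114-region, 2,752-point, 720-s profile is exposed (`full_preset`)
  but intended for HPC-scale batch use via the sweep checkpointing.
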