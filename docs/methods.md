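# Methods

## Model and procedure

A transport coefficient is estimated as the Green–Kubo (GK) integral of a
microscopic current autocorrelation function (CAF). The current series
(length n_steps, time step Δt) is split into M non-overlapping, contiguous
intervals of N frames (trailing remainder discarded, so intervals are
independent on the scale of the correlation time); per-interval linear
correlations are computed by zero-padded FFT and averaged:

    C_k = (1/M) Σ_A c_k^(A),   c_k^(A) = [1/(N−k)] Σ_i J_{i+k} J_i .

The per-lag uncertainty is the standard error of the mean of the M(N−k)
lag-k products,

    u(C_k) = sqrt( ( ⟨J² J²⟩_k − C_k² ) / (M(N−k) − 1) ),

where ⟨J²J²⟩_k is the lag-k correlation of the squared series averaged over
intervals — one extra FFT, same O(N log N) cost. The running integral uses
the trapezoidal rule; its uncertainty propagates u(C_k) with lag–lag
covariances neglected, so u(I_k) is non-decreasing and grows as √k once
u(C_k) has flattened. The running coefficient γ_i is the inverse-variance
weighted average of I_k from origin i to the last computed lag, with the
scatter-based uncertainty

    u(γ_i) = sqrt( Σ_k w_k (γ_i − I_k)² / (n_i Σ_k w_k) ),  w_k = 1/u²(I_k),

where n_i is the number of tail points (this convention reproduces the
closed-form example I=[2,4], u=[1,2] → γ=2.4, u=√0.32). Diagonal tensor
components are combined pointwise by the same inverse-variance/scatter form
with a 1/(n_components−1) prefactor. The coefficient is read off the plateau
of γ_i over origins and converted to output units by the property prefactor
(κ: 1/(V k_B T) → S/m; η: V/(k_B T) per off-diagonal channel, the three
channels combined isotropically → mPa·s; D: unit conversion only → m²/s).
Internally everything is carried in MD units (e, amu, nm, ps, fs, bar, K);
conversions are centralized in `units.py` and round-trip to 1e−12.

### Assumptions

- The current is stationary; intervals are long against its correlation
  time (otherwise interval means are biased and u(C) is unreliable).
- The uncertainty recursion treats lag-k products and adjacent lags as
  uncorrelated. Both are violated when Δt ≪ τ: u(C_k) is then a *uniform
  underestimate* of the absolute error (by roughly √(2τ/Δt)). This is
  harmless where it matters — γ_i uses only relative weights, and u(γ_i),
  the isotropic combination and the replica average all re-estimate the
  scale from observed scatter — but it means |C_k|/u(C_k) must not be used
  as a significance test, and the package never does.
- Collective currents (electric current, pressure) give one sample per
  replica; single-particle currents pool intervals over molecules
  (M = n_molecules × n_intervals), which is why short runs suffice for
  diffusion.

## Replica combination

Replicas of the same protocol are exchangeable, so `average_replicas` is the
pointwise equal-weight mean with a scatter standard error (prefactor
1/(R(R−1))). Weighting replicas by their own scatter-estimated u(γ_i) was
evaluated and rejected: on a correlated running-integral tail the scatter
estimate itself fluctuates by large factors between statistically identical
replicas, and inverse-variance weights then occasionally collapse onto a
single replica, producing overconfident, badly biased averages. The
equal-weight SEM was verified to give honest coverage on synthetic ground
truth (Ornstein–Uhlenbeck currents, 30/30 seeds within 3σ).

## Plateau identification

Automatic mode scans candidate origins (at most `max_candidates = 512`,
uniformly subsampled) and accepts the earliest origin i for which at least
`min_fraction = 0.5` of the later origins j satisfy
|γ_j − γ_i| ≤ `agreement_sigma` (=1) × u(γ_j). Two findings from synthetic
validation shaped the final rule:

1. A purely statistical agreement test is fooled by the *approach region*:
   while the integral is still accumulating signal, γ_i is biased low but
   varies slowly, and far-tail origins with large u always "agree".
2. The reliable discriminator is physical: origins before the CAF has
   decayed cannot be plateau origins. Candidates therefore start at
   `plateau_gate` (=2) × the CAF decay time — the first lag where the
   lightly smoothed |C| falls below 5% of |C_0| (`decay_time`), computed per
   replica and medianed. The gate scales correctly with simulation length
   and leaves the agreement rule to handle genuine non-convergence.

If no origin qualifies, the estimate carries status `no_plateau` and a NaN
value; the CLI exits with code 2. An explicit window `(t_start, t_end)`
bypasses detection: the value at the earliest origin inside the window is
returned and the max–min spread across the window is reported as a
diagnostic. All thresholds are keyword arguments.

The decay-time gate is an envelope heuristic. For CAFs with weak
slow modes buried in noise (viscosity of cold, glassy liquids) it can gate
too early; the per-replica running-coefficient curves written by the CLI are
the intended check, and an explicit window is the fallback.

## Tunable parameters

| knob | default | units | notes |
|---|---|---|---|
| interval_length | user-set | ps | shorter → more intervals, better u(C); must exceed the plateau origin needed |
| max_lag | N/2 | lags | avoids the worst of the (N−k)^{-1/2} small-sample tail; full N−1 available |
| u_floor | 1e-150 | CAF units | floor on u before forming 1/u² weights (zero-u points get the maximum finite weight); weights are normalized by their maximum, so the floor never overflows |
| agreement_sigma, min_fraction | 1.0, 0.5 | — | plateau agreement rule |
| plateau_gate | 2.0 | × decay time | origin gate (auto mode) |
| stride | 1 | — | recording-stride decimation for robustness scans |

## Comparison estimators

- **Windowed average**: sliding mean of I over a window W (entry i averages
  I_i..I_{i+W/Δt}); the series shortens by W/Δt points. Used to demonstrate
  the variance/length trade-off the weighted estimator avoids.
- **Tail fits**: Σ A_i e^{−t/τ_i} (τ > 0 via log parametrization,
  Levenberg–Marquardt, amplitudes initialized from C(t_switch)/k and τ from
  a log-spaced span of the lag range) or a·exp(−t^α) (α > 0, tail integral
  by adaptive quadrature at 1e−10 relative). Candidate switch times default
  to 20 log-spaced sample times up to half the CAF; the fit region is
  t ≥ t_switch, R² is computed on that region only, and the best-R²
  candidate wins. Total = trapezoidal integral below the switch + analytic
  tail. Non-converged candidates are skipped with a log entry.
- **Einstein relations**: origin-averaged MSD via the FFT decomposition
  (S1 from prefix sums, S2 from the positional autocorrelation; lag 0 pinned
  to 0), OLS slope on an explicit, mandatory fit window. The OLS stderr is
  propagated but understates the error of a single collective MSD (lag
  points are strongly correlated); honest uncertainties come from scatter
  over particles, groups or replicas, which is how the tests use it.
- **Nernst–Einstein** κ_NE = e²/(V k_B T) Σ N_i z_i² D_i and **Yeh–Hummer**
  D + 2.8373 k_B T/(6πηL) as closed forms (2.8373 stored as the exact
  literal).

## Synthetic ground truth

The generators draw from NumPy's PCG64 (`default_rng`); a seed fixes the
full bitstream. The OU current uses the exact discretization
J_{n+1} = J_n e^{−Δt/τ} + σ√(1−e^{−2Δt/τ}) ξ, so the analytic CAF
σ²e^{−t/τ} (integral σ²τ) holds at any Δt — discretization bias is removed
from the validation, not just reduced. Multi-exponential CAFs are sums of
independent OU processes. Langevin particles use the exact OU velocity
update (VACF = (k_BT/m)e^{−γt}, D = k_BT/(mγ)); positions are the Euler
quadrature x_{n+1} = x_n + v_nΔt, whose diffusion bias is O((γΔt)²) — the
discrete trapezoidal VACF integral equals the same expression, so the GK and
Einstein routes share one discrete truth. The toy ionic system provides
multi-atom ions (+1/−1 over 3 and 2 atoms), Maxwell–Boltzmann velocities and
ballistic frames, making dM/dt = J exact for the dipole/current consistency
check.

What the generators do *not* emulate: oscillatory CAFs with negative lobes,
slow stretched relaxation, cross-correlations between components,
finite-size effects, or any genuine interatomic dynamics. Passing tests
therefore validate the estimator arithmetic and its statistical behaviour
under the Gaussian-current assumption, not force-field physics.

## Numerical choices

- FFT correlations zero-pad to `next_fast_len(N + max_lag)`; the linear
  (non-circular) result matches the direct double sum to ≤1e−10 relative.
  Intervals are processed in chunks of 128 to bound the transform workspace.
- The CAF variance uses the Bessel-corrected divisor M(N−k)−1; negative
  estimates from cancellation are clamped to zero, and second moments
  resolved only at machine precision (raw < 1e−12 × ⟨J²J²⟩) are snapped to
  zero so exactly constant intervals give u = 0 exactly.
- The running-coefficient scatter term is computed on mean-shifted
  integrals (γ is shift-equivariant) to limit cancellation; weights are
  max-normalized per channel before use.
- `decay_time` smooths C with a flat window of N_lags/200 before
  thresholding.
- The uncertainty "flat region" used by the validation suite is
  [2 × decay time, 0.2 N]: below the upper edge the (N−k) sample count is
  within 25% of N, keeping u(C_k) flat to ~12%, which is where the √k
  growth law for u(I_k) applies.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` use OU currents of 1–20 ns at
Δt = 1 fs for the scaling laws, 50 seeded runs of 10 × 1 ns replicas for
ground-truth recovery, 100 Langevin particles × 10⁵ steps for the
GK/Einstein comparison, and 5 × 4 ns replicas for the robustness scans —
sizes chosen so the whole validation completes in minutes on one CPU while
every statistical claim retains a comfortable margin.

## Known limitations

- The pressure-tensor calculator implements the kinetic + r⊗f virial form,
  valid for non-periodic or minimum-image-consistent force/position pairs;
  for periodic post-processing, prefer the pressure series recorded by the
  MD engine (the missing-forces error message says so).
- Lag–lag covariances of the CAF are neglected throughout (by
  construction of the method); u(I_k) is an independence approximation.
- The trajectory reader handles the package's native extended-XYZ-style
  text format plus a CSV topology sidecar; engine formats (TRR, LAMMPS
  dumps) are expected to be converted by adapters, not parsed here.
- Automatic plateau detection is a heuristic with exposed knobs, not a
  hypothesis test; non-convergence is reported, and the explicit-window
  mode is authoritative when the user knows the physics.
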