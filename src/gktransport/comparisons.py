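"""Comparison estimators: windowed averaging, tail fitting, Einstein
relations, Nernst-Einstein and Yeh-Hummer.

These are the conventional routes the uncertainty-weighted estimator is
benchmarked against:

- a sliding-window mean of the running integral (requires choosing the
  window length W);
- numeric integration of the CAF up to a switch time plus an analytic
  tail from a fitted model (a sum of exponentials, or a stretched
  exponential), with the switch time chosen to maximize R^2 of the fit;
- Einstein relations: the long-time MSD slope of the conjugate
  displacement (dipole moment for conductivity, COM positions for
  diffusion);
- the Nernst-Einstein conductivity from per-species diffusion
  coefficients, and the Yeh-Hummer finite-size correction for D in a
  periodic cubic box.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

from . import units
from .correlation import CAFResult
from .estimator import RunningIntegral, TransportEstimate

__all__ = [
    "TailFit",
    "MSDResult",
    "windowed_average",
    "fit_exponential_tail",
    "fit_stretched_tail",
    "msd",
    "einstein_estimate",
    "nernst_einstein",
    "yeh_hummer",
]

log = logging.getLogger(__name__)


@dataclass
class TailFit:
    """A fitted CAF tail model and the resulting total integral.

    ``total_integral`` = trapezoidal integral of the CAF on
    [0, t_switch] + closed-form (or quadrature) integral of the fitted
    model on [t_switch, inf).  Units: CAF units * ps.
    """

    model: str
    params: dict
    t_switch: float
    r_squared: float
    numeric_part: float
    tail_part: float
    candidates: list = field(default_factory=list)

    @property
    def total_integral(self) -> float:
        return self.numeric_part + self.tail_part


@dataclass
class MSDResult:
    """Mean squared displacement vs lag time (origin- and particle-averaged)."""

    times: np.ndarray  # ps
    msd: np.ndarray
    n_particles: int = 1

    def __post_init__(self):
        if np.any(self.msd < -1e-9):
            raise ValueError("MSD must be non-negative")


def windowed_average(ri: RunningIntegral, window: float) -> np.ndarray:
    """Sliding mean of the running integral over a window of length W.

    ``window`` in fs.  Entry i is the mean of the integral points
    i .. i + W/dt; the output is shorter than the input by W/dt points
    (the largest usable origin is the correlation length minus the
    window).  Returns shape (n_channels, K - W/dt).
    """
    w = int(round(window / ri.dt))
    if window < 2 * ri.dt:
        raise ValueError(f"window {window} fs must be at least 2 dt = {2 * ri.dt} fs")
    k_len = ri.I.shape[1]
    if w >= k_len:
        raise ValueError(
            f"window of {w} points exceeds the {k_len}-point running integral"
        )
    c = np.cumsum(np.pad(ri.I, ((0, 0), (1, 0))), axis=1)
    return (c[:, w + 1 :] - c[:, : k_len - w]) / (w + 1)


def _multi_exponential(t, amps, taus):
    return sum(a * np.exp(-t / tau) for a, tau in zip(amps, taus))


def _r_squared(y, y_fit):
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def _default_switch_grid(t: np.ndarray, n: int = 20) -> np.ndarray:
    """Candidate switch times: log-spaced sample times up to half the CAF."""
    lo = t[1]
    hi = t[len(t) // 2]
    targets = np.geomspace(lo, hi, n)
    idx = np.unique(np.searchsorted(t, targets))
    idx = idx[idx < len(t)]
    return t[idx]


def _select_channel(caf: CAFResult, channel: int) -> tuple[np.ndarray, np.ndarray]:
    t = caf.times
    c = caf.C[channel]
    return t, c


def _fit_one_exponential_switch(t, c, k, t_switch):
    sel = t >= t_switch - 1e-12
    ts, cs = t[sel], c[sel]
    if ts.size < 2 * k + 2:
        raise RuntimeError("too few points past the switch time")
    scale = abs(cs[0]) if cs[0] != 0 else max(abs(cs).max(), 1e-300)
    tau0 = np.geomspace(max(t[1], ts[0] / 10 + t[1]), max(t[-1], 10 * t[1]), k + 2)[1:-1]

    def residuals(theta):
        amps = theta[:k] * scale
        taus = np.exp(theta[k:])
        return (_multi_exponential(ts, amps, taus) - cs) / scale

    x0 = np.concatenate([np.full(k, cs[0] / scale / k), np.log(tau0)])
    res = optimize.least_squares(residuals, x0, method="lm", max_nfev=20000)
    amps = res.x[:k] * scale
    taus = np.exp(res.x[k:])
    fit = _multi_exponential(ts, amps, taus)
    r2 = _r_squared(cs, fit)
    order = np.argsort(taus)
    return amps[order], taus[order], r2


def fit_exponential_tail(caf: CAFResult, k: int = 2,
                         switch_grid=None, channel: int = 0) -> TailFit:
    """Fit sum_i A_i exp(-t/tau_i) to the CAF tail and integrate.

    For each candidate switch time the decaying part C(t >= t_switch)
    is least-squares fitted (positive tau enforced through a log
    parametrization); the switch time maximizing R^2 on the fitted
    region wins.  The transport integral is the trapezoidal integral of
    the data below the switch plus the closed-form tail
    sum_i A_i tau_i exp(-t_switch/tau_i).

    Candidates whose fit fails to converge are skipped with a log entry;
    if every candidate fails a RuntimeError is raised.
    """
    if k < 1:
        raise ValueError("need at least one exponential")
    t, c = _select_channel(caf, channel)
    if switch_grid is None:
        switch_grid = _default_switch_grid(t)
    candidates = []
    for t_switch in np.atleast_1d(switch_grid):
        try:
            amps, taus, r2 = _fit_one_exponential_switch(t, c, k, t_switch)
        except Exception as exc:  # skip non-converged candidates
            log.info("tail fit at t_switch=%.4g ps failed: %s", t_switch, exc)
            continue
        below = t <= t_switch + 1e-12
        numeric = float(np.trapezoid(c[below], t[below]))
        tail = float(np.sum(amps * taus * np.exp(-t_switch / taus)))
        candidates.append(
            TailFit(model=f"exp{k}",
                    params={"A": amps, "tau": taus},
                    t_switch=float(t_switch), r_squared=r2,
                    numeric_part=numeric, tail_part=tail)
        )
    if not candidates:
        raise RuntimeError("tail fit failed at every candidate switch time")
    best = max(candidates, key=lambda f: f.r_squared)
    best.candidates = [(f.t_switch, f.r_squared, f.total_integral) for f in candidates]
    return best


def fit_stretched_tail(caf: CAFResult, switch_grid=None,
                       channel: int = 0) -> TailFit:
    """Fit a stretched exponential a*exp(-t^alpha) to the CAF tail.

    The tail integral of a*exp(-t^alpha) on [t_switch, inf) has no
    elementary closed form and is evaluated by adaptive quadrature
    (relative tolerance 1e-10); alpha is constrained positive.
    """
    t, c = _select_channel(caf, channel)
    if switch_grid is None:
        switch_grid = _default_switch_grid(t)
    candidates = []
    for t_switch in np.atleast_1d(switch_grid):
        sel = t >= t_switch - 1e-12
        ts, cs = t[sel], c[sel]
        if ts.size < 4:
            continue
        scale = abs(cs[0]) if cs[0] != 0 else 1.0

        def residuals(theta):
            a = theta[0] * scale
            alpha = math.exp(min(theta[1], 4.0))  # cap avoids overflow in t**alpha
            return (a * np.exp(-np.power(ts, alpha)) - cs) / scale

        try:
            res = optimize.least_squares(residuals, [cs[0] / scale, 0.0],
                                         method="lm", max_nfev=20000)
        except Exception as exc:
            log.info("stretched fit at t_switch=%.4g ps failed: %s", t_switch, exc)
            continue
        a = res.x[0] * scale
        alpha = math.exp(res.x[1])
        fit = a * np.exp(-np.power(ts, alpha))
        r2 = _r_squared(cs, fit)
        below = t <= t_switch + 1e-12
        numeric = float(np.trapezoid(c[below], t[below]))
        tail, _ = integrate.quad(
            lambda x: a * math.exp(-(x**alpha)), t_switch, np.inf,
            epsrel=1e-10, epsabs=0.0, limit=500,
        )
        candidates.append(
            TailFit(model="stretched", params={"a": a, "alpha": alpha},
                    t_switch=float(t_switch), r_squared=r2,
                    numeric_part=numeric, tail_part=float(tail))
        )
    if not candidates:
        raise RuntimeError("stretched-tail fit failed at every candidate switch time")
    best = max(candidates, key=lambda f: f.r_squared)
    best.candidates = [(f.t_switch, f.r_squared, f.total_integral) for f in candidates]
    return best


def msd(vectors: np.ndarray, dt: float, max_lag: int | None = None,
        unwrapped: bool = True) -> MSDResult:
    """Origin-averaged mean squared displacement via the FFT decomposition.

    Parameters
    ----------
    vectors : ndarray, (n_steps, 3) or (n_steps, n_particles, 3)
        Unwrapped positions (nm) or a collective displacement vector
        such as the dipole moment (e nm); the MSD is averaged over time
        origins and, when present, over particles.
    dt : float
        Sampling step in fs.

    Notes
    -----
    MSD(k) = S1(k) - 2 S2(k) with S1 from cumulative sums of |r|^2 and
    S2 the positional autocorrelation computed by FFT; equals the
    O(N^2) direct double loop to ~1e-8 relative.
    """
    if not unwrapped:
        raise ValueError("MSD needs unwrapped input")
    x = np.asarray(vectors, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, None, :]
    if x.ndim != 3:
        raise ValueError("input must be (n_steps, [n_particles,] 3)")
    n = x.shape[0]
    if max_lag is None:
        max_lag = n - 1
    if not 1 <= max_lag <= n - 1:
        raise ValueError(f"max_lag must be in [1, {n - 1}]")
    from .correlation import _batch_correlate

    flat = x.transpose(1, 2, 0).reshape(-1, n)  # (P*3, T)
    # S2(k) = <r_i . r_{i+k}> per particle, summed over components
    s2 = _batch_correlate(flat, flat, max_lag) * (n - np.arange(max_lag + 1))
    s2 = s2.reshape(x.shape[1], 3, max_lag + 1).sum(axis=1)  # (P, K+1) raw sums
    d = (x**2).sum(axis=2)  # (T, P)
    # S1(k) = sum_{i=0}^{n-k-1} (|r_i|^2 + |r_{i+k}|^2) via prefix sums
    csum = np.vstack([np.zeros(d.shape[1]), np.cumsum(d, axis=0)])  # (T+1, P)
    k = np.arange(max_lag + 1)
    head = csum[n - k] - csum[0]  # sum of first n-k terms
    tail = csum[n] - csum[k]  # sum of last n-k terms
    s1 = (head + tail).T  # (P, K+1)
    counts = n - k
    msd_k = (s1 - 2.0 * s2) / counts
    msd_k = np.clip(msd_k, 0.0, None).mean(axis=0)
    msd_k[0] = 0.0  # exact by definition; FFT rounding leaves ~1e-14
    times = k * dt * 1e-3
    return MSDResult(times=times, msd=msd_k, n_particles=x.shape[1])


def einstein_estimate(msd_result: MSDResult, fit_window: tuple[float, float],
                      prop: str, volume_nm3: float | None = None,
                      temperature: float | None = None) -> TransportEstimate:
    """Transport coefficient from the MSD slope over an explicit window.

    Ordinary least squares on the window (ps), slope times the
    property's Einstein prefactor; the standard error of the slope is
    propagated.  The fit window is a mandatory, explicit input.
    """
    t0, t1 = fit_window
    sel = (msd_result.times >= t0) & (msd_result.times <= t1)
    if sel.sum() < 2:
        raise ValueError(f"fit window ({t0}, {t1}) ps holds fewer than 2 MSD points")
    res = stats.linregress(msd_result.times[sel], msd_result.msd[sel])
    f = units.einstein_prefactor(prop, volume_nm3, temperature)
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return TransportEstimate(
        value=float(res.slope) * f,
        uncertainty=stderr * f,
        property=prop,
        units=units.output_unit(prop),
        plateau_window=(float(t0), float(t1)),
        provenance={"route": "einstein", "intercept": float(res.intercept)},
    )


def nernst_einstein(d_by_species: dict, z_by_species: dict, n_by_species: dict,
                    volume: float, temperature: float) -> float:
    """Nernst-Einstein conductivity (S/m) from species diffusion coefficients.

    kappa_NE = e^2/(V kB T) * sum_i N_i z_i^2 D_i with D in m^2/s and V
    in m^3.  Neglects interionic correlations; exact only in the dilute
    limit.
    """
    if volume <= 0 or temperature <= 0:
        raise ValueError("volume and temperature must be positive")
    missing = set(d_by_species) ^ set(z_by_species) | set(d_by_species) ^ set(n_by_species)
    if missing:
        raise ValueError(f"species maps are not congruent; mismatched keys: {sorted(missing)}")
    total = sum(
        n_by_species[s] * z_by_species[s] ** 2 * d_by_species[s] for s in d_by_species
    )
    return units.E_CHARGE**2 / (volume * units.KB * temperature) * total


def yeh_hummer(d: float, temperature: float, eta: float, box_length: float) -> float:
    """Yeh-Hummer finite-size corrected diffusion coefficient (m^2/s).

    D_corrected = D + 2.8373 kB T / (6 pi eta L) for a cubic periodic
    box of edge L (m) and shear viscosity eta (Pa s).
    """
    if eta <= 0 or box_length <= 0 or temperature <= 0:
        raise ValueError("temperature, viscosity and box length must be positive")
    return d + units.YEH_HUMMER_XI * units.KB * temperature / (
        6.0 * math.pi * eta * box_length
    )
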