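"""Uncertainty-weighted Green-Kubo estimator.

From a CAF with per-lag uncertainties this module builds

1. the running integral I_k (trapezoidal cumulative integral of the
   CAF) with propagated uncertainty u(I_k) (covariance between lags
   neglected),
2. the running transport coefficient gamma_i: the inverse-variance
   weighted average of I_k from an averaging origin i to the end of the
   correlation function, with a scatter-based uncertainty,
3. isotropic and replica combinations of running coefficients
   (pointwise inverse-variance weighted means with scatter-based
   uncertainties), and
4. the plateau value of gamma_i, which is reported as the transport
   coefficient.

Because u(I_k) grows as sqrt(k) once the CAF rattles around zero, the
weights 1/u^2(I_k) automatically de-emphasize the poorly sampled long
lags, removing the arbitrary cutoff of plain tail averaging.
"""

from __future__ import annotations

import builtins
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import units
from .correlation import CAFResult

__all__ = [
    "RunningIntegral",
    "RunningCoefficient",
    "TransportEstimate",
    "running_integral",
    "running_coefficient",
    "isotropic_average",
    "average_replicas",
    "plateau_estimate",
    "apply_prefactor",
]

log = logging.getLogger(__name__)

#: floor applied to uncertainties before forming 1/u^2 weights, so an
#: exactly-zero uncertainty yields the maximum finite weight instead of
#: a division by zero.
DEFAULT_U_FLOOR = 1e-150


@dataclass
class RunningIntegral:
    """Cumulative trapezoidal integral of a CAF with propagated uncertainty.

    ``I`` and ``u`` have shape (n_channels, K) where K = n_lags - 1;
    entry k covers the integral up to lag k + 1.  Units: CAF units * fs.
    """

    I: np.ndarray
    u: np.ndarray
    dt: float
    lags: np.ndarray
    pairs: tuple

    @property
    def times(self) -> np.ndarray:
        """Upper integration edge of each entry, in ps."""
        return self.lags * self.dt * 1e-3


@dataclass
class RunningCoefficient:
    """Weighted tail average of the running integral vs averaging origin.

    ``gamma`` and ``u`` have shape (n_channels, K); origin i averages
    the integral points i..K-1.  The last origin has a single point and
    an undefined (NaN) uncertainty.
    """

    gamma: np.ndarray
    u: np.ndarray
    origin_times: np.ndarray
    n_points_used: np.ndarray
    channels: tuple = ()

    def __post_init__(self):
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=np.float64))
        self.u = np.atleast_2d(np.asarray(self.u, dtype=np.float64))
        if self.gamma.shape != self.u.shape:
            raise ValueError("gamma and u must share a shape")
        if not self.channels:
            self.channels = tuple(str(i) for i in range(self.gamma.shape[0]))

    @property
    def n_channels(self) -> int:
        return self.gamma.shape[0]

    def scaled(self, factor: float) -> "RunningCoefficient":
        """Multiply values and uncertainties by a physical prefactor."""
        return RunningCoefficient(
            gamma=self.gamma * factor,
            u=self.u * abs(factor),
            origin_times=self.origin_times,
            n_points_used=self.n_points_used,
            channels=self.channels,
        )


@dataclass
class TransportEstimate:
    """A transport coefficient with uncertainty and plateau provenance."""

    value: float
    uncertainty: float
    property: str = "generic"
    units: str = ""
    plateau_window: tuple = (np.nan, np.nan)
    status: str = "plateau"
    spread: float = np.nan
    provenance: dict = field(default_factory=dict)

    # note: the `property` field shadows the builtin inside this class body
    @builtins.property
    def converged(self) -> bool:
        return self.status == "plateau"


def running_integral(caf: CAFResult) -> RunningIntegral:
    """Trapezoidal running integral of the CAF with propagated uncertainty.

    I_k = (dt/2) * sum_{i=0}^{k} (C_i + C_{i+1});
    u(I_k) = (dt/2) * sqrt( sum_{i=0}^{k} (u^2(C_i) + u^2(C_{i+1})) ).
    """
    if caf.n_lags < 2:
        raise ValueError("need at least 2 CAF lags to integrate")
    c, u = caf.C, caf.u
    half_dt = 0.5 * caf.dt
    integral = half_dt * np.cumsum(c[:, :-1] + c[:, 1:], axis=1)
    if np.isnan(u).any():
        warnings.warn(
            "CAF uncertainties are undefined; running-integral uncertainty is NaN",
            stacklevel=2,
        )
    var = np.cumsum(u[:, :-1] ** 2 + u[:, 1:] ** 2, axis=1)
    u_i = half_dt * np.sqrt(var)
    return RunningIntegral(
        I=integral, u=u_i, dt=caf.dt, lags=np.arange(1, caf.n_lags), pairs=caf.pairs
    )


def running_coefficient(ri: RunningIntegral,
                        u_floor: float = DEFAULT_U_FLOOR) -> RunningCoefficient:
    """Inverse-variance weighted tail average of the running integral.

    gamma_i = sum_{k>=i} I_k/u^2(I_k) / sum_{k>=i} 1/u^2(I_k);
    u(gamma_i) = sqrt( sum_{k>=i} (gamma_i - I_k)^2/u^2(I_k)
                       / (n_i * sum_{k>=i} 1/u^2(I_k)) )
    with n_i the number of tail points.  gamma_i always lies between the
    smallest and largest tail integral; under equal uncertainties it
    reduces to the arithmetic mean.
    """
    I, u = ri.I, ri.u
    n_ch, k_len = I.shape
    if k_len < 2:
        raise ValueError("need at least 2 integral points")
    if np.any(u[np.isfinite(u)] < u_floor):
        warnings.warn(
            f"zero/near-zero integral uncertainties floored at {u_floor:g} "
            "to form finite weights",
            stacklevel=2,
        )
    w = 1.0 / np.maximum(u, u_floor) ** 2
    # weights are scale-invariant; normalize to avoid overflow near the floor
    w /= w.max(axis=1, keepdims=True)
    # shift improves conditioning of the scatter term; gamma is shift-equivariant
    shift = np.mean(I, axis=1, keepdims=True)
    ic = I - shift
    sw = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
    swi = np.cumsum((w * ic)[:, ::-1], axis=1)[:, ::-1]
    swi2 = np.cumsum((w * ic**2)[:, ::-1], axis=1)[:, ::-1]
    gamma = swi / sw + shift
    n_pts = np.arange(k_len, 0, -1)[None, :]
    scatter = np.clip(swi2 - swi**2 / sw, 0.0, None)
    u_gamma = np.sqrt(scatter / (n_pts * sw))
    u_gamma[:, -1] = np.nan  # a single point has no scatter estimate
    return RunningCoefficient(
        gamma=gamma,
        u=u_gamma,
        origin_times=ri.times,
        n_points_used=n_pts[0],
        channels=tuple("".join(p) if isinstance(p, tuple) else str(p) for p in ri.pairs),
    )


def _weighted_combine(gamma: np.ndarray, u: np.ndarray, ddof: int,
                      u_floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise inverse-variance mean with scatter-based uncertainty."""
    w = 1.0 / np.maximum(u, u_floor) ** 2
    w = w / w.max(axis=0, keepdims=True)
    sw = w.sum(axis=0)
    mean = (w * gamma).sum(axis=0) / sw
    scatter = (w * (gamma - mean) ** 2).sum(axis=0)
    u_out = np.sqrt(scatter / (ddof * sw))
    return mean, u_out


def _combine_rcs(rcs: list[RunningCoefficient], u_floor: float,
                 label: str) -> RunningCoefficient:
    first = rcs[0]
    for rc in rcs[1:]:
        if rc.gamma.shape[1] != first.gamma.shape[1] or not np.allclose(
            rc.origin_times, first.origin_times
        ):
            raise ValueError("running coefficients must share the origin grid")
    gamma = np.concatenate([rc.gamma for rc in rcs], axis=0)
    u = np.concatenate([rc.u for rc in rcs], axis=0)
    n = gamma.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean, u_out = _weighted_combine(gamma, u, n - 1, u_floor)
    return RunningCoefficient(
        gamma=mean[None, :],
        u=u_out[None, :],
        origin_times=first.origin_times,
        n_points_used=first.n_points_used,
        channels=(label,),
    )


def isotropic_average(components: RunningCoefficient | list[RunningCoefficient],
                      u_floor: float = DEFAULT_U_FLOOR) -> RunningCoefficient:
    """Combine tensor components into the isotropic running coefficient.

    Pointwise inverse-variance weighted mean over the diagonal channels,
    with a scatter-based uncertainty carrying a 1/(n_components - 1)
    prefactor (1/2 for the usual three Cartesian components).
    """
    if isinstance(components, RunningCoefficient):
        components = [
            RunningCoefficient(
                gamma=components.gamma[i : i + 1],
                u=components.u[i : i + 1],
                origin_times=components.origin_times,
                n_points_used=components.n_points_used,
                channels=(components.channels[i],),
            )
            for i in range(components.n_channels)
        ]
    if len(components) == 1 and components[0].n_channels == 1:
        warnings.warn("single component: isotropic average is the identity", stacklevel=2)
        return components[0]
    return _combine_rcs(components, u_floor, "iso")


def average_replicas(replicas: list[RunningCoefficient]) -> RunningCoefficient:
    """Average running coefficients over independent replicas.

    Collective currents are sensitive to the initial configuration, so
    individual replicas may not each show a plateau; their average
    converges much better.  Replicas of the same protocol are
    exchangeable, so the combination is the pointwise equal-weight mean
    with a scatter-based standard error carrying the 1/(n_replicas - 1)
    prefactor.  (Weighting replicas by their own scatter-estimated
    uncertainties is avoided: on a correlated running-integral tail
    those estimates fluctuate by large factors between statistically
    identical replicas, and inverse-variance weights would then lock
    onto whichever replica's uncertainty happened to collapse.)
    """
    if len(replicas) < 2:
        warnings.warn("fewer than 2 replicas: average is the identity", stacklevel=2)
        return replicas[0]
    for r in replicas:
        if r.n_channels != 1:
            raise ValueError("replica averaging expects single-channel running coefficients")
    first = replicas[0]
    for rc in replicas[1:]:
        if rc.gamma.shape[1] != first.gamma.shape[1] or not np.allclose(
            rc.origin_times, first.origin_times
        ):
            raise ValueError("running coefficients must share the origin grid")
    gamma = np.concatenate([rc.gamma for rc in replicas], axis=0)
    n = gamma.shape[0]
    mean = gamma.mean(axis=0)
    u = np.sqrt(((gamma - mean) ** 2).sum(axis=0) / (n * (n - 1)))
    return RunningCoefficient(
        gamma=mean[None, :],
        u=u[None, :],
        origin_times=first.origin_times,
        n_points_used=first.n_points_used,
        channels=("replica_mean",),
    )


def plateau_estimate(rc: RunningCoefficient, window="auto",
                     agreement_sigma: float = 1.0, min_fraction: float = 0.5,
                     min_origin: float = 0.0,
                     max_candidates: int = 512) -> TransportEstimate:
    """Identify the plateau of the running coefficient.

    With an explicit ``window=(t_start, t_end)`` (ps), returns gamma at
    the earliest origin inside the window together with its uncertainty,
    and reports the max-min spread across the window as a consistency
    diagnostic.

    With ``window="auto"``, scans candidate origins at or after
    ``min_origin`` (ps) and returns the earliest origin i such that at
    least ``min_fraction`` of the later origins j satisfy
    |gamma_j - gamma_i| <= agreement_sigma * u(gamma_j).  If no origin
    qualifies the estimate carries status ``"no_plateau"`` and a NaN
    value — a non-converged run is reported, never silently averaged.

    ``min_origin`` guards against the systematic approach region:
    while the running integral is still accumulating signal, gamma_i is
    biased low yet varies slowly, so a purely statistical agreement
    test can accept it.  The pipelines set ``min_origin`` to a multiple
    of the CAF decay time (see :func:`gktransport.correlation.decay_time`).
    """
    if rc.n_channels != 1:
        raise ValueError("plateau detection expects a single-channel running coefficient")
    gamma = rc.gamma[0]
    u = rc.u[0]
    t = rc.origin_times
    valid = np.isfinite(gamma) & np.isfinite(u)
    if not valid.any():
        raise ValueError("running coefficient has no finite points")
    idx = np.flatnonzero(valid)

    if window != "auto":
        t0, t1 = window
        sel = idx[(t[idx] >= t0) & (t[idx] <= t1)]
        if sel.size == 0:
            raise ValueError(f"no finite origins inside window ({t0}, {t1}) ps")
        i0 = sel[0]
        spread = float(gamma[sel].max() - gamma[sel].min())
        log.info(
            "plateau window (%.4g, %.4g) ps: gamma=%.6g u=%.3g spread=%.3g",
            t0, t1, gamma[i0], u[i0], spread,
        )
        return TransportEstimate(
            value=float(gamma[i0]), uncertainty=float(u[i0]),
            plateau_window=(float(t[i0]), float(t[sel[-1]])), spread=spread,
        )

    gated = idx[t[idx] >= min_origin]
    if gated.size >= 3:
        idx = gated
    elif min_origin > 0:
        warnings.warn(
            f"fewer than 3 origins at or after min_origin={min_origin:g} ps; "
            "scanning the full origin range instead",
            stacklevel=2,
        )
    if idx.size < 3:
        raise ValueError("too few origins for automatic plateau detection")
    if idx.size > max_candidates:
        cand = idx[np.unique(np.linspace(0, idx.size - 2, max_candidates).astype(int))]
    else:
        cand = idx[:-1]
    for i in cand:
        later = idx[idx > i]
        if later.size == 0:
            continue
        agree = np.abs(gamma[later] - gamma[i]) <= agreement_sigma * u[later]
        if agree.mean() >= min_fraction:
            log.info(
                "auto plateau from origin %.4g ps (agreement %.0f%% of %d later origins): "
                "gamma=%.6g u=%.3g",
                t[i], 100 * agree.mean(), later.size, gamma[i], u[i],
            )
            return TransportEstimate(
                value=float(gamma[i]), uncertainty=float(u[i]),
                plateau_window=(float(t[i]), float(t[idx[-1]])),
                spread=float(gamma[later].max() - gamma[later].min()),
            )
    log.info("no plateau found under auto criterion")
    return TransportEstimate(
        value=float("nan"), uncertainty=float("nan"), status="no_plateau",
    )


def apply_prefactor(raw: TransportEstimate, prop: str,
                    volume_nm3: float | None = None,
                    temperature: float | None = None) -> TransportEstimate:
    """Convert a raw (MD-unit) GK estimate to physical output units.

    Conductivity uses 1/(V kB T) and reports S/m; each off-diagonal
    viscosity channel uses V/(kB T) and reports mPa*s; diffusion needs
    neither V nor T and reports m^2/s.
    """
    f = units.gk_prefactor(prop, volume_nm3, temperature)
    return TransportEstimate(
        value=raw.value * f,
        uncertainty=raw.uncertainty * f,
        property=prop,
        units=units.output_unit(prop),
        plateau_window=raw.plateau_window,
        status=raw.status,
        spread=raw.spread * f if np.isfinite(raw.spread) else raw.spread,
        provenance=dict(raw.provenance),
    )
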