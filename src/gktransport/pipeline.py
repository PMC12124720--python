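"""End-to-end transport pipelines: current series in, coefficient out.

Each pipeline runs split -> CAF (+uncertainty) -> running integral ->
uncertainty-weighted running coefficient -> physical prefactor ->
isotropic combination -> replica combination -> plateau, and returns
the final estimate together with the combined and per-replica running
coefficients for convergence reporting.
"""

from __future__ import annotations

import logging

import numpy as np

from . import units
from .correlation import caf, decay_time
from .estimator import (
    RunningCoefficient,
    TransportEstimate,
    average_replicas,
    isotropic_average,
    plateau_estimate,
    running_coefficient,
    running_integral,
)
from .series import CurrentSeries, pool_intervals, split_series, stride_decimate

__all__ = ["replica_running_coefficient", "estimate_transport"]

log = logging.getLogger(__name__)


def _default_max_lag(n: int) -> int:
    # cap at half the interval to avoid the worst small-sample tail
    return max(1, n // 2)


def _intervals_for_replica(replica, interval_length_fs: float, stride: int):
    """A replica is one collective series, or a list of per-molecule series."""
    if isinstance(replica, CurrentSeries):
        replica = [replica]
    sets = []
    for i, s in enumerate(replica):
        if stride > 1:
            s = stride_decimate(s, stride)
        sets.append(split_series(s, interval_length_fs, series_id=f"mol{i}"))
    return pool_intervals(sets)


def replica_running_coefficient(replica, prop: str, interval_length: float,
                                max_lag: float | None = None,
                                volume: float | None = None,
                                temperature: float | None = None,
                                stride: int = 1,
                                return_decay_time: bool = False):
    """Isotropic running coefficient of one replica, in output units.

    Parameters
    ----------
    replica : CurrentSeries or list of CurrentSeries
        One collective current, or (for single-particle properties) the
        per-molecule series whose intervals are pooled.
    interval_length, max_lag : float
        In ps.  ``max_lag`` defaults to half the interval.
    return_decay_time : bool
        Also return the CAF decay time (ps) used to gate automatic
        plateau detection.
    """
    intervals = _intervals_for_replica(replica, interval_length * 1e3, stride)
    n = intervals.interval_length
    lag_cap = _default_max_lag(n) if max_lag is None else min(
        n - 1, int(round(max_lag * 1e3 / intervals.dt))
    )
    result = caf(intervals, max_lag=lag_cap)
    log.info(
        "%s CAF: M=%d intervals of N=%d frames (dt=%.4g fs), max lag %d",
        prop, result.M, result.N, result.dt, lag_cap,
    )
    rc = running_coefficient(running_integral(result))
    rc = rc.scaled(units.gk_prefactor(prop, volume, temperature))
    rc = isotropic_average(rc)
    if return_decay_time:
        return rc, decay_time(result)
    return rc


def estimate_transport(replicas, prop: str, interval_length: float,
                       max_lag: float | None = None,
                       volume: float | None = None,
                       temperature: float | None = None,
                       plateau="auto", stride: int = 1,
                       agreement_sigma: float = 1.0,
                       min_fraction: float = 0.5,
                       plateau_gate: float = 2.0):
    """Full pipeline over replicas.

    Parameters
    ----------
    replicas : list
        One entry per independent simulation: a CurrentSeries, or a
        list of per-molecule CurrentSeries for single-particle
        properties.
    plateau : "auto" or (t_start, t_end) in ps
    plateau_gate : float
        In auto mode, candidate plateau origins start at
        ``plateau_gate`` times the median CAF decay time across
        replicas, so the systematically biased approach region is never
        mistaken for a plateau.

    Returns
    -------
    estimate : TransportEstimate
    combined : RunningCoefficient
        Replica-averaged running coefficient (the solid convergence
        curve).
    per_replica : list of RunningCoefficient
        Individual replica curves (the dashed ones).
    """
    if prop not in units.PROPERTIES:
        raise ValueError(f"unknown property {prop!r}")
    if isinstance(replicas, CurrentSeries):
        replicas = [replicas]
    per_replica = []
    decay_times = []
    for rep in replicas:
        rc, t_dec = replica_running_coefficient(
            rep, prop, interval_length, max_lag=max_lag, volume=volume,
            temperature=temperature, stride=stride, return_decay_time=True,
        )
        per_replica.append(rc)
        decay_times.append(t_dec)
    combined = average_replicas(per_replica) if len(per_replica) > 1 else per_replica[0]
    min_origin = plateau_gate * float(np.median(decay_times))
    if plateau == "auto":
        log.info("auto plateau gated at %.4g ps (%.2g x median CAF decay time)",
                 min_origin, plateau_gate)
    estimate = plateau_estimate(combined, window=plateau,
                                agreement_sigma=agreement_sigma,
                                min_fraction=min_fraction,
                                min_origin=min_origin)
    estimate.property = prop
    estimate.units = units.output_unit(prop)
    estimate.provenance = {
        "n_replicas": len(per_replica),
        "interval_length_ps": interval_length,
        "stride": stride,
    }
    log.info("%s estimate: %s +- %s %s (%s)", prop, estimate.value,
             estimate.uncertainty, estimate.units, estimate.status)
    return estimate, combined, per_replica
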