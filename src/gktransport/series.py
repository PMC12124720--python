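"""Containers for microscopic current time series.

A :class:`CurrentSeries` is a uniformly sampled, multi-component real time
series (an electric current, the off-diagonal pressure components, a
molecule's centre-of-mass velocity, ...) with its time step and unit
metadata.  :class:`IntervalSet` holds the series chopped into M
non-overlapping intervals of equal length N, the statistical unit over
which correlation functions and their uncertainties are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PROPERTY_TAGS = (
    "electric_current",
    "pressure_offdiag",
    "com_velocity",
    "com_position",
    "dipole_moment",
    "generic",
)


@dataclass
class CurrentSeries:
    """Uniformly sampled multi-component current.

    Parameters
    ----------
    values : ndarray, shape (n_components, n_steps)
        Physical current samples.
    dt : float
        Sampling time step in fs.
    component_labels : tuple of str
        One unique label per component, e.g. ``("x", "y", "z")`` or
        ``("xy", "xz", "yz")``.
    property_tag : str
        One of :data:`PROPERTY_TAGS`.
    units : str
        Free-form unit string of the samples.
    """

    values: np.ndarray
    dt: float
    component_labels: tuple = ()
    property_tag: str = "generic"
    units: str = ""

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_components, n_steps) array")
        n_comp, n_steps = self.values.shape
        if n_steps < 2:
            raise ValueError(f"a current series needs at least 2 steps, got {n_steps}")
        if not np.isfinite(self.values).all():
            raise ValueError("current samples must all be finite")
        if self.dt <= 0:
            raise ValueError(f"time step must be positive, got {self.dt}")
        if not self.component_labels:
            self.component_labels = tuple(str(i) for i in range(n_comp))
        self.component_labels = tuple(self.component_labels)
        if len(self.component_labels) != n_comp:
            raise ValueError("one label per component required")
        if len(set(self.component_labels)) != n_comp:
            raise ValueError("component labels must be unique")
        if self.property_tag not in PROPERTY_TAGS:
            raise ValueError(
                f"unknown property_tag {self.property_tag!r}; expected one of {PROPERTY_TAGS}"
            )

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Total covered duration (n_steps * dt) in fs."""
        return self.n_steps * self.dt


def stride_decimate(series: CurrentSeries, factor: int) -> CurrentSeries:
    """Keep every ``factor``-th sample and scale dt accordingly.

    Emulates recording the current at a lower frequency during the
    simulation, for robustness scans of the recording stride.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"stride factor must be >= 1, got {factor}")
    if factor >= series.n_steps:
        raise ValueError(
            f"stride factor {factor} leaves fewer than 2 of {series.n_steps} samples"
        )
    if factor == 1:
        return series
    return CurrentSeries(
        values=series.values[:, ::factor].copy(),
        dt=series.dt * factor,
        component_labels=series.component_labels,
        property_tag=series.property_tag,
        units=series.units,
    )


@dataclass
class IntervalSet:
    """M equal-length intervals of a current series.

    ``data`` has shape (M, n_components, N); intervals are the averaging
    unit of the correlation analysis.  Intervals pooled from different
    replicas (or from different molecules, for single-particle
    properties) may coexist in one set.
    """

    data: np.ndarray
    dt: float
    component_labels: tuple = ()
    origin_series_ids: tuple = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("interval data must be (M, n_components, N)")
        m, n_comp, n = self.data.shape
        if m < 1 or n < 2:
            raise ValueError(f"need M >= 1 intervals of N >= 2 frames, got M={m}, N={n}")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if not self.component_labels:
            self.component_labels = tuple(str(i) for i in range(n_comp))
        self.component_labels = tuple(self.component_labels)
        if len(self.component_labels) != n_comp:
            raise ValueError("one label per component required")
        if not self.origin_series_ids:
            self.origin_series_ids = tuple(f"interval{i}" for i in range(m))

    @property
    def n_intervals(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    @property
    def interval_length(self) -> int:
        return self.data.shape[2]


def split_series(series: CurrentSeries, interval_length: float,
                 series_id: str = "series") -> IntervalSet:
    """Split a series into non-overlapping, contiguous intervals.

    Parameters
    ----------
    interval_length : float
        Interval duration in fs.  N = floor(interval_length / dt) frames
        per interval; M = floor(n_steps / N) intervals; trailing
        remainder frames are discarded.
    """
    if interval_length <= 0:
        raise ValueError(f"interval length must be positive, got {interval_length} fs")
    n = int(np.floor(interval_length / series.dt + 1e-9))
    if n < 2:
        raise ValueError(
            f"interval of {interval_length} fs holds fewer than 2 samples at dt={series.dt} fs"
        )
    if n > series.n_steps:
        raise ValueError(
            f"interval length {interval_length} fs exceeds series duration "
            f"{series.duration} fs"
        )
    m = series.n_steps // n
    data = (
        series.values[:, : m * n]
        .reshape(series.n_components, m, n)
        .transpose(1, 0, 2)
        .copy()
    )
    return IntervalSet(
        data=data,
        dt=series.dt,
        component_labels=series.component_labels,
        origin_series_ids=tuple(f"{series_id}/{i}" for i in range(m)),
    )


def pool_intervals(sets: list[IntervalSet]) -> IntervalSet:
    """Pool intervals from several sets into one.

    Used for single-particle properties, where each molecule contributes
    its own intervals (M_total = n_molecules * n_intervals_per_molecule),
    and optionally for pooling replicas at the correlation level.
    """
    if not sets:
        raise ValueError("no interval sets to pool")
    first = sets[0]
    for s in sets[1:]:
        if s.interval_length != first.interval_length:
            raise ValueError("pooled interval sets must share the interval length")
        if s.n_components != first.n_components:
            raise ValueError("pooled interval sets must share the component count")
        if abs(s.dt - first.dt) > 1e-9 * first.dt:
            raise ValueError("pooled interval sets must share the time step")
    data = np.concatenate([s.data for s in sets], axis=0)
    ids = tuple(i for s in sets for i in s.origin_series_ids)
    return IntervalSet(
        data=data,
        dt=first.dt,
        component_labels=first.component_labels,
        origin_series_ids=ids,
    )
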