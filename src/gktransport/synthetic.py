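"""Stochastic processes with known analytic transport answers.

Every estimator in this package can be validated without running MD:

- Ornstein-Uhlenbeck (OU) currents are stationary Gaussian processes
  with CAF sigma^2 * exp(-t/tau) and Green-Kubo integral sigma^2 * tau,
  matching the Gaussian-current assumption behind the CAF uncertainty
  analysis.
- Sums of independent OU processes realize multi-exponential CAFs
  sum_i A_i exp(-t/tau_i) with integral sum_i A_i tau_i.
- Overdamped Brownian walkers have MSD slope 6 D.
- Inertial Langevin particles have VACF (kB T / m) exp(-gamma_f t) per
  component and D = kB T / (m gamma_f), so the VACF-integral and
  MSD-slope routes can be cross-checked against the same ground truth.
- A toy ionic configuration provides a neutral multi-atom topology with
  Maxwell-Boltzmann velocities for exercising the current calculators.

All generators draw from ``numpy.random.default_rng`` (PCG64); a given
seed fixes the full output bitstream.  The OU update uses the exact
discretization, so the analytic CAF holds at any time step.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.signal import lfilter

from . import units
from .currents import FrameData, Topology
from .series import CurrentSeries

__all__ = [
    "ou_series",
    "multi_exponential_series",
    "brownian_trajectory",
    "langevin_trajectory",
    "ionic_toy_system",
    "ou_caf",
]


def ou_caf(t, sigma2: float, tau: float):
    """Analytic OU autocorrelation sigma^2 exp(-t/tau) (t, tau in ps)."""
    return sigma2 * np.exp(-np.asarray(t, dtype=float) / tau)


def _ou_components(rng, n_components, n_steps, a, innov_sd):
    xi = rng.standard_normal((n_components, n_steps))
    x0 = rng.standard_normal(n_components) * innov_sd / math.sqrt(1.0 - a * a)
    zi = (a * x0)[:, None]
    out, _ = lfilter([innov_sd], [1.0, -a], xi, axis=-1, zi=zi)
    return out


def ou_series(tau: float, sigma2: float, dt: float, n_steps: int,
              n_components: int = 3, seed: int | None = None,
              property_tag: str = "generic") -> CurrentSeries:
    """Stationary Ornstein-Uhlenbeck current.

    Parameters
    ----------
    tau : float
        Correlation time in ps.
    sigma2 : float
        Stationary variance per component.
    dt : float
        Time step in fs (a warning is issued when dt > tau/10).
    n_components : int
        Independent components (default 3, mimicking a Cartesian
        current).

    Notes
    -----
    Exact discretization: J_{n+1} = J_n e^{-dt/tau}
    + sigma sqrt(1 - e^{-2 dt/tau}) xi_n with standard normal xi, so the
    sampled process has exactly the analytic CAF sigma^2 e^{-t/tau} at
    every lag.
    """
    if tau <= 0 or sigma2 <= 0:
        raise ValueError("tau and sigma2 must be positive")
    dt_ps = dt * 1e-3
    if dt_ps > tau / 10:
        warnings.warn(
            f"dt = {dt_ps} ps is coarse relative to tau = {tau} ps", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    a = math.exp(-dt_ps / tau)
    innov_sd = math.sqrt(sigma2 * (1.0 - a * a))
    values = _ou_components(rng, n_components, n_steps, a, innov_sd)
    return CurrentSeries(values=values, dt=dt, property_tag=property_tag,
                         component_labels=("x", "y", "z")[:n_components]
                         if n_components <= 3 else (),
                         units="arb")


def multi_exponential_series(terms: list[tuple[float, float]], dt: float,
                             n_steps: int, n_components: int = 3,
                             seed: int | None = None) -> CurrentSeries:
    """Sum of independent OU processes: CAF = sum_i A_i exp(-t/tau_i).

    ``terms`` is a list of (A_i, tau_i) with amplitudes in CAF units and
    times in ps; the analytic Green-Kubo integral is sum_i A_i tau_i.
    """
    if not terms:
        raise ValueError("need at least one (A, tau) term")
    rng = np.random.default_rng(seed)
    dt_ps = dt * 1e-3
    total = np.zeros((n_components, n_steps))
    for amp, tau in terms:
        if amp <= 0 or tau <= 0:
            raise ValueError("amplitudes and times must be positive")
        a = math.exp(-dt_ps / tau)
        innov_sd = math.sqrt(amp * (1.0 - a * a))
        total += _ou_components(rng, n_components, n_steps, a, innov_sd)
    return CurrentSeries(values=total, dt=dt, property_tag="generic",
                         component_labels=("x", "y", "z")[:n_components]
                         if n_components <= 3 else (),
                         units="arb")


def brownian_trajectory(D: float, dt: float, n_steps: int, n_particles: int = 1,
                        seed: int | None = None) -> np.ndarray:
    """Overdamped Brownian walkers: positions (n_steps, n_particles, 3) in nm.

    ``D`` is the diffusion coefficient in m^2/s; steps are
    dx = sqrt(2 D dt) xi per component, giving MSD(t) = 6 D t exactly in
    expectation.  Positions are unwrapped by construction.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = np.random.default_rng(seed)
    d_nm2_ps = D / (units.NM**2 / units.PS)
    step_sd = math.sqrt(2.0 * d_nm2_ps * dt * 1e-3)
    steps = rng.standard_normal((n_steps - 1, n_particles, 3)) * step_sd
    pos = np.zeros((n_steps, n_particles, 3))
    np.cumsum(steps, axis=0, out=pos[1:])
    return pos


def langevin_trajectory(mass: float, temperature: float, friction: float,
                        dt: float, n_steps: int, n_particles: int = 1,
                        seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Inertial Langevin particles with exact velocity dynamics.

    Parameters
    ----------
    mass : float
        Particle mass in amu.
    temperature : float
        Bath temperature in K.
    friction : float
        Friction rate gamma_f in 1/ps.

    Returns
    -------
    positions, velocities : ndarray, shape (n_steps, n_particles, 3)
        nm and nm/ps.  Velocities follow the exact OU discretization, so
        VACF(t) = (kB T / m) exp(-gamma_f t) per component and
        D = kB T / (m gamma_f); positions are the Euler quadrature
        x_{n+1} = x_n + v_n dt (bias O(gamma_f dt)).
    """
    if mass <= 0 or temperature <= 0 or friction <= 0:
        raise ValueError("mass, temperature and friction must be positive")
    rng = np.random.default_rng(seed)
    dt_ps = dt * 1e-3
    v_sd = units.maxwell_boltzmann_sigma(mass, temperature)  # nm/ps
    a = math.exp(-friction * dt_ps)
    innov_sd = v_sd * math.sqrt(1.0 - a * a)
    xi = rng.standard_normal((n_particles * 3, n_steps))
    v0 = rng.standard_normal(n_particles * 3) * v_sd
    vel, _ = lfilter([innov_sd], [1.0, -a], xi, axis=-1, zi=(a * v0)[:, None])
    vel = vel.T.reshape(n_steps, n_particles, 3)
    pos = np.zeros_like(vel)
    np.cumsum(vel[:-1] * dt_ps, axis=0, out=pos[1:])
    return pos, vel


def langevin_diffusion_coefficient(mass: float, temperature: float,
                                   friction: float) -> float:
    """Analytic D = kB T / (m gamma_f) of the Langevin generator, in m^2/s."""
    d_nm2_ps = units.KB_KJMOL * temperature / (mass * friction)
    return d_nm2_ps * units.NM**2 / units.PS


_CATION_MASSES = (14.0, 1.0, 12.0)
_CATION_CHARGES = (0.7, 0.25, 0.05)
_ANION_MASSES = (16.0, 16.0)
_ANION_CHARGES = (-0.4, -0.6)


def ionic_toy_system(n_pairs: int, temperature: float = 300.0,
                     box: float = 5.0, n_frames: int = 1, dt: float = 1.0,
                     seed: int | None = None) -> tuple[Topology, list[FrameData]]:
    """Neutral toy electrolyte: multi-atom ions with Maxwell-Boltzmann velocities.

    Cations carry +1 e over three atoms and anions -1 e over two atoms,
    so centre-of-mass and molecular-charge bookkeeping is non-trivial.
    Frames are ballistic (atoms translate at constant velocity), which
    makes dM/dt = J hold exactly for the dipole/current consistency
    check.  ``box`` in nm, ``dt`` in fs.
    """
    if n_pairs < 1:
        raise ValueError("need at least one ion pair")
    rng = np.random.default_rng(seed)
    masses, charges, mol_of, species = [], [], [], []
    mol = 0
    for _ in range(n_pairs):
        masses.extend(_CATION_MASSES)
        charges.extend(_CATION_CHARGES)
        mol_of.extend([mol] * len(_CATION_MASSES))
        species.append("cation")
        mol += 1
        masses.extend(_ANION_MASSES)
        charges.extend(_ANION_CHARGES)
        mol_of.extend([mol] * len(_ANION_MASSES))
        species.append("anion")
        mol += 1
    topo = Topology(
        masses=np.array(masses),
        charges=np.array(charges),
        molecule_of=np.array(mol_of, dtype=int),
        species_of=tuple(species),
    )
    n_atoms = topo.n_atoms
    pos0 = rng.uniform(0.0, box, size=(n_atoms, 3))
    sigma = units.maxwell_boltzmann_sigma(topo.masses, temperature)
    vel = rng.standard_normal((n_atoms, 3)) * sigma[:, None]
    frames = []
    dt_ps = dt * 1e-3
    for i in range(n_frames):
        t = i * dt_ps
        frames.append(
            FrameData(
                positions=pos0 + vel * t,
                velocities=vel.copy(),
                box=np.array([box, box, box]),
                time=t,
                unwrapped=True,
            )
        )
    return topo, frames
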