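"""Microscopic currents from trajectory frames.

The Green-Kubo route to each transport property starts from a specific
microscopic current:

- electric conductivity: the collective charge current
  J = sum_k Q_k V_k over molecules with total charge Q_k and
  centre-of-mass velocity V_k (ions as units, molecular charges times
  COM velocities);
- viscosity: the off-diagonal components of the pressure tensor
  P = (1/V) sum_i m_i v_i (x) v_i + (1/V) sum_i r_i (x) f_i;
- self-diffusion: per-molecule COM velocities (the VACF integral per
  component is a diffusion-tensor component).

The Einstein routes use the conjugate displacements: the translational
dipole moment M = sum_k Q_k R_k and COM positions, both of which demand
unwrapped coordinates.

Internal units: amu, e, nm, ps; pressure converted to bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .series import CurrentSeries

__all__ = [
    "Topology",
    "FrameData",
    "com_velocities",
    "com_positions",
    "electric_current",
    "dipole_moment",
    "pressure_tensor",
    "offdiagonal_pressure",
    "electric_current_series",
    "species_velocity_series",
    "unwrap_positions",
]


@dataclass
class Topology:
    """Per-atom masses/charges and the atom-to-molecule map.

    ``species_of`` labels each molecule; ``molecular_charges`` are the
    sums of the atomic charges of each molecule.
    """

    masses: np.ndarray
    charges: np.ndarray
    molecule_of: np.ndarray
    species_of: tuple = ()

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.charges = np.asarray(self.charges, dtype=np.float64)
        self.molecule_of = np.asarray(self.molecule_of, dtype=np.intp)
        n = self.masses.size
        if self.charges.size != n or self.molecule_of.size != n:
            raise ValueError("masses, charges and molecule_of must be congruent")
        if np.any(self.masses <= 0):
            raise ValueError("atomic masses must be positive")
        if self.molecule_of.min() < 0:
            raise ValueError("molecule indices must be non-negative")
        n_mol = int(self.molecule_of.max()) + 1
        counts = np.bincount(self.molecule_of, minlength=n_mol)
        if np.any(counts == 0):
            raise ValueError("every molecule index up to the maximum must own atoms")
        if self.species_of and len(self.species_of) != n_mol:
            raise ValueError("one species label per molecule required")
        self.species_of = tuple(self.species_of)

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_of.max()) + 1

    @property
    def molecular_masses(self) -> np.ndarray:
        return np.bincount(self.molecule_of, weights=self.masses,
                           minlength=self.n_molecules)

    @property
    def molecular_charges(self) -> np.ndarray:
        return np.bincount(self.molecule_of, weights=self.charges,
                           minlength=self.n_molecules)

    def molecules_of_species(self, species: str) -> np.ndarray:
        if species not in self.species_of:
            raise ValueError(
                f"unknown species {species!r}; known: {sorted(set(self.species_of))}"
            )
        return np.flatnonzero(np.array(self.species_of) == species)


@dataclass
class FrameData:
    """One trajectory frame: positions/velocities (optionally forces) and box.

    positions nm, velocities nm/ps, forces kJ/mol/nm, box lengths nm,
    time ps.  ``unwrapped`` flags whether positions are continuous
    across periodic images (required for displacement-based estimators).
    """

    positions: np.ndarray
    velocities: np.ndarray | None = None
    forces: np.ndarray | None = None
    box: np.ndarray | None = None
    time: float = 0.0
    unwrapped: bool = False

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        for name in ("velocities", "forces"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.float64)
                if arr.shape != self.positions.shape:
                    raise ValueError(f"{name} must match positions shape")
                setattr(self, name, arr)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def volume(self) -> float:
        if self.box is None:
            raise ValueError("frame has no box")
        return float(np.prod(self.box))


def _per_molecule_mass_weighted(topo: Topology, atom_vectors: np.ndarray) -> np.ndarray:
    """Mass-weighted per-molecule average of a per-atom 3-vector field."""
    n_mol = topo.n_molecules
    out = np.empty((n_mol, 3))
    w = topo.masses[:, None] * atom_vectors
    for axis in range(3):
        out[:, axis] = np.bincount(topo.molecule_of, weights=w[:, axis],
                                   minlength=n_mol)
    return out / topo.molecular_masses[:, None]


def com_velocities(frame: FrameData, topo: Topology) -> np.ndarray:
    """Per-molecule centre-of-mass velocities V_k = sum(m v)/sum(m), nm/ps."""
    if frame.velocities is None:
        raise ValueError("frame has no velocities")
    return _per_molecule_mass_weighted(topo, frame.velocities)


def com_positions(frame: FrameData, topo: Topology) -> np.ndarray:
    """Per-molecule centre-of-mass positions, nm."""
    return _per_molecule_mass_weighted(topo, frame.positions)


def electric_current(frame: FrameData, topo: Topology) -> np.ndarray:
    """Collective electric current J = sum_k Q_k V_k, in e nm/ps."""
    v = com_velocities(frame, topo)
    return topo.molecular_charges @ v


def dipole_moment(frame: FrameData, topo: Topology) -> np.ndarray:
    """Translational dipole moment M = sum_k Q_k R_k, in e nm.

    Requires unwrapped positions: on wrapped coordinates the dipole
    displacement (and hence its MSD) is meaningless.
    """
    if not frame.unwrapped:
        raise ValueError(
            "dipole moment needs unwrapped positions; unwrap the trajectory "
            "first (see unwrap_positions)"
        )
    r = com_positions(frame, topo)
    return topo.molecular_charges @ r


def pressure_tensor(frame: FrameData, topo: Topology) -> np.ndarray:
    """Instantaneous pressure tensor in bar.

    P = (1/V) sum_i m_i v_i (x) v_i + (1/V) sum_i r_i (x) f_i.  The
    virial term as written is valid for non-periodic or minimum-image
    consistent position/force pairs; for periodic post-processing prefer
    a pressure series recorded by the MD engine itself.
    """
    if frame.velocities is None:
        raise ValueError("pressure tensor needs velocities")
    if frame.forces is None:
        raise ValueError(
            "pressure tensor needs forces; without them, provide the pressure "
            "series recorded by the MD engine instead"
        )
    v = frame.velocities
    kinetic = np.einsum("i,ia,ib->ab", topo.masses, v, v)
    virial = np.einsum("ia,ib->ab", frame.positions, frame.forces)
    return (kinetic + virial) / frame.volume * units.PRESSURE_INTERNAL_TO_BAR


def offdiagonal_pressure(p: np.ndarray) -> np.ndarray:
    """Extract the (xy, xz, yz) components of a pressure tensor."""
    p = np.asarray(p)
    return np.array([p[0, 1], p[0, 2], p[1, 2]])


def _frame_dt_ps(frames) -> float:
    times = np.array([f.time for f in frames])
    if len(times) < 2:
        raise ValueError("need at least 2 frames")
    steps = np.diff(times)
    if steps.min() <= 0 or (steps.max() - steps.min()) > 1e-6 * steps.mean():
        raise ValueError("frames must be uniformly sampled in time")
    return float(steps.mean())


def electric_current_series(frames, topo: Topology) -> CurrentSeries:
    """Electric current time series from a frame sequence."""
    dt_ps = _frame_dt_ps(frames)
    j = np.array([electric_current(f, topo) for f in frames])
    return CurrentSeries(values=j.T, dt=dt_ps * 1e3,
                         component_labels=("x", "y", "z"),
                         property_tag="electric_current", units="e*nm/ps")


def pressure_offdiagonal_series(frames, topo: Topology) -> CurrentSeries:
    """Off-diagonal pressure component series (xy, xz, yz) in bar."""
    dt_ps = _frame_dt_ps(frames)
    p = np.array([offdiagonal_pressure(pressure_tensor(f, topo)) for f in frames])
    return CurrentSeries(values=p.T, dt=dt_ps * 1e3,
                         component_labels=("xy", "xz", "yz"),
                         property_tag="pressure_offdiag", units="bar")


def dipole_moment_series(frames, topo: Topology) -> CurrentSeries:
    """Translational dipole moment series M(t) in e nm."""
    dt_ps = _frame_dt_ps(frames)
    m = np.array([dipole_moment(f, topo) for f in frames])
    return CurrentSeries(values=m.T, dt=dt_ps * 1e3,
                         component_labels=("x", "y", "z"),
                         property_tag="dipole_moment", units="e*nm")


def species_velocity_series(frames, topo: Topology,
                            species: str) -> list[CurrentSeries]:
    """Per-molecule COM velocity series for one species.

    Returns one 3-component series per molecule.  Downstream, each
    molecule's intervals are pooled into a single interval set, so with
    n_int intervals per molecule the CAF averages over
    M = n_molecules * n_int intervals.
    """
    mols = topo.molecules_of_species(species)
    dt_ps = _frame_dt_ps(frames)
    v = np.array([com_velocities(f, topo) for f in frames])  # (T, n_mol, 3)
    return [
        CurrentSeries(values=v[:, m].T, dt=dt_ps * 1e3,
                      component_labels=("x", "y", "z"),
                      property_tag="com_velocity", units="nm/ps")
        for m in mols
    ]


def unwrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping of a (T, n, 3) position history.

    Minimum-image heuristic: whenever a per-frame displacement exceeds
    half a box length it is shifted by a whole box vector.  Requires a
    sampling interval short enough that no particle genuinely moves
    more than half a box between frames.
    """
    positions = np.asarray(positions, dtype=np.float64)
    box = np.asarray(box, dtype=np.float64).reshape(1, 1, 3)
    disp = np.diff(positions, axis=0)
    disp -= box * np.round(disp / box)
    out = np.empty_like(positions)
    out[0] = positions[0]
    np.cumsum(disp, axis=0, out=out[1:])
    out[1:] += positions[0]
    return out
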