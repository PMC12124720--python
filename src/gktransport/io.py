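"""On-disk formats: HDF5/CSV current files, CAF/estimate exports,
native text trajectories and replica manifests.

Current file layout (versioned here, v1):

- HDF5: group ``/currents`` with dataset ``values`` (n_components x
  n_steps, float64) and attrs ``dt_fs``, ``property``, ``units``,
  ``component_labels``.  Replicas live under ``/replicas/<name>/currents``
  and per-molecule series (single-particle properties) under
  ``/molecules/<index>/currents`` with the same attrs.
- CSV fallback: header line ``# dt_fs=<v> property=<p> units=<u>
  components=<a,b,c>``, one column per component.

The native trajectory format is extended-XYZ-style text: an atom count
line, a comment line with ``Lattice="lx 0 0 0 ly 0 0 0 lz" time=<ps>
unwrapped=<T|F>``, then per-atom rows ``symbol x y z vx vy vz [fx fy
fz]`` (nm, nm/ps, kJ/mol/nm).  The topology sidecar is a CSV with
columns ``atom,mass,charge,molecule,species``.  Adapters for engine
formats (GROMACS TRR, LAMMPS dump) are expected to convert into these
containers; no engine parsers are bundled.
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import numpy as np
import yaml

from .correlation import CAFResult
from .currents import FrameData, Topology
from .estimator import RunningCoefficient, TransportEstimate
from .series import CurrentSeries

__all__ = [
    "write_current_file",
    "read_current_file",
    "write_current_csv",
    "read_current_csv",
    "write_caf",
    "read_caf",
    "write_estimate",
    "export_gamma_csv",
    "read_manifest",
    "read_topology",
    "write_topology",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
]


def _write_series_group(group: h5py.Group, series: CurrentSeries) -> None:
    g = group.create_group("currents") if "currents" not in group else group["currents"]
    g.create_dataset("values", data=series.values, dtype=np.float64)
    g.attrs["dt_fs"] = float(series.dt)
    g.attrs["property"] = series.property_tag
    g.attrs["units"] = series.units
    g.attrs["component_labels"] = list(series.component_labels)


def _read_series_group(group: h5py.Group) -> CurrentSeries:
    g = group["currents"]
    for attr in ("dt_fs", "property", "units", "component_labels"):
        if attr not in g.attrs:
            raise ValueError(f"current file is missing mandatory attribute {attr!r}")
    return CurrentSeries(
        values=g["values"][...],
        dt=float(g.attrs["dt_fs"]),
        component_labels=tuple(str(c) for c in g.attrs["component_labels"]),
        property_tag=str(g.attrs["property"]),
        units=str(g.attrs["units"]),
    )


def write_current_file(path, series) -> None:
    """Write a current file.

    ``series`` may be a single :class:`CurrentSeries` (stored at
    ``/currents``), a dict name -> series (stored under ``/replicas``)
    or a list of per-molecule series (stored under ``/molecules``).
    """
    with h5py.File(path, "w") as f:
        if isinstance(series, CurrentSeries):
            _write_series_group(f, series)
        elif isinstance(series, dict):
            rep = f.create_group("replicas")
            for name, s in series.items():
                _write_series_group(rep.create_group(str(name)), s)
        elif isinstance(series, (list, tuple)):
            mols = f.create_group("molecules")
            for i, s in enumerate(series):
                _write_series_group(mols.create_group(str(i)), s)
        else:
            raise TypeError(f"cannot store object of type {type(series)}")


def read_current_file(path):
    """Read a current file; returns a series, a dict or a list per layout."""
    with h5py.File(path, "r") as f:
        if "currents" in f:
            return _read_series_group(f)
        if "replicas" in f:
            return {name: _read_series_group(g) for name, g in f["replicas"].items()}
        if "molecules" in f:
            keys = sorted(f["molecules"], key=int)
            return [_read_series_group(f["molecules"][k]) for k in keys]
    raise ValueError(f"{path}: no /currents, /replicas or /molecules group found")


def write_current_csv(path, series: CurrentSeries) -> None:
    header = (
        f"dt_fs={series.dt} property={series.property_tag} "
        f"units={series.units} components={','.join(series.component_labels)}"
    )
    np.savetxt(path, series.values.T, header=header)


def read_current_csv(path) -> CurrentSeries:
    with open(path) as fh:
        first = fh.readline()
    m = re.match(
        r"#\s*dt_fs=(\S+)\s+property=(\S+)\s+units=(\S*)\s+components=(\S+)", first
    )
    if not m:
        raise ValueError(f"{path}: missing '# dt_fs=... property=...' header")
    values = np.loadtxt(path, ndmin=2)
    return CurrentSeries(
        values=values.T,
        dt=float(m.group(1)),
        property_tag=m.group(2),
        units=m.group(3),
        component_labels=tuple(m.group(4).split(",")),
    )


def write_caf(path, result: CAFResult) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("caf")
        g.create_dataset("lags", data=result.lags)
        g.create_dataset("C", data=result.C)
        g.create_dataset("u", data=result.u)
        g.attrs["dt_fs"] = float(result.dt)
        g.attrs["M"] = int(result.M)
        g.attrs["N"] = int(result.N)
        g.attrs["pairs"] = ["".join(p) for p in result.pairs]


def read_caf(path) -> CAFResult:
    with h5py.File(path, "r") as f:
        g = f["caf"]
        pairs = tuple((p[: len(p) // 2], p[len(p) // 2 :]) for p in
                      (str(x) for x in g.attrs["pairs"]))
        return CAFResult(
            lags=g["lags"][...], C=g["C"][...], u=g["u"][...],
            M=int(g.attrs["M"]), N=int(g.attrs["N"]),
            dt=float(g.attrs["dt_fs"]), pairs=pairs,
        )


def write_estimate(path, estimate: TransportEstimate,
                   rc: RunningCoefficient | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("estimate")
        g.attrs["value"] = estimate.value
        g.attrs["uncertainty"] = estimate.uncertainty
        g.attrs["property"] = estimate.property
        g.attrs["units"] = estimate.units
        g.attrs["status"] = estimate.status
        g.attrs["plateau_window_ps"] = list(estimate.plateau_window)
        if rc is not None:
            g.create_dataset("origin_times_ps", data=rc.origin_times)
            g.create_dataset("gamma", data=rc.gamma)
            g.create_dataset("u", data=rc.u)


def export_gamma_csv(path, rc: RunningCoefficient) -> None:
    """CSV of the running coefficient vs averaging origin, for plotting."""
    cols = [rc.origin_times]
    names = ["origin_ps"]
    for i, ch in enumerate(rc.channels):
        cols.extend([rc.gamma[i], rc.u[i]])
        names.extend([f"gamma_{ch}", f"u_{ch}"])
    np.savetxt(path, np.column_stack(cols), header=" ".join(names))


def read_manifest(path) -> dict:
    """Replica manifest: plain-text YAML mapping replica name -> file path.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"{path}: manifest must map replica names to file paths")
    return {str(k): str((path.parent / v)) for k, v in raw.items()}


def write_topology(path, topo: Topology) -> None:
    with open(path, "w") as fh:
        fh.write("atom,mass,charge,molecule,species\n")
        for i in range(topo.n_atoms):
            mol = topo.molecule_of[i]
            sp = topo.species_of[mol] if topo.species_of else ""
            fh.write(f"{i},{topo.masses[i]:.10g},{topo.charges[i]:.10g},{mol},{sp}\n")


def read_topology(path) -> Topology:
    masses, charges, mols, species_by_mol = [], [], [], {}
    with open(path) as fh:
        header = fh.readline().strip().lower().split(",")
        expected = ["atom", "mass", "charge", "molecule", "species"]
        if [h.strip() for h in header] != expected:
            raise ValueError(f"{path}: expected header {','.join(expected)}")
        for line in fh:
            if not line.strip():
                continue
            _, mass, charge, mol, sp = [x.strip() for x in line.split(",")]
            masses.append(float(mass))
            charges.append(float(charge))
            mols.append(int(mol))
            species_by_mol[int(mol)] = sp
    species = tuple(species_by_mol[m] for m in sorted(species_by_mol))
    return Topology(masses=np.array(masses), charges=np.array(charges),
                    molecule_of=np.array(mols), species_of=species)


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"time=(\S+)")
_UNWRAP_RE = re.compile(r"unwrapped=(\S+)")


def write_xyz_trajectory(path, frames, symbols=None) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            n = frame.positions.shape[0]
            syms = symbols if symbols is not None else ["X"] * n
            fh.write(f"{n}\n")
            box = frame.box if frame.box is not None else np.zeros(3)
            lattice = f"{box[0]:.10g} 0 0 0 {box[1]:.10g} 0 0 0 {box[2]:.10g}"
            flag = "T" if frame.unwrapped else "F"
            fh.write(f'Lattice="{lattice}" time={frame.time:.10g} unwrapped={flag}\n')
            for i in range(n):
                row = [f"{syms[i]}"]
                row += [f"{x:.12g}" for x in frame.positions[i]]
                if frame.velocities is not None:
                    row += [f"{x:.12g}" for x in frame.velocities[i]]
                if frame.forces is not None:
                    row += [f"{x:.12g}" for x in frame.forces[i]]
                fh.write(" ".join(row) + "\n")


def read_xyz_trajectory(path) -> list[FrameData]:
    """Read the native extended-XYZ-style text trajectory."""
    frames = []
    with open(path) as fh:
        while True:
            count_line = fh.readline()
            if not count_line.strip():
                break
            n = int(count_line)
            comment = fh.readline()
            m = _LATTICE_RE.search(comment)
            box = None
            if m:
                lat = np.array([float(x) for x in m.group(1).split()])
                box = lat.reshape(3, 3).diagonal().copy()
                if np.all(box == 0):
                    box = None
            tm = _TIME_RE.search(comment)
            time = float(tm.group(1)) if tm else 0.0
            um = _UNWRAP_RE.search(comment)
            unwrapped = bool(um and um.group(1).upper().startswith("T"))
            rows = [fh.readline().split() for _ in range(n)]
            data = np.array([[float(x) for x in row[1:]] for row in rows])
            ncols = data.shape[1]
            if ncols not in (3, 6, 9):
                raise ValueError(
                    f"{path}: expected 3 (positions), 6 (+velocities) or 9 "
                    f"(+forces) numeric columns, got {ncols}"
                )
            frames.append(
                FrameData(
                    positions=data[:, :3],
                    velocities=data[:, 3:6] if ncols >= 6 else None,
                    forces=data[:, 6:9] if ncols == 9 else None,
                    box=box,
                    time=time,
                    unwrapped=unwrapped,
                )
            )
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames
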