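"""File IO: legacy-ASCII VTK snapshots, CSV waveforms, HDF5 checkpoints,
YAML run configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .lpm import BoundaryWaveforms, CycleSolution


def write_vtk_structured(path, spec, scalars=None, vectors=None):
    """Write node-centred fields as a legacy-ASCII VTK structured-points file.

    ``scalars``/``vectors``: dicts name -> array of shape (nx, ny, nz) /
    (nx, ny, nz, 3); arrays are written in physical units as provided.
    """
    scalars = scalars or {}
    vectors = vectors or {}
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    n = nx * ny * nz
    lines = [
        "# vtk DataFile Version 3.0",
        "coaflow field snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {spec.dx} {spec.dx} {spec.dx}",
        f"POINT_DATA {n}",
    ]
    # VTK structured points expect x varying fastest
    for name, arr in scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.asarray(arr).transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.9g}" for v in flat[i:i + 9])
                     for i in range(0, n, 9))
    for name, arr in vectors.items():
        lines.append(f"VECTORS {name} double")
        flat = np.asarray(arr).transpose(2, 1, 0, 3).reshape(-1, 3)
        lines.extend(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in flat)
    Path(path).write_text("\n".join(lines) + "\n")


def write_cycle_csv(path, sol: CycleSolution):
    header = "t,Q_av,P_LV,P_ao,P_desc,V_LV,Q_coa,Q_ub,Q_ar,Q_mv"
    data = np.column_stack([sol.t, sol.Q_av, sol.P_LV, sol.P_ao, sol.P_desc,
                            sol.V_LV, sol.Q_coa, sol.Q_ub, sol.Q_ar,
                            sol.Q_mv])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def write_waveforms_csv(path, waves: BoundaryWaveforms):
    header = "t,Q_inlet,p_outlet,Q_branches_total"
    data = np.column_stack([waves.t, waves.Q_inlet, waves.p_outlet,
                            waves.Q_branches_total])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def read_waveforms_csv(path) -> BoundaryWaveforms:
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = data["t"]
    return BoundaryWaveforms(
        t=t, Q_inlet=data["Q_inlet"], p_outlet=data["p_outlet"],
        Q_branches_total=data["Q_branches_total"], T=float(t[-1] - t[0]))


def checkpoint_save(path, sim):
    """Raw population checkpoint (HDF5)."""
    import h5py

    with h5py.File(path, "w") as h:
        h.create_dataset("f", data=sim.f, compression="gzip")
        h.attrs["step_count"] = sim.step_count
        h.attrs["dx"] = sim.spec.dx
        h.attrs["dt"] = sim.spec.dt


def checkpoint_load(path, sim):
    import h5py

    with h5py.File(path, "r") as h:
        sim.f[...] = h["f"][...]
        sim.step_count = int(h.attrs["step_count"])
    return sim


def load_config(path):
    """Run config from YAML or JSON."""
    import yaml

    from .coupling import RunConfig

    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.from_dict(data)


def save_config(path, config):
    import yaml

    Path(path).write_text(yaml.safe_dump(config.to_dict()))


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
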