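"""Persistence: HDF5 field/trace stores, TOML run configs, JSON manifests."""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import h5py
import numpy as np

from tiesim.cable import MembraneTrace, SimConfig
from tiesim.field import AxonPotentialSeries, PhasorField
from tiesim.pipeline import SweepPlan
from tiesim.stimulus import StimulusSpec


def save_phasor_field(path, field: PhasorField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("potentials", data=field.potentials)
        x, y, z = field.grid.coordinates()
        f.create_dataset("coordinates/x", data=x)
        f.create_dataset("coordinates/y", data=y)
        f.create_dataset("coordinates/z", data=z)
        f.attrs["frequency_hz"] = field.frequency
        f.attrs["source"] = field.source
        f.attrs["spacing_mm"] = field.grid.spacing


def save_axon_series(path, series: AxonPotentialSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("ve_mv", data=series.ve)
        f.create_dataset("times_s", data=series.times)
        f.create_dataset("node_positions_mm", data=series.node_positions)
        f.attrs["axon_id"] = series.axon_id


def load_axon_series(path) -> AxonPotentialSeries:
    with h5py.File(path, "r") as f:
        return AxonPotentialSeries(
            axon_id=int(f.attrs["axon_id"]),
            node_positions=f["node_positions_mm"][()],
            times=f["times_s"][()],
            ve=f["ve_mv"][()])


def save_trace(path, trace: MembraneTrace, stride: int = 1) -> None:
    """Persist a membrane trace, optionally thinned in time."""
    with h5py.File(path, "w") as f:
        f.create_dataset("vm_mv", data=trace.vm[:, ::stride])
        f.create_dataset("times_ms", data=trace.times[::stride])
        f.create_dataset("node_positions_mm", data=trace.node_positions)
        f.attrs["axon_id"] = trace.axon_id
        f.attrs["node_spacing_mm"] = trace.node_spacing
        f.attrs["time_stride"] = stride


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"unsupported TOML value {v!r}")


def dump_config_toml(plan: SweepPlan, stim: StimulusSpec | None = None,
                     config: SimConfig | None = None) -> str:
    """Serialise a run configuration to TOML text."""
    stim = stim or StimulusSpec()
    config = config or SimConfig()
    lines = ["[sweep]"]
    sweep = {
        "carriers_hz": list(plan.carriers),
        "beats_hz": list(plan.beats),
        "array_conditions": [list(c) for c in plan.array_conditions],
        "resolution_mm": plan.resolution,
        "stride": plan.stride,
        "interpolate": plan.interpolate,
    }
    for k, v in sweep.items():
        lines.append(f"{k} = {_toml_value(v)}")
    lines += ["", "[stimulus]"]
    for k, v in (("fc_hz", stim.f1), ("fb_hz", stim.beat),
                 ("a1_ma", stim.a1), ("a2_ma", stim.a2),
                 ("phi1_rad", stim.phi1), ("phi2_rad", stim.phi2)):
        lines.append(f"{k} = {_toml_value(v)}")
    lines += ["", "[simulation]"]
    for k, v in (("dt_s", config.dt), ("t_window_s", config.t_window),
                 ("t_guard_s", config.t_guard), ("l_guard_mm", config.l_guard),
                 ("v_thr_mv", config.v_thr), ("wrapping", config.wrapping)):
        lines.append(f"{k} = {_toml_value(v)}")
    return "\n".join(lines) + "\n"


def load_config_toml(text: str):
    """Parse a TOML run configuration into (SweepPlan, StimulusSpec,
    SimConfig)."""
    data = tomllib.loads(text)
    sw = data.get("sweep", {})
    plan = SweepPlan(
        carriers=tuple(sw.get("carriers_hz", SweepPlan().carriers)),
        beats=tuple(sw.get("beats_hz", SweepPlan().beats)),
        array_conditions=tuple(
            tuple(c) for c in sw.get(
                "array_conditions",
                [list(c) for c in SweepPlan().array_conditions])),
        resolution=sw.get("resolution_mm", SweepPlan().resolution),
        stride=sw.get("stride", 1),
        interpolate=sw.get("interpolate", True),
    )
    st = data.get("stimulus", {})
    fc = st.get("fc_hz", 1000.0)
    fb = st.get("fb_hz", 30.0)
    stim = StimulusSpec(a1=st.get("a1_ma", 0.5), a2=st.get("a2_ma", 0.5),
                        f1=fc, f2=fc + fb, phi1=st.get("phi1_rad", 0.0),
                        phi2=st.get("phi2_rad", 0.0))
    si = data.get("simulation", {})
    config = SimConfig(dt=si.get("dt_s", 10e-6),
                       t_window=si.get("t_window_s", 0.100),
                       t_guard=si.get("t_guard_s", 0.020),
                       l_guard=si.get("l_guard_mm", 1.0),
                       v_thr=si.get("v_thr_mv", -20.0),
                       wrapping=si.get("wrapping", True))
    return plan, stim, config


def write_manifest(path, plan: SweepPlan, scalings: dict,
                   errors: dict | None = None) -> None:
    """JSON run manifest: resolved plan, versions and scaling factors."""
    import tiesim

    manifest = {
        "tiesim_version": tiesim.__version__,
        "plan": {
            "carriers_hz": list(plan.carriers),
            "beats_hz": list(plan.beats),
            "array_conditions": [list(c) for c in plan.array_conditions],
            "resolution_mm": plan.resolution,
            "stride": plan.stride,
            "interpolate": plan.interpolate,
            "scaled_down": plan.stride > 1 or plan.resolution > 0.1,
        },
        "scaling_factors": {
            f"fc{fc:g}_{ori}{ax}": (None if np.isnan(s) else s)
            for (fc, ori, ax), s in scalings.items()
        },
        "errors": {f"fc{fc:g}_{ori}{ax}": e
                   for (fc, ori, ax), e in (errors or {}).items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
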