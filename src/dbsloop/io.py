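"""Run persistence: HDF5 trace containers and scenario configs.

Each simulation run is written to one HDF5 file holding the bipolar
LFP (with sampling-rate metadata), the stimulation current trace, the
controller call log (time, ARV, error, modulated parameter,
activation fraction) and per-population spike rasters, plus the
scenario configuration as attributes.  Configurations round-trip
through YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import yaml

from .experiments import LFP_FS, NetworkRun, ScenarioConfig

__all__ = ["save_run", "load_run", "save_config", "load_config"]


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg)))


def load_config(path: str | Path) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text())
    return ScenarioConfig(**data)


def save_run(run: NetworkRun, cfg: ScenarioConfig, path: str | Path) -> None:
    """Persist one run's traces and config to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = yaml.safe_dump(dataclasses.asdict(cfg))
        g = f.create_group("lfp")
        g.create_dataset("bipolar", data=run.lfp, compression="gzip")
        g.attrs["fs_hz"] = LFP_FS
        f.create_dataset("i_dbs_ma", data=run.i_dbs, compression="gzip")
        f.attrs["dt_ms"] = run.dt_ms
        log = f.create_group("controller")
        log.create_dataset("t_ms", data=run.t_ctrl_ms)
        log.create_dataset("arv", data=run.arv)
        log.create_dataset("e", data=run.e)
        log.create_dataset("u", data=run.u)
        log.create_dataset("fraction_activated", data=run.fraction_activated)
        if run.center_hz is not None:
            log.attrs["center_hz"] = run.center_hz
        if run.b_target is not None:
            log.attrs["b_target"] = run.b_target
        spikes = f.create_group("spikes")
        for name, raster in run.spikes.items():
            spikes.create_dataset(name, data=raster, compression="gzip")


def load_run(path: str | Path) -> tuple[NetworkRun, ScenarioConfig]:
    with h5py.File(path, "r") as f:
        cfg = ScenarioConfig(**yaml.safe_load(f.attrs["config"]))
        log = f["controller"]
        run = NetworkRun(
            lfp=f["lfp/bipolar"][...],
            i_dbs=f["i_dbs_ma"][...],
            t_ctrl_ms=log["t_ms"][...],
            arv=log["arv"][...],
            e=log["e"][...],
            u=log["u"][...],
            fraction_activated=log["fraction_activated"][...],
            spikes={k: f["spikes"][k][...] for k in f["spikes"]},
            dt_ms=float(f.attrs["dt_ms"]),
            center_hz=float(log.attrs["center_hz"]) if "center_hz" in log.attrs else None,
            b_target=float(log.attrs["b_target"]) if "b_target" in log.attrs else None,
        )
    return run, cfg
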