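"""Run configuration, persistence and orchestration.

A run is described by a plain-dict (or YAML) configuration mirroring
``NetworkConfig``; ``run_experiment`` executes simulate -> metrics for every
grid point of a sweep and writes rasters (CSV + JSON sidecar), a metrics JSON
and a manifest sufficient to regenerate everything.  The numbered scripts
under ``analysis/`` drive these functions; they and the library surface are
the package's interface.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .metrics import analyse_run
from .models import IzhikevichParams, find_hopf_current
from .netsim import NetworkConfig, SpikeRaster, simulate_homogeneous
from .synapses import PSCKernel, ReversalSpec

__all__ = [
    "write_raster",
    "read_raster",
    "config_from_dict",
    "config_to_dict",
    "run_experiment",
]


def write_raster(r: SpikeRaster, path: str | Path, meta: dict | None = None) -> None:
    """Two-column CSV (neuron_index, time_ms) plus a JSON sidecar with N,
    duration and any extra metadata."""
    path = Path(path)
    pd.DataFrame({"neuron_index": r.neuron, "time_ms": r.time}).to_csv(path, index=False)
    sidecar = {"N": r.N, "duration_ms": r.duration}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_raster(path: str | Path) -> SpikeRaster:
    """Lossless round trip of :func:`write_raster`.

    Malformed rows are reported with their line number; a sidecar N smaller
    than the maximum neuron index is rejected.
    """
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    try:
        df = pd.read_csv(path, dtype={"neuron_index": np.int64, "time_ms": np.float64})
    except (ValueError, TypeError) as exc:
        # locate the first offending row for the error message
        raw = pd.read_csv(path, dtype=str)
        for i, row in raw.iterrows():
            try:
                int(row["neuron_index"]), float(row["time_ms"])
            except (ValueError, TypeError):
                raise ValueError(f"{path}: malformed row at line {i + 2}") from exc
        raise
    if len(df) and df["neuron_index"].max() >= sidecar["N"]:
        raise ValueError(
            f"{path}: sidecar N={sidecar['N']} smaller than max neuron index "
            f"{df['neuron_index'].max()}"
        )
    return SpikeRaster(
        df["neuron_index"].to_numpy(), df["time_ms"].to_numpy(),
        int(sidecar["N"]), float(sidecar["duration_ms"]),
    )


_CONFIG_FIELDS = {
    "model", "N", "J", "sigma", "Iext", "synapse_mode", "dt",
    "t_total", "t_transient", "seed", "record_dt",
}


def config_from_dict(d: dict[str, Any]) -> NetworkConfig:
    """Build a validated NetworkConfig from a plain dict (YAML-friendly).

    Unknown keys and invariant violations raise ValueError naming the field.
    """
    d = dict(d)
    kern = d.pop("kernel", None)
    rev = d.pop("reversal", None)
    unknown = set(d) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = dict(d)
    if kern is not None:
        kwargs["kernel"] = PSCKernel(**kern)
    if rev is not None:
        kwargs["reversal"] = ReversalSpec(**rev)
    try:
        return NetworkConfig(**kwargs)
    except ValueError as exc:
        msg = str(exc)
        for f in ("t_transient", "dt", "N"):
            if f in msg:
                raise ValueError(f"invalid config field {f!r}: {msg}") from exc
        raise


def config_to_dict(cfg: NetworkConfig) -> dict[str, Any]:
    d = {f: getattr(cfg, f) for f in sorted(_CONFIG_FIELDS)}
    d["kernel"] = {
        "tauL": cfg.kernel.tauL, "tauR": cfg.kernel.tauR,
        "tauD": cfg.kernel.tauD, "mode": cfg.kernel.mode,
    }
    d["reversal"] = asdict(cfg.reversal)
    return d


def _config_hash(d: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_experiment(config: dict[str, Any] | str | Path, out_dir: str | Path) -> dict:
    """Execute one run (or a small sweep) and persist raster, metrics, manifest.

    ``config`` is a dict or a YAML path with NetworkConfig fields; list-valued
    ``J``, ``sigma`` or ``Iext`` entries define a grid (outer product).  Each
    grid point writes ``raster_<tag>.csv``(+json) and its metrics; the
    manifest records the resolved configs and hashes so any result is
    regenerable from the manifest alone.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    assert isinstance(config, dict)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grids = {
        k: (list(config[k]) if isinstance(config.get(k), (list, tuple)) else [config.get(k)])
        for k in ("J", "sigma", "Iext")
    }
    base = {k: v for k, v in config.items() if k not in ("J", "sigma", "Iext")}
    i_ah = find_hopf_current(IzhikevichParams()) if base.get("model", "izhikevich") == "izhikevich" else None
    manifest: dict[str, Any] = {"runs": []}
    results = {}
    for J in grids["J"]:
        for sigma in grids["sigma"]:
            for Iext in grids["Iext"]:
                d = dict(base)
                for k, v in (("J", J), ("sigma", sigma), ("Iext", Iext)):
                    if v is not None:
                        d[k] = v
                cfg = config_from_dict(d)
                tag = _config_hash(config_to_dict(cfg))
                done = out / f"metrics_{tag}.json"
                if done.exists():  # resumable: completed grid points are kept
                    manifest["runs"].append({"tag": tag, "config": config_to_dict(cfg)})
                    continue
                res = simulate_homogeneous(cfg)
                regime = analyse_run(res, I_AH=i_ah)
                write_raster(res.raster, out / f"raster_{tag}.csv",
                             meta={"config": config_to_dict(cfg)})
                (out / f"metrics_{tag}.json").write_text(
                    json.dumps(regime.to_dict(), indent=1)
                )
                manifest["runs"].append(
                    {"tag": tag, "config": config_to_dict(cfg)}
                )
                results[tag] = regime
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results
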