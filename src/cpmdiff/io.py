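"""Configuration parsing, run archives and report serialisation.

A run archive is a single HDF5 container holding everything needed to
re-analyse the run without re-simulating it: the resolved configuration (as
YAML text plus a SHA-256 hash), the master seed, the sampled owner maps and
medium fields, the per-sample cell table, acceptance / convergence /clamp
counters and the pattern report JSON.  The ``report`` CLI subcommand
recomputes the report from the archive alone and must reproduce it byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import ConfigurationError
from .metrics import PatternReport
from .scenarios import Perturbation, ScenarioConfig, SimResult

_SECTIONS = ("scenario", "init", "params", "perturbation")

# mapping between the file layout (sectioned) and ScenarioConfig fields
_INIT_KEYS = {"A0": "A0", "I0": "I0", "noise": "init_noise", "medium_I0": "medium_I0"}


def config_from_mapping(raw: dict[str, Any]) -> ScenarioConfig:
    """Validate and resolve a parsed config mapping into a ScenarioConfig."""
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    fields: dict[str, Any] = dict(raw.get("scenario") or {})
    init = raw.get("init") or {}
    bad = set(init) - set(_INIT_KEYS)
    if bad:
        raise ConfigurationError(f"unknown init keys: {sorted(bad)}")
    for k, v in init.items():
        fields[_INIT_KEYS[k]] = v
    params = raw.get("params") or {}
    if not isinstance(params, dict):
        raise ConfigurationError("params section must be a mapping")
    fields["param_overrides"] = params
    if raw.get("perturbation"):
        fields["perturbation"] = Perturbation(**dict(raw["perturbation"]))
    cfg = ScenarioConfig.from_dict(fields)
    cfg.model_params()  # force parameter validation (dt bounds, ranges, ...)
    return cfg


def config_to_mapping(cfg: ScenarioConfig) -> dict[str, Any]:
    d = cfg.to_dict()
    pert = d.pop("perturbation")
    init = {
        "A0": d.pop("A0"),
        "I0": d.pop("I0"),
        "noise": d.pop("init_noise"),
        "medium_I0": d.pop("medium_I0"),
    }
    params = d.pop("param_overrides")
    out: dict[str, Any] = {"scenario": d, "init": init, "params": params}
    if pert:
        out["perturbation"] = pert
    return out


def parse_config(path: str | Path) -> ScenarioConfig:
    """Parse and validate a scenario config file (YAML)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return config_from_mapping(yaml.safe_load(path.read_text()))


def write_config(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_mapping(cfg), sort_keys=True, default_flow_style=None)
    )


def config_hash(cfg: ScenarioConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# archives
# ---------------------------------------------------------------------------


def write_archive(
    result: SimResult, report: PatternReport, path: str | Path
) -> None:
    cfg = ScenarioConfig.from_dict(result.config)
    with h5py.File(path, "w") as h5:
        h5.attrs["config_yaml"] = yaml.safe_dump(
            config_to_mapping(cfg), sort_keys=True
        )
        h5.attrs["config_hash"] = config_hash(cfg)
        h5.attrs["seed"] = int(result.seed)
        h5.attrs["clamp_events"] = int(result.clamp_events)
        h5.attrs["report_json"] = report.to_json()
        h5.create_dataset("sample_steps", data=result.sample_steps)
        h5.create_dataset("owners", data=result.owners, compression="gzip")
        h5.create_dataset("fields", data=result.fields, compression="gzip")
        h5.create_dataset("acceptance", data=result.acceptance)
        h5.create_dataset("convergence", data=result.convergence)
        g = h5.create_group("cell_table")
        for col in ("step", "cell_id", "volume", "A", "I", "type"):
            g.create_dataset(col, data=result.table[col].to_numpy())


def load_archive(path: str | Path) -> tuple[SimResult, dict[str, Any]]:
    """Load an archive; returns (SimResult, stored report dict)."""
    with h5py.File(path, "r") as h5:
        cfg = config_from_mapping(yaml.safe_load(h5.attrs["config_yaml"]))
        table = pd.DataFrame(
            {col: h5["cell_table"][col][:] for col in h5["cell_table"]}
        )
        result = SimResult(
            config=cfg.to_dict(),
            seed=int(h5.attrs["seed"]),
            sample_steps=h5["sample_steps"][:],
            owners=h5["owners"][:],
            fields=h5["fields"][:],
            table=table,
            acceptance=h5["acceptance"][:],
            convergence=h5["convergence"][:],
            clamp_events=int(h5.attrs["clamp_events"]),
        )
        report = json.loads(h5.attrs["report_json"])
    return result, report


def write_cell_table(result: SimResult, path: str | Path) -> None:
    result.table.to_csv(path, index=False)


def render_snapshot(result: SimResult, k: int, path: str | Path) -> None:
    """Optional rendered image of sample k: cells coloured by type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    owner = result.owners[k]
    tau = result.types_at(k)
    img = np.zeros(owner.shape, dtype=np.int8)
    cells = owner > 0
    img[cells] = tau[owner[cells]]
    img[owner == -1] = 3
    cmap = ListedColormap(["black", "#2060c0", "#c03030", "green"])
    fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
    ax.imshow(img, cmap=cmap, vmin=0, vmax=3, interpolation="nearest")
    ax.set_title(f"step {int(result.sample_steps[k])}")
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
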