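"""Scenario configuration, aggregate initialisation and the simulation driver.

A scenario crosses three ingredients:

* population: a single cell, or a compact aggregate of identical cells
  seeded as equal square blocks tiling a centred rectangle in the medium;
* adhesion: ``high`` (cells immobilised: no index-copy attempts at all),
  ``low`` (mobile cells that prefer mutual contact, J_cc < 2 J_cm) or
  ``none`` (mobile cells that energetically prefer medium contact,
  J_cc >= 2 J_cm, and disperse);
* communication: ``direct`` (contact coupling, s = 0), ``indirect``
  (medium-mediated, d = 0) or ``mixed`` (both channels on).

All cells are identical in parameters and start from the same initial
concentrations apart from a tiny seeded multiplicative jitter
(``init.noise``, default 1%).  The population is statistically homogeneous:
the jitter carries no spatial information, it only breaks the exact
permutation symmetry of otherwise bit-identical cells so that the
lateral-inhibition instability of the coupled network can select winners
(see docs/methods.md).

Each Monte-Carlo step runs one cycle in a fixed order: index-copy attempts
(skipped entirely when every cell is fixed), then ``ode_substeps``
interleaved medium/network forward-Euler sub-steps, then the type update.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field, asdict
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import (
    Cells,
    ConfigurationError,
    Lattice,
    ModelParams,
    contact_pairs,
    make_J,
    monte_carlo_step,
)
from .medium import MediumField, boundary_map, pde_step
from .network import NetworkState, classify, euler_step

ADHESION_LEVELS = ("none", "low", "high")
#: "none" is the uncoupled control (s = d = 0)
COMMUNICATION_MODES = ("none", "direct", "indirect", "mixed")
POPULATIONS = ("single_cell", "aggregate")

# frozen adhesion regimes: contact energies and membrane temperature.
# low: J_cc < 2 J_cm, mutual contact preferred; cells rearrange slowly;
# none: J_cc >= 2 J_cm, separating two cells lowers the energy, so cells
# stay dispersed.
_ADHESION = {
    "high": dict(j_cc=4.0, j_cm=8.0, T=5.0, fixed=True),
    "low": dict(j_cc=4.0, j_cm=8.0, T=5.0, fixed=False),
    "none": dict(j_cc=16.0, j_cm=5.0, T=8.0, fixed=False),
}

# frozen communication rates (see docs/methods.md for the calibration)
S_RATE = 4.0
D_RATE = 0.7
_COMMUNICATION = {
    "none": dict(s=0.0, d=0.0),
    "direct": dict(s=0.0, d=D_RATE),
    "indirect": dict(s=S_RATE, d=0.0),
    "mixed": dict(s=S_RATE, d=D_RATE),
}


@dataclass
class Perturbation:
    """Transient perturbation: at ``step`` reset the concentrations of a
    random ``fraction`` of cells to the configured initial values."""

    step: int
    fraction: float = 0.2


@dataclass
class ScenarioConfig:
    name: str = "scenario"
    adhesion: str = "high"
    communication: str = "direct"
    population: str = "aggregate"
    #: "compact": contiguous aggregate; "dispersed": scattered, for the
    #: non-adhesive scenarios in which cells do not form an aggregate
    placement: str = "compact"
    n_cells: int = 49
    cell_size: int = 6
    lattice: tuple[int, int] = (100, 100)
    mcs_total: int = 30000
    sample_interval: int = 600
    seed: int = 7
    A0: float = 1.5
    I0: float = 1.25
    init_noise: float = 0.01
    medium_I0: float = 0.0
    param_overrides: dict[str, Any] = dc_field(default_factory=dict)
    perturbation: Perturbation | None = None

    def __post_init__(self) -> None:
        if self.adhesion not in ADHESION_LEVELS:
            raise ConfigurationError(f"unknown adhesion level {self.adhesion!r}")
        if self.communication not in COMMUNICATION_MODES:
            raise ConfigurationError(
                f"unknown communication mode {self.communication!r}"
            )
        if self.population not in POPULATIONS:
            raise ConfigurationError(f"unknown population {self.population!r}")
        if self.placement not in ("compact", "dispersed"):
            raise ConfigurationError(f"unknown placement {self.placement!r}")
        if self.population == "single_cell":
            self.n_cells = 1
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        comm = _COMMUNICATION[self.communication]
        for key in ("s", "d"):
            if key in self.param_overrides:
                want_on = comm[key] > 0
                got_on = float(self.param_overrides[key]) > 0
                if want_on != got_on:
                    raise ConfigurationError(
                        f"override {key}={self.param_overrides[key]} contradicts "
                        f"communication={self.communication!r}"
                    )
        if self.perturbation is not None and not isinstance(
            self.perturbation, Perturbation
        ):
            self.perturbation = Perturbation(**dict(self.perturbation))

    def model_params(self) -> ModelParams:
        """Resolve adhesion level, communication mode and overrides into the
        full parameter set."""
        adh = _ADHESION[self.adhesion]
        kwargs: dict[str, Any] = dict(
            J=make_J(adh["j_cc"], adh["j_cm"]),
            T=adh["T"],
            **_COMMUNICATION[self.communication],
        )
        overrides = dict(self.param_overrides)
        if {"j_cc", "j_cm"} & overrides.keys():
            kwargs["J"] = make_J(
                float(overrides.pop("j_cc", adh["j_cc"])),
                float(overrides.pop("j_cm", adh["j_cm"])),
            )
        kwargs.update(overrides)
        return ModelParams(**kwargs)

    @property
    def all_fixed(self) -> bool:
        return self.adhesion == "high"

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["lattice"] = list(self.lattice)
        return d

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ScenarioConfig":
        raw = dict(raw)
        if "lattice" in raw:
            raw["lattice"] = tuple(raw["lattice"])
        if raw.get("perturbation"):
            raw["perturbation"] = Perturbation(**dict(raw["perturbation"]))
        else:
            raw.pop("perturbation", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def preset(scenario: str, **overrides: Any) -> ScenarioConfig:
    """Load a frozen packaged scenario configuration by name; keyword
    arguments override the resolved config fields (including ``name``)."""
    ref = importlib.resources.files("cpmdiff.configs").joinpath(f"{scenario}.yaml")
    if not ref.is_file():
        raise ConfigurationError(f"no packaged scenario named {scenario!r}")
    from .io import config_from_mapping

    cfg = config_from_mapping(yaml.safe_load(ref.read_text()))
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def preset_names() -> list[str]:
    ref = importlib.resources.files("cpmdiff.configs")
    return sorted(
        p.name[: -len(".yaml")]
        for p in ref.iterdir()
        if p.name.endswith(".yaml") and not p.name.startswith("grid")
    )


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def init_aggregate(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[Lattice, Cells, MediumField]:
    """Seed the initial state: a centred compact aggregate of equal square
    cells surrounded by medium, a uniform medium field, and identical
    intracellular concentrations (up to the configured jitter).

    Compact placement tiles cells into a near-square block row-major; with a
    non-square count the last row is left-aligned and partially filled,
    keeping the aggregate contiguous.  Dispersed placement (the non-adhesive
    scenarios, in which no aggregate forms) scatters the same square cells
    over a jittered grid of well-separated slots.
    """
    H, W = cfg.lattice
    n, cs = cfg.n_cells, cfg.cell_size
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lat = Lattice.empty(H, W)
    if cfg.placement == "dispersed":
        slots_per_side = int(np.ceil(np.sqrt(n)))
        pitch = (min(H, W) - 2 - cs) // slots_per_side
        if pitch < cs + 1:
            raise ConfigurationError(
                f"{n} dispersed cells of {cs}x{cs} pixels do not fit a "
                f"{H}x{W} lattice with separation"
            )
        chosen = rng.choice(slots_per_side**2, size=n, replace=False)
        jitter_max = max(1, pitch - cs - 1)
        for k, slot in enumerate(np.sort(chosen)):
            rr, cc = divmod(int(slot), slots_per_side)
            i = 1 + rr * pitch + int(rng.integers(0, jitter_max))
            j = 1 + cc * pitch + int(rng.integers(0, jitter_max))
            lat.owner[i : i + cs, j : j + cs] = k + 1
    else:
        cols = int(np.ceil(np.sqrt(n)))
        rows = int(np.ceil(n / cols))
        if rows * cs > H - 4 or cols * cs > W - 4:
            raise ConfigurationError(
                f"{n} cells of {cs}x{cs} pixels do not fit a {H}x{W} lattice "
                "with a medium margin"
            )
        r0 = (H - rows * cs) // 2
        c0 = (W - cols * cs) // 2
        for k in range(n):
            rr, cc = divmod(k, cols)
            i = r0 + rr * cs
            j = c0 + cc * cs
            lat.owner[i : i + cs, j : j + cs] = k + 1

    cells = Cells.uniform(
        n, target_volume=cs * cs, A0=cfg.A0, I0=cfg.I0, fixed=cfg.all_fixed
    )
    if cfg.init_noise > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        # multiplicative log-normal jitter: strictly positive, mean ~ A0
        cells.A[1:] *= np.exp(cfg.init_noise * rng.standard_normal(n))
        cells.I[1:] *= np.exp(cfg.init_noise * rng.standard_normal(n))
    field = MediumField.uniform(lat, cfg.medium_I0)
    return lat, cells, field


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """In-memory trajectory archive of one scenario run."""

    config: dict[str, Any]
    seed: int
    sample_steps: np.ndarray  # (k,)
    owners: np.ndarray  # (k, H, W) int32
    fields: np.ndarray  # (k, H, W) float64
    table: pd.DataFrame  # step, cell_id, volume, A, I, type
    acceptance: np.ndarray  # accepted copies between consecutive samples
    convergence: np.ndarray  # type-label Hamming fraction vs previous sample
    clamp_events: int

    def types_at(self, k: int) -> np.ndarray:
        """Per-cell type codes (length n_cells + 1) at sample index k."""
        step = int(self.sample_steps[k])
        sub = self.table[self.table["step"] == step].sort_values("cell_id")
        tau = np.zeros(len(sub) + 1, dtype=np.int8)
        tau[sub["cell_id"].to_numpy()] = sub["type"].to_numpy()
        return tau

    @property
    def n_samples(self) -> int:
        return len(self.sample_steps)


class Simulation:
    """Mutable state of one running scenario."""

    def __init__(self, cfg: ScenarioConfig, seed: int | None = None) -> None:
        self.cfg = cfg
        self.seed = int(cfg.seed if seed is None else seed)
        self.params = cfg.model_params()
        self.rng = np.random.default_rng(self.seed)
        self.lat, self.cells, self.field = init_aggregate(cfg, self.rng)
        self.net = NetworkState.from_cells(self.cells)
        self.step_count = 0
        self.static = cfg.all_fixed
        self._refresh_geometry()

    def _refresh_geometry(self) -> None:
        self.pairs = contact_pairs(self.lat.owner, self.cells.n_cells)
        self.bmap = boundary_map(self.lat.owner, self.cells.n_cells)

    def apply_perturbation(self) -> None:
        """Reset A, I of a random fraction of cells to the configured
        initial values (the transient-perturbation probe)."""
        pert = self.cfg.perturbation
        n = self.cells.n_cells
        k = max(1, int(round(pert.fraction * n)))
        chosen = self.rng.choice(np.arange(1, n + 1), size=k, replace=False)
        self.net.A[chosen] = self.cfg.A0
        self.net.I[chosen] = self.cfg.I0
        self.cells.A, self.cells.I = self.net.A, self.net.I

    def step(self) -> int:
        """One full Monte-Carlo cycle: copies -> medium/network -> types."""
        accepted = 0
        if not self.static:
            accepted = monte_carlo_step(
                self.lat, self.cells, self.params, self.rng, self.field.values
            )
            self._refresh_geometry()
            self.net.A, self.net.I = self.cells.A, self.cells.I
        for _ in range(self.params.ode_substeps):
            iext, has = pde_step(
                self.field, self.lat, self.net, self.params, self.bmap
            )
            self.net.I_ext, self.net.has_boundary = iext, has
            euler_step(self.net, self.pairs, self.params, 1)
        self.cells.A, self.cells.I = self.net.A, self.net.I
        self.tau = classify(self.net)
        self.step_count += 1
        return accepted

    def _snapshot_rows(self) -> pd.DataFrame:
        n = self.cells.n_cells
        return pd.DataFrame(
            {
                "step": self.step_count,
                "cell_id": np.arange(1, n + 1),
                "volume": self.cells.volume[1:],
                "A": self.cells.A[1:],
                "I": self.cells.I[1:],
                "type": self.cells.cell_type[1:],
            }
        )

    def run(self) -> SimResult:
        cfg = self.cfg
        steps, owners, fields, rows = [], [], [], []
        acc_between, accs, conv = 0, [], []
        prev_tau = None

        def sample() -> None:
            nonlocal acc_between, prev_tau
            steps.append(self.step_count)
            owners.append(self.lat.owner.copy())
            fields.append(self.field.values.copy())
            rows.append(self._snapshot_rows())
            accs.append(acc_between)
            acc_between = 0
            tau = self.cells.cell_type[1:]
            conv.append(
                float(np.mean(tau != prev_tau)) if prev_tau is not None else np.nan
            )
            prev_tau = tau

        self.tau = classify(self.net)
        sample()
        for step in range(1, cfg.mcs_total + 1):
            if cfg.perturbation is not None and step == cfg.perturbation.step:
                self.apply_perturbation()
            acc_between += self.step()
            if step % cfg.sample_interval == 0 or step == cfg.mcs_total:
                sample()
        return SimResult(
            config=cfg.to_dict(),
            seed=self.seed,
            sample_steps=np.asarray(steps, dtype=np.int64),
            owners=np.stack(owners),
            fields=np.stack(fields),
            table=pd.concat(rows, ignore_index=True),
            acceptance=np.asarray(accs, dtype=np.int64),
            convergence=np.asarray(conv, dtype=np.float64),
            clamp_events=self.net.clamp_events,
        )


def run_scenario(cfg: ScenarioConfig, seed: int | None = None):
    """Run one scenario end to end; returns (SimResult, PatternReport)."""
    from .metrics import compute_report

    result = Simulation(cfg, seed=seed).run()
    report = compute_report(result)
    return result, report


def run_grid(
    configs: list[ScenarioConfig], master_seed: int = 0
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Run a collection of scenarios with per-scenario seeds derived from a
    master seed; failures are recorded and the grid continues.

    Returns (summary table, {name: (result, report) | {"error": ...}}).
    """
    seeds = [
        int(ss.generate_state(1)[0] % 2**31)
        for ss in np.random.SeedSequence(master_seed).spawn(len(configs))
    ]
    outputs: dict[str, Any] = {}
    summary_rows = []
    for cfg, seed in zip(configs, seeds):
        row: dict[str, Any] = {
            "scenario": cfg.name,
            "adhesion": cfg.adhesion,
            "communication": cfg.communication,
            "seed": seed,
        }
        try:
            result, report = run_scenario(cfg, seed=seed)
        except Exception as exc:  # grid keeps going; the failure is the record
            outputs[cfg.name] = {"error": f"{type(exc).__name__}: {exc}"}
            row["error"] = str(exc)
        else:
            outputs[cfg.name] = (result, report)
            row.update(report.summary_row())
        summary_rows.append(row)
    return pd.DataFrame(summary_rows), outputs
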