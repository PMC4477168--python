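"""Shared fixtures: small hand-built lattices, synthetic results, and a
session-wide cache of full scenario runs (each frozen scenario is simulated
once and shared by every test that asserts something about it)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cpmdiff import Lattice, ModelParams, SimResult, make_J, preset, run_scenario
from cpmdiff.core import T_BLUE


def build_lattice(height, width, assignments):
    """Empty lattice with a frontier ring; ``assignments`` maps cell-id to a
    list of (i, j) pixels."""
    lat = Lattice.empty(height, width)
    for cid, pixels in assignments.items():
        for i, j in pixels:
            lat.owner[i, j] = cid
    return lat


def random_lattice(rng, max_side=20, n_cells=4):
    """Random owner map: each interior pixel medium or one of n_cells cells
    (cells may be fragmented; the energy functions do not require
    connectivity)."""
    h = int(rng.integers(6, max_side + 1))
    w = int(rng.integers(6, max_side + 1))
    lat = Lattice.empty(h, w)
    interior = lat.owner[1:-1, 1:-1]
    interior[...] = rng.integers(0, n_cells + 1, size=interior.shape)
    # ensure every cell id owns at least one pixel
    flat = interior.reshape(-1)
    for cid in range(1, n_cells + 1):
        if not (flat == cid).any():
            flat[int(rng.integers(0, flat.size))] = cid
    return lat


def make_cells_for(lat, n_cells, rng=None, lam_target=None):
    """Cells container consistent with the lattice's current owner map."""
    from cpmdiff import Cells

    counts = lat.recount_volumes(n_cells)
    cells = Cells.uniform(n_cells, target_volume=1, A0=1.0, I0=1.0)
    cells.volume = counts.copy()
    if lam_target is not None:
        cells.target_volume = np.full(n_cells + 1, lam_target, dtype=np.int64)
        cells.target_volume[0] = 0
    else:
        cells.target_volume = counts.copy()
    if rng is not None:
        cells.A[1:] = rng.uniform(0.5, 2.0, n_cells)
        cells.I[1:] = rng.uniform(0.5, 2.0, n_cells)
    return cells


def synthetic_result(owner, types, seed=0, n_samples=2, types_list=None):
    """SimResult with ``n_samples`` identical snapshots of a hand-built
    pattern (``types``: per-cell type codes for cells 1..n)."""
    owner = np.asarray(owner, dtype=np.int32)
    n = int(owner.max())
    rows = []
    steps = list(range(n_samples))
    per_sample = types_list or [types] * n_samples
    for step, tau in zip(steps, per_sample):
        tau = np.asarray(tau)
        rows.append(
            pd.DataFrame(
                {
                    "step": step,
                    "cell_id": np.arange(1, n + 1),
                    "volume": [int((owner == c).sum()) for c in range(1, n + 1)],
                    "A": np.where(tau == T_BLUE, 2.0, 0.5),
                    "I": 1.0,
                    "type": tau,
                }
            )
        )
    return SimResult(
        config={},
        seed=seed,
        sample_steps=np.asarray(steps, dtype=np.int64),
        owners=np.stack([owner] * n_samples),
        fields=np.zeros((n_samples,) + owner.shape),
        table=pd.concat(rows, ignore_index=True),
        acceptance=np.zeros(n_samples, dtype=np.int64),
        convergence=np.full(n_samples, np.nan),
        clamp_events=0,
    )


def unit_cell_block(side=5, margin=2):
    """(side x side) block of 1-pixel cells, ids row-major from 1."""
    size = side + 2 * margin
    lat = Lattice.empty(size, size)
    for r in range(side):
        for c in range(side):
            lat.owner[margin + r, margin + c] = r * side + c + 1
    return lat


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def basic_params():
    return ModelParams(J=make_J(4.0, 8.0), lam=2.0, T=6.0)


def tiny_config(**overrides):
    """A fast mobile scenario for plumbing tests (~1 s)."""
    kw = dict(
        lattice=(36, 36),
        n_cells=9,
        cell_size=4,
        mcs_total=40,
        sample_interval=10,
        adhesion="low",
        communication="mixed",
        name="tiny",
        seed=3,
    )
    kw.update(overrides)
    return preset("low_mixed", **kw)


@pytest.fixture(scope="session")
def runs():
    """Session cache of full scenario runs keyed by (preset, overrides)."""
    cache = {}

    def get(name, **overrides):
        key = (name, repr(sorted(overrides.items())))
        if key not in cache:
            cache[key] = run_scenario(preset(name, **overrides))
        return cache[key]

    return get
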