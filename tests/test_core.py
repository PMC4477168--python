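"""Lattice, effective energy and Metropolis index-copy dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpmdiff import (
    Cells,
    Lattice,
    ModelParams,
    ParameterError,
    accept_probability,
    boundary_energy,
    contact_neighbors,
    delta_H,
    make_J,
    monte_carlo_step,
    total_energy,
    volume_energy,
)
from cpmdiff.core import FRONTIER, MOORE, VON_NEUMANN, ConfigurationError

from conftest import build_lattice, make_cells_for, random_lattice


def force_types(cells, types):
    """Set A, I so that cells.cell_type equals the requested codes."""
    for cid, t in types.items():
        cells.A[cid], cells.I[cid] = (2.0, 1.0) if t == 1 else (1.0, 2.0)


class TestBoundaryEnergy:
    def test_single_heterotypic_contact(self):
        # two 1-pixel cells side by side; medium contacts zeroed out
        lat = build_lattice(3, 4, {1: [(1, 1)], 2: [(1, 2)]})
        cells = make_cells_for(lat, 2)
        force_types(cells, {1: 1, 2: 2})
        J = np.zeros((3, 3))
        J[1, 2] = J[2, 1] = 10.0
        params = ModelParams(J=J)
        assert boundary_energy(lat, cells, params) == pytest.approx(10.0)

    def test_perimeter_counts_against_brute_force(self, rng):
        # one cell in medium: energy must equal J_cm times the number of
        # cell-medium neighbour pairs, counted by exhaustive enumeration
        lat = random_lattice(rng, max_side=12, n_cells=1)
        cells = make_cells_for(lat, 1)
        params = ModelParams(J=make_J(0.0, 4.0))
        owner = lat.owner
        pairs = 0
        H, W = owner.shape
        for i in range(H):
            for j in range(W):
                for di, dj in ((0, 1), (1, 0)):
                    ii, jj = i + di, j + dj
                    if ii >= H or jj >= W:
                        continue
                    a, b = owner[i, j], owner[ii, jj]
                    if a != b and FRONTIER not in (a, b):
                        pairs += 1
        assert boundary_energy(lat, cells, params) == pytest.approx(4.0 * pairs)

    def test_single_owner_has_zero_boundary(self):
        lat = Lattice.empty(6, 6)
        lat.owner[1:-1, 1:-1] = 1
        cells = make_cells_for(lat, 1)
        params = ModelParams(J=make_J(7.0, 3.0))
        assert boundary_energy(lat, cells, params) == 0.0

    def test_missing_J_entry_is_configuration_error(self):
        lat = build_lattice(3, 4, {1: [(1, 1)], 2: [(1, 2)]})
        cells = make_cells_for(lat, 2)
        force_types(cells, {1: 1, 2: 2})
        params = ModelParams()
        params.J = np.full((3, 3), np.nan)  # entries never provided
        with pytest.raises(ConfigurationError, match="type pair"):
            boundary_energy(lat, cells, params)


class TestVolumeEnergy:
    @pytest.mark.parametrize(
        "lam,volumes,targets,expected",
        [
            (1.0, [4, 9], [4, 9], 0.0),  # at target
            (1.0, [6], [4], 4.0),  # (6-4)^2
            (2.0, [5, 1], [4, 4], 2 * (1 + 9)),  # deviations +1, -3
        ],
    )
    def test_elastic_term(self, lam, volumes, targets, expected):
        n = len(volumes)
        cells = Cells.uniform(n, target_volume=1, A0=1, I0=1)
        cells.volume[1:] = volumes
        cells.target_volume[1:] = targets
        params = ModelParams(lam=lam)
        assert volume_energy(cells, params) == pytest.approx(expected)


class TestDeltaH:
    def test_matches_global_recompute(self, rng):
        """Incremental dH equals before/after global energy difference on
        >= 1000 random proposals over random lattices (tol 1e-9)."""
        checked = 0
        while checked < 1000:
            n_cells = int(rng.integers(2, 6))
            lat = random_lattice(rng, max_side=20, n_cells=n_cells)
            cells = make_cells_for(lat, n_cells, rng=rng, lam_target=5)
            params = ModelParams(
                J=make_J(float(rng.uniform(1, 10)), float(rng.uniform(1, 10))),
                lam=float(rng.uniform(0.5, 3.0)),
            )
            H, W = lat.owner.shape
            for _ in range(40):
                i = int(rng.integers(1, H - 1))
                j = int(rng.integers(1, W - 1))
                di, dj = MOORE[int(rng.integers(0, 8))]
                ti, tj = i + di, j + dj
                so, to = int(lat.owner[i, j]), int(lat.owner[ti, tj])
                if so == to or FRONTIER in (so, to):
                    continue
                before = total_energy(lat, cells, params)
                dh = delta_H(lat, cells, params, (i, j), (ti, tj))
                lat.owner[ti, tj] = so
                if to > 0:
                    cells.volume[to] -= 1
                if so > 0:
                    cells.volume[so] += 1
                after = total_energy(lat, cells, params)
                # restore
                lat.owner[ti, tj] = to
                if to > 0:
                    cells.volume[to] += 1
                if so > 0:
                    cells.volume[so] -= 1
                assert dh == pytest.approx(after - before, abs=1e-9)
                checked += 1

    def test_annihilating_copy_includes_volume_jump(self):
        # removing a 1-pixel cell's last pixel: volume term jumps by
        # lam[(0-vt)^2 - (1-vt)^2]
        lat = build_lattice(3, 4, {1: [(1, 1)], 2: [(1, 2)]})
        cells = make_cells_for(lat, 2, lam_target=4)
        params = ModelParams(J=np.zeros((3, 3)), lam=1.0)
        dh = delta_H(lat, cells, params, (1, 1), (1, 2))
        expected = ((0 - 4) ** 2 - (1 - 4) ** 2) + ((2 - 4) ** 2 - (1 - 4) ** 2)
        assert dh == pytest.approx(expected)

    def test_same_owner_copy_is_a_precondition_error(self):
        lat = build_lattice(3, 4, {1: [(1, 1), (1, 2)]})
        cells = make_cells_for(lat, 1)
        with pytest.raises(ValueError, match="change ownership"):
            delta_H(lat, cells, ModelParams(), (1, 1), (1, 2))


class TestAcceptProbability:
    @pytest.mark.parametrize(
        "dh,T,expected",
        [(-5.0, 1.0, 1.0), (0.0, 3.0, 1.0), (2.0, 2.0, math.exp(-1))],
    )
    def test_boltzmann_rule(self, dh, T, expected):
        assert accept_probability(dh, T) == pytest.approx(expected)

    @pytest.mark.parametrize("T", [0.0, -1.0])
    def test_nonpositive_temperature_rejected(self, T):
        with pytest.raises(ParameterError):
            accept_probability(1.0, T)

    @given(
        dh=st.floats(-50, 50, allow_nan=False),
        T=st.floats(0.01, 100, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_is_a_probability_and_monotone(self, dh, T):
        p = accept_probability(dh, T)
        assert 0.0 <= p <= 1.0
        assert accept_probability(dh + 1.0, T) <= p


def _mobile_setup(seed=5, h=24, w=24, n_cells=4, cs=5):
    """A small mobile configuration for Monte-Carlo dynamics tests."""
    lat = Lattice.empty(h, w)
    for k in range(n_cells):
        r, c = divmod(k, 2)
        lat.owner[3 + r * cs : 3 + (r + 1) * cs, 3 + c * cs : 3 + (c + 1) * cs] = k + 1
    cells = Cells.uniform(n_cells, target_volume=cs * cs, A0=2.0, I0=1.0)
    cells.volume = lat.recount_volumes(n_cells)
    cells.volume[0] = 0
    params = ModelParams(J=make_J(4.0, 8.0), lam=2.0, T=6.0)
    return lat, cells, params, np.random.default_rng(seed)


class TestMonteCarloStep:
    def test_fixed_cells_never_move(self):
        lat, cells, params, rng = _mobile_setup()
        cells.fixed[1:] = True
        before = lat.owner.copy()
        for _ in range(5):
            assert monte_carlo_step(lat, cells, params, rng) == 0
        np.testing.assert_array_equal(lat.owner, before)

    def test_zero_temperature_energy_is_monotone(self):
        lat, cells, params, rng = _mobile_setup()
        params.zero_temperature = True
        h = total_energy(lat, cells, params)
        for _ in range(10):
            monte_carlo_step(lat, cells, params, rng)
            h2 = total_energy(lat, cells, params)
            assert h2 <= h + 1e-9
            h = h2

    def test_bookkeeping_volumes_plus_medium_is_area(self):
        lat, cells, params, rng = _mobile_setup()
        area = int((lat.owner != FRONTIER).sum())
        for _ in range(10):
            monte_carlo_step(lat, cells, params, rng)
            counts = lat.recount_volumes(cells.n_cells)
            np.testing.assert_array_equal(counts[1:], cells.volume[1:])
            assert counts.sum() == area

    def test_no_cell_is_ever_annihilated(self):
        lat, cells, params, rng = _mobile_setup()
        cells.target_volume[1:] = 1  # energy pushes cells to shrink hard
        params.T = 20.0
        for _ in range(60):
            monte_carlo_step(lat, cells, params, rng)
            assert (cells.volume[1:] >= 1).all()

    def test_identical_seed_identical_trajectory(self):
        out = []
        for _ in range(2):
            lat, cells, params, rng = _mobile_setup(seed=42)
            for _ in range(8):
                monte_carlo_step(lat, cells, params, rng)
            out.append((lat.owner.copy(), cells.volume.copy()))
        np.testing.assert_array_equal(out[0][0], out[1][0])
        np.testing.assert_array_equal(out[0][1], out[1][1])

    def test_volume_stays_in_band_around_target(self):
        # regression band frozen from pilot runs under the default adhesion
        # parameters: fluctuations of a 25-pixel cell stay well within half
        # its target volume
        lat, cells, params, rng = _mobile_setup()
        for _ in range(300):
            monte_carlo_step(lat, cells, params, rng)
            assert (np.abs(cells.volume[1:] - cells.target_volume[1:]) <= 13).all()

    def test_kernel_matches_pure_python_reference(self):
        """One Monte-Carlo step agrees bit for bit with an independent
        pure-python implementation fed the same random draws."""
        lat, cells, params, rng = _mobile_setup(seed=9)
        lat2 = Lattice(lat.owner.copy())
        cells2 = cells.copy()
        field = np.zeros(lat.owner.shape)
        field[lat.medium_mask] = 1.5
        field2 = field.copy()

        H, W = lat.owner.shape
        n = H * W
        seed_rng = np.random.default_rng(77)
        src_i = seed_rng.integers(1, H - 1, size=n)
        src_j = seed_rng.integers(1, W - 1, size=n)
        dirs = seed_rng.integers(0, 8, size=n)
        urand = seed_rng.random(n)

        # package path (replay the same draws through a stub generator)
        class Replay:
            def __init__(self):
                self.calls = iter([src_i, src_j, dirs, urand])

            def integers(self, *a, **kw):
                return next(self.calls)

            def random(self, *a, **kw):
                return next(self.calls)

        acc = monte_carlo_step(lat, cells, params, Replay(), field)

        # reference path
        ref_acc = _reference_mcs(
            lat2.owner, cells2, params, field2, src_i, src_j, dirs, urand
        )
        assert acc == ref_acc
        np.testing.assert_array_equal(lat.owner, lat2.owner)
        np.testing.assert_array_equal(cells.volume, cells2.volume)
        np.testing.assert_allclose(field, field2, rtol=0, atol=0)


def _reference_mcs(owner, cells, params, field, src_i, src_j, dirs, urand):
    """Straightforward re-implementation of the index-copy sweep."""
    tau = cells.cell_type
    J, lam, T = params.J, params.lam, params.T
    accepted = 0
    for k in range(len(src_i)):
        i, j = int(src_i[k]), int(src_j[k])
        di, dj = MOORE[int(dirs[k])]
        ti, tj = i + di, j + dj
        so, to = int(owner[i, j]), int(owner[ti, tj])
        if so == to or FRONTIER in (so, to):
            continue
        if so > 0 and cells.fixed[so]:
            continue
        if to > 0 and (cells.fixed[to] or cells.volume[to] == 1):
            continue
        dh = 0.0
        for du, dv in VON_NEUMANN:
            uo = int(owner[ti + du, tj + dv])
            if uo == FRONTIER:
                continue
            if uo != to:
                dh -= J[tau[uo], tau[to]]
            if uo != so:
                dh += J[tau[uo], tau[so]]
        if to > 0:
            v, vt = cells.volume[to], cells.target_volume[to]
            dh += lam * ((v - 1 - vt) ** 2 - (v - vt) ** 2)
        if so > 0:
            v, vt = cells.volume[so], cells.target_volume[so]
            dh += lam * ((v + 1 - vt) ** 2 - (v - vt) ** 2)
        if not (dh <= 0 or urand[k] < math.exp(-dh / T)):
            continue
        med_nbrs = [
            (ti + du, tj + dv)
            for du, dv in VON_NEUMANN
            if owner[ti + du, tj + dv] == 0
        ]
        if to == 0:
            c = field[ti, tj]
            if c > 0:
                if med_nbrs:
                    for u in med_nbrs:
                        field[u] += c / len(med_nbrs)
                else:
                    cells.I[so] = (cells.I[so] * cells.volume[so] + c) / (
                        cells.volume[so] + 1
                    )
            field[ti, tj] = 0.0
            cells.volume[so] += 1
        elif so == 0:
            val = 0.0
            for u in med_nbrs:
                take = field[u] / (len(med_nbrs) + 1)
                field[u] -= take
                val += take
            field[ti, tj] = val
            cells.volume[to] -= 1
        else:
            cells.volume[so] += 1
            cells.volume[to] -= 1
        owner[ti, tj] = so
        accepted += 1
    return accepted


class TestContacts:
    def test_isolated_cell_has_no_neighbors(self):
        lat = build_lattice(5, 5, {1: [(2, 2)]})
        assert contact_neighbors(lat, 1) == set()

    def test_touching_cells_see_each_other(self):
        lat = build_lattice(3, 4, {1: [(1, 1)], 2: [(1, 2)]})
        assert contact_neighbors(lat, 1) == {2}
        assert contact_neighbors(lat, 2) == {1}

    def test_unit_block_against_brute_force_scan(self):
        # 2x2 block of unit cells: 4-neighbourhood gives each cell exactly 2
        # contacts; verify against an exhaustive pixel-pair scan
        lat = build_lattice(
            4, 4, {1: [(1, 1)], 2: [(1, 2)], 3: [(2, 1)], 4: [(2, 2)]}
        )
        brute = {c: set() for c in range(1, 5)}
        owner = lat.owner
        for i in range(4):
            for j in range(4):
                for di, dj in ((0, 1), (1, 0)):
                    if i + di >= 4 or j + dj >= 4:
                        continue
                    a, b = int(owner[i, j]), int(owner[i + di, j + dj])
                    if a > 0 and b > 0 and a != b:
                        brute[a].add(b)
                        brute[b].add(a)
        for cid in range(1, 5):
            got = contact_neighbors(lat, cid)
            assert got == brute[cid]
            assert len(got) == 2

    def test_unknown_cell_id_raises(self):
        lat = build_lattice(4, 4, {1: [(1, 1)]})
        with pytest.raises(KeyError):
            contact_neighbors(lat, 9)
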