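"""Cellular Potts (Glazier-Graner-Hogeweg) lattice core.

Cells are sets of pixels on a 2-D lattice evolving by stochastic index-copy
attempts accepted with a Boltzmann criterion on an effective energy

    H = H_boundary + H_volume,

where ``H_boundary`` sums a type-dependent contact energy J over unordered
neighbouring pixel pairs owned by different cells (pairs inside one cell
contribute nothing) and ``H_volume`` penalises deviations of each cell's
pixel count from its target volume with an elastic term ``lam*(v - v_tg)**2``.

Conventions used throughout the package:

* owner map: ``int32`` array; ``0`` is the extracellular medium, ``-1`` the
  non-flux frontier ring at the lattice edge (never owned, never exchanged),
  cells are ``1..n_cells``.
* per-cell arrays have length ``n_cells + 1``; slot 0 is a medium
  placeholder and is never a valid cell.
* type codes: ``0`` medium, ``1`` blue (``A >= I``), ``2`` red (``I > A``).
* boundary-energy pairs and cell contacts use the 4-neighbourhood
  (von Neumann); copy-attempt targets are drawn from the 8-neighbourhood
  (Moore) so cells can also move diagonally.  Each unordered neighbouring
  pixel pair is counted once.

A copy that would reduce a cell to zero pixels is always rejected: the
population of cells is a fixed feature of every scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from numba import njit

MEDIUM = 0
FRONTIER = -1

#: type codes
T_MEDIUM, T_BLUE, T_RED = 0, 1, 2

# 4-neighbourhood (boundary energy, contacts) and 8-neighbourhood (copy targets)
VON_NEUMANN = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)], dtype=np.int64)
MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


class ConfigurationError(ValueError):
    """Inconsistent model configuration (missing J entry, bad mode, ...)."""


class ParameterError(ValueError):
    """A parameter value outside its admissible range."""


def make_J(j_cell_cell: float, j_cell_medium: float) -> np.ndarray:
    """Build the 3x3 symmetric contact-energy table.

    Adhesion in this model is type-blind: blue and red cells share the same
    contact energies; differentiation is purely chemical.  The table is
    indexed by type code (0 medium, 1 blue, 2 red); the medium-medium entry
    is zero by convention.
    """
    J = np.zeros((3, 3), dtype=np.float64)
    J[1:, 1:] = j_cell_cell
    J[0, 1:] = J[1:, 0] = j_cell_medium
    return J


@dataclass
class ModelParams:
    """All model rates and integration controls.

    Kinetic rates (``k1..k4``) govern the intracellular activator-inhibitor
    network, ``k5`` the degradation of inhibitor in the medium, ``s`` the
    cell<->medium exchange rate (indirect communication), ``d`` the
    contact-coupling rate (direct communication) and ``D`` the medium
    diffusion rate (pixel^2 per unit time).  Communication mode is encoded
    purely by ``(s, d)``: direct => s == 0, indirect => d == 0, mixed =>
    both positive.
    """

    J: np.ndarray = dc_field(default_factory=lambda: make_J(4.0, 8.0))
    lam: float = 2.0
    T: float = 6.0
    zero_temperature: bool = False
    k1: float = 1.0
    k2: float = 1.2
    k3: float = 1.0
    k4: float = 2.0
    k5: float = 0.05
    s: float = 0.0
    d: float = 0.0
    D: float = 5.0
    dt_ode: float = 0.005
    ode_substeps: int = 10
    mcs_total: int = 30000
    i_floor: float = 1e-9
    a_floor: float = 0.01

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=np.float64)
        if self.J.shape != (3, 3):
            raise ConfigurationError("J must be a 3x3 type-pair table")
        if not np.allclose(self.J, self.J.T, equal_nan=True):
            raise ConfigurationError("J must be symmetric in its type arguments")
        for name in ("lam", "k1", "k2", "k3", "k4", "k5", "s", "d", "D"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.T <= 0 and not self.zero_temperature:
            raise ParameterError(
                "T must be positive; request the zero-temperature limit via "
                "zero_temperature=True, not T=0"
            )
        # explicit-scheme bounds (shared ODE/PDE sub-step)
        if self.D > 0 and self.dt_ode > 1.0 / (4.0 * self.D):
            raise ParameterError(
                f"dt_ode={self.dt_ode} violates the explicit diffusion "
                f"stability bound 1/(4 D) = {1.0 / (4.0 * self.D):g}"
            )

    @property
    def dt_mcs(self) -> float:
        """Model time elapsed per Monte-Carlo step."""
        return self.dt_ode * self.ode_substeps


@dataclass
class Lattice:
    """Pixel grid mapping each site to a cell id, the medium, or the frontier."""

    owner: np.ndarray

    def __post_init__(self) -> None:
        self.owner = np.ascontiguousarray(self.owner, dtype=np.int32)
        if self.owner.ndim != 2:
            raise ConfigurationError("owner map must be 2-D")

    @classmethod
    def empty(cls, height: int, width: int) -> "Lattice":
        """All-medium lattice with a one-pixel non-flux frontier ring."""
        owner = np.zeros((height, width), dtype=np.int32)
        owner[0, :] = owner[-1, :] = FRONTIER
        owner[:, 0] = owner[:, -1] = FRONTIER
        return cls(owner)

    @property
    def height(self) -> int:
        return self.owner.shape[0]

    @property
    def width(self) -> int:
        return self.owner.shape[1]

    @property
    def frontier_mask(self) -> np.ndarray:
        return self.owner == FRONTIER

    @property
    def medium_mask(self) -> np.ndarray:
        return self.owner == MEDIUM

    def recount_volumes(self, n_cells: int) -> np.ndarray:
        """Fresh per-cell pixel counts (index 0 = medium pixel count)."""
        counts = np.bincount(
            self.owner[self.owner >= 0].ravel(), minlength=n_cells + 1
        )
        return counts[: n_cells + 1].astype(np.int64)


@dataclass
class Cells:
    """Per-cell state (arrays of length n_cells + 1; slot 0 unused).

    ``A`` and ``I`` are intracellular concentrations in arbitrary units and
    must stay strictly positive.  ``cell_type`` is always derived from them
    (blue if A >= I, ties blue), never stored independently.
    """

    volume: np.ndarray
    target_volume: np.ndarray
    fixed: np.ndarray
    A: np.ndarray
    I: np.ndarray

    @classmethod
    def uniform(
        cls,
        n_cells: int,
        target_volume: int,
        A0: float,
        I0: float,
        fixed: bool = False,
    ) -> "Cells":
        shape = n_cells + 1
        vol = np.full(shape, target_volume, dtype=np.int64)
        vol[0] = 0
        a = np.full(shape, float(A0))
        i = np.full(shape, float(I0))
        a[0] = i[0] = 0.0
        return cls(
            volume=vol,
            target_volume=vol.copy(),
            fixed=np.full(shape, bool(fixed)),
            A=a,
            I=i,
        )

    @property
    def n_cells(self) -> int:
        return len(self.volume) - 1

    @property
    def cell_type(self) -> np.ndarray:
        """Type codes derived from the A/I ratio (index 0 is medium)."""
        tau = np.where(self.A >= self.I, T_BLUE, T_RED).astype(np.int8)
        tau[0] = T_MEDIUM
        return tau

    def copy(self) -> "Cells":
        return Cells(
            self.volume.copy(),
            self.target_volume.copy(),
            self.fixed.copy(),
            self.A.copy(),
            self.I.copy(),
        )


# ---------------------------------------------------------------------------
# effective energy
# ---------------------------------------------------------------------------


def _pair_types(owner: np.ndarray, tau: np.ndarray):
    """Yield (type_a, type_b) arrays for unordered 4-neighbour pairs with
    different owners, both non-frontier."""
    for o1, o2 in (
        (owner[:, :-1], owner[:, 1:]),
        (owner[:-1, :], owner[1:, :]),
    ):
        m = (o1 != o2) & (o1 != FRONTIER) & (o2 != FRONTIER)
        yield tau[o1[m]], tau[o2[m]]


def boundary_energy(lat: Lattice, cells: Cells, params: ModelParams) -> float:
    """Total contact energy: sum of J(type_i, type_j) over unordered
    neighbouring pixel pairs with different owners (same-cell pairs are
    excluded by construction, the (1 - delta) factor)."""
    tau = cells.cell_type
    total = 0.0
    for ta, tb in _pair_types(lat.owner, tau):
        vals = params.J[ta, tb]
        if np.isnan(vals).any():
            k = int(np.flatnonzero(np.isnan(vals))[0])
            raise ConfigurationError(
                f"no J entry for type pair ({int(ta[k])}, {int(tb[k])})"
            )
        total += float(vals.sum())
    return total


def volume_energy(cells: Cells, params: ModelParams) -> float:
    """Elastic volume constraint: sum_cells lam * (v - v_tg)^2."""
    dv = cells.volume[1:] - cells.target_volume[1:]
    return float(params.lam * np.dot(dv, dv))


def total_energy(lat: Lattice, cells: Cells, params: ModelParams) -> float:
    return boundary_energy(lat, cells, params) + volume_energy(cells, params)


def delta_H(
    lat: Lattice,
    cells: Cells,
    params: ModelParams,
    source_pixel: tuple[int, int],
    target_pixel: tuple[int, int],
    tau: np.ndarray | None = None,
) -> float:
    """Energy change of copying the source pixel's owner onto the target.

    Computed from local terms only: the four boundary pairs touching the
    target pixel plus the volume terms of the two affected cells.  The
    source and target must be (Moore) neighbours with different owners and
    neither may be on the frontier.
    """
    owner = lat.owner
    si, sj = source_pixel
    ti, tj = target_pixel
    if max(abs(si - ti), abs(sj - tj)) != 1:
        raise ValueError("source and target must be lattice neighbours")
    so = int(owner[si, sj])
    to = int(owner[ti, tj])
    if so == to:
        raise ValueError("copy would not change ownership")
    if so == FRONTIER or to == FRONTIER:
        raise ValueError("frontier pixels never exchange material")
    if tau is None:
        tau = cells.cell_type
    J = params.J
    dH = 0.0
    H, W = owner.shape
    for di, dj in VON_NEUMANN:
        ui, uj = ti + di, tj + dj
        if not (0 <= ui < H and 0 <= uj < W):
            continue
        uo = int(owner[ui, uj])
        if uo == FRONTIER:
            continue
        if uo != to:
            dH -= J[tau[uo], tau[to]]
        if uo != so:
            dH += J[tau[uo], tau[so]]
    lam = params.lam
    if to > 0:
        v, vt = int(cells.volume[to]), int(cells.target_volume[to])
        dH += lam * ((v - 1 - vt) ** 2 - (v - vt) ** 2)
    if so > 0:
        v, vt = int(cells.volume[so]), int(cells.target_volume[so])
        dH += lam * ((v + 1 - vt) ** 2 - (v - vt) ** 2)
    return float(dH)


def accept_probability(dH: float, T: float) -> float:
    """Boltzmann acceptance: 1 if dH <= 0, else exp(-dH / T)."""
    if T <= 0:
        raise ParameterError(
            "T must be positive (the zero-temperature limit is a flag, not T=0)"
        )
    if dH <= 0:
        return 1.0
    return math.exp(-dH / T)


# ---------------------------------------------------------------------------
# Monte-Carlo dynamics (numba kernel)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _mcs_kernel(
    owner,
    tau,
    J,
    vol,
    vtg,
    fixed,
    A,
    I,
    fld,
    lam,
    T,
    zero_T,
    src_i,
    src_j,
    dir_idx,
    urand,
    moore,
    vn,
):  # pragma: no cover - exercised via monte_carlo_step
    H, W = owner.shape
    accepted = 0
    for n in range(src_i.size):
        i = src_i[n]
        j = src_j[n]
        ti = i + moore[dir_idx[n], 0]
        tj = j + moore[dir_idx[n], 1]
        so = owner[i, j]
        to = owner[ti, tj]
        if so == to:
            continue
        if so == -1 or to == -1:
            continue
        if so > 0 and fixed[so]:
            continue
        if to > 0 and (fixed[to] or vol[to] == 1):
            continue
        dH = 0.0
        for k in range(4):
            ui = ti + vn[k, 0]
            uj = tj + vn[k, 1]
            uo = owner[ui, uj]
            if uo == -1:
                continue
            if uo != to:
                dH -= J[tau[uo], tau[to]]
            if uo != so:
                dH += J[tau[uo], tau[so]]
        if to > 0:
            dv = vol[to] - vtg[to]
            dH += lam * ((dv - 1) * (dv - 1) - dv * dv)
        if so > 0:
            dv = vol[so] - vtg[so]
            dH += lam * ((dv + 1) * (dv + 1) - dv * dv)
        if dH <= 0.0:
            ok = True
        elif zero_T:
            ok = False
        else:
            ok = urand[n] < math.exp(-dH / T)
        if not ok:
            continue
        # Field bookkeeping.  Intracellular concentrations are intensive and
        # never altered by pixel moves: the membrane is impermeable to the
        # field except through the explicit exchange term (rate s).
        if to == 0:
            # advancing membrane displaces the absorbed pixel's inhibitor
            # into the adjacent medium pixels (mass-neutral)
            c = fld[ti, tj]
            if c > 0.0:
                nmed = 0
                for k in range(4):
                    if owner[ti + vn[k, 0], tj + vn[k, 1]] == 0:
                        nmed += 1
                if nmed > 0:
                    share = c / nmed
                    for k in range(4):
                        ui = ti + vn[k, 0]
                        uj = tj + vn[k, 1]
                        if owner[ui, uj] == 0:
                            fld[ui, uj] += share
                else:
                    # enclosed pocket: the cell takes up the trapped mass
                    I[so] = (I[so] * vol[so] + c) / (vol[so] + 1)
            fld[ti, tj] = 0.0
            vol[so] += 1
        elif so == 0:
            # retraction: the vacated pixel draws a proportional share of
            # each adjacent medium pixel's content (mass-neutral)
            nmed = 0
            for k in range(4):
                if owner[ti + vn[k, 0], tj + vn[k, 1]] == 0:
                    nmed += 1
            val = 0.0
            if nmed > 0:
                for k in range(4):
                    ui = ti + vn[k, 0]
                    uj = tj + vn[k, 1]
                    if owner[ui, uj] == 0:
                        take = fld[ui, uj] / (nmed + 1)
                        fld[ui, uj] -= take
                        val += take
            fld[ti, tj] = val
            vol[to] -= 1
        else:
            vol[so] += 1
            vol[to] -= 1
        owner[ti, tj] = so
        accepted += 1
    return accepted


def monte_carlo_step(
    lat: Lattice,
    cells: Cells,
    params: ModelParams,
    rng: np.random.Generator,
    field: np.ndarray | None = None,
) -> int:
    """One Monte-Carlo step: width*height random index-copy attempts.

    Each attempt picks a random interior pixel and a random Moore neighbour;
    if the owners differ and neither cell is fixed, the copy is accepted
    with ``accept_probability(delta_H, T)``.  Volumes and intracellular /
    medium inhibitor mass are updated incrementally.  Returns the number of
    accepted copies.
    """
    owner = lat.owner
    H, W = owner.shape
    n_attempts = H * W
    if bool(cells.fixed[1:].all()) and cells.n_cells > 0:
        return 0  # fixed cells: no index-copy attempts at all
    if field is None:
        field = np.zeros((H, W), dtype=np.float64)
    src_i = rng.integers(1, H - 1, size=n_attempts)
    src_j = rng.integers(1, W - 1, size=n_attempts)
    dir_idx = rng.integers(0, 8, size=n_attempts)
    urand = rng.random(n_attempts)
    tau = cells.cell_type
    return int(
        _mcs_kernel(
            owner,
            tau,
            params.J,
            cells.volume,
            cells.target_volume,
            cells.fixed,
            cells.A,
            cells.I,
            field,
            float(params.lam),
            float(params.T),
            params.zero_temperature,
            src_i,
            src_j,
            dir_idx,
            urand,
            MOORE,
            VON_NEUMANN,
        )
    )


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def contact_pairs(owner: np.ndarray, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Unordered (a, b) cell-id pairs sharing at least one 4-neighbour pixel
    contact, a < b.  Medium and frontier are excluded."""
    keys = []
    base = n_cells + 1
    for o1, o2 in (
        (owner[:, :-1], owner[:, 1:]),
        (owner[:-1, :], owner[1:, :]),
    ):
        m = (o1 > 0) & (o2 > 0) & (o1 != o2)
        a = np.minimum(o1[m], o2[m]).astype(np.int64)
        b = np.maximum(o1[m], o2[m]).astype(np.int64)
        keys.append(a * base + b)
    if not keys:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    uniq = np.unique(np.concatenate(keys))
    return uniq // base, uniq % base


def contact_neighbors(lat: Lattice, cell_id: int) -> set[int]:
    """Distinct other cells owning a pixel 4-adjacent to ``cell_id``'s pixels.

    The contact set is recomputed fresh from the owner map on every call;
    the medium is never a neighbour.
    """
    owner = lat.owner
    if cell_id <= 0 or not (owner == cell_id).any():
        raise KeyError(f"unknown cell id {cell_id}")
    n_cells = int(owner.max())
    a, b = contact_pairs(owner, n_cells)
    out: set[int] = set()
    out.update(b[a == cell_id].tolist())
    out.update(a[b == cell_id].tolist())
    return out
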