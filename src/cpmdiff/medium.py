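"""Extracellular inhibitor field on medium pixels.

The medium carries a single scalar field: the inhibitor concentration
``I_ext``, which diffuses passively (rate ``D``), degrades (rate ``k5``) and
exchanges with cells at their boundaries (rate ``s``):

    dI_ext/dt = D * lap(I_ext) - k5 * I_ext            on medium pixels
    + exchange s * (I_sigma - I_ext)  at pixels bounding cell sigma

The field is defined on medium pixels only; pixels owned by cells or by the
non-flux frontier are not part of its state.  The explicit five-point
Laplacian uses reflecting (non-flux) conditions at the lattice frontier and
at cell-medium interfaces, so with ``k5 = 0`` and ``s = 0`` total field mass
is conserved exactly.

Exchange discretisation: each cell's boundary concentration ``I_ext_sigma``
is the mean of the field over the distinct medium pixels 4-adjacent to the
cell.  The cell side applies the concentration rate ``s * (I_ext_sigma -
I_sigma)`` once per cell; the medium side moves the matching *amount*
``v_sigma * s * (I_ext_sigma - I_sigma) * dt``: uptake is drawn from the
boundary pixels in proportion to their content (capped at 20% of the
boundary mass per sub-step, the cap mirrored on the cell side through an
effective boundary concentration), secretion is deposited uniformly.  With
inhibitor amounts defined as concentration times pixel count the exchange
is exactly antisymmetric, so the combined quantity
sum_cells I_sigma * v_sigma + sum_medium I_ext  changes only through
reactions, degradation and the frontier-free diffusion stencil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Lattice, MEDIUM, ModelParams
from .network import NetworkState


class SchemeInstabilityError(RuntimeError):
    """The explicit field update produced negative concentrations."""


#: tolerance below zero before the update is declared unstable
NEGATIVE_TOL = -1e-6


@dataclass
class MediumField:
    """Inhibitor concentration per medium pixel (2-D array, lattice shape).

    Values at cell-owned or frontier pixels are bookkeeping zeros, never
    read as field state.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)

    @classmethod
    def uniform(cls, lat: Lattice, value: float = 0.0) -> "MediumField":
        v = np.where(lat.medium_mask, float(value), 0.0)
        return cls(v)

    def total_mass(self, lat: Lattice) -> float:
        return float(self.values[lat.medium_mask].sum())


@dataclass
class BoundaryMap:
    """Distinct (medium pixel, cell) adjacencies, flattened pixel indices."""

    pix: np.ndarray
    cell: np.ndarray
    count: np.ndarray  # boundary pixel count per cell (length n_cells + 1)


def boundary_map(owner: np.ndarray, n_cells: int) -> BoundaryMap:
    """All distinct (medium pixel, adjacent cell) pairs, 4-neighbourhood.

    A medium pixel touching the same cell on two sides is counted once for
    that cell; a pixel touching two different cells appears once per cell.
    """
    H, W = owner.shape
    flat = np.arange(H * W, dtype=np.int64).reshape(H, W)
    keys = []
    base = n_cells + 1
    shifts = (
        (owner[:, :-1], owner[:, 1:], flat[:, :-1], flat[:, 1:]),
        (owner[:-1, :], owner[1:, :], flat[:-1, :], flat[1:, :]),
    )
    for o1, o2, f1, f2 in shifts:
        m = (o1 == MEDIUM) & (o2 > 0)
        keys.append(f1[m] * base + o2[m])
        m = (o2 == MEDIUM) & (o1 > 0)
        keys.append(f2[m] * base + o1[m])
    uniq = np.unique(np.concatenate(keys)) if keys else np.empty(0, np.int64)
    pix = uniq // base
    cell = uniq % base
    count = np.bincount(cell, minlength=n_cells + 1)
    return BoundaryMap(pix=pix, cell=cell, count=count)


def boundary_concentrations(
    field: MediumField, bmap: BoundaryMap
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell boundary mean of the field and a has-boundary mask.

    Cells with no medium contact get NaN (flagged, not a surprise): their
    indirect-communication term is defined to contribute zero.
    """
    n = len(bmap.count)
    sums = np.zeros(n)
    np.add.at(sums, bmap.cell, field.values.ravel()[bmap.pix])
    has = bmap.count > 0
    means = np.full(n, np.nan)
    means[has] = sums[has] / bmap.count[has]
    has[0] = False
    means[0] = np.nan
    return means, has


def boundary_concentration(
    field: MediumField, lat: Lattice, cell_id: int
) -> float | None:
    """Boundary medium concentration of one cell, or None if the cell is
    fully enclosed (no medium contact)."""
    owner = lat.owner
    if cell_id <= 0 or not (owner == cell_id).any():
        raise KeyError(f"unknown cell id {cell_id}")
    bmap = boundary_map(owner, int(owner.max()))
    means, has = boundary_concentrations(field, bmap)
    if not has[cell_id]:
        return None
    return float(means[cell_id])


def pde_step(
    field: MediumField,
    lat: Lattice,
    state: NetworkState,
    params: ModelParams,
    bmap: BoundaryMap | None = None,
    dt: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One explicit field sub-step; returns (I_ext per cell, has_boundary).

    Order inside the sub-step: the per-cell boundary means are read from the
    pre-step field, then diffusion, degradation and the exchange deposits are
    applied.  The returned means are the ones the matching cell-side Euler
    sub-step must use, keeping the exchange antisymmetric.
    """
    owner = lat.owner
    if dt is None:
        dt = params.dt_ode
    if bmap is None:
        bmap = boundary_map(owner, state.n_cells)
    iext, has = boundary_concentrations(field, bmap)

    f = field.values
    med = owner == MEDIUM
    lap = np.zeros_like(f)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb_f = np.roll(f, shift, axis=axis)
        nb_med = np.roll(med, shift, axis=axis)
        # flux only between two medium pixels; everything else reflects
        lap += np.where(nb_med, nb_f - f, 0.0)
    new = f + dt * (params.D * lap - params.k5 * f)

    if params.s > 0 and len(bmap.pix):
        # amount entering cell sigma this sub-step:
        #   v_sigma * s * (I_ext_sigma - I_sigma) * dt
        # Uptake (amount > 0) is drawn from the cell's boundary pixels in
        # proportion to their content and is capped at 20% of the boundary
        # mass (a cell with very little medium contact cannot take more
        # than is there); the cap is mirrored on the cell side through an
        # exchange-limited effective boundary concentration, keeping the
        # exchange exactly antisymmetric.  Secretion (amount < 0) is
        # deposited uniformly over the boundary pixels.
        vol = np.zeros(state.n_cells + 1)
        vol[1:] = np.bincount(
            owner[owner > 0].ravel(), minlength=state.n_cells + 1
        )[1:]
        flux = np.where(has, params.s * (iext - state.I), 0.0)
        flux = np.where(np.isnan(flux), 0.0, flux)
        amount = vol * flux * dt
        bsum = iext * bmap.count  # total boundary content per cell
        # 0.2 cap: even a pixel shared by four uptaking cells plus the
        # diffusion outflow (4 D dt) cannot be overdrawn
        up = amount > 0
        realized = np.where(up, np.minimum(amount, 0.2 * bsum), amount)
        scale = vol * params.s * dt
        limited = up & (realized < amount) & (scale > 0)
        iext = np.where(limited, state.I + realized / np.where(scale > 0, scale, 1.0), iext)
        take_frac = np.zeros_like(amount)
        take = up & (bsum > 0)
        take_frac[take] = realized[take] / bsum[take]
        dep_per_pixel = np.zeros_like(amount)
        dep = amount < 0
        dep_per_pixel[dep] = -amount[dep] / bmap.count[dep]
        pix_vals = f.ravel()[bmap.pix]
        delta = np.zeros(f.size)
        np.add.at(
            delta,
            bmap.pix,
            dep_per_pixel[bmap.cell] - take_frac[bmap.cell] * pix_vals,
        )
        new = new + delta.reshape(f.shape)

    new = np.where(med, new, 0.0)
    if (new < NEGATIVE_TOL).any():
        raise SchemeInstabilityError(
            f"medium field went negative (min {new.min():g}); "
            f"reduce dt (currently {dt:g}) or the exchange rate s"
        )
    np.maximum(new, 0.0, out=new)
    field.values = new
    return iext, has
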