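"""Per-cell activator-inhibitor network with cell-to-cell communication.

Every cell carries an identical two-node network: an activator A that
autocatalyses and induces the inhibitor I, and an inhibitor that represses A:

    dA/dt = k1 * A^2 / I - k2 * A
    dI/dt = k3 * A^2 - k4 * I
            + s * (I_ext - I)                          (indirect, via medium)
            + d * (sum_{n in N} I_n - #N * I)          (direct, via contacts)

The inhibitor is the communication signal: it moves by plain diffusion,
without receptors, either to cells in physical contact (rate ``d``) or to
and from the extracellular medium (rate ``s``); the activator never leaves
the cell.  A cell's type is derived from the A/I ratio: blue if A >= I
(ties blue), red otherwise.

The uncoupled network has a single positive fixed point

    A* = k1 k4 / (k2 k3),    I* = k3 A*^2 / k4 = (k1 / k2) A*,

stable when k2 < k4, and with A*/I* = k2/k1 an isolated cell always ends up
blue for k2 >= k1.  Red states (A collapsed near zero, I sustained by
imported inhibitor) only exist in the coupled system: multistability here is
a property of communicating cells, not of one cell in isolation.  See
docs/methods.md for the linear analysis behind the parameter defaults.

Integration is forward Euler with ``params.ode_substeps`` sub-steps of
``params.dt_ode`` per Monte-Carlo step; the inhibitor is clamped at a small
positive floor (``params.i_floor``) and every clamp event is counted so a
run that ever hit the guard can be flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .core import Cells, ModelParams, T_BLUE, T_MEDIUM, T_RED


class PositivityError(ValueError):
    """An inhibitor concentration reached zero or below."""


class IntegrationBlowupError(RuntimeError):
    """Forward-Euler state became non-finite."""


@dataclass
class NetworkState:
    """Concentration state of all cells (arrays of length n_cells + 1).

    ``I_ext`` holds each cell's boundary medium concentration (the mean of
    the inhibitor field over medium pixels adjacent to the cell); cells with
    no medium contact carry NaN there and a False ``has_boundary`` flag, so
    the indirect term contributes exactly zero for them.
    """

    A: np.ndarray
    I: np.ndarray
    I_ext: np.ndarray = dc_field(default=None)  # type: ignore[assignment]
    has_boundary: np.ndarray = dc_field(default=None)  # type: ignore[assignment]
    clamp_events: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.I = np.asarray(self.I, dtype=np.float64)
        n = len(self.A)
        if self.I_ext is None:
            self.I_ext = np.full(n, np.nan)
        if self.has_boundary is None:
            self.has_boundary = np.zeros(n, dtype=bool)

    @classmethod
    def from_cells(cls, cells: Cells) -> "NetworkState":
        return cls(A=cells.A, I=cells.I)

    @property
    def n_cells(self) -> int:
        return len(self.A) - 1


def uncoupled_fixed_point(params: ModelParams) -> tuple[float, float]:
    """Closed-form positive fixed point of the isolated network."""
    a = params.k1 * params.k4 / (params.k2 * params.k3)
    i = params.k3 * a * a / params.k4
    return a, i


def _neighbor_sums(
    I: np.ndarray, pairs: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    a, b = pairs
    s = np.zeros_like(I)
    deg = np.zeros_like(I)
    np.add.at(s, a, I[b])
    np.add.at(s, b, I[a])
    np.add.at(deg, a, 1.0)
    np.add.at(deg, b, 1.0)
    return s, deg


def ode_rhs(
    state: NetworkState,
    neighbors: tuple[np.ndarray, np.ndarray],
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dA/dt, dI/dt) for every cell.

    ``neighbors`` is the unordered contact-pair representation produced by
    :func:`cpmdiff.core.contact_pairs` (recomputed each Monte-Carlo step:
    neighbour sets change continually as cells move).
    """
    A, I = state.A, state.I
    if (I[1:] <= 0).any():
        bad = int(np.flatnonzero(I[1:] <= 0)[0]) + 1
        raise PositivityError(f"inhibitor concentration of cell {bad} is <= 0")
    dA = params.k1 * A * A / np.where(I > 0, I, 1.0) - params.k2 * A
    dI = params.k3 * A * A - params.k4 * I
    if params.s > 0:
        indirect = np.where(state.has_boundary, state.I_ext - I, 0.0)
        indirect = np.where(np.isnan(indirect), 0.0, indirect)
        dI = dI + params.s * indirect
    if params.d > 0 and len(neighbors[0]):
        nsum, deg = _neighbor_sums(I, neighbors)
        dI = dI + params.d * (nsum - deg * I)
    dA[0] = dI[0] = 0.0  # slot 0 is the medium placeholder
    return dA, dI


def euler_step(
    state: NetworkState,
    neighbors: tuple[np.ndarray, np.ndarray],
    params: ModelParams,
    n_steps: int = 1,
) -> NetworkState:
    """Advance the cell network ``n_steps`` forward-Euler sub-steps in place.

    The boundary concentration ``state.I_ext`` is held frozen across the
    sub-steps; the simulation driver interleaves single sub-steps with the
    medium update so both sides of the exchange see the same pre-step values.
    """
    dt = params.dt_ode
    for _ in range(n_steps):
        dA, dI = ode_rhs(state, neighbors, params)
        state.A = state.A + dt * dA
        state.I = state.I + dt * dI
        # basal activator level: leaky expression keeps A at a small floor,
        # so a suppressed (red) cell can re-activate once the inhibition it
        # receives falls away.  This is a model feature, not a numerical
        # guard, and is therefore not counted as a clamp event.
        np.maximum(state.A[1:], params.a_floor, out=state.A[1:])
        low = state.I[1:] < params.i_floor
        if low.any():
            state.clamp_events += int(low.sum())
            state.I[1:][low] = params.i_floor
        if not (np.isfinite(state.A).all() and np.isfinite(state.I).all()):
            raise IntegrationBlowupError(
                f"non-finite concentrations after Euler sub-step "
                f"(dt={dt}, max A={np.nanmax(state.A):g})"
            )
    return state


def classify(state: NetworkState) -> np.ndarray:
    """Per-cell type codes: blue where A >= I (ties blue), red where I > A."""
    tau = np.where(state.A >= state.I, T_BLUE, T_RED).astype(np.int8)
    tau[0] = T_MEDIUM
    return tau
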