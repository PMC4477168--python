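"""Quantitative pattern statistics with permutation nulls.

The simulator's qualitative outcomes ("spaced blue cells", "red rim around a
blue core", "blue dots in the centre", "heterogeneous but unpatterned") are
operationalised as cell-level statistics, each tested against a null that
shuffles type labels over the fixed cell positions (999 shuffles, seeded from
the run):

* ``fraction_blue`` - share of blue cells in the final snapshot;
* ``border_enrichment`` - per type, share among aggregate-border cells
  divided by overall share (border cell = at least one pixel 4-adjacent to
  medium); > 1 means the type is over-represented on the rim;
* ``adjacency_z`` - z-score of the observed number of blue-blue contact
  edges under the label-permutation null; strongly negative means blue
  cells avoid each other (spacing), strongly positive a contiguous blue
  block;
* ``centrality_gap`` - mean centroid-to-aggregate-centroid distance of red
  cells minus that of blue cells (positive: blue is more central), with a
  permutation p-value;
* ``stability_index`` - mean fraction of cells keeping their type label
  between consecutive samples over the final window (1.0 iff labels are
  constant there).

Every statistic treats a cell as one observation; pixels only enter through
centroids and adjacency.  Statistics that are undefined for a snapshot
(single-type populations, empty contact graphs) are reported as None with an
explicit reason rather than NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np

from .core import T_BLUE, contact_pairs
from .medium import boundary_map

N_PERMUTATIONS = 999
METRICS_SEED_STREAM = 0x5EED  # sub-stream key so run and metrics draws differ

PATTERN_CLASSES = (
    "spaced",
    "radial",
    "central-clusters",
    "homogeneous",
    "unpatterned-heterogeneous",
    "unclassified",
)


@dataclass
class ClassifyThresholds:
    """Frozen rule thresholds for the pattern classifier."""

    homogeneous_majority: float = 0.95
    z_spaced: float = -2.0  # blue-blue avoidance
    z_core: float = 2.0  # contiguous blue core
    alpha: float = 0.05


@dataclass
class PatternReport:
    n_cells: int
    fraction_blue: float
    border_cells: int
    interior_cells: int
    border_enrichment: dict[str, float] | None
    border_enrichment_red_p: float | None
    adjacency_z: float | None
    blue_blue_edges: int | None
    centrality_gap: float | None
    centrality_p: float | None
    stability_index: float
    window_steps: list[int]
    clamp_events: int
    flagged: bool  # any clamp / instability event during the run
    seed: int
    undefined: dict[str, str] = dc_field(default_factory=dict)
    pattern_class: str = "unclassified"

    def to_dict(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        for k, v in d.items():
            if isinstance(v, np.generic):
                d[k] = v.item()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary_row(self) -> dict[str, Any]:
        """Flat row for grid summary tables."""
        enr = self.border_enrichment or {}
        return {
            "n_cells": self.n_cells,
            "fraction_blue": self.fraction_blue,
            "border_enrichment_red": enr.get("red"),
            "adjacency_z": self.adjacency_z,
            "centrality_gap": self.centrality_gap,
            "centrality_p": self.centrality_p,
            "stability_index": self.stability_index,
            "pattern_class": self.pattern_class,
            "flagged": self.flagged,
        }


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def border_partition(owner: np.ndarray, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Split cell ids into (border, interior): border cells own at least one
    pixel 4-adjacent to a medium pixel."""
    bmap = boundary_map(owner, n_cells)
    ids = np.arange(1, n_cells + 1)
    is_border = bmap.count[1:] > 0
    return ids[is_border], ids[~is_border]


def cell_centroids(owner: np.ndarray, n_cells: int) -> np.ndarray:
    """(n_cells + 1, 2) centroid coordinates; row 0 is unused."""
    H, W = owner.shape
    ii, jj = np.mgrid[0:H, 0:W]
    mask = owner > 0
    ids = owner[mask]
    out = np.zeros((n_cells + 1, 2))
    cnt = np.bincount(ids, minlength=n_cells + 1).astype(float)
    out[:, 0] = np.bincount(ids, weights=ii[mask], minlength=n_cells + 1)
    out[:, 1] = np.bincount(ids, weights=jj[mask], minlength=n_cells + 1)
    nz = cnt > 0
    out[nz] /= cnt[nz, None]
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def compute_report(
    result,
    n_perm: int = N_PERMUTATIONS,
    thresholds: ClassifyThresholds | None = None,
    window_fraction: float = 0.1,
) -> PatternReport:
    """Compute the full pattern report for one run.

    All statistics are computed over the final sampling window (the last
    ``window_fraction`` of samples, at least two): headline quantities such
    as the blue fraction come from the final snapshot, while the permutation
    statistics pool the observed quantity over the window samples.  Each
    permutation replicate assigns every cell a random rank slot (one shared
    shuffle across all window samples); at sample k the cells occupying the
    lowest ``n_blue(k)`` slots are blue under the null.  This respects each
    sample's label counts and maximally preserves cross-sample label
    persistence under the null (conservative for mobile runs).  Slots are
    attached to cells through a geometric canonical order (final-snapshot
    centroids, lexicographic; ties broken by id), so the null - and with it
    every statistic - is exactly invariant under a relabelling of cell ids
    that does not change the geometry.  For a fixed-cell run
    all window samples are identical and the pooled statistics reduce to
    single-snapshot ones.  All permutation draws are seeded from the run's
    recorded seed, so re-analysis of an archive reproduces the report bit
    for bit.
    """
    if result.n_samples < 2:
        raise ValueError("need at least 2 samples for the stability window")
    owner = result.owners[-1]
    n_cells = int(result.table["cell_id"].max())
    tau = result.types_at(result.n_samples - 1)
    blue = tau[1:] == T_BLUE
    n_blue = int(blue.sum())
    fraction_blue = n_blue / n_cells

    rng = np.random.default_rng(
        np.random.SeedSequence((int(result.seed), METRICS_SEED_STREAM))
    )
    undefined: dict[str, str] = {}

    k_window = max(2, int(np.ceil(window_fraction * result.n_samples)))
    idx = list(range(result.n_samples - k_window, result.n_samples))
    window_types = [result.types_at(k)[1:] for k in idx]
    window_blue = [t == T_BLUE for t in window_types]
    mixed = [0 < b.sum() < n_cells for b in window_blue]

    border_ids, interior_ids = border_partition(owner, n_cells)
    # rank slots: one shared shuffle per replicate, attached to cells in a
    # geometry-canonical order (see docstring)
    cent_final = cell_centroids(owner, n_cells)[1:]
    order = np.lexsort((np.arange(n_cells), cent_final[:, 1], cent_final[:, 0]))
    canon = np.empty(n_cells, dtype=np.int64)
    canon[order] = np.arange(n_cells)
    slots = rng.permuted(np.tile(np.arange(n_cells), (n_perm, 1)), axis=1)
    slots = slots[:, canon]

    # border enrichment (window-pooled) --------------------------------------
    enrichment = None
    enr_red_p = None
    obs_acc, null_acc, n_valid = 0.0, np.zeros(n_perm), 0
    enr_final = None
    for k, j in enumerate(idx):
        if not mixed[k]:
            continue
        b_ids, _ = border_partition(result.owners[j], n_cells)
        if len(b_ids) == 0:
            continue
        red_k = ~window_blue[k]
        bsel = b_ids - 1
        obs_k = red_k[bsel].mean() / red_k.mean()
        obs_acc += obs_k
        null_red = slots >= int(window_blue[k].sum())
        null_acc += null_red[:, bsel].mean(axis=1) / red_k.mean()
        n_valid += 1
        if j == idx[-1]:
            blue_k = window_blue[k]
            enr_final = {
                "blue": float(blue_k[bsel].mean() / blue_k.mean()),
                "red": float(obs_k),
            }
    if n_valid == 0:
        undefined["border_enrichment"] = (
            "no window sample with both types and border cells"
        )
    else:
        enrichment = enr_final or {"blue": None, "red": float(obs_acc / n_valid)}
        enr_red_p = float(
            (1 + np.sum(null_acc / n_valid >= obs_acc / n_valid - 1e-12))
            / (n_perm + 1)
        )

    # blue-blue adjacency z (window-pooled) ----------------------------------
    adjacency_z = None
    bb_edges = None
    obs_bb, null_bb, any_edges = 0, np.zeros(n_perm), False
    for k, j in enumerate(idx):
        if not mixed[k]:
            continue
        a, bpair = contact_pairs(result.owners[j], n_cells)
        if len(a) == 0:
            continue
        any_edges = True
        blue_k = window_blue[k]
        obs_bb += int(np.sum(blue_k[a - 1] & blue_k[bpair - 1]))
        pb = slots < int(blue_k.sum())
        null_bb += (pb[:, a - 1] & pb[:, bpair - 1]).sum(axis=1)
    if not any(mixed):
        undefined["adjacency_z"] = "only one cell type present"
    elif not any_edges:
        undefined["adjacency_z"] = "no cell-cell contacts"
    else:
        bb_edges = int(obs_bb)
        sd = null_bb.std()
        if sd == 0:
            undefined["adjacency_z"] = "degenerate permutation null"
        else:
            adjacency_z = float((obs_bb - null_bb.mean()) / sd)

    # centrality (window-pooled) ----------------------------------------------
    centrality_gap = None
    centrality_p = None
    obs_gap, null_gap, n_valid = 0.0, np.zeros(n_perm), 0
    for k, j in enumerate(idx):
        if not mixed[k]:
            continue
        cent = cell_centroids(result.owners[j], n_cells)[1:]
        agg = cent.mean(axis=0)
        dist = np.hypot(cent[:, 0] - agg[0], cent[:, 1] - agg[1])
        blue_k = window_blue[k]
        obs_gap += dist[~blue_k].mean() - dist[blue_k].mean()
        nb = int(blue_k.sum())
        pb = slots < nb
        sum_d = dist.sum()
        blue_d = (dist[None, :] * pb).sum(axis=1)
        null_gap += (sum_d - blue_d) / (n_cells - nb) - blue_d / nb
        n_valid += 1
    if n_valid == 0:
        undefined["centrality_gap"] = "only one cell type present"
    else:
        centrality_gap = float(obs_gap / n_valid)
        gaps = null_gap / n_valid
        centrality_p = float(
            (1 + np.sum(np.abs(gaps) >= abs(centrality_gap) - 1e-12)) / (n_perm + 1)
        )

    # stability over the final window ---------------------------------------
    agree = [
        float(np.mean(t1 == t2)) for t1, t2 in zip(window_types, window_types[1:])
    ]
    stability = float(np.mean(agree))

    report = PatternReport(
        n_cells=n_cells,
        fraction_blue=float(fraction_blue),
        border_cells=len(border_ids),
        interior_cells=len(interior_ids),
        border_enrichment=enrichment,
        border_enrichment_red_p=enr_red_p,
        adjacency_z=adjacency_z,
        blue_blue_edges=bb_edges,
        centrality_gap=centrality_gap,
        centrality_p=centrality_p,
        stability_index=stability,
        window_steps=[int(result.sample_steps[k]) for k in idx],
        clamp_events=int(result.clamp_events),
        flagged=bool(result.clamp_events > 0),
        seed=int(result.seed),
        undefined=undefined,
    )
    report.pattern_class = classify_pattern(report, thresholds)
    return report


def classify_pattern(
    report: PatternReport, thresholds: ClassifyThresholds | None = None
) -> str:
    """Rule-based mapping from report statistics to a pattern class.

    Rules are checked in order; a report matching none of them is labelled
    ``unclassified`` rather than forced into a class.
    """
    t = thresholds or ClassifyThresholds()
    fb = report.fraction_blue
    z = report.adjacency_z
    gap = report.centrality_gap
    gap_sig = (
        gap is not None
        and report.centrality_p is not None
        and report.centrality_p < t.alpha
    )
    enr = report.border_enrichment or {}
    red_border_sig = (
        enr.get("red") is not None
        and enr["red"] > 1.0
        and report.border_enrichment_red_p is not None
        and report.border_enrichment_red_p < t.alpha
    )

    if max(fb, 1.0 - fb) >= t.homogeneous_majority:
        return "homogeneous"
    if z is not None and z >= t.z_core and red_border_sig:
        return "radial"
    if gap_sig and gap > 0 and (z is None or z < t.z_core):
        return "central-clusters"
    if z is not None and z <= t.z_spaced and fb < 0.5 and not gap_sig:
        return "spaced"
    if (z is None or abs(z) < abs(t.z_spaced)) and not gap_sig and not red_border_sig:
        return "unpatterned-heterogeneous"
    return "unclassified"
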