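"""Ribbon-receptor pairing, per-cell assignment, and count summaries.

A synapse is considered functional when a pre-synaptic ribbon (Ctbp2
channel) and a post-synaptic receptor patch (Gria2 channel) lie within a
pairing distance of each other.  Pairing is the greedy globally-closest
matching: repeatedly match the closest unmatched ribbon-receptor pair
whose centroid separation does not exceed ``max_pair_distance``; whatever
remains unmatched is an orphan.  Proximity pairing doubles as a background
filter — isolated specks of off-target staining rarely have a partner in
the other channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import Component

logger = logging.getLogger(__name__)

__all__ = [
    "SynapsePair",
    "PairingResult",
    "pair_components",
    "assign_to_cells",
    "count_cells",
    "count_summary",
]


@dataclass(frozen=True)
class SynapsePair:
    ribbon: Component
    receptor: Component
    distance: float  # µm, centroid-to-centroid


@dataclass(frozen=True)
class PairingResult:
    pairs: tuple[SynapsePair, ...]
    orphan_ribbons: tuple[Component, ...]
    orphan_receptors: tuple[Component, ...]

    @property
    def n_ribbons(self) -> int:
        return len(self.pairs) + len(self.orphan_ribbons)

    @property
    def n_receptors(self) -> int:
        return len(self.pairs) + len(self.orphan_receptors)


def pair_components(
    ribbons: Sequence[Component],
    receptors: Sequence[Component],
    max_pair_distance: float = 1.0,
) -> PairingResult:
    """Greedy mutual-proximity matching of ribbons to receptors.

    Candidate pairs within ``max_pair_distance`` are sorted by
    (distance, ribbon id, receptor id) — the id order is the documented,
    deterministic tie-break — and accepted greedily while both members are
    unmatched.  Each component therefore appears in at most one pair, and
    pairs plus orphans partition both input sets exactly.
    """
    if max_pair_distance <= 0:
        raise ValueError("max_pair_distance must be positive")
    if ribbons and receptors:
        rpos = np.asarray([c.centroid for c in ribbons])
        gpos = np.asarray([c.centroid for c in receptors])
        d = np.sqrt(((rpos[:, None, :] - gpos[None, :, :]) ** 2).sum(axis=2))
        ii, jj = np.nonzero(d <= max_pair_distance)
        order = sorted(zip(d[ii, jj], ii, jj))
    else:
        order = []
    used_r: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for dist, i, j in order:
        if i in used_r or j in used_g:
            continue
        used_r.add(i)
        used_g.add(j)
        pairs.append(SynapsePair(ribbons[i], receptors[j], float(dist)))
    orphan_ribbons = tuple(c for i, c in enumerate(ribbons) if i not in used_r)
    orphan_receptors = tuple(c for j, c in enumerate(receptors) if j not in used_g)
    return PairingResult(tuple(pairs), orphan_ribbons, orphan_receptors)


def assign_to_cells(
    result: PairingResult,
    cells: Sequence[Mapping],
    max_cell_distance: float = 7.0,
) -> dict[int, PairingResult]:
    """Split a stack-level pairing result into per-cell results.

    Each pair is assigned to the cell whose soma centre is nearest to the
    ribbon centroid; orphans are assigned by their own centroid.  Components
    farther than ``max_cell_distance`` from every soma centre are flagged
    unassigned (logged) and excluded from per-cell counts.

    ``cells`` are mappings with at least ``cell_id`` and ``soma_center``
    (the form stored in stack metadata).
    """
    if not cells:
        raise ValueError("at least one cell is required")
    centers = np.asarray([c["soma_center"] for c in cells], dtype=float)
    ids = [int(c["cell_id"]) for c in cells]

    def nearest(pos) -> int | None:
        dist = np.sqrt(((centers - np.asarray(pos)) ** 2).sum(axis=1))
        k = int(np.argmin(dist))
        return ids[k] if dist[k] <= max_cell_distance else None

    buckets: dict[int, dict[str, list]] = {
        i: {"pairs": [], "orb": [], "orc": []} for i in ids
    }
    n_unassigned = 0
    for p in result.pairs:
        cid = nearest(p.ribbon.centroid)
        if cid is None:
            n_unassigned += 1
        else:
            buckets[cid]["pairs"].append(p)
    for c in result.orphan_ribbons:
        cid = nearest(c.centroid)
        if cid is None:
            n_unassigned += 1
        else:
            buckets[cid]["orb"].append(c)
    for c in result.orphan_receptors:
        cid = nearest(c.centroid)
        if cid is None:
            n_unassigned += 1
        else:
            buckets[cid]["orc"].append(c)
    if n_unassigned:
        logger.warning(
            "%d component(s) farther than %.2f µm from every soma were "
            "left unassigned", n_unassigned, max_cell_distance,
        )
    return {
        cid: PairingResult(tuple(b["pairs"]), tuple(b["orb"]), tuple(b["orc"]))
        for cid, b in buckets.items()
    }


def count_cells(
    per_cell: Mapping[int, PairingResult],
    condition: str = "",
    frequency: str = "",
    organ: str = "",
) -> pd.DataFrame:
    """One row per cell: paired / orphan / total ribbon counts plus labels."""
    rows = []
    for cid in sorted(per_cell):
        r = per_cell[cid]
        rows.append(
            {
                "organ": organ,
                "cell_id": cid,
                "condition": condition,
                "frequency": frequency,
                "paired": len(r.pairs),
                "orphan_ribbons": len(r.orphan_ribbons),
                "orphan_receptors": len(r.orphan_receptors),
                "total_ribbons": len(r.pairs) + len(r.orphan_ribbons),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "organ", "cell_id", "condition", "frequency",
            "paired", "orphan_ribbons", "orphan_receptors", "total_ribbons",
        ],
    )


def count_summary(
    cell_counts: pd.DataFrame,
    by: Sequence[str] = ("condition", "frequency"),
) -> pd.DataFrame:
    """Mean and s.e.m. of per-IHC counts by condition and frequency region.

    The s.e.m. is the sample standard deviation (ddof=1) over cells divided
    by the square root of the cell count; total = paired + orphan holds for
    every row by construction of the per-cell table.
    """
    if len(cell_counts) < 1:
        raise ValueError("need at least one cell")
    metrics = ["total_ribbons", "paired", "orphan_ribbons"]
    rows = []
    for keys, grp in cell_counts.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(by, keys))
        n = len(grp)
        row["n_cells"] = n
        for m in metrics:
            vals = grp[m].to_numpy(dtype=float)
            row[f"{m}_mean"] = vals.mean()
            row[f"{m}_sem"] = (
                vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
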