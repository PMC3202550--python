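"""Neighbourhood crowding indices over the 3 x 3 subplot window.

Two indices quantify crowding around a focal tree, both computed over the
15 x 15 m square of nine 5 x 5 m subplots centred on the focal tree's
subplot, using start-of-period diameters:

* ``BA``  -- size-symmetric index: summed basal area of all live neighbours
  in the window (the focal tree itself excluded).
* ``BAL`` -- size-asymmetric index: summed basal area of neighbours with
  strictly larger diameter than the focal tree, a proxy for shading by
  taller individuals.

Only trees in the central four subplots (rows 1-2, cols 1-2, 0-based) have
a full window inside their plot and are focal-eligible for modelling.  For
simulation purposes an index with the window clipped at the plot boundary
can be requested for edge trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .census import SUBPLOT_GRID, TreeRecord, tree_basal_area_m2

__all__ = [
    "CENTRAL_SUBPLOTS",
    "WINDOW_AREA_HA",
    "EligibilityError",
    "CrowdingIndices",
    "is_focal_eligible",
    "window_subplots",
    "compute_crowding",
    "crowding_table",
]

#: The four central subplots of the 4 x 4 grid (0-based row, col).
CENTRAL_SUBPLOTS = frozenset({(1, 1), (1, 2), (2, 1), (2, 2)})
#: Area of the 15 x 15 m window in hectares.
WINDOW_AREA_HA = 0.0225


class EligibilityError(ValueError):
    """Raised when a window is requested for a non-central subplot."""


def is_focal_eligible(subplot_row: int, subplot_col: int) -> bool:
    return (subplot_row, subplot_col) in CENTRAL_SUBPLOTS


def window_subplots(focal_subplot: tuple[int, int]) -> frozenset[tuple[int, int]]:
    """The 3 x 3 block of subplots centred on a central focal subplot."""
    row, col = focal_subplot
    if (row, col) not in CENTRAL_SUBPLOTS:
        raise EligibilityError(
            f"subplot {focal_subplot} is not one of the central four; its "
            "15 x 15 m window would extend outside the plot"
        )
    return frozenset(
        (r, c) for r in range(row - 1, row + 2) for c in range(col - 1, col + 2)
    )


@dataclass(frozen=True)
class CrowdingIndices:
    """Crowding of one focal tree: window sums in m^2 per 15 x 15 m window."""

    tree_id: str
    ba: float
    bal: float
    focal_eligible: bool


def compute_crowding(
    records: Sequence[TreeRecord],
    census: str,
    include_edge_trees: bool = False,
    per_hectare: bool = False,
) -> list[CrowdingIndices]:
    """Compute BA and BAL for live trees at ``census``.

    By default only focal-eligible trees (central four subplots) are
    returned, with the full 3 x 3 window.  With ``include_edge_trees`` every
    live tree is returned and edge trees use the window clipped at the plot
    boundary -- useful for whole-stand simulation, not for fitting.

    Ties in diameter contribute to BA only: "larger" is strict, so
    ``bal <= ba`` always, with equality iff every neighbour is strictly
    larger than the focal tree.  Dead or absent trees contribute nothing.
    ``per_hectare`` rescales the window sums by the 0.0225 ha window area;
    since covariates are standardized before modelling this rescaling is
    inert for inference.
    """
    live = [rec for rec in records if rec.is_alive(census)]
    order: dict[str, int] = {}
    by_plot: dict[str, list[TreeRecord]] = {}
    for i, rec in enumerate(live):
        order[rec.tree_id] = i
        by_plot.setdefault(rec.plot_id, []).append(rec)

    scale = 1.0 / WINDOW_AREA_HA if per_hectare else 1.0
    out: list[CrowdingIndices | None] = [None] * len(live)
    for plot_records in by_plot.values():
        rows = np.array([r.subplot_row for r in plot_records])
        cols = np.array([r.subplot_col for r in plot_records])
        diam = np.array([r.diameter_at(census) for r in plot_records], dtype=float)
        area = tree_basal_area_m2(diam)
        # pairwise window membership: neighbour n is in focal i's window iff
        # both subplot offsets are within one; self excluded
        in_window = (
            (np.abs(rows[:, None] - rows[None, :]) <= 1)
            & (np.abs(cols[:, None] - cols[None, :]) <= 1)
        )
        np.fill_diagonal(in_window, False)
        ba = in_window @ area
        larger = diam[None, :] > diam[:, None]
        bal = (in_window & larger) @ area
        for i, rec in enumerate(plot_records):
            eligible = is_focal_eligible(rec.subplot_row, rec.subplot_col)
            if eligible or include_edge_trees:
                out[order[rec.tree_id]] = CrowdingIndices(
                    tree_id=rec.tree_id,
                    ba=float(ba[i]) * scale,
                    bal=float(bal[i]) * scale,
                    focal_eligible=eligible,
                )
    return [c for c in out if c is not None]


def crowding_table(
    records: Sequence[TreeRecord],
    census: str,
    include_edge_trees: bool = False,
    per_hectare: bool = False,
) -> pd.DataFrame:
    """Crowding indices as a DataFrame (tree_id, census, BA, BAL, focal_eligible)."""
    indices = compute_crowding(
        records, census, include_edge_trees=include_edge_trees, per_hectare=per_hectare
    )
    return pd.DataFrame(
        {
            "tree_id": [c.tree_id for c in indices],
            "census": census,
            "BA": [c.ba for c in indices],
            "BAL": [c.bal for c in indices],
            "focal_eligible": [c.focal_eligible for c in indices],
        }
    )
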