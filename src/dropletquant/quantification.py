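"""Per-cell aggregation of droplet features.

Builds the per-cell records behind the study-level questions: how much
droplet signal does each cell carry, which cells have no detectable droplets
at all, and is the 'cut' mitotic-failure phenotype associated with low
droplet content. Cell identity comes either from a user-supplied cell label
image (droplets assigned by centroid containment) or from a pre-built
phenotype table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PHENOTYPE_COLUMNS",
    "AssignmentResult",
    "assign_droplets_to_cells",
    "per_cell_mean_total",
    "cut_by_droplet_contingency",
]

PHENOTYPE_COLUMNS = ["cell_id", "strain", "medium", "cut_status",
                     "droplet_count", "total_intensity"]


@dataclass
class AssignmentResult:
    """Outcome of droplet-to-cell assignment.

    ``table`` holds one record per cell (zero-droplet cells included);
    ``unassigned`` lists droplets whose centroid fell on background.
    """

    table: pd.DataFrame
    unassigned: pd.DataFrame


def _validate_phenotype_table(table: pd.DataFrame) -> pd.DataFrame:
    if len(table) and table["cell_id"].duplicated().any():
        raise ValueError("cell_id values must be unique")
    return table


def assign_droplets_to_cells(droplets: pd.DataFrame,
                             cell_labels: np.ndarray,
                             *,
                             strain: str = "",
                             medium: str = "") -> AssignmentResult:
    """Assign each droplet to the cell label under its centroid pixel.

    Every label present in ``cell_labels`` (k > 0) yields a cell record even
    if no droplet lands in it; droplets whose centroid sits on label 0 are
    reported separately and increment no cell.
    """
    cell_labels = np.asarray(cell_labels)
    cell_ids = np.unique(cell_labels)
    cell_ids = cell_ids[cell_ids > 0]
    counts = {int(c): 0 for c in cell_ids}
    totals = {int(c): 0.0 for c in cell_ids}
    unassigned_idx = []
    for idx, row in droplets.iterrows():
        r = int(round(float(row["centroid_row"])))
        c = int(round(float(row["centroid_col"])))
        if not (0 <= r < cell_labels.shape[0] and 0 <= c < cell_labels.shape[1]):
            raise ValueError(f"droplet centroid ({r}, {c}) outside the image")
        label = int(cell_labels[r, c])
        if label == 0:
            unassigned_idx.append(idx)
        else:
            counts[label] += 1
            totals[label] += float(row["integrated_intensity"])
    records = [{
        "cell_id": cid,
        "strain": strain,
        "medium": medium,
        "cut_status": False,
        "droplet_count": counts[cid],
        "total_intensity": totals[cid],
    } for cid in sorted(counts)]
    table = pd.DataFrame(records, columns=PHENOTYPE_COLUMNS)
    unassigned = droplets.loc[unassigned_idx].copy()
    return AssignmentResult(table=_validate_phenotype_table(table), unassigned=unassigned)


def per_cell_mean_total(table: pd.DataFrame) -> float:
    """Mean total droplet intensity per cell, zero-droplet cells included."""
    _validate_phenotype_table(table)
    if len(table) == 0:
        raise ValueError("empty phenotype table")
    return float(table["total_intensity"].mean())


def cut_by_droplet_contingency(table: pd.DataFrame) -> np.ndarray:
    """2x2 contingency of 'cut' status against droplet presence.

    Rows: cut, non-cut. Columns: no detectable droplets, has droplets.
    With this orientation a one-sided Fisher test with alternative
    ``"greater"`` asks whether 'cut' cells are enriched among droplet-free
    cells.
    """
    _validate_phenotype_table(table)
    if len(table) == 0:
        raise ValueError("empty phenotype table")
    cut = table["cut_status"].astype(bool).to_numpy()
    has = (table["droplet_count"].to_numpy() > 0)
    return np.array([
        [int((cut & ~has).sum()), int((cut & has).sum())],
        [int((~cut & ~has).sum()), int((~cut & has).sum())],
    ])
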