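"""Per-cell puncta density and the two quality-control exclusion rules.

The density statistic is condensates per 100 µm³ of nuclear volume.  Before
any cross-condition comparison two exclusions apply, in order:

1. cells with nuclear volume strictly below 200 µm³ are dropped (a volume
   that small suggests a mis-segmented or out-of-frame cell);
2. among the remaining expressing cells of each condition, the lowest third
   by mean reporter intensity is dropped (adjacent bright cells shed
   diffuse signal into dim neighbours and cause false-positive spots).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .segmentation import PunctaSet

__all__ = [
    "CellQCRecord",
    "compute_cell_metrics",
    "apply_qc_filters",
    "records_to_frame",
    "condition_summary",
]


@dataclass
class CellQCRecord:
    cell_id: str
    condition: str
    nucleus_volume_um3: float
    mean_reporter_intensity: float
    n_puncta: int
    puncta_density: float  # puncta per 100 um^3
    excluded_small_volume: bool = False
    excluded_low_expression: bool = False


def compute_cell_metrics(
    puncta_sets: list[PunctaSet],
    condition: str = "",
    session: str = "",
) -> list[CellQCRecord]:
    """Compute the per-cell density records for one condition/session.

    density = 100 × n_puncta / nucleus volume [µm³].  The mean reporter
    intensity over the nucleus mask comes from the segmentation stage.
    """
    records = []
    for ps in puncta_sets:
        cell = ps.cell
        if cell.volume_um3 <= 0:
            raise ValueError(f"cell {cell.nucleus_id}: zero nucleus volume")
        prefix = f"{session}:" if session else ""
        records.append(
            CellQCRecord(
                cell_id=f"{prefix}{cell.nucleus_id}",
                condition=condition or ps.condition,
                nucleus_volume_um3=cell.volume_um3,
                mean_reporter_intensity=cell.mean_intensity_by_channel.get(
                    "reporter", float("nan")
                ),
                n_puncta=len(ps.puncta),
                puncta_density=100.0 * len(ps.puncta) / cell.volume_um3,
            )
        )
    return records


def apply_qc_filters(
    records: list[CellQCRecord],
    volume_cutoff_um3: float = 200.0,
    low_expression_fraction: float = 1.0 / 3.0,
    expression_floor: float = 0.0,
) -> tuple[list[CellQCRecord], list[CellQCRecord]]:
    """Apply the two exclusion rules; returns ``(kept, flagged)``.

    Volume exclusion is strict ``< volume_cutoff_um3``.  The expression
    exclusion is rank-based per condition: among volume-passing cells whose
    mean reporter intensity exceeds ``expression_floor``, the
    ``floor(n * low_expression_fraction)`` lowest-intensity cells are
    flagged, ties broken by cell_id order.  Cells at or below the floor are
    not "expressing" and do not enter the tercile but are kept.
    """
    out = [replace(r, excluded_small_volume=False, excluded_low_expression=False)
           for r in records]
    for r in out:
        if r.nucleus_volume_um3 < volume_cutoff_um3:
            r.excluded_small_volume = True

    by_condition: dict[str, list[CellQCRecord]] = {}
    for r in out:
        if not r.excluded_small_volume and r.mean_reporter_intensity > expression_floor:
            by_condition.setdefault(r.condition, []).append(r)
    for cond_records in by_condition.values():
        n_excl = int(np.floor(len(cond_records) * low_expression_fraction))
        ranked = sorted(cond_records,
                        key=lambda r: (r.mean_reporter_intensity, r.cell_id))
        for r in ranked[:n_excl]:
            r.excluded_low_expression = True

    kept = [r for r in out if not (r.excluded_small_volume or r.excluded_low_expression)]
    flagged = [r for r in out if r.excluded_small_volume or r.excluded_low_expression]
    return kept, flagged


def records_to_frame(records: list[CellQCRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def condition_summary(kept: list[CellQCRecord]) -> pd.DataFrame:
    """Per-condition summary (n cells, median density, IQR) for box plots."""
    df = records_to_frame(kept)
    if df.empty:
        return pd.DataFrame(
            columns=["condition", "n_cells", "median_density", "iqr_density"]
        )
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        q1, med, q3 = grp["puncta_density"].quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "condition": cond,
                "n_cells": len(grp),
                "median_density": med,
                "iqr_density": q3 - q1,
            }
        )
    return pd.DataFrame(rows)
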