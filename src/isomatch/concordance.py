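"""Per-individual and population concordance of isotope assignment and KDE.

For each individual, the isotope-assignment binary map is intersected with
the KDE non-breeding range rasterized on the same grid; the overlap is
reported as a cell count and as a percentage of the KDE's cells (the KDE is
the denominator: the question is how much of the tracked range the isotope
method recovers). The matched pairing compares the 50% KDE with the 1:1
(q=0.50) odds map and the 75% KDE with the 3:1 (q=0.75) map.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assignment import BinaryMask

KDE_LEVELS = (0.50, 0.75)
ODDS_LEVELS = (0.50, 0.75)
#: matched pairing: (KDE level, odds level)
MATCHED_PAIRS = ((0.50, 0.50), (0.75, 0.75))

#: Column layout of the published per-individual concordance table.
TABLE1_COLUMNS = [
    "id", "lat", "lon",
    "kde_km2_50", "kde_km2_75", "kde_cells_50", "kde_cells_75",
    "cn_cells_11", "cn_cells_31", "hcn_cells_11", "hcn_cells_31",
    "ov_hcn_cells_50", "ov_hcn_cells_75", "ov_hcn_pct_50", "ov_hcn_pct_75",
    "ov_cn_cells_50", "ov_cn_cells_75", "ov_cn_pct_50", "ov_cn_pct_75",
]


def round_half_up(x, decimals: int = 1):
    """Round half away from zero (the convention of the printed tables).

    numpy's default rounds half to even; printed values like 10.1 for
    21/207*100 = 10.14... are insensitive, but exact .x5 boundaries are not.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def overlap(kde_mask: BinaryMask, assign_mask: BinaryMask) -> tuple[int, float]:
    """(intersection cell count, percent of KDE cells overlapped).

    The percentage denominator is the KDE cell count, reported to one
    decimal (half away from zero).
    """
    if not kde_mask.grid.same_geometry(assign_mask.grid):
        raise ValueError("masks must share one grid")
    n_kde = kde_mask.n_assigned
    if n_kde == 0:
        raise ValueError("empty KDE mask")
    cells = int((kde_mask.cells & assign_mask.cells).sum())
    return cells, round_half_up(cells / n_kde * 100.0, 1)


@dataclass
class OverlapRecord:
    """One individual's row of the concordance table."""

    id: str
    lat: float
    lon: float
    kde_km2: dict[float, float]  # KDE level -> area
    kde_cells: dict[float, int]  # KDE level -> cell count
    assigned_cells: dict[tuple[str, float], int]  # (isotope_set, odds) -> count
    overlap_cells: dict[tuple[str, float], int] = field(default_factory=dict)
    overlap_pct: dict[tuple[str, float], float] = field(default_factory=dict)

    def as_row(self) -> dict:
        # an isotope set an individual could not be assigned with (e.g. no
        # delta-2H measurement) yields missing values in its columns
        nan = float("nan")
        ac, oc, op = self.assigned_cells, self.overlap_cells, self.overlap_pct
        return {
            "id": self.id, "lat": self.lat, "lon": self.lon,
            "kde_km2_50": self.kde_km2[0.50], "kde_km2_75": self.kde_km2[0.75],
            "kde_cells_50": self.kde_cells[0.50], "kde_cells_75": self.kde_cells[0.75],
            "cn_cells_11": ac.get(("CN", 0.50), nan),
            "cn_cells_31": ac.get(("CN", 0.75), nan),
            "hcn_cells_11": ac.get(("HCN", 0.50), nan),
            "hcn_cells_31": ac.get(("HCN", 0.75), nan),
            "ov_hcn_cells_50": oc.get(("HCN", 0.50), nan),
            "ov_hcn_cells_75": oc.get(("HCN", 0.75), nan),
            "ov_hcn_pct_50": op.get(("HCN", 0.50), nan),
            "ov_hcn_pct_75": op.get(("HCN", 0.75), nan),
            "ov_cn_cells_50": oc.get(("CN", 0.50), nan),
            "ov_cn_cells_75": oc.get(("CN", 0.75), nan),
            "ov_cn_pct_50": op.get(("CN", 0.50), nan),
            "ov_cn_pct_75": op.get(("CN", 0.75), nan),
        }

    @classmethod
    def from_row(cls, row) -> "OverlapRecord":
        return cls(
            id=str(row["id"]), lat=float(row["lat"]), lon=float(row["lon"]),
            kde_km2={0.50: float(row["kde_km2_50"]), 0.75: float(row["kde_km2_75"])},
            kde_cells={0.50: int(row["kde_cells_50"]), 0.75: int(row["kde_cells_75"])},
            assigned_cells={
                ("CN", 0.50): int(row["cn_cells_11"]), ("CN", 0.75): int(row["cn_cells_31"]),
                ("HCN", 0.50): int(row["hcn_cells_11"]), ("HCN", 0.75): int(row["hcn_cells_31"]),
            },
            overlap_cells={
                ("HCN", 0.50): int(row["ov_hcn_cells_50"]),
                ("HCN", 0.75): int(row["ov_hcn_cells_75"]),
                ("CN", 0.50): int(row["ov_cn_cells_50"]),
                ("CN", 0.75): int(row["ov_cn_cells_75"]),
            },
            overlap_pct={
                ("HCN", 0.50): float(row["ov_hcn_pct_50"]),
                ("HCN", 0.75): float(row["ov_hcn_pct_75"]),
                ("CN", 0.50): float(row["ov_cn_pct_50"]),
                ("CN", 0.75): float(row["ov_cn_pct_75"]),
            },
        )


def build_record(id: str, kde_masks: dict[float, BinaryMask],
                 assign_masks: dict[tuple[str, float], BinaryMask],
                 kde_km2: dict[float, float],
                 centroid: tuple[float, float]) -> OverlapRecord:
    """Assemble one individual's concordance row with the matched pairing."""
    rec = OverlapRecord(
        id=id, lon=round_half_up(centroid[0], 1), lat=round_half_up(centroid[1], 1),
        kde_km2={lvl: kde_km2[lvl] for lvl in KDE_LEVELS},
        kde_cells={lvl: kde_masks[lvl].n_assigned for lvl in KDE_LEVELS},
        assigned_cells={key: m.n_assigned for key, m in assign_masks.items()},
    )
    for iso_set in ("HCN", "CN"):
        for kde_lvl, odds in MATCHED_PAIRS:
            key = (iso_set, odds)
            if key not in assign_masks:
                continue
            cells, pct = overlap(kde_masks[kde_lvl], assign_masks[key])
            rec.overlap_cells[(iso_set, kde_lvl)] = cells
            rec.overlap_pct[(iso_set, kde_lvl)] = pct
    return rec


@dataclass
class ConcordanceSummary:
    """Column means and match counts over a set of overlap records."""

    n: int
    means: dict[str, float]
    match_counts: dict[tuple[str, float], int]
    medians: dict[str, float] = field(default_factory=dict)


def summarize(records: Sequence[OverlapRecord]) -> ConcordanceSummary:
    """Column-wise means (km^2 and cells to nearest integer, percents to one
    decimal, half away from zero) and the number of individuals with any
    overlap, per isotope set and pairing."""
    if not records:
        raise ValueError("no records to summarize")
    df = pd.DataFrame([r.as_row() for r in records])
    means: dict[str, float] = {}
    medians: dict[str, float] = {}
    for col in TABLE1_COLUMNS:
        if col == "id":
            continue
        col_mean = float(df[col].mean())
        col_med = float(df[col].median())
        # overlap cells and percents are printed to one decimal; KDE areas,
        # KDE cell counts and assigned-cell counts to the nearest integer
        decimals = 1 if (col.startswith("ov_") or col in ("lat", "lon")) else 0
        means[col] = round_half_up(col_mean, decimals)
        medians[col] = round_half_up(col_med, decimals)
    match_counts = {
        key: int(sum(1 for r in records if r.overlap_cells.get(key, 0) > 0))
        for key in (("HCN", 0.50), ("HCN", 0.75), ("CN", 0.50), ("CN", 0.75))
    }
    return ConcordanceSummary(n=len(records), means=means,
                              match_counts=match_counts, medians=medians)


def report(records: Sequence[OverlapRecord],
           summary: ConcordanceSummary | None = None,
           format: str = "csv") -> str:
    """Render the concordance table (with a mean row) as CSV or Markdown."""
    if format not in ("csv", "markdown"):
        raise ValueError(f"unknown format {format!r}")
    if summary is None:
        summary = summarize(records)
    df = pd.DataFrame([r.as_row() for r in records], columns=TABLE1_COLUMNS)
    mean_row = {"id": "mean", **{c: summary.means[c] for c in TABLE1_COLUMNS if c != "id"}}
    # the printed table leaves position blank in the mean row
    mean_row["lat"] = mean_row["lon"] = ""
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    for col in TABLE1_COLUMNS:
        if col.startswith(("kde_", "cn_", "hcn_")) and not df[col].isna().any():
            df[col] = df[col].astype(int)
        elif col.startswith("ov_"):
            df[col] = df[col].astype(float)
    if format == "markdown":
        return df.to_markdown(index=False)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()


def records_from_table(df: pd.DataFrame) -> list[OverlapRecord]:
    """Parse per-individual rows of a concordance CSV (mean row excluded)."""
    body = df[df["id"].astype(str).str.lower() != "mean"]
    return [OverlapRecord.from_row(row) for _, row in body.iterrows()]
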