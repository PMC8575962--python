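"""Time-binned ancestral birth-location enrichment maps.

Records are grouped into fixed year bins, aggregated to rounded lat/lon
cells, and each cell is scored by the odds ratio of a unique-tree 2x2 table
(in-group at cell / elsewhere vs background at cell / elsewhere), with a
Haldane-Anscombe 0.5 correction on any zero cell. Passing cells satisfy both
the odds-ratio and unique-tree-count filters.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

from .simdata.annotate import TIME_BINS, BirthRecord

__all__ = [
    "LocationCell",
    "bin_records",
    "location_enrichment",
    "small_set_mode",
    "export_map",
    "read_geojson_cells",
]

logger = logging.getLogger(__name__)

Bin = tuple[int, int]


@dataclass(frozen=True)
class LocationCell:
    time_bin: Bin
    lat: float
    lon: float
    n_in_trees: int
    n_bg_trees: int
    n_in_records: int
    n_bg_records: int
    odds_ratio: float
    passes: bool


def bin_records(
    records: list[BirthRecord],
    bins: tuple[Bin, ...] = TIME_BINS,
) -> dict[Bin, list[BirthRecord]]:
    """Group records by year bin: left-closed/right-open except the final bin,
    which is closed on both ends. Out-of-range records are dropped (logged)."""
    out: dict[Bin, list[BirthRecord]] = {b: [] for b in bins}
    dropped = 0
    last = len(bins) - 1
    for r in records:
        for i, (y0, y1) in enumerate(bins):
            if y0 <= r.year < y1 or (i == last and r.year == y1):
                out[(y0, y1)].append(r)
                break
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d birth records outside the year bins", dropped)
    return out


def _cell_key(r: BirthRecord, rounding: int) -> tuple[float, float]:
    return (round(r.lat, rounding), round(r.lon, rounding))


def _unique_trees_by_cell(
    records: list[BirthRecord], rounding: int
) -> tuple[dict[tuple[float, float], set[str]], set[str]]:
    cells: dict[tuple[float, float], set[str]] = {}
    all_trees: set[str] = set()
    for r in records:
        cells.setdefault(_cell_key(r, rounding), set()).add(r.tree_id)
        all_trees.add(r.tree_id)
    return cells, all_trees


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Cross-product OR with a 0.5 added to every cell when any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def location_enrichment(
    in_records: list[BirthRecord],
    bg_records: list[BirthRecord],
    rounding: int = 2,
    min_trees: int = 10,
    min_or: float = 4.0,
    bins: tuple[Bin, ...] = TIME_BINS,
) -> list[LocationCell]:
    """Per (time bin, rounded cell) odds ratios of unique-tree counts.

    A cell passes iff OR >= ``min_or`` and in-group unique trees >=
    ``min_trees``. A tree contributes at most once per (bin, cell). Record
    counts are also carried for map sizing.
    """
    if rounding not in (0, 2):
        raise ValueError("rounding must be 0 or 2")
    if not in_records:
        logger.warning("empty in-group: no cells to score")
        return []
    in_binned = bin_records(in_records, bins)
    bg_binned = bin_records(bg_records, bins)
    cells: list[LocationCell] = []
    for b in bins:
        in_cells, in_trees = _unique_trees_by_cell(in_binned[b], rounding)
        bg_cells, bg_trees = _unique_trees_by_cell(bg_binned[b], rounding)
        in_rec_counts: dict[tuple[float, float], int] = {}
        bg_rec_counts: dict[tuple[float, float], int] = {}
        for r in in_binned[b]:
            k = _cell_key(r, rounding)
            in_rec_counts[k] = in_rec_counts.get(k, 0) + 1
        for r in bg_binned[b]:
            k = _cell_key(r, rounding)
            bg_rec_counts[k] = bg_rec_counts.get(k, 0) + 1
        for key in sorted(set(in_cells) | set(bg_cells)):
            n_in = len(in_cells.get(key, ()))
            n_bg = len(bg_cells.get(key, ()))
            odds = _odds_ratio(
                n_in, len(in_trees) - n_in, n_bg, len(bg_trees) - n_bg
            )
            cells.append(
                LocationCell(
                    b, key[0], key[1], n_in, n_bg,
                    in_rec_counts.get(key, 0), bg_rec_counts.get(key, 0),
                    odds, odds >= min_or and n_in >= min_trees,
                )
            )
    return cells


def small_set_mode(
    in_records: list[BirthRecord],
    bg_records: list[BirthRecord],
    min_trees: int = 2,
    min_or: float = 4.0,
    bins: tuple[Bin, ...] = TIME_BINS,
) -> list[LocationCell]:
    """Coarse variant for small in-groups: integer-degree cells and a relaxed
    unique-tree requirement, same odds-ratio filter."""
    return location_enrichment(
        in_records, bg_records, rounding=0, min_trees=min_trees, min_or=min_or,
        bins=bins,
    )


def export_map(cells: list[LocationCell], geojson_path: str | Path,
               csv_path: str | Path | None = None) -> None:
    """Write a GeoJSON FeatureCollection (and optional CSV) of cells.

    Features carry log2(OR) for coloring and log10 of the in-group record
    count for sizing.
    """
    features = []
    for c in cells:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [c.lon, c.lat]},
                "properties": {
                    "bin_start": c.time_bin[0],
                    "bin_end": c.time_bin[1],
                    "n_in_trees": c.n_in_trees,
                    "n_bg_trees": c.n_bg_trees,
                    "n_in_records": c.n_in_records,
                    "n_bg_records": c.n_bg_records,
                    "odds_ratio": c.odds_ratio,
                    "log2_or": math.log2(c.odds_ratio),
                    "log10_n_records": (
                        math.log10(c.n_in_records) if c.n_in_records > 0 else None
                    ),
                    "passes": c.passes,
                },
            }
        )
    Path(geojson_path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
    if csv_path is not None:
        with open(csv_path, "w") as fh:
            fh.write("bin_start,bin_end,lat,lon,n_in_trees,n_bg_trees,"
                     "n_in_records,n_bg_records,odds_ratio,log2_or,passes\n")
            for c in cells:
                fh.write(
                    f"{c.time_bin[0]},{c.time_bin[1]},{c.lat!r},{c.lon!r},"
                    f"{c.n_in_trees},{c.n_bg_trees},{c.n_in_records},"
                    f"{c.n_bg_records},{c.odds_ratio!r},"
                    f"{math.log2(c.odds_ratio)!r},{c.passes}\n"
                )


def read_geojson_cells(path: str | Path) -> list[LocationCell]:
    data = json.loads(Path(path).read_text())
    cells = []
    for f in data["features"]:
        p = f["properties"]
        lon, lat = f["geometry"]["coordinates"]
        cells.append(
            LocationCell(
                (p["bin_start"], p["bin_end"]), lat, lon,
                p["n_in_trees"], p["n_bg_trees"],
                p["n_in_records"], p["n_bg_records"],
                p["odds_ratio"], p["passes"],
            )
        )
    return cells
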