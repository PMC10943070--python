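"""Proximity ligation assay spot quantification relative to the plasma membrane.

A PLA spot is classed *junctional* when its Euclidean distance to the cell's
membrane trace (a closed polyline, distances to the nearest segment) is at
most the band width — 1 micrometre by default, inclusive at the boundary —
and *cytoplasmic* otherwise.  Per cell the junctional:cytoplasmic ratio is
computed (undefined when no cytoplasmic spots exist), and antibody-pair
groups are compared with the Kruskal-Wallis omnibus test (tie-corrected)
followed by Dunn's pairwise z tests with Bonferroni adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import kruskal, norm, rankdata
from shapely.geometry import LineString, Point

from .errors import GeometryError, StatisticsError

logger = logging.getLogger(__name__)

DEFAULT_BAND_WIDTH = 1.0  # micrometres

JUNCTIONAL = "junctional"
CYTOPLASMIC = "cytoplasmic"


@dataclass
class PlaCellRecord:
    """Spot coordinates and membrane trace of one cell (micrometres).

    ``membrane`` must be a closed polyline (first vertex equals last, >= 3
    distinct vertices).  If coordinates were recorded in pixels, supply
    ``pixel_size`` (um/pixel); both spots and membrane are rescaled.
    """

    cell_id: str
    group: str
    spots: np.ndarray  # (n, 2)
    membrane: np.ndarray  # (m, 2), closed
    pixel_size: float | None = None

    def in_micrometres(self) -> "PlaCellRecord":
        if self.pixel_size is None:
            return self
        return PlaCellRecord(
            cell_id=self.cell_id,
            group=self.group,
            spots=self.spots * self.pixel_size,
            membrane=self.membrane * self.pixel_size,
            pixel_size=None,
        )


def _validated_trace(membrane: np.ndarray) -> LineString:
    membrane = np.asarray(membrane, dtype=float)
    if membrane.ndim != 2 or membrane.shape[1] != 2 or membrane.shape[0] < 4:
        raise GeometryError("membrane trace needs >= 3 vertices plus the closing vertex")
    if not np.allclose(membrane[0], membrane[-1]):
        raise GeometryError("membrane trace is not closed (first vertex != last)")
    return LineString(membrane)


def classify_spots(
    cell: PlaCellRecord,
    band_width: float = DEFAULT_BAND_WIDTH,
    contact_segments=None,
) -> pd.DataFrame:
    """Label each spot junctional/cytoplasmic by distance to the membrane.

    Returns columns ``cell, group, x, y, distance, label``; a spot is
    junctional iff distance <= band_width (inclusive).  ``contact_segments``
    optionally restricts the junction to a subset of membrane segments
    (indices into the closed trace, segment i = vertices i..i+1), e.g. the
    cell-cell contact arcs; by default the whole trace counts.
    """
    cell = cell.in_micrometres()
    trace = _validated_trace(cell.membrane)
    if contact_segments is not None:
        membrane = np.asarray(cell.membrane, dtype=float)
        n_segments = len(membrane) - 1
        bad = [i for i in contact_segments if not 0 <= i < n_segments]
        if bad or not list(contact_segments):
            raise GeometryError(
                f"contact_segments must be non-empty indices in [0, {n_segments}): {bad}"
            )
        pieces = [LineString(membrane[i : i + 2]) for i in contact_segments]
        trace = pieces
    spots = np.asarray(cell.spots, dtype=float).reshape(-1, 2)
    if isinstance(trace, list):
        distances = np.array(
            [min(seg.distance(Point(x, y)) for seg in trace) for x, y in spots]
        )
    else:
        distances = np.array([trace.distance(Point(x, y)) for x, y in spots])
    labels = np.where(distances <= band_width, JUNCTIONAL, CYTOPLASMIC)
    return pd.DataFrame(
        {
            "cell": cell.cell_id,
            "group": cell.group,
            "x": spots[:, 0] if len(spots) else np.array([]),
            "y": spots[:, 1] if len(spots) else np.array([]),
            "distance": distances,
            "label": labels,
        }
    )


@dataclass
class PlaRatio:
    cell_id: str
    group: str
    n_junctional: int
    n_cytoplasmic: int
    ratio: float | None  # None when cytoplasmic count is 0 (undefined)


def junctional_ratio(labels: pd.DataFrame) -> PlaRatio:
    """Junctional:cytoplasmic ratio of one cell's labeled spots."""
    n_j = int((labels["label"] == JUNCTIONAL).sum())
    n_c = int((labels["label"] == CYTOPLASMIC).sum())
    cell_id = labels["cell"].iloc[0] if len(labels) else ""
    group = labels["group"].iloc[0] if len(labels) else ""
    if n_c == 0:
        logger.info("cell %s: no cytoplasmic spots, ratio undefined", cell_id)
        return PlaRatio(cell_id, group, n_j, n_c, None)
    return PlaRatio(cell_id, group, n_j, n_c, n_j / n_c)


def dunn_pairwise(groups: dict, pairs=None) -> list[dict]:
    """Dunn's z tests on pooled ranks with tie correction, Bonferroni-adjusted
    over the requested comparisons (all pairs by default)."""
    names = list(groups)
    pairs = list(pairs) if pairs is not None else list(combinations(names, 2))
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    ranks = rankdata(values)
    mean_ranks, start = {}, 0
    for g in names:
        mean_ranks[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    sigma2 = N * (N + 1) / 12.0 - tie_term
    results = []
    for a, b in pairs:
        se = np.sqrt(sigma2 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * norm.sf(abs(z))
        results.append(
            dict(group_a=a, group_b=b, z=float(z), p=float(p), p_adjusted=float(min(1.0, p * len(pairs))))
        )
    return results


def compare_groups(ratios_by_group: dict, pairs=None) -> dict:
    """Kruskal-Wallis omnibus plus Dunn pairwise comparisons.

    ``ratios_by_group`` maps group label -> iterable of defined per-cell
    ratios (undefined ratios must be excluded upstream).  Requires >= 2
    groups with >= 2 values each.
    """
    clean = {g: [float(v) for v in vals] for g, vals in ratios_by_group.items()}
    if len(clean) < 2 or any(len(v) < 2 for v in clean.values()):
        raise StatisticsError("need >= 2 groups with >= 2 defined ratios each")
    samples = list(clean.values())
    try:
        h_stat, p_value = kruskal(*samples)
    except ValueError:  # every observation identical: no evidence of difference
        h_stat, p_value = 0.0, 1.0
    return {
        "kruskal_h": float(h_stat),
        "kruskal_p": float(p_value),
        "group_sizes": {g: len(v) for g, v in clean.items()},
        "pairwise": dunn_pairwise(clean, pairs),
    }


def ratios_from_records(
    records, band_width: float = DEFAULT_BAND_WIDTH
) -> pd.DataFrame:
    """Per-cell ratio table from cell records; undefined ratios carried as NaN."""
    rows = []
    for record in records:
        r = junctional_ratio(classify_spots(record, band_width))
        rows.append(
            dict(
                cell=r.cell_id,
                group=r.group,
                n_junctional=r.n_junctional,
                n_cytoplasmic=r.n_cytoplasmic,
                ratio=np.nan if r.ratio is None else r.ratio,
            )
        )
    return pd.DataFrame(rows, columns=["cell", "group", "n_junctional", "n_cytoplasmic", "ratio"])


def read_cell_records(spots_csv, membranes_csv, pixel_size: float | None = None) -> list:
    """Assemble cell records from a spots CSV (cell, group, x, y) and a
    membranes CSV (cell, vertex, x, y; vertices ordered, trace closed)."""
    spots = pd.read_csv(spots_csv)
    membranes = pd.read_csv(membranes_csv)
    records = []
    for cell_id, spot_grp in spots.groupby("cell", sort=True):
        mem = membranes[membranes["cell"] == cell_id].sort_values("vertex")
        if mem.empty:
            raise GeometryError(f"no membrane trace for cell {cell_id!r}")
        records.append(
            PlaCellRecord(
                cell_id=str(cell_id),
                group=str(spot_grp["group"].iloc[0]),
                spots=spot_grp[["x", "y"]].to_numpy(dtype=float),
                membrane=mem[["x", "y"]].to_numpy(dtype=float),
                pixel_size=pixel_size,
            )
        )
    return records


def simulate_pla_cells(
    n_cells: int,
    group: str,
    spots_per_cell: int,
    junctional_frac: float,
    side: float = 10.0,
    band_width: float = DEFAULT_BAND_WIDTH,
    rng: np.random.Generator | None = None,
) -> list:
    """Synthetic square cells with a known junctional spot fraction.

    Junctional spots are uniform in the inward band of width ``band_width``
    along the square membrane; the rest are uniform in the interior.  Used as
    the programmatic fixture generator for the PLA stage.
    """
    rng = rng or np.random.default_rng(0)
    square = np.array([[0, 0], [side, 0], [side, side], [0, side], [0, 0]], dtype=float)
    records = []
    for i in range(n_cells):
        n_j = int(round(spots_per_cell * junctional_frac))
        n_c = spots_per_cell - n_j
        # band spots: pick an edge offset and a depth within the band
        t = rng.uniform(0, 4 * side, size=n_j)
        depth = rng.uniform(0, band_width, size=n_j)
        pts = []
        for tj, dj in zip(t, depth):
            edge, offset = int(tj // side), tj % side
            if edge == 0:
                pts.append([offset, dj])
            elif edge == 1:
                pts.append([side - dj, offset])
            elif edge == 2:
                pts.append([side - offset, side - dj])
            else:
                pts.append([dj, side - offset])
        interior = rng.uniform(band_width, side - band_width, size=(n_c, 2))
        spots = np.array(pts + interior.tolist()) if (n_j + n_c) else np.empty((0, 2))
        records.append(
            PlaCellRecord(
                cell_id=f"{group}_cell{i + 1}",
                group=group,
                spots=spots,
                membrane=square.copy(),
            )
        )
    return records
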