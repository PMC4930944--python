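"""Differential-coverage genome binning.

Genomes whose relative abundance differs between two samples occupy distinct
positions in the plane spanned by their scaffolds' log10 depths in the two
samples; bins are extracted either by an explicit polygon in that plane (the
reproducible form of interactive selection) or by deterministic density
clustering, and are then refined with marker duplication flags and read-pair
linkage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .coverage_profiling import CoverageProfile
from .linkage_graph import LinkageEdge, expand_bin
from .marker_genes import MarkerCatalog, MarkerHit, completeness, duplication

__all__ = [
    "Bin",
    "RefinementReport",
    "select_by_polygon",
    "cluster_coverage",
    "refine_bin",
    "write_bin_tsv",
    "write_provenance",
]


@dataclass
class Bin:
    bin_id: str
    scaffold_ids: set[str]
    provenance: dict = field(default_factory=dict)
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scaffold_ids:
            raise ValueError("bin must contain at least one scaffold")


@dataclass
class RefinementReport:
    added: list[str]
    flagged: list[str]
    removed: list[str]
    before: dict[str, float]
    after: dict[str, float]


# -- polygon selection -------------------------------------------------------


def _orient(ax, ay, bx, by, cx, cy) -> float:
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


def _on_segment(px, py, ax, ay, bx, by) -> bool:
    if _orient(ax, ay, bx, by, px, py) != 0.0:
        return False
    return min(ax, bx) <= px <= max(ax, bx) and min(ay, by) <= py <= max(ay, by)


def _segments_cross(p1, p2, p3, p4) -> bool:
    d1 = _orient(*p3, *p4, *p1)
    d2 = _orient(*p3, *p4, *p2)
    d3 = _orient(*p1, *p2, *p3)
    d4 = _orient(*p1, *p2, *p4)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 and d2 and d3 and d4:
        return True
    for (q, a, b) in ((p3, p1, p2), (p4, p1, p2), (p1, p3, p4), (p2, p3, p4)):
        if _on_segment(*q, *a, *b):
            return True
    return False


def _validate_polygon(vertices: Sequence[tuple[float, float]]) -> None:
    if len(vertices) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    n = len(vertices)
    edges = [(vertices[i], vertices[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges legitimately share a vertex
            if _segments_cross(edges[i][0], edges[i][1], edges[j][0], edges[j][1]):
                raise ValueError("self-intersecting polygon")


def point_in_polygon(x: float, y: float, vertices: Sequence[tuple[float, float]]) -> bool:
    """Even-odd membership; points on the boundary count as inside."""
    n = len(vertices)
    inside = False
    for i in range(n):
        ax, ay = vertices[i]
        bx, by = vertices[(i + 1) % n]
        if _on_segment(x, y, ax, ay, bx, by):
            return True
        if (ay > y) != (by > y):
            x_cross = ax + (y - ay) * (bx - ax) / (by - ay)
            if x < x_cross:
                inside = not inside
    return inside


def select_by_polygon(
    profiles: Iterable[CoverageProfile],
    sample_x: str,
    sample_y: str,
    polygon: Sequence[tuple[float, float]],
) -> set[str]:
    """Scaffolds whose (log10(depth_x + 0.01), log10(depth_y + 0.01)) lies
    inside or on the polygon (even-odd rule)."""
    _validate_polygon(polygon)
    selected = set()
    for p in profiles:
        if point_in_polygon(p.log_depth(sample_x), p.log_depth(sample_y), polygon):
            selected.add(p.scaffold_id)
    return selected


# -- density clustering ------------------------------------------------------


def cluster_coverage(
    profiles: Iterable[CoverageProfile],
    sample_x: str,
    sample_y: str,
    radius: float,
    min_members: int = 2,
) -> list[list[str]]:
    """Density-connected components in 2-D log-depth space.

    Two scaffolds are neighbors when their Euclidean distance is <=
    ``radius``; components with >= ``min_members`` are returned largest
    first, ties broken by the lexicographically smallest member, so the
    result is independent of input order.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    profiles = sorted(profiles, key=lambda p: p.scaffold_id)
    if not profiles:
        return []
    pts = np.array([(p.log_depth(sample_x), p.log_depth(sample_y)) for p in profiles])
    pairs = cKDTree(pts).query_pairs(r=radius, output_type="ndarray")
    n = len(profiles)
    if len(pairs):
        data = np.ones(len(pairs))
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for prof, lab in zip(profiles, labels):
        groups.setdefault(int(lab), []).append(prof.scaffold_id)
    candidates = [sorted(g) for g in groups.values() if len(g) >= min_members]
    candidates.sort(key=lambda g: (-len(g), g[0]))
    return candidates


# -- refinement --------------------------------------------------------------


def refine_bin(
    candidate: Iterable[str],
    profiles: Mapping[str, CoverageProfile],
    hits: Sequence[MarkerHit],
    catalog: MarkerCatalog,
    edges: Sequence[LinkageEdge],
    *,
    bin_id: str = "bin_1",
    rounds: int = 1,
    auto_trim: bool = False,
    max_trim_fraction: float = 0.01,
    provenance: dict | None = None,
) -> tuple[Bin, RefinementReport]:
    """Refine a candidate scaffold set.

    1. grow along linkage edges (``rounds`` rounds);
    2. flag scaffolds whose removal eliminates a duplicated marker while
       removing < ``max_trim_fraction`` of the bin length;
    3. recompute completeness/duplication before and after.

    Flagged scaffolds are removed only with ``auto_trim``.
    """
    seed = set(candidate)
    before = {
        "completeness_pct": completeness(seed, hits, catalog),
        "duplication_pct": duplication(seed, hits, catalog),
    }
    expanded, added = expand_bin(seed, edges, rounds=rounds)

    marker_counts: dict[str, int] = {}
    per_scaffold: dict[str, set[str]] = {}
    for h in hits:
        if h.scaffold_id in expanded:
            marker_counts[h.marker_id] = marker_counts.get(h.marker_id, 0) + 1
            per_scaffold.setdefault(h.scaffold_id, set()).add(h.marker_id)
    duplicated = {m for m, c in marker_counts.items() if c > 1}
    total_len = sum(profiles[s].length_bp for s in expanded if s in profiles)
    flagged: list[str] = []
    for sid in sorted(expanded):
        markers = per_scaffold.get(sid, set())
        if not markers & duplicated:
            continue
        # removal eliminates a duplicated marker iff some duplicated marker
        # drops to a single copy once this scaffold's copies are gone
        hits_on_sid = [h for h in hits if h.scaffold_id == sid]
        eliminates = False
        for m in markers & duplicated:
            n_on_sid = sum(1 for h in hits_on_sid if h.marker_id == m)
            if marker_counts[m] - n_on_sid <= 1:
                eliminates = True
        length = profiles[sid].length_bp if sid in profiles else 0
        if eliminates and total_len > 0 and length / total_len < max_trim_fraction:
            flagged.append(sid)

    removed: list[str] = []
    final = set(expanded)
    if auto_trim:
        for sid in flagged:
            if len(final) > 1:
                final.discard(sid)
                removed.append(sid)

    after = {
        "completeness_pct": completeness(final, hits, catalog),
        "duplication_pct": duplication(final, hits, catalog),
    }
    flags: dict[str, list[str]] = {}
    for sid in added:
        flags.setdefault(sid, []).append("linkage-added")
    for sid in flagged:
        flags.setdefault(sid, []).append("duplicate-marker")
    result = Bin(bin_id, final, provenance or {}, flags)
    return result, RefinementReport(added, flagged, removed, before, after)


def write_bin_tsv(bins: Iterable[Bin], path: str | Path) -> None:
    rows = []
    for b in bins:
        for sid in sorted(b.scaffold_ids):
            rows.append((b.bin_id, sid, ";".join(b.flags.get(sid, []))))
    pd.DataFrame(rows, columns=["bin_id", "scaffold_id", "flag"]).to_csv(
        path, sep="\t", index=False
    )


def write_provenance(bins: Iterable[Bin], path: str | Path) -> None:
    payload = {b.bin_id: b.provenance for b in bins}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
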