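"""Scaffold-scaffold linkage from read pairs spanning scaffolds.

Read pairs whose two mates map to different scaffolds witness physical
contiguity (or shared repeats) between those scaffolds.  Counting such pairs
per unordered scaffold pair yields a simple undirected graph used to refine
coverage-derived bins and to pull out the read set of a bin for re-assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .alignments import AlignmentRecord

__all__ = [
    "LinkageEdge",
    "build_linkage",
    "linkage_network",
    "expand_bin",
    "extract_read_ids",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_read_ids",
]

DEFAULT_MIN_LINKS = 2


@dataclass(frozen=True)
class LinkageEdge:
    """Unordered scaffold pair with the number of supporting read pairs.

    ``library`` is 'pe', 'mp', or 'mixed' when both library types support
    the edge; callers may weight the types differently.
    """

    scaffold_a: str
    scaffold_b: str
    n_links: int
    library: str = "pe"

    def __post_init__(self) -> None:
        if self.scaffold_a == self.scaffold_b:
            raise ValueError("linkage edge endpoints must differ")
        if self.n_links < 1:
            raise ValueError("n_links must be >= 1")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.scaffold_a, self.scaffold_b)))  # type: ignore[return-value]


def build_linkage(
    records: Iterable[AlignmentRecord],
    min_links: int = DEFAULT_MIN_LINKS,
) -> list[LinkageEdge]:
    """Count read pairs whose mates map (primary alignments) to two
    different scaffolds; keep pairs supported by >= ``min_links``.

    Both mates must be present in ``records`` — pass pre-filtered records so
    that "both mates passing alignment filters" holds by construction.
    """
    first: dict[str, AlignmentRecord] = {}
    second: dict[str, AlignmentRecord] = {}
    for rec in records:
        if not rec.is_mapped or rec.is_secondary:
            continue
        (first if rec.is_read1 else second)[rec.read_id] = rec
    counts: dict[tuple[str, str], int] = {}
    libraries: dict[tuple[str, str], set[str]] = {}
    for read_id, r1 in first.items():
        r2 = second.get(read_id)
        if r2 is None or r1.scaffold == r2.scaffold:
            continue
        key = tuple(sorted((r1.scaffold, r2.scaffold)))
        counts[key] = counts.get(key, 0) + 1
        libraries.setdefault(key, set()).add(r1.library)
    edges = []
    for key in sorted(counts):
        if counts[key] < min_links:
            continue
        libs = libraries[key]
        lib = libs.pop() if len(libs) == 1 else "mixed"
        edges.append(LinkageEdge(key[0], key[1], counts[key], lib))
    return edges


def linkage_network(edges: Iterable[LinkageEdge]) -> nx.Graph:
    graph = nx.Graph()
    for e in edges:
        graph.add_edge(e.scaffold_a, e.scaffold_b, n_links=e.n_links, library=e.library)
    return graph


def expand_bin(
    bin_scaffolds: Iterable[str],
    edges: Iterable[LinkageEdge],
    rounds: int = 1,
) -> tuple[set[str], list[str]]:
    """Breadth-first growth of a bin along linkage edges.

    Each round adds every scaffold sharing an edge with the current set.
    Returns ``(expanded_set, added)`` with the additions listed separately
    from the seed set, in sorted discovery order.
    """
    current = set(bin_scaffolds)
    graph = linkage_network(edges)
    added: list[str] = []
    for _ in range(rounds):
        frontier = set()
        for sid in current:
            if sid in graph:
                frontier.update(graph.neighbors(sid))
        new = sorted(frontier - current)
        if not new:
            break
        added.extend(new)
        current.update(new)
    return current, added


def extract_read_ids(
    bin_scaffolds: Iterable[str],
    records: Iterable[AlignmentRecord],
) -> list[str]:
    """Ids of all read pairs with either mate mapped (primary) to a bin
    scaffold, deduplicated and sorted."""
    members = set(bin_scaffolds)
    ids = set()
    for rec in records:
        if rec.is_secondary or not rec.is_mapped:
            continue
        if rec.scaffold in members or (rec.mate_scaffold in members):
            ids.add(rec.read_id)
    return sorted(ids)


def write_edges_tsv(edges: Iterable[LinkageEdge], path: str | Path) -> None:
    pd.DataFrame(
        [(e.scaffold_a, e.scaffold_b, e.n_links, e.library) for e in edges],
        columns=["scaffold_a", "scaffold_b", "n_links", "library"],
    ).to_csv(path, sep="\t", index=False)


def read_edges_tsv(path: str | Path) -> list[LinkageEdge]:
    frame = pd.read_csv(path, sep="\t")
    return [
        LinkageEdge(str(r.scaffold_a), str(r.scaffold_b), int(r.n_links), str(r.library))
        for r in frame.itertuples(index=False)
    ]


def write_read_ids(ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(ids) + ("\n" if ids else ""))
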