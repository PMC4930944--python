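"""Essential single-copy marker genes: detection, completeness, duplication.

A genome is expected to carry each of a catalog of essential single-copy
genes exactly once (the default catalog size is 107), so the fraction of
distinct catalog markers found in a bin estimates completeness, and repeated
markers estimate contamination by foreign or strain scaffolds.

Detection is a strategy with two built-ins: exact search for the synthetic
signature sequences registered by the community generator, and import of an
externally produced hit table (e.g. from an HMM search over predicted ORFs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerCatalog",
    "MarkerHit",
    "SignatureRegistry",
    "default_catalog",
    "detect_markers",
    "load_marker_table",
    "write_marker_tsv",
    "completeness",
    "duplication",
    "bin_taxonomy",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MarkerCatalog:
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ValueError("marker catalog must be non-empty")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in set(self.marker_ids)


def default_catalog(n_markers: int = 107) -> MarkerCatalog:
    return MarkerCatalog(tuple(f"mg{i:03d}" for i in range(1, n_markers + 1)))


@dataclass(frozen=True)
class MarkerHit:
    scaffold_id: str
    marker_id: str
    taxonomy_label: str
    start_bp: int
    strand: str = "+"


@dataclass(frozen=True)
class SignatureRow:
    marker_id: str
    taxonomy_label: str
    signature: str


class SignatureRegistry:
    """Catalog of planted marker signature sequences.

    Each row maps a unique nucleotide signature to (marker_id, taxonomy);
    detection reduces to exact substring search on both strands.
    """

    def __init__(self, rows: Iterable[SignatureRow]):
        self.rows = list(rows)
        sigs = [r.signature for r in self.rows]
        if len(set(sigs)) != len(sigs):
            raise ValueError("signature sequences must be unique")

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.marker_id, r.taxonomy_label, r.signature) for r in self.rows],
            columns=["marker_id", "taxonomy_label", "signature"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SignatureRegistry":
        frame = pd.read_csv(path, sep="\t")
        return cls(
            SignatureRow(str(r.marker_id), str(r.taxonomy_label), str(r.signature))
            for r in frame.itertuples(index=False)
        )


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return
        yield pos
        start = pos + 1


def detect_markers(
    scaffolds: Mapping[str, str],
    catalog: MarkerCatalog,
    mode: str = "signature",
    registry: SignatureRegistry | None = None,
    table: str | Path | pd.DataFrame | None = None,
) -> list[MarkerHit]:
    """Locate marker occurrences on scaffolds.

    ``signature`` mode scans both strands for every registered signature;
    ``imported`` mode reads a (scaffold, marker, taxonomy[, start]) table
    produced by an external HMM/BLAST workflow.
    """
    if mode == "signature":
        if registry is None:
            raise ValueError("signature mode requires a SignatureRegistry")
        hits: list[MarkerHit] = []
        for sid in scaffolds:
            seq = scaffolds[sid].upper()
            for row in registry.rows:
                for pos in _find_all(seq, row.signature):
                    hits.append(MarkerHit(sid, row.marker_id, row.taxonomy_label, pos, "+"))
                rc = _revcomp(row.signature)
                if rc != row.signature:
                    for pos in _find_all(seq, rc):
                        hits.append(MarkerHit(sid, row.marker_id, row.taxonomy_label, pos, "-"))
        return hits
    if mode == "imported":
        if table is None:
            raise ValueError("imported mode requires a hit table")
        return load_marker_table(table, catalog)
    raise ValueError(f"unknown detection mode {mode!r}")


def load_marker_table(
    table: str | Path | pd.DataFrame,
    catalog: MarkerCatalog,
) -> list[MarkerHit]:
    """Import external marker hits; rows with unknown marker ids are skipped
    with a logged warning."""
    frame = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t")
    known = set(catalog.marker_ids)
    hits: list[MarkerHit] = []
    for row in frame.itertuples(index=False):
        marker = str(row.marker_id)
        if marker not in known:
            logger.warning("skipping hit with unknown marker id %r on %r", marker, row.scaffold_id)
            continue
        start = int(getattr(row, "start_bp", 0))
        hits.append(MarkerHit(str(row.scaffold_id), marker, str(row.taxonomy_label), start))
    return hits


def write_marker_tsv(hits: Iterable[MarkerHit], path: str | Path) -> None:
    pd.DataFrame(
        [(h.scaffold_id, h.marker_id, h.taxonomy_label, h.start_bp, h.strand) for h in hits],
        columns=["scaffold_id", "marker_id", "taxonomy_label", "start_bp", "strand"],
    ).to_csv(path, sep="\t", index=False)


def _bin_hits(bin_scaffolds: Iterable[str], hits: Iterable[MarkerHit]) -> list[MarkerHit]:
    members = set(bin_scaffolds)
    return [h for h in hits if h.scaffold_id in members]


def completeness(
    bin_scaffolds: Iterable[str],
    hits: Iterable[MarkerHit],
    catalog: MarkerCatalog,
) -> float:
    """100 * distinct catalog markers present in the bin / catalog size."""
    if len(catalog) == 0:
        raise ValueError("empty marker catalog")
    distinct = {h.marker_id for h in _bin_hits(bin_scaffolds, hits)}
    return 100.0 * len(distinct) / len(catalog)


def duplication(
    bin_scaffolds: Iterable[str],
    hits: Iterable[MarkerHit],
    catalog: MarkerCatalog,
) -> float:
    """100 * (total hits - distinct markers) / catalog size."""
    if len(catalog) == 0:
        raise ValueError("empty marker catalog")
    in_bin = _bin_hits(bin_scaffolds, hits)
    distinct = {h.marker_id for h in in_bin}
    return 100.0 * (len(in_bin) - len(distinct)) / len(catalog)


def bin_taxonomy(bin_scaffolds: Iterable[str], hits: Iterable[MarkerHit]) -> str | None:
    """Majority taxonomy label of the bin's marker hits (ties broken
    lexicographically); None when the bin has no hits."""
    labels = [h.taxonomy_label for h in _bin_hits(bin_scaffolds, hits)]
    if not labels:
        return None
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return min(counts, key=lambda k: (-counts[k], k))
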