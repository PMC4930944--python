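"""Per-scaffold, per-sample coverage profiles.

Differential-coverage binning lives in the coordinate system built here: for
every scaffold, its length, GC content and mean per-base depth in each mapped
sample.  Depth is aligned bases divided by scaffold length, which makes the
table robust to mixed read lengths and gives the exact conservation property
``sum(depth * length) == total filtered aligned bases`` per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignments import AlignmentRecord

__all__ = [
    "AlignmentFilterParams",
    "CoverageProfile",
    "MissingIdentityError",
    "filter_alignments",
    "compute_coverage",
    "scaffold_properties",
    "length_filter",
    "coverage_frame",
    "write_coverage_tsv",
    "read_coverage_tsv",
]

#: pseudo-depth added before log10 so zero-depth scaffolds stay plottable
LOG_DEPTH_EPSILON = 0.01


class MissingIdentityError(ValueError):
    """An alignment record does not carry mismatch/identity information."""


@dataclass(frozen=True)
class AlignmentFilterParams:
    """Read-mapping stringency: keep reads aligning at >= ``min_identity``
    over >= ``min_aligned_fraction`` of their length (both inclusive)."""

    min_identity: float = 0.95
    min_aligned_fraction: float = 0.70

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_aligned_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class CoverageProfile:
    scaffold_id: str
    length_bp: int
    gc_pct: float
    depth: dict[str, float] = field(default_factory=dict)

    def log_depth(self, sample: str) -> float:
        return math.log10(self.depth.get(sample, 0.0) + LOG_DEPTH_EPSILON)


def filter_alignments(
    records: Iterable[AlignmentRecord],
    params: AlignmentFilterParams | None = None,
) -> list[AlignmentRecord]:
    """Drop unmapped and secondary records, then apply identity and
    aligned-fraction thresholds (inclusive).

    Raises :class:`MissingIdentityError` naming the first mapped record that
    carries no mismatch information.
    """
    params = params or AlignmentFilterParams()
    kept: list[AlignmentRecord] = []
    for rec in records:
        if not rec.is_mapped or rec.is_secondary:
            continue
        identity = rec.identity
        if identity is None:
            raise MissingIdentityError(
                f"record {rec.read_id!r} on {rec.scaffold!r} has no identity information"
            )
        if identity >= params.min_identity and rec.aligned_fraction >= params.min_aligned_fraction:
            kept.append(rec)
    return kept


def scaffold_properties(sequence: str) -> tuple[int, float]:
    """Length and GC percent of a scaffold sequence.

    N (and any other ambiguity code) is excluded from both the numerator and
    the denominator of the GC fraction; length counts all characters.
    """
    if not sequence:
        raise ValueError("empty scaffold sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    gc_pct = 100.0 * gc / denom if denom else 0.0
    return len(seq), gc_pct


def compute_coverage(
    records: Iterable[AlignmentRecord],
    scaffolds: Mapping[str, str],
    sample_id: str,
    profiles: Mapping[str, CoverageProfile] | None = None,
) -> dict[str, CoverageProfile]:
    """Mean per-base depth of every scaffold for one sample.

    ``records`` should already be filtered.  Scaffolds without records get
    depth 0.  Passing an existing ``profiles`` dict accumulates additional
    samples into the same objects.
    """
    if not scaffolds:
        raise ValueError("empty scaffold set")
    out: dict[str, CoverageProfile] = dict(profiles) if profiles else {}
    for sid, seq in scaffolds.items():
        if sid not in out:
            length, gc = scaffold_properties(seq)
            out[sid] = CoverageProfile(sid, length, gc)
    bases: dict[str, int] = {}
    for rec in records:
        if not rec.is_mapped:
            continue
        if rec.scaffold not in out:
            raise KeyError(f"record {rec.read_id!r} maps to unknown scaffold {rec.scaffold!r}")
        bases[rec.scaffold] = bases.get(rec.scaffold, 0) + rec.aligned_len
    for sid, prof in out.items():
        prof.depth[sample_id] = bases.get(sid, 0) / prof.length_bp
    return out


def length_filter(
    profiles: Iterable[CoverageProfile],
    min_bp: int = 1000,
    strict: bool = False,
) -> list[CoverageProfile]:
    """Keep scaffolds with length >= ``min_bp`` (``strict=True`` uses >,
    the convention of the plotting filter at 5 kbp)."""
    if strict:
        return [p for p in profiles if p.length_bp > min_bp]
    return [p for p in profiles if p.length_bp >= min_bp]


def coverage_frame(
    profiles: Iterable[CoverageProfile],
    marker_hits: Iterable | None = None,
) -> pd.DataFrame:
    """Tabulate profiles: scaffold_id, length_bp, gc_pct, depth_<sample>...

    With ``marker_hits`` (see :mod:`ebprbin.marker_genes`) two plot-data
    columns are appended: ``n_markers`` and the majority ``taxonomy`` of the
    scaffold's marker hits.
    """
    profiles = list(profiles)
    samples: list[str] = []
    for p in profiles:
        for s in p.depth:
            if s not in samples:
                samples.append(s)
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "scaffold_id": p.scaffold_id,
            "length_bp": p.length_bp,
            "gc_pct": p.gc_pct,
        }
        for s in samples:
            row[f"depth_{s}"] = p.depth.get(s, 0.0)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if marker_hits is not None:
        counts: dict[str, int] = {}
        taxa: dict[str, list[str]] = {}
        for hit in marker_hits:
            counts[hit.scaffold_id] = counts.get(hit.scaffold_id, 0) + 1
            taxa.setdefault(hit.scaffold_id, []).append(hit.taxonomy_label)
        frame["n_markers"] = [counts.get(s, 0) for s in frame["scaffold_id"]]
        frame["taxonomy"] = [
            max(set(t), key=t.count) if (t := taxa.get(s)) else ""
            for s in frame["scaffold_id"]
        ]
    return frame


def write_coverage_tsv(
    profiles: Iterable[CoverageProfile],
    path: str | Path,
    marker_hits: Iterable | None = None,
) -> None:
    coverage_frame(profiles, marker_hits).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> dict[str, CoverageProfile]:
    frame = pd.read_csv(path, sep="\t")
    samples = [c[len("depth_"):] for c in frame.columns if c.startswith("depth_")]
    out: dict[str, CoverageProfile] = {}
    for row in frame.itertuples(index=False):
        prof = CoverageProfile(str(row.scaffold_id), int(row.length_bp), float(row.gc_pct))
        for s in samples:
            prof.depth[s] = float(getattr(row, f"depth_{s}"))
        out[prof.scaffold_id] = prof
    return out
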