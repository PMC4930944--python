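"""Lightweight alignment records and SAM round-tripping.

The pipeline works on :class:`AlignmentRecord` objects — a minimal view of a
read alignment carrying exactly the fields the downstream stages consume:
which scaffold the read and its mate hit, how much of the read aligned, and
how many mismatches the aligner reported.  pysam does the actual SAM parsing
and writing; coordinates are 0-based half-open internally and converted at
the SAM boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

__all__ = ["AlignmentRecord", "write_sam", "read_sam"]


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read (half of a pair).

    ``aligned_len`` counts the bases of the read that are aligned to the
    scaffold (soft-clipped bases excluded); ``mismatches`` is the edit
    distance over those aligned columns (SAM ``NM``), ``None`` when the
    aligner did not report it.
    """

    read_id: str
    scaffold: str | None
    pos0: int = 0
    read_len: int = 0
    aligned_len: int = 0
    mismatches: int | None = None
    clip_start: int = 0
    is_read1: bool = True
    is_reverse: bool = False
    mate_scaffold: str | None = None
    mate_pos0: int = 0
    is_secondary: bool = False
    library: str = "pe"
    sample: str | None = None

    @property
    def is_mapped(self) -> bool:
        return self.scaffold is not None

    @property
    def identity(self) -> float | None:
        """Fraction of identical aligned columns, 1 - NM / aligned length."""
        if self.mismatches is None or self.aligned_len <= 0:
            return None
        return 1.0 - self.mismatches / self.aligned_len

    @property
    def aligned_fraction(self) -> float:
        if self.read_len <= 0:
            return 0.0
        return self.aligned_len / self.read_len


def _flag(rec: AlignmentRecord) -> int:
    flag = 0x1  # paired
    flag |= 0x40 if rec.is_read1 else 0x80
    if rec.is_reverse:
        flag |= 0x10
    if not rec.is_mapped:
        flag |= 0x4
    if rec.is_secondary:
        flag |= 0x100
    return flag


def write_sam(
    records: Iterable[AlignmentRecord],
    scaffold_lengths: Mapping[str, int],
    path: str | Path,
) -> int:
    """Write records as plain-text SAM; returns the number of records written.

    Library membership (pe/mp) goes into the ``RG`` tag, mismatches into
    ``NM``.  Read sequences are not stored (``*``): every consumer works from
    lengths and tags.
    """
    names = list(scaffold_lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": int(scaffold_lengths[n])} for n in names],
            "RG": [{"ID": lib} for lib in ("pe", "mp")],
        }
    )
    index = {n: i for i, n in enumerate(names)}
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            seg.flag = _flag(rec)
            if rec.is_mapped:
                seg.reference_id = index[rec.scaffold]
                seg.reference_start = rec.pos0
                seg.mapping_quality = 60
                cigar = []
                if rec.clip_start:
                    cigar.append((4, rec.clip_start))
                cigar.append((0, rec.aligned_len))
                tail = rec.read_len - rec.clip_start - rec.aligned_len
                if tail:
                    cigar.append((4, tail))
                seg.cigartuples = cigar
            else:
                seg.reference_id = -1
            if rec.mate_scaffold is not None:
                seg.next_reference_id = index[rec.mate_scaffold]
                seg.next_reference_start = rec.mate_pos0
            tags = [("RG", rec.library)]
            if rec.mismatches is not None:
                tags.append(("NM", rec.mismatches))
            seg.set_tags(tags)
            out.write(seg)
            n += 1
    return n


def read_sam(path: str | Path, sample: str | None = None) -> list[AlignmentRecord]:
    """Parse a SAM/BAM file back into :class:`AlignmentRecord` objects."""
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        for seg in handle:
            clip_start = 0
            aligned = 0
            read_len = 0
            if seg.cigartuples:
                if seg.cigartuples[0][0] == 4:
                    clip_start = seg.cigartuples[0][1]
                for op, ln in seg.cigartuples:
                    if op in (0, 1, 7, 8):  # M, I, =, X consume the query
                        aligned += ln
                    if op in (0, 1, 4, 7, 8):
                        read_len += ln
            if seg.query_sequence and len(seg.query_sequence) > read_len:
                read_len = len(seg.query_sequence)
            nm = seg.get_tag("NM") if seg.has_tag("NM") else None
            library = seg.get_tag("RG") if seg.has_tag("RG") else "pe"
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    scaffold=None if seg.is_unmapped else seg.reference_name,
                    pos0=0 if seg.is_unmapped else seg.reference_start,
                    read_len=read_len,
                    aligned_len=aligned,
                    mismatches=nm,
                    clip_start=clip_start,
                    is_read1=not seg.is_read2,
                    is_reverse=seg.is_reverse,
                    mate_scaffold=seg.next_reference_name,
                    mate_pos0=seg.next_reference_start if seg.next_reference_start >= 0 else 0,
                    is_secondary=seg.is_secondary,
                    library=str(library),
                    sample=sample,
                )
            )
    return out
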