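"""Genome-bin summary statistics (size, contigs, N50, GC, abundance)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coverage_profiling import CoverageProfile, scaffold_properties
from .marker_genes import MarkerCatalog, MarkerHit, completeness, duplication

__all__ = ["BinStats", "split_contigs", "n50", "summarize_bin", "stats_frame"]

DEFAULT_MIN_N_RUN = 10


@dataclass
class BinStats:
    bin_id: str
    size_bp: int
    n_scaffolds: int
    n_contigs: int
    contig_n50_bp: int
    max_contig_bp: int
    gc_pct: float
    completeness_pct: float
    contamination_pct: float
    rel_abundance_pct: dict[str, float] = field(default_factory=dict)


def split_contigs(scaffold_sequence: str, min_n_run: int = DEFAULT_MIN_N_RUN) -> list[str]:
    """Split a scaffold into contigs at runs of >= ``min_n_run`` Ns.

    Shorter N runs stay inside a contig (assembler gap dialects differ, so
    the threshold is configurable); empty fragments are dropped.
    """
    seq = scaffold_sequence.upper()
    contigs: list[str] = []
    start = 0
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            if j - i >= min_n_run:
                if i > start:
                    contigs.append(seq[start:i])
                start = j
            i = j
        else:
            i += 1
    if n > start:
        contigs.append(seq[start:])
    return contigs


def n50(lengths: Sequence[int]) -> int:
    """Largest length L such that fragments >= L total at least half the
    assembly; equivalently the length at which the descending cumulative sum
    first reaches total/2 (>= convention)."""
    if not lengths:
        raise ValueError("n50 of an empty length set")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    running = 0
    for l in ordered:
        running += l
        if running >= half:
            return l
    return ordered[-1]  # unreachable


def summarize_bin(
    bin_id: str,
    bin_scaffolds: Iterable[str],
    sequences: Mapping[str, str],
    profiles: Mapping[str, CoverageProfile],
    hits: Sequence[MarkerHit],
    catalog: MarkerCatalog,
    min_n_run: int = DEFAULT_MIN_N_RUN,
) -> BinStats:
    """Table of bin statistics.

    GC is length-weighted over scaffolds; relative abundance per sample is
    the bin's share of all aligned bases,
    100 * sum_bin(depth*length) / sum_all(depth*length).
    """
    members = sorted(set(bin_scaffolds))
    for sid in members:
        if sid not in sequences:
            raise KeyError(f"bin scaffold {sid!r} missing from sequence set")
        if sid not in profiles:
            raise KeyError(f"bin scaffold {sid!r} missing from coverage profiles")
    contig_lengths: list[int] = []
    size = 0
    gc_weighted = 0.0
    denom = 0
    for sid in members:
        seq = sequences[sid]
        length, gc = scaffold_properties(seq)
        size += length
        # weight GC by the number of unambiguous bases it was computed over
        acgt = sum(seq.upper().count(b) for b in "ACGT")
        gc_weighted += gc * acgt
        denom += acgt
        contig_lengths.extend(len(c) for c in split_contigs(seq, min_n_run))
    samples = sorted({s for p in profiles.values() for s in p.depth})
    rel = {}
    for s in samples:
        total = sum(p.depth.get(s, 0.0) * p.length_bp for p in profiles.values())
        bin_bases = sum(profiles[sid].depth.get(s, 0.0) * profiles[sid].length_bp for sid in members)
        rel[s] = 100.0 * bin_bases / total if total > 0 else 0.0
    return BinStats(
        bin_id=bin_id,
        size_bp=size,
        n_scaffolds=len(members),
        n_contigs=len(contig_lengths),
        contig_n50_bp=n50(contig_lengths),
        max_contig_bp=max(contig_lengths),
        gc_pct=gc_weighted / denom if denom else 0.0,
        completeness_pct=completeness(members, hits, catalog),
        contamination_pct=duplication(members, hits, catalog),
        rel_abundance_pct=rel,
    )


def stats_frame(stats: Iterable[BinStats]) -> pd.DataFrame:
    rows = []
    for st in stats:
        row = {
            "bin_id": st.bin_id,
            "size_bp": st.size_bp,
            "n_scaffolds": st.n_scaffolds,
            "n_contigs": st.n_contigs,
            "contig_n50_bp": st.contig_n50_bp,
            "max_contig_bp": st.max_contig_bp,
            "gc_pct": round(st.gc_pct, 3),
            "completeness_pct": round(st.completeness_pct, 3),
            "contamination_pct": round(st.contamination_pct, 3),
        }
        for s, v in st.rel_abundance_pct.items():
            row[f"abundance_pct_{s}"] = round(v, 3)
        rows.append(row)
    return pd.DataFrame(rows)
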