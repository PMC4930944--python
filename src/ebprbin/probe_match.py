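"""In-silico evaluation of rRNA-targeted oligonucleotide probes.

A FISH probe hybridizes where its reverse complement occurs in the 16S
sequence, so site finding is a sliding Hamming comparison of the probe's
reverse complement against the target (optionally tolerating one 1-base
insertion or deletion, the classic near-target indel trap).  Competitor
probes are unlabeled variants matching weakly mismatched non-target sites;
their distance to the labeled probe should be small (typically 1).
Hybridization thermodynamics are out of scope — formamide concentrations are
carried as metadata only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeSpec",
    "ProbeMatch",
    "DESIGNED_PROBES",
    "reverse_complement",
    "match_probe",
    "competitor_check",
    "coverage_table",
    "map_ecoli_positions",
    "validate_span",
    "read_probe_tsv",
    "write_probe_tsv",
]

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    """Uppercase DNA alphabet; RNA U becomes T."""
    return seq.upper().replace("U", "T").replace(" ", "")


@dataclass(frozen=True)
class ProbeSpec:
    """A 5'->3' oligonucleotide probe with hybridization metadata.

    ``ecoli_start``/``ecoli_end`` are 1-based inclusive positions of the
    target site on the E. coli 16S reference; ``formamide_pct`` is the
    recommended hybridization-buffer stringency (metadata only).
    """

    name: str
    sequence: str
    ecoli_start: int | None = None
    ecoli_end: int | None = None
    target_description: str = ""
    formamide_pct: str | None = None
    competitors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seq = _normalize(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not seq or any(b not in "ACGT" for b in seq):
            raise ValueError(f"probe {self.name!r}: sequence must be non-degenerate ACGT/U")
        if self.ecoli_start is not None and self.ecoli_end is not None:
            span = self.ecoli_end - self.ecoli_start + 1
            if span != len(seq):
                raise ValueError(
                    f"probe {self.name!r}: declared span {self.ecoli_start}-{self.ecoli_end} "
                    f"covers {span} bases but the probe is a {len(seq)}-mer"
                )

    def __len__(self) -> int:
        return len(self.sequence)


#: probes designed against the Propionivibrio GAO 16S sequence, with their
#: unlabeled single-mismatch competitors
DESIGNED_PROBES: tuple[ProbeSpec, ...] = (
    ProbeSpec("Prop207", "GCTCCAAAAGCGCAAGGTCCGAAG", 207, 230,
              "Ca. Propionivibrio aalborgensis", "35", ("Prop207c",)),
    ProbeSpec("Prop207c", "GCTCCAAAAGCACAAGGTCCGAAG", 207, 230,
              "Competitor for Prop207", None),
    ProbeSpec("Prop470", "ATGCGGGTACCGTCATCTACTCAGG", 470, 494,
              "Some Propionivibrio spp.", "70+", ("Prop470c1", "Prop470c2", "Prop470c3")),
    ProbeSpec("Prop470c1", "ATTCGGGTACCGTCATCTACTCAGG", 470, 494,
              "Competitor for Prop470", None),
    ProbeSpec("Prop470c2", "ATGCTGGTACCGTCATCTACTCAGG", 470, 494,
              "Competitor for Prop470", None),
    ProbeSpec("Prop470c3", "ATGCGGGTACCGTCATCTACTCCGG", 470, 494,
              "Competitor for Prop470", None),
)


@dataclass(frozen=True)
class ProbeMatch:
    sequence_id: str
    start: int  # 1-based on the target
    mismatches: int
    indel: str | None = None


def _mismatch(target_base: str, probe_base: str) -> int:
    """1 if the (possibly degenerate) target base cannot pair the probe
    base; non-IUPAC characters are universal mismatches."""
    allowed = IUPAC.get(target_base)
    if allowed is None:
        return 1
    return 0 if probe_base in allowed else 1


def _hamming(window: str, site: str) -> int:
    return sum(_mismatch(t, p) for t, p in zip(window, site))


def match_probe(
    probe: ProbeSpec,
    target: str,
    max_mismatch: int = 0,
    allow_single_indel: bool = False,
    sequence_id: str = "",
) -> list[ProbeMatch]:
    """Find probe binding sites on a target sequence.

    Slides the reverse complement of the probe along the target and reports
    every window within ``max_mismatch`` substitutions.  With
    ``allow_single_indel`` windows matching with one 1-base insertion or
    deletion are also reported, the gap counted as one mismatch-equivalent.
    Degenerate IUPAC codes in the target match when any expansion matches;
    other characters count as universal mismatches (logged once).
    Matches are sorted by (mismatches, start); ``start`` is 1-based.
    """
    site = reverse_complement(probe.sequence)
    m = len(site)
    seq = _normalize(target)
    if m > len(seq):
        raise ValueError(f"probe {probe.name!r} ({m} nt) longer than target ({len(seq)} nt)")
    if any(b not in IUPAC for b in set(seq)):
        bad = sorted(set(b for b in seq if b not in IUPAC))
        logger.warning("target %r contains non-nucleotide characters %s; treated as mismatches",
                       sequence_id or "<unnamed>", bad)
    matches: list[ProbeMatch] = []
    seen: set[tuple[int, str | None]] = set()
    for start in range(len(seq) - m + 1):
        d = _hamming(seq[start : start + m], site)
        if d <= max_mismatch:
            matches.append(ProbeMatch(sequence_id, start + 1, d, None))
            seen.add((start + 1, None))
    if allow_single_indel and max_mismatch >= 1:
        budget = max_mismatch - 1  # the gap itself costs one mismatch-equivalent
        # deletion in the target: site skips one base, window is m-1 long
        for start in range(len(seq) - (m - 1) + 1):
            window = seq[start : start + m - 1]
            best = None
            for gap in range(m):
                gapped = site[:gap] + site[gap + 1 :]
                d = _hamming(window, gapped)
                if d <= budget and (best is None or d < best[0]):
                    best = (d, gap)
            if best is not None and (start + 1, "del") not in seen:
                matches.append(ProbeMatch(sequence_id, start + 1, best[0] + 1, f"del@{best[1] + 1}"))
                seen.add((start + 1, "del"))
        # insertion in the target: window is m+1 long, one target base skipped
        for start in range(len(seq) - (m + 1) + 1):
            window = seq[start : start + m + 1]
            best = None
            for gap in range(m + 1):
                reduced = window[:gap] + window[gap + 1 :]
                d = _hamming(reduced, site)
                if d <= budget and (best is None or d < best[0]):
                    best = (d, gap)
            if best is not None and (start + 1, "ins") not in seen:
                matches.append(ProbeMatch(sequence_id, start + 1, best[0] + 1, f"ins@{best[1] + 1}"))
                seen.add((start + 1, "ins"))
    matches.sort(key=lambda m: (m.mismatches, m.start, m.indel or ""))
    return matches


def competitor_check(probe: ProbeSpec, competitor: ProbeSpec) -> tuple[int, list[int]]:
    """Hamming distance and 1-based differing positions between two probes
    of equal length."""
    if len(probe) != len(competitor):
        raise ValueError(
            f"probes {probe.name!r} ({len(probe)} nt) and {competitor.name!r} "
            f"({len(competitor)} nt) differ in length"
        )
    positions = [
        i + 1 for i, (a, b) in enumerate(zip(probe.sequence, competitor.sequence)) if a != b
    ]
    return len(positions), positions


def coverage_table(
    probes: Sequence[ProbeSpec],
    sequences: Iterable[tuple[str, str, str]],
    max_mismatch: int = 0,
    taxa: Sequence[str] | None = None,
    allow_single_indel: bool = False,
) -> pd.DataFrame:
    """Per-(probe, taxon) coverage: percent of each taxon's sequences with
    at least one site within ``max_mismatch``.

    ``sequences`` yields (sequence_id, taxonomy_label, sequence).  Taxa with
    no sequences are reported as NaN (not applicable, not 0).  The
    ``total_other_hits`` column counts matching sequences outside all listed
    taxa.
    """
    seqs = list(sequences)
    observed = []
    for _, tax, _ in seqs:
        if tax not in observed:
            observed.append(tax)
    listed = list(taxa) if taxa is not None else observed
    rows = []
    for probe in probes:
        hit_ids = set()
        for sid, _, seq in seqs:
            if match_probe(probe, seq, max_mismatch, allow_single_indel, sid):
                hit_ids.add(sid)
        row: dict[str, object] = {"probe": probe.name}
        for tax in listed:
            group = [sid for sid, t, _ in seqs if t == tax]
            if not group:
                row[tax] = float("nan")
            else:
                row[tax] = 100.0 * sum(1 for sid in group if sid in hit_ids) / len(group)
        row["total_other_hits"] = sum(
            1 for sid, t, _ in seqs if t not in listed and sid in hit_ids
        )
        rows.append(row)
    return pd.DataFrame(rows)


def validate_span(probe: ProbeSpec) -> bool:
    """Check the declared E. coli span against the probe length."""
    if probe.ecoli_start is None or probe.ecoli_end is None:
        raise ValueError(f"probe {probe.name!r} declares no E. coli span")
    return probe.ecoli_end - probe.ecoli_start + 1 == len(probe)


def map_ecoli_positions(
    probe: ProbeSpec,
    ecoli_16s_reference: str,
    max_mismatch: int = 2,
) -> tuple[int, int]:
    """Locate the probe's site on a user-provided E. coli 16S reference.

    Returns the 1-based inclusive span of the unique best match (<=
    ``max_mismatch`` substitutions); errors when no site exists or the best
    mismatch count is shared by several sites.
    """
    matches = match_probe(probe, ecoli_16s_reference, max_mismatch, sequence_id="ecoli_16s")
    if not matches:
        raise ValueError(f"probe {probe.name!r}: no site within {max_mismatch} mismatches")
    best = matches[0].mismatches
    ties = [m for m in matches if m.mismatches == best]
    if len(ties) > 1:
        raise ValueError(
            f"probe {probe.name!r}: ambiguous site (best distance {best} at "
            f"positions {[m.start for m in ties]})"
        )
    start = ties[0].start
    return start, start + len(probe) - 1


PROBE_COLUMNS = ["name", "ecoli_pos", "target", "sequence", "fa_pct", "competitors"]


def write_probe_tsv(probes: Iterable[ProbeSpec], path: str | Path) -> None:
    rows = []
    for p in probes:
        pos = f"{p.ecoli_start}-{p.ecoli_end}" if p.ecoli_start is not None else ""
        rows.append((p.name, pos, p.target_description, p.sequence,
                     p.formamide_pct or "", ";".join(p.competitors)))
    pd.DataFrame(rows, columns=PROBE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_probe_tsv(path: str | Path) -> list[ProbeSpec]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    probes = []
    for row in frame.itertuples(index=False):
        start = end = None
        if row.ecoli_pos:
            start_s, _, end_s = str(row.ecoli_pos).partition("-")
            start, end = int(start_s), int(end_s)
        competitors = tuple(c for c in str(row.competitors).split(";") if c)
        probes.append(
            ProbeSpec(str(row.name), str(row.sequence), start, end,
                      str(row.target), str(row.fa_pct) or None, competitors)
        )
    return probes
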