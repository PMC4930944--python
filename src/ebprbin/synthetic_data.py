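"""Synthetic communities, alignments, cycle chemistry and 16S sets.

Every pipeline stage is testable against known ground truth generated here:

* a community of genomes whose relative abundances differ between samples
  (the premise of differential-coverage binning), fragmented into scaffolds
  with recorded adjacency and carrying a planted catalog of single-copy
  marker signatures;
* read-pair alignments whose per-scaffold depth follows the abundance
  matrix and whose junction-spanning pairs link adjacent scaffolds;
* two-population PAO/GAO anaerobic-aerobic cycle chemistry with
  configurable mixing fraction and measurement noise;
* labeled 16S sequence sets with probe sites planted at controlled
  mismatch counts.

All generators are deterministic given their spec and seed; random streams
are partitioned per genome and per sample so adding a genome does not
perturb the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignments import AlignmentRecord
from .marker_genes import (
    MarkerCatalog,
    SignatureRegistry,
    SignatureRow,
    default_catalog,
)
from .stoichiometry import (
    CYCLE_COLUMNS,
    GAO_REFERENCE,
    PAO_REFERENCE,
    ReferenceStoichiometry,
)
from .probe_match import ProbeSpec, reverse_complement

__all__ = [
    "CommunitySpec",
    "CommunityTruth",
    "PlantedMarker",
    "CycleSpec",
    "SixteenSSet",
    "generate_community",
    "write_community",
    "simulate_alignments",
    "expected_depth",
    "abundance_from_depths",
    "default_community_spec",
    "DEFAULT_DEPTH_DESIGN",
    "DEFAULT_MEAN_DEPTH",
    "generate_cycle",
    "write_cycle_csv",
    "generate_16s_set",
    "write_16s_set",
]

MARKER_SIGNATURE_LEN = 63
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=n, p=p)
    return _BASE_BYTES[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# community
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunitySpec:
    """Design of a synthetic community.

    ``abundance_matrix`` is genomes x samples with columns summing to 1;
    ``strain_of`` maps a genome index to ``(parent_index, mutation_rate)``
    declaring it a perturbed copy of an earlier genome (closely related
    strains are what degrade real assemblies and inflate marker
    duplication).
    """

    n_genomes: int
    genome_length_bp: int | Sequence[int]
    abundance_matrix: Sequence[Sequence[float]]
    gc_target: float | Sequence[float] = 0.5
    sample_ids: tuple[str, ...] = ()
    n_markers: int = 107
    fragment_mean_bp: int = 8000
    fragment_min_bp: int = 1000
    strain_of: Mapping[int, tuple[int, float]] = field(default_factory=dict)
    taxonomy: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundance_matrix, dtype=float)
        if ab.ndim != 2 or ab.shape[0] != self.n_genomes:
            raise ValueError("abundance_matrix must be n_genomes x n_samples")
        if (ab < 0).any():
            raise ValueError("abundances must be non-negative")
        colsums = ab.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(f"abundance_matrix columns must sum to 1, got {colsums}")
        object.__setattr__(self, "abundance_matrix", ab)
        if not self.sample_ids:
            object.__setattr__(
                self, "sample_ids", tuple(f"s{i + 1}" for i in range(ab.shape[1]))
            )
        if len(self.sample_ids) != ab.shape[1]:
            raise ValueError("sample_ids must match abundance_matrix columns")
        for g in range(self.n_genomes):
            if self.genome_length(g) <= 0:
                raise ValueError("genome lengths must be > 0")
            gc = self.gc_of(g)
            if not (0.0 < gc < 1.0):
                raise ValueError("gc_target must be in (0, 1)")
        if self.fragment_min_bp < 1:
            raise ValueError("fragment_min_bp must be >= 1")
        for g in range(self.n_genomes):
            if self.fragment_min_bp > self.genome_length(g):
                raise ValueError(
                    f"fragment_min_bp {self.fragment_min_bp} exceeds genome {g} length"
                )
        for g, (parent, rate) in self.strain_of.items():
            if not (0 <= parent < g):
                raise ValueError("strain parent must be an earlier genome index")
            if not (0.0 <= rate <= 1.0):
                raise ValueError("mutation rate must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def genome_length(self, g: int) -> int:
        if isinstance(self.genome_length_bp, (int, np.integer)):
            return int(self.genome_length_bp)
        return int(self.genome_length_bp[g])

    def gc_of(self, g: int) -> float:
        if isinstance(self.gc_target, (float, int)):
            return float(self.gc_target)
        return float(self.gc_target[g])

    def genome_id(self, g: int) -> str:
        return f"g{g + 1:02d}"

    def taxonomy_of(self, g: int) -> str:
        if g in self.strain_of:
            return self.taxonomy_of(self.strain_of[g][0])
        if self.taxonomy is not None:
            return str(self.taxonomy[g])
        return f"taxon_{g + 1:02d}"


@dataclass(frozen=True)
class PlantedMarker:
    scaffold_id: str
    marker_id: str
    taxonomy_label: str
    start_bp: int


@dataclass
class CommunityTruth:
    """Ground truth of a generated community."""

    genome_sequences: dict[str, str]
    scaffold_sequences: dict[str, str]
    scaffold_to_genome: dict[str, str]
    scaffold_order: dict[str, list[str]]
    planted_markers: list[PlantedMarker]
    adjacency: list[tuple[str, str]]
    registry: SignatureRegistry
    catalog: MarkerCatalog
    taxonomy: dict[str, str]

    def scaffolds_of(self, genome_id: str) -> list[str]:
        return list(self.scaffold_order[genome_id])


def _fragment_lengths(rng: np.random.Generator, total: int, mean: int, minimum: int) -> list[int]:
    """Consecutive fragment lengths summing exactly to ``total``."""
    if mean >= total:
        return [total]
    lengths: list[int] = []
    remaining = total
    while remaining > 0:
        draw = int(round(rng.normal(mean, 0.15 * mean)))
        draw = max(minimum, draw)
        if draw >= remaining or remaining - draw < minimum:
            lengths.append(remaining)
            remaining = 0
        else:
            lengths.append(draw)
            remaining -= draw
    return lengths


def _plant_positions(
    rng: np.random.Generator,
    fragment_lengths: Sequence[int],
    n_markers: int,
    sig_len: int,
) -> list[tuple[int, int]]:
    """Choose (fragment_index, offset) per marker, non-overlapping and never
    crossing a fragment boundary."""
    starts = np.concatenate([[0], np.cumsum(fragment_lengths)])[:-1]
    capacity = [max(0, l - sig_len + 1) for l in fragment_lengths]
    if sum(capacity) == 0:
        raise ValueError("fragments too short to host marker signatures")
    weights = np.array(capacity, dtype=float)
    weights /= weights.sum()
    taken: list[tuple[int, int]] = []  # genome-coordinate intervals
    out: list[tuple[int, int]] = []
    for _ in range(n_markers):
        for _attempt in range(1000):
            frag = int(rng.choice(len(fragment_lengths), p=weights))
            if capacity[frag] == 0:
                continue
            offset = int(rng.integers(0, capacity[frag]))
            gpos = int(starts[frag] + offset)
            if all(gpos + sig_len <= a or gpos >= b for a, b in taken):
                taken.append((gpos, gpos + sig_len))
                out.append((frag, offset))
                break
        else:
            raise ValueError("could not place all marker signatures; genome too small")
    return out


def generate_community(spec: CommunitySpec) -> CommunityTruth:
    """Generate genomes, scaffolds and planted-marker ground truth.

    Each non-strain genome carries all ``n_markers`` catalog markers planted
    as unique 63-bp signature sequences wholly inside one scaffold; strain
    genomes are mutated copies of their parent (sharing its fragmentation),
    so intact signature copies show up as duplicated markers.
    Regenerating with the same spec and seed is bit-identical.
    """
    catalog = default_catalog(spec.n_markers)
    genome_sequences: dict[str, str] = {}
    scaffold_sequences: dict[str, str] = {}
    scaffold_to_genome: dict[str, str] = {}
    scaffold_order: dict[str, list[str]] = {}
    planted: list[PlantedMarker] = []
    adjacency: list[tuple[str, str]] = []
    registry_rows: list[SignatureRow] = []
    taxonomy: dict[str, str] = {}
    boundaries: dict[int, list[int]] = {}
    marker_layout: dict[int, list[tuple[int, int]]] = {}

    for g in range(spec.n_genomes):
        gid = spec.genome_id(g)
        glen = spec.genome_length(g)
        tax = spec.taxonomy_of(g)
        taxonomy[gid] = tax
        if g in spec.strain_of:
            parent, rate = spec.strain_of[g]
            parent_seq = genome_sequences[spec.genome_id(parent)]
            if len(parent_seq) != glen:
                raise ValueError("strain genome must declare its parent's length")
            rng_mut = np.random.default_rng([spec.seed, 5, g])
            codes = np.frombuffer(parent_seq.encode("ascii"), dtype=np.uint8).copy()
            mask = rng_mut.random(glen) < rate
            if mask.any():
                idx = np.nonzero(mask)[0]
                shift = rng_mut.integers(1, 4, size=len(idx))
                lookup = np.full(256, 0, dtype=np.uint8)
                for b, c in _CODE.items():
                    lookup[ord(b)] = c
                old = lookup[codes[idx]]
                codes[idx] = _BASE_BYTES[(old + shift) % 4]
            seq = codes.tobytes().decode("ascii")
            frag_lengths = [
                b - a
                for a, b in zip(
                    [0] + boundaries[parent][:-1], boundaries[parent]
                )
            ]
            layout = marker_layout[parent]
        else:
            rng_seq = np.random.default_rng([spec.seed, 1, g])
            seq = _random_seq(rng_seq, glen, spec.gc_of(g))
            rng_frag = np.random.default_rng([spec.seed, 2, g])
            frag_lengths = _fragment_lengths(
                rng_frag, glen, spec.fragment_mean_bp, spec.fragment_min_bp
            )
            rng_mark = np.random.default_rng([spec.seed, 3, g])
            layout = _plant_positions(
                rng_mark, frag_lengths, spec.n_markers, MARKER_SIGNATURE_LEN
            )
            # overwrite the genome with the signature sequences
            starts = np.concatenate([[0], np.cumsum(frag_lengths)])[:-1]
            chars = list(seq)
            for k, (frag, offset) in enumerate(layout):
                signature = _random_seq(rng_mark, MARKER_SIGNATURE_LEN, 0.5)
                gpos = int(starts[frag] + offset)
                chars[gpos : gpos + MARKER_SIGNATURE_LEN] = signature
                registry_rows.append(
                    SignatureRow(catalog.marker_ids[k], tax, signature)
                )
            seq = "".join(chars)
        boundaries[g] = list(np.cumsum(frag_lengths))
        marker_layout[g] = layout
        genome_sequences[gid] = seq

        start = 0
        ids = []
        for k, flen in enumerate(frag_lengths):
            sid = f"{gid}_scf{k + 1:03d}"
            scaffold_sequences[sid] = seq[start : start + flen]
            scaffold_to_genome[sid] = gid
            ids.append(sid)
            start += flen
        scaffold_order[gid] = ids
        adjacency.extend(zip(ids, ids[1:]))
        for k, (frag, offset) in enumerate(layout):
            planted.append(
                PlantedMarker(ids[frag], catalog.marker_ids[k], tax, offset)
            )

    return CommunityTruth(
        genome_sequences=genome_sequences,
        scaffold_sequences=scaffold_sequences,
        scaffold_to_genome=scaffold_to_genome,
        scaffold_order=scaffold_order,
        planted_markers=planted,
        adjacency=adjacency,
        registry=SignatureRegistry(registry_rows),
        catalog=catalog,
        taxonomy=taxonomy,
    )


def write_community(truth: CommunityTruth, outdir: str | Path) -> dict[str, Path]:
    """Write scaffold FASTA plus ground-truth/registry TSVs; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scaffolds": outdir / "scaffolds.fasta",
        "scaffold_truth": outdir / "scaffold_truth.tsv",
        "planted_markers": outdir / "planted_markers.tsv",
        "adjacency": outdir / "adjacency.tsv",
        "registry": outdir / "marker_registry.tsv",
    }
    records = [
        SeqRecord(Seq(truth.scaffold_sequences[sid]), id=sid, description="")
        for gid in sorted(truth.scaffold_order)
        for sid in truth.scaffold_order[gid]
    ]
    SeqIO.write(records, paths["scaffolds"], "fasta")
    pd.DataFrame(
        [(s, g, truth.taxonomy[g]) for s, g in sorted(truth.scaffold_to_genome.items())],
        columns=["scaffold_id", "genome_id", "taxonomy_label"],
    ).to_csv(paths["scaffold_truth"], sep="\t", index=False)
    pd.DataFrame(
        [(m.scaffold_id, m.marker_id, m.taxonomy_label, m.start_bp) for m in truth.planted_markers],
        columns=["scaffold_id", "marker_id", "taxonomy_label", "start_bp"],
    ).to_csv(paths["planted_markers"], sep="\t", index=False)
    pd.DataFrame(truth.adjacency, columns=["scaffold_a", "scaffold_b"]).to_csv(
        paths["adjacency"], sep="\t", index=False
    )
    truth.registry.write_tsv(paths["registry"])
    return paths


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def expected_depth(spec: CommunitySpec, g: int, sample: str, mean_depth: float) -> float:
    """Analytic expected depth: abundance * n_genomes * mean_depth, so
    ``mean_depth`` is the depth of a genome at average abundance."""
    s = spec.sample_ids.index(sample)
    return float(spec.abundance_matrix[g, s]) * spec.n_genomes * mean_depth


def simulate_alignments(
    truth: CommunityTruth,
    spec: CommunitySpec,
    mean_depth: float,
    read_bp: int = 150,
    insert_bp: int = 300,
    insert_sd: float | None = None,
    count_model: str = "poisson",
    nb_dispersion: float = 10.0,
    library: str = "pe",
) -> dict[str, list[AlignmentRecord]]:
    """Simulate error-free read-pair alignments per sample.

    Fragments of mean length ``insert_bp`` are drawn uniformly along each
    genome at a rate giving the genome its expected depth; the two
    ``read_bp`` reads of each fragment are mapped to scaffolds.  A read
    crossing a scaffold junction is soft-clipped to the scaffold holding the
    majority of its bases, so junction-spanning pairs surface as
    cross-scaffold mates (and exercise the aligned-fraction filter), while
    pairs whose insert spans the junction get full-length mates on the two
    adjacent scaffolds.  Identity is explicit (NM=0).  Per-genome pair
    counts are Poisson by default or negative-binomial
    (``count_model='nb'``) for overdispersed libraries.
    """
    if not truth.scaffold_sequences:
        raise ValueError("empty community truth")
    if mean_depth <= 0:
        raise ValueError("mean depth must be > 0")
    shortest = min(len(s) for s in truth.scaffold_sequences.values())
    if read_bp >= shortest:
        raise ValueError(
            f"read length {read_bp} must be shorter than the shortest scaffold ({shortest})"
        )
    if insert_sd is None:
        insert_sd = 0.1 * insert_bp
    out: dict[str, list[AlignmentRecord]] = {s: [] for s in spec.sample_ids}
    for si, sample in enumerate(spec.sample_ids):
        records = out[sample]
        for g in range(spec.n_genomes):
            gid = spec.genome_id(g)
            scaffolds = truth.scaffold_order[gid]
            lengths = np.array([len(truth.scaffold_sequences[s]) for s in scaffolds])
            starts = np.concatenate([[0], np.cumsum(lengths)])[:-1]
            ends = starts + lengths
            glen = int(lengths.sum())
            depth = expected_depth(spec, g, sample, mean_depth)
            lam = depth * glen / (2.0 * read_bp)
            rng = np.random.default_rng([spec.seed, 4, si, g])
            if count_model == "poisson":
                n_pairs = int(rng.poisson(lam))
            elif count_model == "nb":
                p = nb_dispersion / (nb_dispersion + lam)
                n_pairs = int(rng.negative_binomial(nb_dispersion, p))
            else:
                raise ValueError(f"unknown count model {count_model!r}")
            if n_pairs == 0:
                continue
            inserts = np.rint(rng.normal(insert_bp, insert_sd, size=n_pairs)).astype(int)
            inserts = np.clip(inserts, read_bp, glen)
            frag_starts = np.floor(
                rng.random(n_pairs) * (glen - inserts + 1)
            ).astype(int)

            def place(a: int, b: int) -> tuple[int, int, int, int]:
                """Map genome interval [a, b) to (scaffold index, pos0,
                aligned_len, clip_start) by the majority rule."""
                ia = int(np.searchsorted(ends, a, side="right"))
                ib = int(np.searchsorted(ends, b - 1, side="right"))
                if ia == ib:
                    return ia, a - int(starts[ia]), b - a, 0
                left = int(ends[ia]) - a
                right = b - int(starts[ib])
                if left >= right:
                    return ia, a - int(starts[ia]), left, 0
                return ib, 0, right, b - a - right

            for i in range(n_pairs):
                s0 = int(frag_starts[i])
                ins = int(inserts[i])
                r1 = place(s0, s0 + read_bp)
                r2 = place(s0 + ins - read_bp, s0 + ins)
                read_id = f"{sample}:{gid}:{i:06d}"
                records.append(
                    AlignmentRecord(
                        read_id=read_id,
                        scaffold=scaffolds[r1[0]],
                        pos0=r1[1],
                        read_len=read_bp,
                        aligned_len=r1[2],
                        mismatches=0,
                        clip_start=r1[3],
                        is_read1=True,
                        is_reverse=False,
                        mate_scaffold=scaffolds[r2[0]],
                        mate_pos0=r2[1],
                        library=library,
                        sample=sample,
                    )
                )
                records.append(
                    AlignmentRecord(
                        read_id=read_id,
                        scaffold=scaffolds[r2[0]],
                        pos0=r2[1],
                        read_len=read_bp,
                        aligned_len=r2[2],
                        mismatches=0,
                        clip_start=r2[3],
                        is_read1=False,
                        is_reverse=True,
                        mate_scaffold=scaffolds[r1[0]],
                        mate_pos0=r1[1],
                        library=library,
                        sample=sample,
                    )
                )
    return out


#: designed per-genome depths (two samples, exactly 5-fold contrasts, every
#: genome at >= 20x in its weaker sample) for the default study community
DEFAULT_DEPTH_DESIGN = np.array(
    [
        [20.0, 100.0],
        [100.0, 20.0],
        [40.0, 100.0],
        [100.0, 40.0],
        [20.0, 200.0],
        [200.0, 20.0],
        [40.0, 200.0],
        [200.0, 40.0],
        [28.0, 141.0],
        [141.0, 28.0],
    ]
)


def abundance_from_depths(depths: np.ndarray) -> tuple[np.ndarray, float]:
    """Convert a per-genome target depth matrix into (abundance matrix,
    mean_depth) for :func:`simulate_alignments`.  Column totals must agree
    (a single mean-depth scalar scales all samples)."""
    depths = np.asarray(depths, dtype=float)
    colsums = depths.sum(axis=0)
    if not np.allclose(colsums, colsums[0], rtol=1e-9):
        raise ValueError("per-sample depth totals must be equal")
    abundance = depths / colsums
    return abundance, float(colsums[0]) / depths.shape[0]


DEFAULT_MEAN_DEPTH = abundance_from_depths(DEFAULT_DEPTH_DESIGN)[1]


def default_community_spec(seed: int = 0) -> CommunitySpec:
    """The default two-sample, ten-genome study community used by the bin
    recovery checks; pair with ``mean_depth=DEFAULT_MEAN_DEPTH``."""
    abundance, _ = abundance_from_depths(DEFAULT_DEPTH_DESIGN)
    return CommunitySpec(
        n_genomes=10,
        genome_length_bp=32000,
        abundance_matrix=abundance,
        gc_target=np.linspace(0.38, 0.62, 10),
        sample_ids=("t1", "t2"),
        fragment_mean_bp=8000,
        fragment_min_bp=4000,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cycle chemistry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleSpec:
    """Two-population SBR cycle: ``f_pao`` is the PAO fraction of the
    PAO+GAO biomass; feed carbon is ``vfa_feed_cmol`` C-mmol/L split
    ``acetate_fraction`` acetate / remainder propionate; the influent P/C
    molar ratio sets the initial ortho-P level."""

    f_pao: float
    vfa_feed_cmol: float = 12.5
    acetate_fraction: float = 0.75
    anaerobic_min: float = 120.0
    aerobic_min: float = 180.0
    p_to_c_feed: float = 0.15
    noise_sd_rel: float = 0.0
    n_timepoints: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_pao <= 1.0):
            raise ValueError("f_pao must be in [0, 1]")
        if self.anaerobic_min <= 0 or self.aerobic_min <= 0:
            raise ValueError("phase durations must be > 0")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        if self.vfa_feed_cmol <= 0:
            raise ValueError("vfa_feed_cmol must be > 0")
        if not (0.0 <= self.acetate_fraction <= 1.0):
            raise ValueError("acetate_fraction must be in [0, 1]")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")


def generate_cycle(
    spec: CycleSpec,
    pao_ref: ReferenceStoichiometry = PAO_REFERENCE,
    gao_ref: ReferenceStoichiometry = GAO_REFERENCE,
) -> pd.DataFrame:
    """Piecewise-linear cycle chemistry of an f_pao : (1-f_pao) PAO/GAO mix.

    Anaerobically VFA declines to zero at constant rate while P release,
    glycogen consumption and PHB/PHV formation follow the mixed reference
    stoichiometry per C-mol VFA taken up; aerobically PHA is degraded, P is
    taken up below its initial level and glycogen is replenished.
    Multiplicative Gaussian noise (``noise_sd_rel``) is applied to every
    concentration."""
    f = spec.f_pao
    y_p = f * pao_ref.p_vfa + (1 - f) * gao_ref.p_vfa
    y_gly = f * pao_ref.gly_vfa + (1 - f) * gao_ref.gly_vfa
    y_phb = f * pao_ref.phb_vfa + (1 - f) * gao_ref.phb_vfa
    y_phv = f * pao_ref.phv_vfa + (1 - f) * gao_ref.phv_vfa

    feed = spec.vfa_feed_cmol
    p0 = spec.p_to_c_feed * feed
    gly0 = 1.5 * y_gly * feed  # pool sized so anaerobic demand never empties it
    total = spec.anaerobic_min + spec.aerobic_min
    times = np.linspace(0.0, total, spec.n_timepoints)
    if (times <= spec.anaerobic_min).sum() < 2:
        raise ValueError("time grid must place >= 2 samples in the anaerobic phase")

    rows = []
    ana_end = {
        "po4": p0 + y_p * feed,
        "gly": gly0 - y_gly * feed,
        "phb": y_phb * feed,
        "phv": y_phv * feed,
    }
    for t in times:
        if t <= spec.anaerobic_min:
            u = feed * t / spec.anaerobic_min  # VFA consumed so far
            hac = (feed - u) * spec.acetate_fraction
            hpr = (feed - u) * (1 - spec.acetate_fraction)
            po4 = p0 + y_p * u
            gly = gly0 - y_gly * u
            phb = y_phb * u
            phv = y_phv * u
            phase = "anaerobic"
        else:
            w = (t - spec.anaerobic_min) / spec.aerobic_min  # aerobic progress
            hac = hpr = 0.0
            po4 = ana_end["po4"] + w * (0.1 * p0 - ana_end["po4"])
            gly = ana_end["gly"] + w * (gly0 - ana_end["gly"])
            phb = ana_end["phb"] * (1 - 0.95 * w)
            phv = ana_end["phv"] * (1 - 0.95 * w)
            phase = "aerobic"
        rows.append((t, phase, hac, hpr, po4, gly, phb, phv))
    frame = pd.DataFrame(rows, columns=CYCLE_COLUMNS)
    if spec.noise_sd_rel > 0:
        rng = np.random.default_rng([spec.seed, 7])
        conc = frame.columns[2:]
        noise = rng.normal(1.0, spec.noise_sd_rel, size=(len(frame), len(conc)))
        frame[conc] = np.clip(frame[conc].to_numpy() * noise, 0.0, None)
    return frame


def write_cycle_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# 16S sets with planted probe sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    sequence_id: str
    probe: str
    start: int  # 1-based
    mismatches: int


@dataclass
class SixteenSSet:
    records: list[tuple[str, str, str]]  # (sequence_id, taxonomy, sequence)
    planted: list[PlantedSite]
    probes: list[ProbeSpec]


def _clear_background(
    rng: np.random.Generator,
    codes: np.ndarray,
    sites: list[np.ndarray],
    frozen: np.ndarray,
    skip: dict[int, set[int]],
) -> None:
    """Redraw non-frozen bases until no window is within 1 mismatch of any
    probe site (planted windows excluded via ``skip``)."""
    from numpy.lib.stride_tricks import sliding_window_view

    for _ in range(200):
        dirty = False
        for pi, site in enumerate(sites):
            m = len(site)
            windows = sliding_window_view(codes, m)
            mism = (windows != site).sum(axis=1)
            offending = np.nonzero(mism <= 1)[0]
            for off in offending:
                if off in skip.get(pi, set()):
                    continue
                span = np.arange(off, off + m)
                free = span[~frozen[span]]
                if len(free) == 0:
                    raise RuntimeError("probe site collision inside a planted span")
                codes[free] = rng.integers(0, 4, size=len(free))
                dirty = True
        if not dirty:
            return
    raise RuntimeError("background rejection sampling did not converge")


def generate_16s_set(
    probes: Sequence[ProbeSpec],
    group_sizes: Mapping[str, int],
    mismatch_plan: Mapping[str, int | Mapping[str, int]],
    seq_length: int = 1500,
    seed: int = 0,
) -> SixteenSSet:
    """Labeled 16S-like sequences with probe sites planted at controlled
    mismatch counts.

    ``mismatch_plan[taxon]`` is either one mismatch count for all probes or
    a per-probe mapping.  Each sequence contains, at a recorded position,
    the reverse complement of each planned probe with exactly the planned
    number of substitutions; the background is rejection-checked to contain
    no accidental site within 1 mismatch of any probe.
    """
    probes = list(probes)
    for p in probes:
        if len(p) > seq_length:
            raise ValueError(f"probe {p.name!r} is longer than the sequences ({seq_length} nt)")
    site_codes = [
        np.frombuffer(reverse_complement(p.sequence).encode(), dtype=np.uint8)
        for p in probes
    ]
    lookup = np.full(256, 255, dtype=np.uint8)
    for b, c in _CODE.items():
        lookup[ord(b)] = c
    site_codes = [lookup[s] for s in site_codes]

    total_sites = sum(len(p) for p in probes)
    if total_sites > seq_length:
        raise ValueError("probes do not fit in one sequence")
    gap = (seq_length - total_sites) // (len(probes) + 1)
    positions = []
    cursor = gap
    for p in probes:
        positions.append(cursor)
        cursor += len(p) + gap

    records: list[tuple[str, str, str]] = []
    planted: list[PlantedSite] = []
    for gi, (taxon, count) in enumerate(sorted(group_sizes.items())):
        plan = mismatch_plan.get(taxon, {})
        for i in range(count):
            rng = np.random.default_rng([seed, 6, gi, i])
            codes = rng.integers(0, 4, size=seq_length).astype(np.uint8)
            frozen = np.zeros(seq_length, dtype=bool)
            skip: dict[int, set[int]] = {}
            seq_id = f"{taxon}_{i + 1:03d}"
            for pi, probe in enumerate(probes):
                k = plan if isinstance(plan, int) else int(plan.get(probe.name, 0))
                if k > len(probe):
                    raise ValueError(
                        f"plan for {probe.name!r} in {taxon!r}: {k} mismatches exceed probe length"
                    )
                pos = positions[pi]
                site = site_codes[pi].copy()
                if k:
                    where = rng.choice(len(site), size=k, replace=False)
                    site[where] = (site[where] + rng.integers(1, 4, size=k)) % 4
                codes[pos : pos + len(site)] = site
                frozen[pos : pos + len(site)] = True
                skip.setdefault(pi, set()).add(pos)
                planted.append(PlantedSite(seq_id, probe.name, pos + 1, k))
            _clear_background(rng, codes, site_codes, frozen, skip)
            records.append((seq_id, taxon, _BASE_BYTES[codes].tobytes().decode("ascii")))
    return SixteenSSet(records, planted, probes)


def write_16s_set(data: SixteenSSet, fasta_path: str | Path, taxonomy_path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=sid, description="") for sid, _, seq in data.records],
        fasta_path,
        "fasta",
    )
    pd.DataFrame(
        [(sid, tax) for sid, tax, _ in data.records],
        columns=["sequence_id", "taxonomy_label"],
    ).to_csv(taxonomy_path, sep="\t", index=False)
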