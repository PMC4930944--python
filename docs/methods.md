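# Methods

This note documents the models implemented in `ebprbin`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter for reproducibility.

## Coverage profiles and alignment filtering

Alignments are filtered at identity ≥ 0.95 and aligned fraction ≥ 0.70 of
the read length (both inclusive; the thresholds are the standard stringency
for mapping short reads back to a metagenome co-assembly). Identity is
defined as 1 − NM / aligned columns, taken from the standard mismatch-count
tag; records without mismatch information raise an explicit error naming
the read rather than being silently kept or dropped. Unmapped and secondary
records are always removed.

Depth is mean per-base coverage — aligned bases divided by scaffold length
— rather than read count. This makes profiles robust to mixed read lengths
(e.g. 2×301 bp MiSeq and 2×150 bp HiSeq libraries over the same assembly)
and gives an exact conservation law used as a test invariant: summed over
scaffolds, depth × length equals the total filtered aligned bases of the
sample. Scaffolds below 1 kbp are excluded from analysis by default
(inclusive bound); plot exports use a strict > 5 kbp cut.

GC content excludes ambiguous bases from numerator and denominator.
Internally all coordinates are 0-based half-open; SAM's 1-based conventions
are converted at the I/O boundary.

## Differential-coverage binning

Scaffolds are placed at (log₁₀(d₁ + ε), log₁₀(d₂ + ε)) for one sample pair,
with pseudo-depth ε = 0.01 so zero-coverage scaffolds remain finite.
Two selection modes:

* **Polygon** — even–odd (ray crossing) membership with boundary points
  counted inside; self-intersecting polygons are rejected. This is the
  scriptable, reviewable equivalent of interactive lasso selection.
* **Density clustering** — single-linkage components of the "within radius
  r" neighbor graph, returned largest-first with ties broken by the
  lexicographically smallest member, so results are independent of input
  order. Default radius 0.1 log units: comfortably above per-scaffold
  sampling scatter at ≥ 20× depth (σ ≈ 0.43/√(aligned reads per scaffold)
  log units per axis) and below the designed inter-genome spacing.

Refinement then (1) grows the bin one round along linkage edges, (2) flags
any scaffold whose removal would eliminate a duplicated marker while
removing < 1 % of the bin length, and (3) recomputes completeness and
duplication. Flagged scaffolds are removed only when `auto_trim` is
enabled; the default is to report, not delete, because a duplicated marker
can also indicate a genuinely strain-mixed population. Strain mixtures are
handled by widening the cluster radius, not by deconvolution.

## Marker genes

Completeness and contamination derive from a catalog of 107 essential
single-copy genes: completeness is the fraction of distinct catalog
markers present; contamination is (total hits − distinct)/catalog size.
The second formula is a deliberate, testable simplification — tools that
weight lineage-specific marker sets report different contamination values
for the same bin, so those published numbers are not comparable to this
estimator.

Detection is a strategy interface: exact substring search against the
synthetic signature registry (both strands), or import of an external hit
table from an HMM/BLAST workflow, with unknown marker ids skipped and
logged. A bin's taxonomy hint is the majority label of its marker hits.

## Read-pair linkage

An edge connects two scaffolds when at least `min_links = 2` read pairs
have their mates mapped (primary alignments, both passing the alignment
filters) to the two scaffolds. One spanning pair is indistinguishable from
chimera or mapping noise, hence the default of two. Paired-end and
mate-pair links are counted identically but labeled (`pe`/`mp`/`mixed`) so
callers may weight them. Bin expansion is breadth-first over this graph and
is monotone; read-set extraction returns the ids of all pairs with either
mate in the bin.

## Bin statistics

Scaffolds are split into contigs at runs of ≥ 10 consecutive Ns; assembler
gap dialects differ, so the threshold is configurable and any comparison of
contig counts between tools should report it. N50 uses the ≥ total/2
convention (the returned value is always a member of the input multiset).
GC is length-weighted over the bin's unambiguous bases. Relative abundance
of a bin in a sample is its share of aligned bases,
100 · Σ_bin(depth·length) / Σ_all(depth·length), which partitions to 100 %
over any disjoint cover of the assembly.

## Cycle stoichiometry and the mixing model

All chemistry is molar: C-mmol/L for carbon species (per carbon atom;
glycogen as anhydroglucose monomer, PHB/PHV as monomer carbon) and
P-mmol/L for ortho-phosphate, with a registry-based mg/L converter.

Anaerobic transformation ratios are computed from phase-endpoint deltas by
default: ΔVFA (acetate + propionate) at anaerobic start minus end, and P
released, glycogen consumed, PHB/PHV formed per C-mol of ΔVFA. A rate-based
option fits least-squares slopes over the first `rate_window_min` minutes
(default 30) and takes ratios of rates. Endpoint deltas are the
reproducible choice for tabulated cycle series; initial-rate estimates from
the same reactor can differ by a few percentage points (an endpoint P/VFA
of 0.30 gives f_PAO = 60 %, where a rate-based analysis of the same system
yields 58 %), so the package reports both rather than tuning one to match
the other.

The mixing model assumes the biomass is a two-component PAO/GAO mixture
whose anaerobic ratios combine linearly. Reference stoichiometry for
acetate-fed enrichments (configurable):

| role | P/VFA | Gly/VFA | PHA/VFA | PHB/VFA | PHV/VFA |
|------|-------|---------|---------|---------|---------|
| PAO  | 0.5   | 0.5     | 1.33    | 1.33    | 0       |
| GAO  | 0     | 1.12    | 1.85    | 1.36    | 0.46    |

The `p_vfa` basis inverts the P/VFA interpolation; the `least_squares`
basis fits all selected ratios in closed form and reports per-ratio
residuals. Estimates outside [0, 1] are clipped with a warning. A
betweenness check reports, per ratio, whether an observation lies inside
the closed interval spanned by the references — observations can
legitimately fall outside (e.g. a measured PHV/VFA above both references
when the feed contains propionate, which neither acetate-fed reference
row represents), and the check states the fact rather than enforcing the
expectation. Note the tabulated GAO PHA/VFA (1.85) slightly exceeds its
PHB+PHV sum (1.82); series-derived ratio sets always satisfy
PHA = PHB + PHV, and the PHA column of a reference is carried as metadata.

PH2MV is excluded from PHA carbon accounting. Phase boundaries come from
the series' phase column; a dissolved-oxygen-threshold detector exists as a
configuration option but is disabled by default.

## Synthetic data: what it emulates, and what it does not

**Community generator.** Random genomes at configurable GC are fragmented
into scaffolds (normal lengths, sd 15 % of the mean, floor at
`fragment_min_bp`); consecutive scaffolds are recorded as adjacency ground
truth, and concatenating a genome's scaffolds in order reproduces it
exactly. Each genome carries the full marker catalog planted as unique
63-bp signature sequences wholly inside single scaffolds, registered in a
signature table — detection then reduces to exact substring search, which
preserves the completeness/duplication arithmetic without shipping HMMs or
gene models. A genome may be declared a strain of an earlier one: a
per-site mutated copy sharing the parent's fragmentation, whose intact
signature copies inflate duplication exactly as co-assembled strains do.
Random streams are partitioned per genome and per sample (seed sequences
keyed by genome and sample index), so adding a genome never perturbs the
draws of the others; all outputs are byte-identical under a fixed seed.

**Read simulator.** Error-free 150 bp pairs at 300 bp mean insert (sd 10 %)
with explicit identity fields (NM=0) so the filters are exercisable.
Fragments are placed uniformly along the genome at a rate giving each
genome its expected depth (abundance × n_genomes × mean_depth; the
abundance→depth mapping deliberately ignores genome-length normalization
because depth, not read share, is what binning consumes). Reads crossing a
scaffold junction are soft-clipped to the scaffold holding the majority of
their bases — this is what makes junction-spanning pairs observable as
cross-scaffold mates and feeds the linkage graph. Per-genome pair counts
are Poisson by default, negative-binomial optionally. Not modeled:
sequencing errors, quality scores, chimeras, GC-coverage bias, mappability.

**Default study community.** Ten 32-kbp genomes, two samples, scaffolds of
mean 8 kbp (min 4 kbp). Per-genome depths are designed, not drawn: each
genome has exactly a 5-fold abundance contrast between the two samples and
at least 20× depth in its weaker sample (20–200×), placing the ten genomes
at pairwise log-depth separations ≥ 0.21 — the regime where
differential-coverage binning is expected to work, which is what the
recovery checks are meant to certify. Genomes below ~5× or without
between-sample contrast are genuinely not separable by this method (one
test asserts exactly that failure mode for equal-abundance genomes of
distinct GC), so passing recovery tests says nothing about rare or stable
populations in real data. Genome sizes are ~100× below real bacterial
genomes; recovery statistics scale with scaffold count and depth, both of
which are at realistic per-scaffold values.

**Cycle generator.** Piecewise-linear two-phase chemistry: anaerobic VFA
uptake to zero at constant rate with release/consumption/formation
proportional to the mixed reference stoichiometry; aerobic PHA degradation,
P uptake to 10 % of the initial level and glycogen replenishment;
multiplicative Gaussian noise per measurement. Defaults: 120 min anaerobic,
180 min aerobic, 31 timepoints (10-min sampling), feed 12.5 C-mmol/L
(≈ 400 mg-COD/L of a 75 % acetate / 25 % propionate feed), influent P/C
0.15, initial glycogen sized at 1.5× the anaerobic demand. No kinetics,
no biomass growth or SRT/HRT accounting, no pH/temperature dependence —
the generator reproduces ratio structure, not dynamics.

**16S generator.** Random sequences (default 1500 nt) carrying, at recorded
positions, the reverse complement of each planned probe with exactly the
planned number of substitutions; the background is rejection-resampled so
no accidental site within 1 mismatch of any probe survives outside planted
spans. Real rRNA secondary structure, conserved stems and phylogenetic
covariance are not modeled, so coverage tables computed on synthetic sets
validate the matching arithmetic, not probe behavior against a curated
database.

## Probe matching conventions

RNA targets are compared in DNA alphabet (U→T). Degenerate IUPAC codes in
targets match when any expansion matches; probes themselves must be
non-degenerate. Non-nucleotide characters are universal mismatches, logged.
Indel handling is limited to a single 1-base gap, counted as one
mismatch-equivalent on top of remaining substitutions. E. coli position
mapping requires a user-supplied reference sequence (none is bundled),
demands a unique best site within 2 mismatches, and cross-checks declared
spans against probe length. Hybridization thermodynamics (formamide
dissociation, ΔG) are out of scope; recommended formamide concentrations
are metadata only.

## Pipeline determinism

The pipeline runs stages in fixed dependency order from a single YAML
config, validates referenced input files before any stage executes, and
writes a manifest with the parameters and a sha256 checksum of every
output. Rerunning an identical config is byte-identical for all
deterministic stages; a stage failure aborts with the stage named, and
partial outputs are retained and flagged in the manifest.

## Problem sizes used in the checks

The recovery checks run the default community (≈ 190 k read pairs per
sample, 39 scaffolds), a 900-cycle noise sweep (9 mixing fractions × 100
seeds), and ≥ 1000 randomized instances per brute-force oracle comparison;
these sizes give stable statistics while keeping the whole suite fast
enough to run on every change.

## Known limitations

* Single sample-pair selection only; no simultaneous multi-sample or
  composition-based (tetranucleotide) binning.
* The contamination estimator is catalog-normalized and not comparable to
  lineage-aware tools.
* Linkage counting trusts mate-reference fields; no insert-size or
  orientation consistency checks.
* The mixing model assumes exactly two metabolic phenotypes; organisms with
  intermediate or shifted stoichiometry bias f_PAO.
* Contig splitting depends on the assembler's N-gap dialect; `min_n_run`
  must match it before comparing contig statistics across tools.
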