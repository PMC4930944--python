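# ebprbin

Reusable pipeline for characterising lab-scale enhanced biological
phosphorus removal (EBPR) enrichments with metagenomics and cycle
chemistry: differential-coverage extraction of population genomes from
multi-sample metagenomes (with single-copy marker-gene completeness and
read-pair scaffold linkage), anaerobic/aerobic cycle stoichiometry with a
PAO/GAO mixing estimator, and in-silico evaluation of rRNA-targeted FISH
probes. A bundled synthetic-data generator provides ground truth for every
stage, so the whole pipeline is testable without downloads.

## Who this is for

Microbial ecologists running sequencing-batch EBPR reactors who want to

* recover the genomes of the dominant populations from shotgun metagenomes
  sequenced at two or more time points,
* quantify how much of the biomass behaves as a polyphosphate-accumulating
  organism (PAO) versus a glycogen-accumulating organism (GAO), and
* check whether their FISH probes actually discriminate the populations
  they think they do.

## The methods in brief

**Differential-coverage binning.** Reads from each sample are mapped to one
co-assembly and filtered at ≥ 95 % identity over ≥ 70 % of the read length.
Each scaffold then has a mean per-base depth per sample; genomes whose
relative abundance shifts between samples separate as clusters in the plane
(log₁₀ d₁, log₁₀ d₂). Bins are selected by explicit polygons or by
deterministic density clustering, expanded along read-pair linkage edges
(≥ 2 spanning pairs), and scored with a 107-gene essential single-copy
marker catalog:

    completeness  = 100 · |distinct markers in bin| / 107
    contamination = 100 · (total hits − distinct markers) / 107

**PAO/GAO mixing model.** Over the anaerobic phase both PAOs and GAOs take
up volatile fatty acids (VFA) and store them as PHA, but only PAOs release
phosphate. With Y_obs = ΔP/ΔVFA measured over the anaerobic phase and the
literature values for pure enrichments (Y_PAO = 0.5, Y_GAO = 0 P-mol/C-mol),
the PAO share of the PAO+GAO biomass is

    f_PAO = (Y_obs − Y_GAO) / (Y_PAO − Y_GAO)

with a least-squares variant over all ratios (P/VFA, Gly/VFA, PHB/VFA,
PHV/VFA) for diagnostics. Ratios come from phase-endpoint deltas by default
or from initial-rate slopes.

**Probe evaluation.** A probe binds where its reverse complement occurs in
a 16S sequence; sites are found by sliding Hamming comparison with optional
single-indel tolerance, competitor probes are verified by pairwise distance,
and per-taxon coverage tables are computed from any labeled sequence set.

## Worked example

Simulate a mixed cycle at 58 % PAO with 1 % measurement noise, then analyse
it:

```bash
ebprbin simulate cycle --f-pao 0.58 --noise 0.01 --seed 11 --out cycle.csv
ebprbin stoich --cycle cycle.csv
```

```json
{
  "method": "endpoint",
  "ratios": {
    "p_vfa": 0.292351,
    "gly_vfa": 0.762112,
    "pha_vfa": 1.559458,
    "phb_vfa": 1.365119,
    "phv_vfa": 0.194339
  },
  "betweenness": {
    "p_vfa": "inside",
    "gly_vfa": "inside",
    "pha_vfa": "inside",
    "phb_vfa": "above",
    "phv_vfa": "inside"
  },
  "pao_fraction": 0.5847,
  "gao_fraction": 0.4153
}
```

The measured P/VFA of 0.29 P-mol/C-mol sits between the pure-GAO (0) and
pure-PAO (0.5) reference values, and inverting the mixing model recovers
the generating composition (58.5 % vs the true 58 %). The `betweenness`
block flags, per ratio, whether the observation lies inside the interval
spanned by the two references.

The full metagenome workflow runs from one config:

```bash
ebprbin run --config pipeline.yaml --out run1/
```

which simulates (or ingests) a community, maps, filters, profiles coverage,
detects markers, builds the linkage graph, extracts and refines bins, and
writes per-bin summary statistics plus a manifest with a checksum for every
output.

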