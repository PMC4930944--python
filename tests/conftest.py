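"""Shared fixtures: the default study community, run once per session."""

from dataclasses import dataclass

import pytest
from hypothesis import HealthCheck, settings

from ebprbin import coverage_profiling as cov
from ebprbin import linkage_graph as lg
from ebprbin import marker_genes as mg
from ebprbin import synthetic_data as sd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@dataclass
class CommunityBundle:
    spec: sd.CommunitySpec
    truth: sd.CommunityTruth
    alignments: dict
    filtered: dict
    profiles: dict
    hits: list
    edges: list


@pytest.fixture(scope="session")
def community() -> CommunityBundle:
    """Default ten-genome, two-sample study community simulated at the
    designed depths, mapped, filtered and profiled once for the session."""
    spec = sd.default_community_spec(seed=1)
    truth = sd.generate_community(spec)
    alignments = sd.simulate_alignments(truth, spec, sd.DEFAULT_MEAN_DEPTH)
    filtered = {}
    profiles: dict[str, cov.CoverageProfile] = {}
    for sample, records in alignments.items():
        kept = cov.filter_alignments(records)
        filtered[sample] = kept
        profiles = cov.compute_coverage(kept, truth.scaffold_sequences, sample, profiles)
    hits = mg.detect_markers(truth.scaffold_sequences, truth.catalog, registry=truth.registry)
    pooled = [r for recs in filtered.values() for r in recs]
    edges = lg.build_linkage(pooled)
    return CommunityBundle(spec, truth, alignments, filtered, profiles, hits, edges)


@pytest.fixture()
def tiny_spec() -> sd.CommunitySpec:
    """Two genomes, two samples, strongly contrasted abundances."""
    return sd.CommunitySpec(
        n_genomes=2,
        genome_length_bp=12000,
        abundance_matrix=[[0.9, 0.1], [0.1, 0.9]],
        sample_ids=("a", "b"),
        fragment_mean_bp=4000,
        fragment_min_bp=1000,
        seed=7,
    )
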