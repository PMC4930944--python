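"""Ground-truth generators: determinism, conservation, planted structure."""

import numpy as np
import pytest

from ebprbin import stoichiometry as st
from ebprbin import synthetic_data as sd


def _single_genome_spec(length=10000, fragment_mean=10000, seed=3, **kw):
    return sd.CommunitySpec(
        n_genomes=1,
        genome_length_bp=length,
        abundance_matrix=[[1.0]],
        sample_ids=("s1",),
        fragment_mean_bp=fragment_mean,
        fragment_min_bp=min(1000, fragment_mean),
        seed=seed,
        **kw,
    )


class TestCommunity:
    def test_unfragmented_genome_yields_single_scaffold(self):
        truth = sd.generate_community(_single_genome_spec())
        assert len(truth.scaffold_sequences) == 1
        (sid,) = truth.scaffold_sequences
        assert len(truth.scaffold_sequences[sid]) == 10000
        assert truth.scaffold_to_genome[sid] == "g01"

    def test_each_genome_carries_full_marker_catalog(self, tiny_spec):
        truth = sd.generate_community(tiny_spec)
        assert len(truth.planted_markers) == 2 * 107
        per_genome = {}
        for m in truth.planted_markers:
            gid = truth.scaffold_to_genome[m.scaffold_id]
            per_genome.setdefault(gid, set()).add(m.marker_id)
        assert all(len(v) == 107 for v in per_genome.values())

    def test_scaffold_concatenation_reproduces_genome(self, tiny_spec):
        truth = sd.generate_community(tiny_spec)
        for gid, order in truth.scaffold_order.items():
            joined = "".join(truth.scaffold_sequences[s] for s in order)
            assert joined == truth.genome_sequences[gid]

    def test_adjacency_pairs_share_a_genome(self, tiny_spec):
        truth = sd.generate_community(tiny_spec)
        for a, b in truth.adjacency:
            assert truth.scaffold_to_genome[a] == truth.scaffold_to_genome[b]

    def test_generation_is_bit_identical(self, tmp_path, tiny_spec):
        d1, d2 = tmp_path / "one", tmp_path / "two"
        sd.write_community(sd.generate_community(tiny_spec), d1)
        sd.write_community(sd.generate_community(tiny_spec), d2)
        assert (d1 / "scaffolds.fasta").read_bytes() == (d2 / "scaffolds.fasta").read_bytes()
        assert (d1 / "marker_registry.tsv").read_bytes() == (d2 / "marker_registry.tsv").read_bytes()

    def test_gc_target_is_respected(self):
        truth = sd.generate_community(_single_genome_spec(length=50000, gc_target=0.62))
        seq = truth.genome_sequences["g01"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        # markers are planted at GC 0.5 over ~13% of this genome
        assert gc == pytest.approx(0.62 * 0.87 + 0.5 * 0.13, abs=0.02)

    def test_fragment_min_longer_than_genome_is_invalid(self):
        with pytest.raises(ValueError, match="fragment_min_bp"):
            sd.CommunitySpec(
                n_genomes=1,
                genome_length_bp=500,
                abundance_matrix=[[1.0]],
                fragment_mean_bp=1000,
                fragment_min_bp=1000,
            )

    def test_abundance_columns_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sd.CommunitySpec(
                n_genomes=2,
                genome_length_bp=5000,
                abundance_matrix=[[0.5, 0.5], [0.4, 0.5]],
                fragment_mean_bp=5000,
            )

    def test_strain_copy_shares_marker_signatures(self):
        spec = sd.CommunitySpec(
            n_genomes=2,
            genome_length_bp=20000,
            abundance_matrix=[[0.5], [0.5]],
            sample_ids=("s1",),
            fragment_mean_bp=20000,
            fragment_min_bp=1000,
            strain_of={1: (0, 0.005)},
            seed=11,
        )
        truth = sd.generate_community(spec)
        # registry only holds the parent's signatures; the mutated strain
        # retains most of them intact, which is what inflates duplication
        assert len(truth.registry) == 107
        assert truth.taxonomy["g02"] == truth.taxonomy["g01"]
        mutated = sum(
            a != b
            for a, b in zip(truth.genome_sequences["g01"], truth.genome_sequences["g02"])
        )
        assert 0 < mutated < 20000 * 0.01


class TestAlignments:
    def test_read_count_matches_depth_length_expectation(self):
        spec = _single_genome_spec(length=1000, fragment_mean=1000, seed=5, n_markers=5)
        truth = sd.generate_community(spec)
        recs = sd.simulate_alignments(truth, spec, mean_depth=10.0, read_bp=100, insert_bp=200)
        n_reads = len(recs["s1"])
        assert abs(n_reads - 100) <= 4 * np.sqrt(100) * 2  # 4 sigma on pair count

    def test_depth_ratio_follows_abundance_contrast(self, tiny_spec):
        truth = sd.generate_community(tiny_spec)
        per_sample = sd.simulate_alignments(truth, tiny_spec, mean_depth=30.0)
        g1 = set(truth.scaffold_order["g01"])
        bases = {}
        for sample, recs in per_sample.items():
            bases[sample] = sum(r.aligned_len for r in recs if r.scaffold in g1)
        ratio = bases["a"] / bases["b"]
        assert ratio == pytest.approx(9.0, rel=0.15)

    def test_mean_depth_matches_analytic_expectation_over_seeds(self):
        """Averaged over 50 seeds, per-scaffold depth is within 2% of
        abundance * n_genomes * mean_depth."""
        depths = []
        for seed in range(50):
            spec = sd.CommunitySpec(
                n_genomes=2,
                genome_length_bp=6000,
                abundance_matrix=[[0.7], [0.3]],
                sample_ids=("s1",),
                n_markers=20,
                fragment_mean_bp=6000,
                fragment_min_bp=1000,
                seed=seed,
            )
            truth = sd.generate_community(spec)
            recs = sd.simulate_alignments(truth, spec, mean_depth=25.0)
            g1 = truth.scaffold_order["g01"][0]
            aligned = sum(r.aligned_len for r in recs["s1"] if r.scaffold == g1)
            depths.append(aligned / 6000)
        expect = sd.expected_depth(spec, 0, "s1", 25.0)
        assert np.mean(depths) == pytest.approx(expect, rel=0.02)

    def test_single_scaffold_genomes_give_no_cross_scaffold_pairs(self, tiny_spec):
        spec = sd.CommunitySpec(
            n_genomes=2,
            genome_length_bp=8000,
            abundance_matrix=tiny_spec.abundance_matrix,
            sample_ids=("a", "b"),
            n_markers=30,
            fragment_mean_bp=8000,
            fragment_min_bp=1000,
            seed=2,
        )
        truth = sd.generate_community(spec)
        for recs in sd.simulate_alignments(truth, spec, mean_depth=20.0).values():
            assert all(r.scaffold == r.mate_scaffold for r in recs)

    def test_junction_spanning_pairs_link_adjacent_scaffolds(self, tiny_spec):
        truth = sd.generate_community(tiny_spec)
        adj = {tuple(sorted(p)) for p in truth.adjacency}
        recs = sd.simulate_alignments(truth, tiny_spec, mean_depth=30.0)
        cross = {
            tuple(sorted((r.scaffold, r.mate_scaffold)))
            for sample in recs.values()
            for r in sample
            if r.scaffold != r.mate_scaffold
        }
        assert cross  # junctions produce cross-scaffold mates
        assert cross <= adj  # and only at true adjacencies

    def test_same_seed_reproduces_alignments(self, tiny_spec):
        truth = sd.generate_community(tiny_spec)
        a = sd.simulate_alignments(truth, tiny_spec, mean_depth=10.0)
        b = sd.simulate_alignments(truth, tiny_spec, mean_depth=10.0)
        assert a == b

    def test_read_longer_than_shortest_scaffold_rejected(self, tiny_spec):
        truth = sd.generate_community(tiny_spec)
        shortest = min(len(s) for s in truth.scaffold_sequences.values())
        with pytest.raises(ValueError, match="shorter"):
            sd.simulate_alignments(truth, tiny_spec, mean_depth=5.0, read_bp=shortest + 1)

    def test_negative_binomial_model_runs(self, tiny_spec):
        truth = sd.generate_community(tiny_spec)
        recs = sd.simulate_alignments(truth, tiny_spec, mean_depth=5.0, count_model="nb")
        assert sum(map(len, recs.values())) > 0


class TestCycle:
    @pytest.mark.parametrize(
        "f_pao, expect",
        [
            (1.0, (0.5, 0.5, 1.33, 0.0)),
            (0.0, (0.0, 1.12, 1.36, 0.46)),
            (0.5, (0.25, 0.81, 1.345, 0.23)),
        ],
    )
    def test_noise_free_ratios_reproduce_reference_mixture(self, f_pao, expect):
        series = sd.generate_cycle(sd.CycleSpec(f_pao=f_pao))
        r = st.transformation_ratios(series)
        p, gly, phb, phv = expect
        assert r.p_vfa == pytest.approx(p, abs=1e-9)
        assert r.gly_vfa == pytest.approx(gly, abs=1e-9)
        assert r.phb_vfa == pytest.approx(phb, abs=1e-9)
        assert r.phv_vfa == pytest.approx(phv, abs=1e-9)

    def test_cycle_shape(self):
        series = sd.generate_cycle(sd.CycleSpec(f_pao=0.6))
        ana = series[series.phase == "anaerobic"]
        aer = series[series.phase == "aerobic"]
        vfa = ana.hac_cmmol + ana.hpr_cmmol
        assert vfa.iloc[0] == pytest.approx(12.5)
        assert vfa.iloc[-1] == pytest.approx(0.0, abs=1e-9)
        assert (np.diff(vfa) < 0).all()
        # aerobic: P taken up below its initial value, glycogen replenished
        assert aer.po4_pmmol.iloc[-1] < ana.po4_pmmol.iloc[0]
        assert aer.gly_cmmol.iloc[-1] == pytest.approx(ana.gly_cmmol.iloc[0])
        assert aer.phb_cmmol.iloc[-1] < ana.phb_cmmol.iloc[-1]

    def test_feed_split_follows_acetate_fraction(self):
        series = sd.generate_cycle(sd.CycleSpec(f_pao=0.5, acetate_fraction=0.75))
        first = series.iloc[0]
        assert first.hac_cmmol == pytest.approx(0.75 * 12.5)
        assert first.hpr_cmmol == pytest.approx(0.25 * 12.5)

    def test_noise_is_seeded_and_multiplicative(self):
        a = sd.generate_cycle(sd.CycleSpec(f_pao=0.5, noise_sd_rel=0.05, seed=4))
        b = sd.generate_cycle(sd.CycleSpec(f_pao=0.5, noise_sd_rel=0.05, seed=4))
        c = sd.generate_cycle(sd.CycleSpec(f_pao=0.5, noise_sd_rel=0.05, seed=5))
        assert a.equals(b)
        assert not a.equals(c)
        assert (a[a.columns[2:]] >= 0).all().all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sd.CycleSpec(f_pao=1.5)
        with pytest.raises(ValueError):
            sd.CycleSpec(f_pao=0.5, anaerobic_min=0)
        with pytest.raises(ValueError):
            sd.CycleSpec(f_pao=0.5, noise_sd_rel=-0.1)


class TestSixteenS:
    def test_planted_sites_have_exact_mismatch_counts(self):
        from ebprbin.probe_match import DESIGNED_PROBES, match_probe

        probes = [DESIGNED_PROBES[0], DESIGNED_PROBES[2]]  # Prop207, Prop470
        data = sd.generate_16s_set(
            probes,
            {"target": 3, "near": 3},
            {"target": 0, "near": {"Prop207": 2, "Prop470": 1}},
            seed=9,
        )
        for sid, tax, seq in data.records:
            for probe in probes:
                exact = match_probe(probe, seq, max_mismatch=0)
                if tax == "target":
                    assert len(exact) == 1
                else:
                    assert not exact
        # the two-mismatch site appears at max_mismatch=2 but not 1
        near = [r for r in data.records if r[1] == "near"][0]
        prop207 = probes[0]
        assert not match_probe(prop207, near[2], max_mismatch=1)
        assert match_probe(prop207, near[2], max_mismatch=2)[0].mismatches == 2

    def test_background_contains_no_accidental_near_sites(self):
        from ebprbin.probe_match import DESIGNED_PROBES, match_probe

        probe = DESIGNED_PROBES[0]
        data = sd.generate_16s_set([probe], {"x": 5}, {"x": 0}, seed=13)
        planted = {(p.sequence_id, p.start) for p in data.planted}
        for sid, _, seq in data.records:
            for m in match_probe(probe, seq, max_mismatch=1):
                assert (sid, m.start) in planted

    def test_impossible_plan_rejected(self):
        from ebprbin.probe_match import DESIGNED_PROBES

        with pytest.raises(ValueError, match="longer"):
            sd.generate_16s_set([DESIGNED_PROBES[0]], {"x": 1}, {"x": 0}, seq_length=10)
        with pytest.raises(ValueError, match="exceed"):
            sd.generate_16s_set([DESIGNED_PROBES[0]], {"x": 1}, {"x": 99})
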