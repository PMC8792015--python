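"""Fragment size filtering, coverage tracks, TSS matrices, enrichment,
and windowed occupancy differences."""

import numpy as np
import pandas as pd
import pytest

from nucbubble.mnase import (
    Fragment,
    FragmentSet,
    GeneAnchor,
    aggregate_profile,
    filter_by_insert_size,
    gene_enrichment,
    occupancy_track,
    tss_matrix,
    window_occupancy_difference,
)
from nucbubble.simulate import FragmentSimConfig, simulate_mnase_fragments


def fs(intervals, chrom="chr1"):
    return FragmentSet(pd.DataFrame(
        [(chrom, s, e) for s, e in intervals], columns=["chrom", "start", "end"]
    ))


def naive_coverage(intervals, start, end):
    cov = np.zeros(end - start, dtype=int)
    for s, e in intervals:
        for i in range(max(s, start), min(e, end)):
            cov[i - start] += 1
    return cov


class TestFilterByInsertSize:
    def test_mononucleosome_kept_sub_removed(self):
        frags = fs([(0, 150), (0, 90), (0, 120), (0, 181)])
        kept = filter_by_insert_size(frags)
        assert sorted(kept.lengths.tolist()) == [120, 150]

    def test_bounds_inclusive_both_ends(self):
        kept = filter_by_insert_size(fs([(0, 120), (0, 180), (0, 119), (0, 181)]))
        assert sorted(kept.lengths.tolist()) == [120, 180]

    def test_random_set_matches_brute_force(self, rng):
        starts = rng.integers(0, 1000, 300)
        lens = rng.integers(50, 260, 300)
        frags = fs(list(zip(starts, starts + lens)))
        kept = filter_by_insert_size(frags, 120, 180)
        assert len(kept) == int(np.sum((lens >= 120) & (lens <= 180)))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_by_insert_size(fs([(0, 150)]), 180, 120)


class TestOccupancyTrack:
    def test_single_fragment(self):
        cov = occupancy_track(fs([(100, 250)]), "chr1", (0, 400))
        assert cov[99] == 0 and cov[100] == 1 and cov[249] == 1 and cov[250] == 0
        assert cov.sum() == 150

    def test_two_identical_fragments_stack(self):
        cov = occupancy_track(fs([(10, 20), (10, 20)]), "chr1", (0, 30))
        assert (cov[10:20] == 2).all()

    def test_random_fragments_match_naive_loop(self, rng):
        iv = [(int(s), int(s + l)) for s, l in zip(rng.integers(0, 300, 120), rng.integers(1, 80, 120))]
        cov = occupancy_track(fs(iv), "chr1", (0, 400))
        np.testing.assert_array_equal(cov, naive_coverage(iv, 0, 400))

    def test_coverage_conservation(self, rng):
        # sum of coverage over an all-containing region == sum of lengths
        iv = [(int(s), int(s + l)) for s, l in zip(rng.integers(0, 500, 200), rng.integers(1, 120, 200))]
        cov = occupancy_track(fs(iv), "chr1", (0, 700))
        assert cov.sum() == sum(e - s for s, e in iv)

    def test_filter_then_track_commutes(self, rng):
        iv = [(int(s), int(s + l)) for s, l in zip(rng.integers(0, 300, 150), rng.integers(60, 250, 150))]
        frags = fs(iv)
        a = occupancy_track(filter_by_insert_size(frags), "chr1", (0, 600))
        kept = [(s, e) for s, e in iv if 120 <= e - s <= 180]
        np.testing.assert_array_equal(a, naive_coverage(kept, 0, 600))


class TestTssMatrix:
    def test_plus_strand_fragment_lands_downstream(self):
        anchors = [GeneAnchor("g", "chr1", 5000, "+")]
        frags = fs([(5035, 5185)])  # midpoint at TSS+110
        m = tss_matrix(frags, anchors, window_bp=300)
        row = m.values[0]
        assert row[m.positions.tolist().index(110)] == 1
        assert row[: m.positions.tolist().index(35)].sum() == 0

    def test_minus_strand_mirror_gives_identical_row(self):
        # genomic mirror around position M: [s,e) -> [M-e, M-s), strand flips
        M = 20000
        plus = tss_matrix(fs([(5035, 5185)]), [GeneAnchor("g", "chr1", 5000, "+")], 300)
        minus = tss_matrix(
            fs([(M - 5185, M - 5035)]), [GeneAnchor("g", "chr1", M - 1 - 5000, "-")], 300
        )
        np.testing.assert_array_equal(plus.values, minus.values)

    def test_no_fragments_all_zero(self):
        m = tss_matrix(fs([]), [GeneAnchor("g", "chr1", 1000, "+")], 200)
        assert m.values.sum() == 0

    def test_window_clipped_at_chromosome_start(self):
        m = tss_matrix(fs([(0, 50)]), [GeneAnchor("g", "chr1", 100, "+")], 500)
        assert m.clipped == [True]
        assert m.values.shape == (1, 1000)

    def test_strand_reflection_equivariance_random(self, rng):
        M = 50000
        iv = [(int(s), int(s + l)) for s, l in zip(rng.integers(0, 40000, 300), rng.integers(80, 200, 300))]
        anchors = [GeneAnchor(f"g{i}", "chr1", int(t), "+") for i, t in enumerate(rng.integers(2000, 38000, 10))]
        fwd = tss_matrix(fs(iv), anchors, 1000)
        mirrored = fs([(M - e, M - s) for s, e in iv])
        m_anchors = [GeneAnchor(a.gene_id, a.chrom, M - 1 - a.tss, "-") for a in anchors]
        rev = tss_matrix(mirrored, m_anchors, 1000)
        np.testing.assert_array_equal(fwd.values, rev.values)


class TestAggregateProfile:
    def test_identical_rows_equal_any_normalized_row(self):
        anchors = [GeneAnchor(f"g{i}", "chr1", 5000, "+") for i in range(4)]
        m = tss_matrix(fs([(5035, 5185)]), anchors, 300)
        prof = aggregate_profile(m)
        row = m.values[0] / m.values[0].mean()
        np.testing.assert_allclose(prof, row)

    def test_planted_plus_one_argmax_near_offset(self):
        cfg = FragmentSimConfig(n_genes=60, seed=5)
        sim = simulate_mnase_fragments(cfg)
        enriched = set(sim.truth.loc[sim.truth["enriched"], "gene_id"])
        anchors = [a for a in sim.anchors if a.gene_id in enriched]
        m = tss_matrix(sim.ip, anchors, window_bp=500)
        prof = aggregate_profile(m)
        assert abs(int(m.positions[prof.argmax()]) - cfg.plus_one_offset_bp) <= 10

    def test_all_background_profile_flat(self):
        cfg = FragmentSimConfig(
            n_genes=200, genome_len=4_000_000, frags_per_gene_ip=500,
            background_frac=1.0, input_background_frac=1.0, enriched_gene_frac=0.0, seed=6,
        )
        sim = simulate_mnase_fragments(cfg)
        m = tss_matrix(sim.ip, sim.anchors, window_bp=500)
        prof = aggregate_profile(m)
        assert prof.std() / prof.mean() < 0.1


class TestGeneEnrichment:
    def test_identical_samples_fold_one(self, rng):
        iv = [(int(s), int(s + 150)) for s in rng.integers(0, 20000, 200)]
        frags = fs(iv)
        anchors = [GeneAnchor(f"g{i}", "chr1", int(t), "+") for i, t in enumerate(rng.integers(2000, 18000, 5))]
        df = gene_enrichment(frags, frags, anchors, window_bp=1000)
        assert np.allclose(df["fold"], 1.0)
        assert not df["enriched"].any()

    def test_five_fold_limit_with_growing_counts(self):
        # IP counts exactly 5x control at equal library sizes: fold -> 5
        anchors = [GeneAnchor("g", "chr1", 5000, "+")]
        folds = []
        for n in (10, 100, 1000):
            ip_iv = [(4900, 5050)] * (5 * n) + [(50000, 50150)] * 0
            ctl_iv = [(4900, 5050)] * n + [(50000, 50150)] * (4 * n)
            folds.append(
                gene_enrichment(fs(ip_iv), fs(ctl_iv), anchors, 1000)["fold"].iloc[0]
            )
        assert abs(folds[-1] - 5.0) < 0.05
        assert abs(folds[-1] - 5.0) < abs(folds[0] - 5.0)

    def test_library_size_scale_invariance(self, rng):
        iv_ip = [(int(s), int(s + 150)) for s in rng.integers(0, 20000, 300)]
        iv_ctl = [(int(s), int(s + 150)) for s in rng.integers(0, 20000, 300)]
        anchors = [GeneAnchor("g", "chr1", 10000, "+")]
        base = gene_enrichment(fs(iv_ip), fs(iv_ctl), anchors, 1000)["fold"].iloc[0]
        # tripling both libraries with the same composition preserves fold
        trip = gene_enrichment(fs(iv_ip * 3), fs(iv_ctl * 3), anchors, 1000)["fold"].iloc[0]
        ip_n, ctl_n = 300, 300
        c_ip = fs(iv_ip).count_overlapping("chr1", 9000, 11000)
        c_ctl = fs(iv_ctl).count_overlapping("chr1", 9000, 11000)
        want = ((3 * c_ip + 1) / (3 * ip_n)) / ((3 * c_ctl + 1) / (3 * ctl_n))
        assert trip == pytest.approx(want)
        assert abs(trip - base) < 0.05  # pseudocount effect only

    def test_planted_enrichment_recovered(self):
        sim = simulate_mnase_fragments(FragmentSimConfig(seed=8))
        df = gene_enrichment(sim.ip, sim.input, sim.anchors, window_bp=300)
        called = set(df.loc[df["enriched"], "gene_id"])
        truth = set(sim.truth.loc[sim.truth["enriched"], "gene_id"])
        tp = len(called & truth)
        assert tp / max(len(called), 1) >= 0.9
        assert tp / len(truth) >= 0.9


class TestWindowDifference:
    def test_equal_matrices_effect_zero_p_one(self):
        anchors = [GeneAnchor(f"g{i}", "chr1", 5000 + 100 * i, "+") for i in range(6)]
        frags = fs([(5035 + 100 * i, 5185 + 100 * i) for i in range(6)])
        m = tss_matrix(frags, anchors, 300)
        df = window_occupancy_difference(m, m, windows=[(100, 200)], n_boot=2000, seed=0)
        assert df["effect"].iloc[0] == 0.0
        assert df["p_value"].iloc[0] > 0.5

    def test_fuzzy_vs_sharp_positioning_significant_downstream(self):
        sharp = simulate_mnase_fragments(
            FragmentSimConfig(n_genes=150, genome_len=3_000_000, fuzziness_bp=10, seed=31)
        )
        fuzzy = simulate_mnase_fragments(
            FragmentSimConfig(n_genes=150, genome_len=3_000_000, fuzziness_bp=60, seed=32)
        )
        ma = tss_matrix(sharp.ip, sharp.anchors, 500)
        mb = tss_matrix(fuzzy.ip, fuzzy.anchors, 500)
        df = window_occupancy_difference(ma, mb, windows=[(100, 200)], n_boot=4000, seed=1)
        assert df["p_value"].iloc[0] < 0.05

    def test_bootstrap_p_close_to_permutation_oracle(self, rng):
        anchors = [GeneAnchor(f"g{i}", "chr1", 2000 + 3000 * i, "+") for i in range(30)]
        iv_a = [(2000 + 3000 * i + 100, 2000 + 3000 * i + 250) for i in range(30)]
        iv_b = [(2000 + 3000 * i + 130, 2000 + 3000 * i + 280) for i in range(30)]
        ma = tss_matrix(fs(iv_a * 2), anchors, 400)
        mb = tss_matrix(fs(iv_b * 2), anchors, 400)
        df = window_occupancy_difference(ma, mb, windows=[(100, 200)], n_boot=20000, seed=2)
        p_boot = df["p_value"].iloc[0]
        # permutation oracle on per-gene window means
        from nucbubble.mnase import normalize_rows
        va, _ = normalize_rows(ma)
        vb, _ = normalize_rows(mb)
        ga = va[:, 100 + 400 : 200 + 400].mean(axis=1)
        gb = vb[:, 100 + 400 : 200 + 400].mean(axis=1)
        obs = abs(ga.mean() - gb.mean())
        pooled = np.concatenate([ga, gb])
        n_perm, hits = 20000, 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:30].mean() - perm[30:].mean()) >= obs - 1e-12:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        assert abs(p_boot - p_perm) < 0.02

    def test_empty_intersection_rejected(self):
        anchors_a = [GeneAnchor("a", "chr1", 5000, "+")]
        anchors_b = [GeneAnchor("b", "chr1", 5000, "+")]
        ma = tss_matrix(fs([(4900, 5050)]), anchors_a, 300)
        mb = tss_matrix(fs([(4900, 5050)]), anchors_b, 300)
        with pytest.raises(ValueError, match="intersection"):
            window_occupancy_difference(ma, mb)


class TestSimulatedFragmentInvariants:
    def test_counts_per_gene_exact_and_in_range(self):
        cfg = FragmentSimConfig(n_genes=30, seed=9)
        sim = simulate_mnase_fragments(cfg)
        assert len(sim.ip) == cfg.n_genes * cfg.frags_per_gene_ip
        assert len(sim.input) == cfg.n_genes * cfg.frags_per_gene_input
        for frags in (sim.ip, sim.input):
            assert (frags.df["start"] < frags.df["end"]).all()
            assert (frags.df["start"] >= 0).all()
            assert (frags.df["end"] <= cfg.genome_len).all()

    def test_degenerate_jitter_all_midpoints_at_offset(self):
        cfg = FragmentSimConfig(
            n_genes=10, fuzziness_bp=0.0, background_frac=0.0, enriched_gene_frac=1.0, seed=10
        )
        sim = simulate_mnase_fragments(cfg)
        mids = (sim.ip.df["start"] + sim.ip.df["end"]) // 2
        truth = sim.truth.set_index("gene_id")
        spacing = cfg.genome_len // cfg.n_genes
        for mid in mids:
            gene = truth.iloc[int(mid) // spacing]
            assert abs(int(mid) - gene.dyad) <= 1  # odd lengths round the midpoint

    def test_minus_strand_dyad_upstream_in_genomic_coords(self):
        sim = simulate_mnase_fragments(FragmentSimConfig(n_genes=40, seed=11))
        minus = sim.truth[sim.truth["strand"] == "-"]
        assert (minus["dyad"] == minus["tss"] - 110).all()

    def test_fixed_seed_bit_identical(self):
        a = simulate_mnase_fragments(FragmentSimConfig(n_genes=20, seed=12))
        b = simulate_mnase_fragments(FragmentSimConfig(n_genes=20, seed=12))
        pd.testing.assert_frame_equal(a.ip.df, b.ip.df)
        pd.testing.assert_frame_equal(a.truth, b.truth)
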