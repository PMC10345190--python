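"""Conservation, half-life, correlation and codon-usage statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from boundary_m6a import simulate
from boundary_m6a.stats import (
    codon_amino_usage,
    conservation_compare,
    correlate,
    degenerate_synonymous_positions,
    group_halflife_compare,
    m6a_rac_ratio,
    match_groups,
    rank_sum_test,
)
from conftest import make_transcript


class TestDegeneratePositions:
    @pytest.fixture
    def coding_tx(self):
        def build(cds):
            tx = make_transcript([len(cds)], [])
            tx.cds_start_offset = 0
            tx.cds_end_offset = len(cds)
            return tx, cds
        return build

    def test_fourfold_third_position(self, coding_tx):
        tx, cds = coding_tx("GGA")          # Gly, 4-fold degenerate
        assert 2 in degenerate_synonymous_positions(tx, cds)

    def test_met_trp_have_no_synonyms(self, coding_tx):
        for codon in ("ATG", "TGG"):
            tx, cds = coding_tx(codon)
            assert degenerate_synonymous_positions(tx, cds) == set()

    def test_leu_first_position(self, coding_tx):
        tx, cds = coding_tx("TTA")          # TTA <-> CTA synonymous
        assert 0 in degenerate_synonymous_positions(tx, cds)

    def test_partial_codon_trimmed_with_warning(self, coding_tx):
        tx, cds = coding_tx("GGAG")
        with pytest.warns(UserWarning, match="partial codon"):
            pos = degenerate_synonymous_positions(tx, cds)
        assert pos == {2}

    def test_unknown_frame_is_error(self):
        tx = make_transcript([9], [])
        with pytest.raises(ValueError, match="CDS"):
            degenerate_synonymous_positions(tx, "GGAGGAGGA")


def wilcoxon_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n = len(x)
    stats = [
        sum(combo) for combo in itertools.combinations(range(1, len(pooled) + 1), n)
    ]
    mean = np.mean(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(stats)


class TestRankSum:
    def test_identical_groups(self):
        assert rank_sum_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == pytest.approx(1.0, abs=0.05)

    def test_exact_small_sample(self):
        """{1,2,3} vs {4,5,6}: exact two-sided p = 0.1 (2 of 20 rankings)."""
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = list(np.round(rng.uniform(0, 10, rng.integers(3, 7)), 6))
        y = list(np.round(rng.uniform(0, 10, rng.integers(3, 7)), 6))
        assert rank_sum_test(x, y) == pytest.approx(wilcoxon_enumeration(x, y), rel=1e-9)

    def test_planted_shift_detected(self, rng):
        x = rng.normal(1.0, 1, 200)
        y = rng.normal(0.0, 1, 200)
        assert rank_sum_test(x, y) < 1e-6


class TestConservationCompare:
    def test_medians_and_p(self, rng):
        latent = rng.normal(1, 1, 300)
        nochange = rng.normal(0, 1, 300)
        out = conservation_compare(latent, nochange)
        assert out["median_latent"] > out["median_nochange"]
        assert out["p_value"] < 1e-6

    def test_restriction_masks(self, rng):
        latent = np.concatenate([rng.normal(2, 0.1, 50), rng.normal(0, 0.1, 50)])
        keep = np.array([True] * 50 + [False] * 50)
        out = conservation_compare(latent, rng.normal(0, 0.1, 60), restrict_latent=keep)
        assert out["n_latent"] == 50
        assert out["median_latent"] == pytest.approx(2, abs=0.1)

    def test_empty_after_restriction_is_error(self, rng):
        with pytest.raises(ValueError, match="latent"):
            conservation_compare([1.0], [2.0], restrict_latent=[False])


class TestM6aRacRatio:
    def test_all_below_threshold(self):
        probs = np.full(10, 0.05)           # threshold is strict >
        assert m6a_rac_ratio(probs, [1, 3, 5]) == (0, 3, 0.0)

    def test_partial(self):
        probs = np.zeros(20)
        probs[[2, 4, 6, 8]] = 0.6
        sites = [2, 4, 6, 8, 10, 12, 14, 16, 18, 1]
        n_m6a, n_rac, ratio = m6a_rac_ratio(probs, sites)
        assert (n_m6a, n_rac) == (4, 10) and ratio == pytest.approx(0.4)

    def test_no_rac(self):
        assert m6a_rac_ratio(np.ones(5), []) == (0, 0, 0.0)

    def test_brute_force_recount(self, rng):
        for _ in range(100):
            probs = rng.uniform(0, 1, 50)
            sites = rng.choice(50, size=rng.integers(1, 20), replace=False)
            n_m6a, n_rac, ratio = m6a_rac_ratio(probs, sites)
            expected = sum(1 for s in sites if probs[s] > 0.05)
            assert n_m6a == expected and n_rac == len(sites)
            assert ratio == pytest.approx(expected / len(sites))


class TestCorrelate:
    def test_perfect_lines(self):
        x = [1.0, 2, 3, 4, 5]
        assert correlate(x, [2 * v + 1 for v in x])[0] == pytest.approx(1.0)
        assert correlate(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_matches_independent_formula(self, rng):
        from scipy import stats as sps
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, p = correlate(x, y)
        # high-precision independent recomputation
        r_ref = float(np.corrcoef(x, y)[0, 1])
        t_ref = r_ref * math.sqrt(8 / (1 - r_ref**2))
        p_ref = 2 * sps.t.sf(abs(t_ref), df=8)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [3, 4])


class TestMatchGroups:
    def test_exact_key_matching(self):
        a = pd.DataFrame({"rac_count": [5, 7]})
        b = pd.DataFrame({"rac_count": [5, 7, 9]})
        pairs = match_groups(a, b, by="rac_count", seed=0)
        assert len(pairs) == 2
        assert sorted(pairs["key_a"]) == [5.0, 7.0]
        assert (pairs["key_a"] == pairs["key_b"]).all()

    def test_disjoint_keys_empty(self):
        a = pd.DataFrame({"rac_count": [1, 2]})
        b = pd.DataFrame({"rac_count": [8, 9]})
        with pytest.warns(UserWarning, match="no matched pairs"):
            pairs = match_groups(a, b, by="rac_count", seed=0)
        assert pairs.empty

    def test_exact_mode_distributions_identical(self, rng):
        a = pd.DataFrame({"rac_count": rng.integers(0, 10, 50)})
        b = pd.DataFrame({"rac_count": rng.integers(0, 10, 80)})
        pairs = match_groups(a, b, by="rac_count", seed=1)
        assert sorted(pairs["key_a"]) == sorted(pairs["key_b"])

    def test_caliper_matching(self):
        a = pd.DataFrame({"cdna_length": [1000.0, 2000.0]})
        b = pd.DataFrame({"cdna_length": [1050.0, 5000.0]})
        pairs = match_groups(a, b, by="cdna_length", seed=0)
        assert len(pairs) == 1
        assert pairs["key_b"].iloc[0] == 1050.0

    def test_without_replacement(self):
        a = pd.DataFrame({"rac_count": [5, 5, 5]})
        b = pd.DataFrame({"rac_count": [5]})
        pairs = match_groups(a, b, by="rac_count", seed=0)
        assert len(pairs) == 1


class TestGroupHalfLife:
    def _table(self, rng, n, beta):
        counts = rng.integers(0, 15, n)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "rac_count": rng.integers(5, 30, n),
                "m6a_count": counts,
                "t12_wt": 8 * np.exp(-beta * counts) * np.exp(rng.normal(0, 0.2, n)),
                "t12_ko": 8 * np.exp(rng.normal(0, 0.2, n)),
            }
        )

    def test_identical_groups_null(self, rng):
        g = self._table(rng, 40, 0.15)
        pairs = pd.DataFrame(
            {"index_a": range(40), "index_b": range(40), "key_a": 0, "key_b": 0}
        )
        out = group_halflife_compare(g, g.copy(), pairs)
        for metric in out["metrics"].values():
            assert metric["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_wt_difference_ko_flat(self, rng):
        """High- vs low-methylation groups differ in WT half-life but not in
        KO half-life (methylation dependence removed)."""
        hi = self._table(rng, 300, 0.15)
        hi["m6a_count"] += 10
        hi["t12_wt"] = 8 * np.exp(-0.15 * hi["m6a_count"]) * np.exp(rng.normal(0, 0.2, 300))
        lo = self._table(rng, 300, 0.15)
        pairs = pd.DataFrame(
            {"index_a": range(300), "index_b": range(300), "key_a": 0, "key_b": 0}
        )
        out = group_halflife_compare(hi, lo, pairs)
        assert out["metrics"]["t12_wt"]["p_value"] < 1e-6
        assert out["metrics"]["t12_ko"]["p_value"] > 0.01
        assert out["metrics"]["m6a_count"]["p_value"] < 1e-6

    def test_missing_ko_column_skipped(self, rng):
        g = self._table(rng, 10, 0.1).drop(columns=["t12_ko"])
        pairs = pd.DataFrame(
            {"index_a": range(10), "index_b": range(10), "key_a": 0, "key_b": 0}
        )
        out = group_halflife_compare(g, g.copy(), pairs)
        assert "t12_ko" in out["skipped"] and "delta_t12" in out["skipped"]
        assert "t12_wt" in out["metrics"]


def fisher_two_sided_oracle(a, b, c, d):
    n, K, N = a + b, a + c, a + b + c + d
    rv = hypergeom(N, K, n)
    support = np.arange(max(0, n - (N - K)), min(n, K) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum())


class TestCodonUsage:
    def test_toy_contingency(self):
        """GAC 30 vs 10 against GAT 10 vs 30: OR = 9, p from enumeration."""
        c1 = [("GAC" * 30, 0), ("GAT" * 10, 0)]
        c2 = [("GAC" * 10, 0), ("GAT" * 30, 0)]
        usage = codon_amino_usage(c1, c2)
        row = usage[(usage["kind"] == "codon") & (usage["name"] == "GAC")].iloc[0]
        assert (row["count_c1"], row["count_c2"]) == (30, 10)
        assert row["odds_ratio"] == pytest.approx(9.0)
        assert row["p_value"] == pytest.approx(
            fisher_two_sided_oracle(30, 10, 10, 30), rel=1e-9
        )

    def test_synonymous_codons_cancel_at_amino_level(self):
        """All-GAC vs all-GAT exons: codon ORs are extreme but the Asp
        amino-acid OR is 1."""
        usage = codon_amino_usage([("GAC" * 30, 0)], [("GAT" * 30, 0)])
        asp = usage[(usage["kind"] == "amino_acid") & (usage["name"] == "D")].iloc[0]
        assert asp["odds_ratio"] == pytest.approx(1.0)
        gac = usage[(usage["kind"] == "codon") & (usage["name"] == "GAC")].iloc[0]
        assert np.isfinite(gac["odds_ratio"]) and gac["odds_ratio"] > 1

    def test_identical_groups(self):
        exons = [("ATGGGAGAC" * 5, 0)]
        usage = codon_amino_usage(exons, list(exons))
        assert np.allclose(usage["odds_ratio"], 1.0)

    def test_first_n_codons_only(self):
        usage = codon_amino_usage([("GAC" * 40, 0)], [("GAC" * 40, 0)], n_codons=30)
        row = usage[(usage["kind"] == "codon") & (usage["name"] == "GAC")].iloc[0]
        assert row["count_c1"] == 30

    def test_stop_codons_excluded(self):
        usage = codon_amino_usage([("TAA" * 10 + "GAC" * 3, 0)], [("GAC" * 3, 0)])
        assert "TAA" not in set(usage["name"])

    def test_unknown_frame_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="unknown frame"):
            usage = codon_amino_usage([("GAC" * 5, 0), ("GAC" * 5, -1)], [("GAC" * 5, 0)])
        row = usage[(usage["kind"] == "codon") & (usage["name"] == "GAC")].iloc[0]
        assert row["count_c1"] == 5

    def test_amino_counts_conserve_codon_counts(self, rng):
        seqs1 = [("".join(rng.choice(list("ACGT"), size=90)), 0) for _ in range(5)]
        seqs2 = [("".join(rng.choice(list("ACGT"), size=90)), 0) for _ in range(5)]
        usage = codon_amino_usage(seqs1, seqs2)
        codons = usage[usage["kind"] == "codon"]
        aminos = usage[usage["kind"] == "amino_acid"]
        assert codons["count_c1"].sum() == aminos["count_c1"].sum()
        assert codons["count_c2"].sum() == aminos["count_c2"].sum()


class TestNullRecovery:
    def test_no_inhibition_no_exon_count_correlation(self):
        """With the silencer weight set to 0 the exon-count / methylation-
        ratio correlation vanishes (|r| < 0.1)."""
        from boundary_m6a import predictor
        from boundary_m6a.motifs import rac_positions

        fx = simulate.generate_genome_fixture(
            simulate.GeneratorConfig(seed=5, n_genes=300)
        )
        cfg = fx.predictor_config
        null_cfg = predictor.SyntheticPredictorConfig(
            intercept=cfg.intercept, enhancer_weight=cfg.enhancer_weight,
            silencer_weight=0.0,
            window_up=cfg.window_up, window_down=cfg.window_down,
        )
        pred = predictor.SyntheticPredictor(fx.weights, null_cfg)
        ratios, n_exons = [], []
        for g, tx in sorted(fx.transcripts.items()):
            pre = fx.pre_mrna(g)
            prof = pred(pre.sequence, g)
            exonic = [
                p for p in rac_positions(pre.sequence)
                if tx.exon_index_at(int(p)) is not None
            ]
            if exonic:
                _, _, ratio = m6a_rac_ratio(prof.probabilities, exonic)
                ratios.append(ratio)
                n_exons.append(tx.n_exons)
        r, _ = correlate(n_exons, ratios)
        assert abs(r) < 0.1
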