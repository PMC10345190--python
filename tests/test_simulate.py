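"""Synthetic-data generators: determinism, planted structure, companions."""

import numpy as np
import pandas as pd
import pytest

from boundary_m6a import edits
from boundary_m6a.motifs import rac_positions
from boundary_m6a.simulate import (
    GeneratorConfig,
    generate_assay_tables,
    generate_conservation_track,
    generate_genome_fixture,
    generate_halflife_tables,
    generate_ip_coverage,
    neutral_config,
    random_transcript,
)
from boundary_m6a.stats import correlate, rank_sum_test


class TestGenomeFixture:
    def test_seed_determinism_byte_identical(self, tmp_path):
        a = generate_genome_fixture(GeneratorConfig(seed=9, n_genes=8))
        b = generate_genome_fixture(GeneratorConfig(seed=9, n_genes=8))
        assert a.genome == b.genome
        assert a.sites.equals(b.sites) and a.exons.equals(b.exons)
        da, db = tmp_path / "a", tmp_path / "b"
        a.write(da)
        b.write(db)
        for name in ("genome.fa", "annotation.gtf", "truth_sites.tsv"):
            assert (da / name).read_bytes() == (db / name).read_bytes()

    def test_c1_fraction_zero(self):
        fx = generate_genome_fixture(GeneratorConfig(seed=3, n_genes=8, c1_fraction=0.0))
        assert (fx.exons["label"] != "C1").all()
        assert fx.latent_sites().empty

    def test_planted_sites_are_rac(self, small_fixture):
        fx = small_fixture
        for gene_id, grp in fx.sites.groupby("gene_id"):
            seq = fx.pre_mrna(gene_id).sequence
            rac = set(rac_positions(seq))
            for pos in grp["tx_position"]:
                assert pos in rac

    def test_intron_ends_canonical(self, small_fixture):
        fx = small_fixture
        for g in list(sorted(fx.transcripts))[:15]:
            seq = fx.pre_mrna(g).sequence
            for s, e in fx.transcripts[g].intron_blocks_transcript():
                assert seq[s:s + 2] == "GT" and seq[e - 2:e] == "AG"

    def test_background_scrubbed_of_weighted_pentamers(self, small_fixture):
        """Weighted pentamers in the mRNA of a gene without plants beyond its
        own are only the planted ones: spot-check that no weighted pentamer
        spans an exon-exon junction after all-intron deletion."""
        fx = small_fixture
        weighted = fx.weights.enhancers | fx.weights.silencers
        for g in list(sorted(fx.transcripts))[:15]:
            tx = fx.transcripts[g]
            if tx.n_exons == 1:
                continue
            mrna = edits.delete_introns(tx, fx.pre_mrna(g), "all").sequence.sequence
            blocks = tx.exon_blocks_transcript()
            bounds = np.cumsum([e - s for s, e in blocks])[:-1]
            for b in bounds:
                for j in range(max(b - 4, 0), b):
                    assert mrna[j:j + 5] not in weighted

    def test_more_increased_sites_in_c1_than_c2(self, small_fixture, small_records):
        """End-to-end: after all-intron deletion, planted C1 exons carry at
        least twice the increased-site fraction of C2 exons."""
        from boundary_m6a.delta import CAT_INCREASED

        fx = small_fixture
        label = fx.exons.set_index(["gene_id", "exon_index"])["label"]
        frac = {}
        for cl in ("C1", "C2"):
            recs = [
                r for r in small_records
                if label.get((r.gene_id, r.exon_index)) == cl
            ]
            frac[cl] = np.mean([r.category == CAT_INCREASED for r in recs])
        assert frac["C1"] >= 2 * frac["C2"]

    def test_neutral_config_plants_nothing(self):
        fx = generate_genome_fixture(neutral_config(seed=4, n_genes=6))
        weighted = fx.weights.enhancers | fx.weights.silencers
        for g in sorted(fx.transcripts):
            seq = fx.pre_mrna(g).sequence
            assert not any(seq[j:j + 5] in weighted for j in range(len(seq) - 4))

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(exon_len_min=50)
        with pytest.raises(ValueError):
            GeneratorConfig(intron_len_min=100)
        with pytest.raises(ValueError):
            GeneratorConfig(c1_fraction=1.5)


class TestRandomTranscript:
    @pytest.mark.parametrize("seed", range(4))
    def test_structure_consistent(self, seed):
        rng = np.random.default_rng(seed)
        tx, pre = random_transcript(rng)
        assert len(pre) == tx.pre_mrna_length
        blocks = tx.exon_blocks_transcript()
        assert sum(e - s for s, e in blocks) == tx.mrna_length


class TestConservation:
    def test_shift_detected(self):
        track = generate_conservation_track(4000, range(0, 400, 2), shift=1.0, seed=0)
        latent = track[list(range(0, 400, 2))]
        background = track[2000:]
        assert rank_sum_test(latent, background) < 1e-6

    def test_zero_shift_indistinguishable(self):
        track = generate_conservation_track(4000, range(0, 400, 2), shift=0.0, seed=0)
        latent = track[list(range(0, 400, 2))]
        assert rank_sum_test(latent, track[2000:]) > 0.01

    def test_finite(self):
        assert np.isfinite(generate_conservation_track(100, [5], 1.0, 1)).all()


class TestHalfLife:
    def _counts(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "m6a_count": rng.poisson(5, n)}
        )

    def test_beta_positive_negative_correlation(self):
        tbl = generate_halflife_tables(self._counts(), beta_wt=0.15, seed=1)
        r_wt, p_wt = correlate(tbl["m6a_count"], tbl["t12_wt"])
        r_ko, _ = correlate(tbl["m6a_count"], tbl["t12_ko"])
        assert r_wt < 0 and p_wt < 0.01
        assert abs(r_ko) < 0.1

    def test_beta_zero_exchangeable(self):
        tbl = generate_halflife_tables(self._counts(), beta_wt=0.0, seed=2)
        assert rank_sum_test(tbl["t12_wt"], tbl["t12_ko"]) > 0.01

    def test_all_positive(self):
        tbl = generate_halflife_tables(self._counts(100), seed=3)
        assert (tbl["t12_wt"] > 0).all() and (tbl["t12_ko"] > 0).all()


class TestIpCoverage:
    def test_null_fold_one(self):
        ip, inp = generate_ip_coverage(2000, [(100, 160)], 30, fold=1.0, seed=0)
        assert abs(ip.coverage.mean() - inp.coverage.mean()) < 2

    def test_fold_enrichment_at_planted_intervals(self):
        ip, inp = generate_ip_coverage(2000, [(100, 160)], 30, fold=4.0, seed=0)
        assert ip.coverage[100:160].mean() > 3 * inp.coverage[100:160].mean()
        assert abs(ip.coverage[500:].mean() - inp.coverage[500:].mean()) < 2

    def test_library_size_bookkeeping(self):
        ip, inp = generate_ip_coverage(500, [], 10, seed=1)
        assert ip.library_size == ip.coverage.sum()
        assert inp.library_size == inp.coverage.sum()


class TestAssayTables:
    def _levels(self):
        return pd.DataFrame(
            {
                "site_id": ["s1", "s2"],
                "level_containing": [1.0, 1.2],
                "level_deleted": [1.5, 2.0],
            }
        )

    def test_zero_noise_exact_recovery(self):
        select_df, decay_df = generate_assay_tables(
            self._levels(), {"c": 0.1}, ct_noise_sd=0.0, decay_noise_sd=0.0, seed=0
        )
        from boundary_m6a.assays import SelectMeasurement, fit_first_order_decay, select_relative_level

        for construct, col in (("intron_containing", "level_containing"),
                               ("intron_deleted", "level_deleted")):
            grp = select_df[select_df["construct"] == construct]
            controls = grp.loc[grp["is_control"], "ct"].tolist()
            for site_id, expected in zip(self._levels()["site_id"], self._levels()[col]):
                cts = grp.loc[grp["site_id"] == site_id, "ct"].tolist()
                level = select_relative_level(SelectMeasurement(construct, site_id, cts, controls))
                assert level == pytest.approx(expected, rel=1e-12)

        grp = decay_df[decay_df["replicate"] == 0]
        fit = fit_first_order_decay(grp["time_h"], grp["level_pct"])
        assert fit.k == pytest.approx(0.1, abs=1e-12)

    def test_control_sites_carry_no_shift(self):
        select_df, _ = generate_assay_tables(self._levels(), {}, ct_noise_sd=0.0, seed=0)
        ctrl = select_df[select_df["is_control"]]
        assert np.allclose(ctrl["ct"], 25.0)

    def test_decay_normalized_to_100_at_t0(self):
        _, decay_df = generate_assay_tables(self._levels(), {"c": 0.2}, seed=5)
        t0 = decay_df[decay_df["time_h"] == 0.0]
        assert np.allclose(t0["level_pct"], 100.0)

    def test_seeded_noise_recovery_within_tolerance(self):
        _, decay_df = generate_assay_tables(
            self._levels(), {"c": 0.2}, decay_noise_sd=0.02, seed=7
        )
        from boundary_m6a.assays import fit_first_order_decay

        mean_levels = decay_df.groupby("time_h")["level_pct"].mean()
        fit = fit_first_order_decay(mean_levels.index.to_numpy(), mean_levels.to_numpy())
        assert fit.k == pytest.approx(0.2, rel=0.1)
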