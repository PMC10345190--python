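"""End-to-end pipeline stages over the synthetic fixture.

Each stage is a plain function: generate the fixture, score pre-mRNAs,
perform intron-deletion edits and DeltaProbability records, cluster exons,
run the downstream statistics, call IP peaks and quantify the assay tables.
The numbered scripts under ``analysis/`` are thin drivers around these;
tests and the acceptance script call them directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import assays, clustering, delta, edits, motifs, peaks, predictor, simulate, stats


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_stage(config: simulate.GeneratorConfig, outdir: str | Path | None = None):
    fixture = simulate.generate_genome_fixture(config)
    if outdir is not None:
        fixture.write(Path(outdir) / "fixture")
    return fixture


def predict_stage(
    fixture: simulate.GenomeFixture, outdir: str | Path | None = None
) -> dict[str, predictor.MethylationProfile]:
    """Score every gene's full-length pre-mRNA with the synthetic predictor."""
    pred = predictor.SyntheticPredictor(fixture.weights, fixture.predictor_config)
    profiles = {
        g: pred(fixture.pre_mrna(g).sequence, g) for g in sorted(fixture.transcripts)
    }
    if outdir is not None:
        rows = []
        for g, prof in profiles.items():
            pos = np.nonzero(prof.probabilities)[0]
            rows.append(
                pd.DataFrame(
                    {"sequence_id": g, "position": pos,
                     "probability": np.round(prof.probabilities[pos], 6)}
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(
            Path(outdir) / "site_probabilities.tsv", sep="\t", index=False
        )
    return profiles


def delta_stage(
    fixture: simulate.GenomeFixture,
    profiles: dict[str, predictor.MethylationProfile],
    selection: str = "all",
    outdir: str | Path | None = None,
) -> tuple[list[delta.DeltaRecord], pd.DataFrame]:
    """Delete introns (``all`` or ``last``), rescore, and collect per-site
    DeltaRecords; also writes the metagene density around the last exon start
    and the latent-site summary."""
    pred = predictor.SyntheticPredictor(fixture.weights, fixture.predictor_config)
    records: list[delta.DeltaRecord] = []
    profiles_after: dict[str, predictor.MethylationProfile] = {}
    edited_txs = {}
    for g, tx in sorted(fixture.transcripts.items()):
        if tx.n_exons == 1:
            continue
        pre = fixture.pre_mrna(g)
        edited = edits.delete_introns(tx, pre, selection)
        prof_after = pred(edited.sequence.sequence, g)
        profiles_after[g] = prof_after
        edited_txs[g] = edited
        records.extend(
            delta.compute_site_deltas(profiles[g], prof_after, edited, tx, pre.sequence)
        )
    frame = delta.records_to_frame(records)
    if outdir is not None:
        out = Path(outdir)
        frame.to_csv(out / f"delta_records_{selection}.tsv", sep="\t", index=False)
        multi = [g for g in sorted(fixture.transcripts) if fixture.transcripts[g].n_exons > 1]
        meta_before = delta.metagene_density(
            [profiles[g] for g in multi],
            [fixture.transcripts[g] for g in multi],
            anchor="last_exon_start",
        )
        delta.metagene_frame(meta_before).to_csv(
            out / "metagene_last_exon_start_full_length.tsv", sep="\t", index=False
        )
        summary = delta.latent_site_summary(records)
        with open(out / f"latent_summary_{selection}.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return records, frame


def cluster_stage(
    fixture: simulate.GenomeFixture,
    records: list[delta.DeltaRecord],
    exon_role: str = "internal",
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict:
    """Bin DeltaValues for exons of one role, k-means into C1/C2, and score
    recovery against the planted labels."""
    subset = [r for r in records if r.exon_role == exon_role]
    matrix = clustering.bin_delta_values(subset)
    assignment = clustering.kmeans_two_groups(matrix, seed=seed)
    summary = clustering.cluster_summary(matrix, assignment, subset)

    truth = fixture.exons.set_index(["gene_id", "exon_index"])["label"]
    planted, predicted = [], []
    for eid in matrix.exon_ids:
        g, i = eid.rsplit(":", 1)
        label = truth.get((g, int(i)))
        if label in (clustering.C1, clustering.C2):
            planted.append(label)
            predicted.append(assignment.labels[eid])
    ari = (
        float(adjusted_rand_score(planted, predicted)) if len(set(planted)) > 1 else float("nan")
    )
    result = {
        "matrix": matrix,
        "assignment": assignment,
        "summary": summary,
        "ari_vs_planted": ari,
        "n_exons": len(matrix.exon_ids),
    }
    if outdir is not None:
        out = Path(outdir)
        clustering.matrix_frame(matrix).to_csv(
            out / f"delta_matrix_{exon_role}.tsv", sep="\t", index=False
        )
        clustering.assignment_frame(assignment).to_csv(
            out / f"cluster_assignment_{exon_role}.tsv", sep="\t", index=False
        )
    return result


def stats_stage(
    fixture: simulate.GenomeFixture,
    profiles: dict[str, predictor.MethylationProfile],
    records: list[delta.DeltaRecord],
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict:
    """Conservation comparison, m6A/exon-number correlation and half-life
    analyses on the generated companion tables."""
    # conservation: latent vs no-change sites
    tracks = simulate.generate_conservation_tracks(fixture)
    latent_scores, nochange_scores = [], []
    for r in records:
        score = tracks[r.gene_id][r.position]
        if r.category == delta.CAT_INCREASED:
            latent_scores.append(score)
        elif r.category == delta.CAT_NO_CHANGE:
            nochange_scores.append(score)
    conservation = stats.conservation_compare(latent_scores, nochange_scores)

    # per-gene m6A census on the full-length pre-mRNA (exonic RAC only)
    gene_rows = []
    for g, tx in sorted(fixture.transcripts.items()):
        prof = profiles[g]
        pre_seq = fixture.pre_mrna(g).sequence
        exonic = [
            p for p in motifs.rac_positions(pre_seq) if tx.exon_index_at(int(p)) is not None
        ]
        n_m6a, n_rac, ratio = stats.m6a_rac_ratio(prof.probabilities, exonic)
        gene_rows.append(
            {"gene_id": g, "exon_count": tx.n_exons, "m6a_count": n_m6a,
             "rac_count": n_rac, "m6a_rac_ratio": ratio,
             "mrna_length": tx.mrna_length}
        )
    census = pd.DataFrame(gene_rows)
    varying = census[census["rac_count"] > 0]
    r_ratio, p_ratio = stats.correlate(varying["exon_count"], varying["m6a_rac_ratio"])

    halflife = simulate.generate_halflife_tables(
        census, base_h=fixture.config.halflife_base_h,
        beta_wt=fixture.config.halflife_beta_wt,
        beta_ko=fixture.config.halflife_beta_ko,
        noise_sd=fixture.config.halflife_noise_sd,
        seed=fixture.config.seed + 3,
    )
    r_wt, p_wt = stats.correlate(halflife["m6a_count"], halflife["t12_wt"])
    r_ko, p_ko = stats.correlate(halflife["m6a_count"], halflife["t12_ko"])

    # matched-group comparison: few- vs many-exon genes matched on RAC count
    med = halflife["exon_count"].median()
    group_a = halflife[halflife["exon_count"] <= med].reset_index(drop=True)
    group_b = halflife[halflife["exon_count"] > med].reset_index(drop=True)
    pairs = stats.match_groups(group_a, group_b, by="rac_count", seed=seed)
    matched = (
        stats.group_halflife_compare(group_a, group_b, pairs) if len(pairs) else None
    )

    result = {
        "conservation": conservation,
        "gene_census": census,
        "exon_count_vs_ratio": (r_ratio, p_ratio),
        "halflife": halflife,
        "corr_m6a_t12_wt": (r_wt, p_wt),
        "corr_m6a_t12_ko": (r_ko, p_ko),
        "matched_compare": matched,
    }
    if outdir is not None:
        out = Path(outdir)
        census.to_csv(out / "gene_m6a_census.tsv", sep="\t", index=False)
        halflife.to_csv(out / "halflife_table.tsv", sep="\t", index=False)
        summary = {
            "conservation_p": conservation["p_value"],
            "exon_count_vs_ratio_r": r_ratio,
            "exon_count_vs_ratio_p": p_ratio,
            "m6a_vs_t12_wt_r": r_wt, "m6a_vs_t12_wt_p": p_wt,
            "m6a_vs_t12_ko_r": r_ko, "m6a_vs_t12_ko_p": p_ko,
        }
        if matched is not None:
            for name, m in matched["metrics"].items():
                summary[f"matched_{name}_p"] = m["p_value"]
        with open(out / "stats_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return result


def codon_stage(
    fixture: simulate.GenomeFixture,
    assignment: clustering.ClusterAssignment,
    exon_role: str = "internal",
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Codon/amino-acid usage of C1 vs C2 exons (frame 0 by fixture
    convention: generated CDS starts at the exon start)."""
    groups: dict[str, list[tuple[str, int]]] = {clustering.C1: [], clustering.C2: []}
    exon_info = fixture.exons.set_index(["gene_id", "exon_index"])
    for eid, label in assignment.labels.items():
        g, i = eid.rsplit(":", 1)
        row = exon_info.loc[(g, int(i))]
        seq = fixture.pre_mrna(g).sequence[row["tx_start"]:row["tx_end"]]
        groups[label].append((seq, 0))
    usage = stats.codon_amino_usage(groups[clustering.C1], groups[clustering.C2])
    if outdir is not None:
        usage.to_csv(Path(outdir) / f"codon_usage_{exon_role}.tsv", sep="\t", index=False)
    return usage


def peaks_stage(
    fixture: simulate.GenomeFixture, outdir: str | Path | None = None
) -> dict:
    """Generate IP/input coverage over the fixture genome, run the window
    Fisher scan per chromosome, call peaks and census short exons."""
    coverage = simulate.generate_fixture_ip_coverage(fixture)
    planted = simulate.fixture_methylated_intervals(fixture)
    all_windows, all_peaks, bed_frames = {}, {}, []
    for chrom, (ip, input_) in sorted(coverage.items()):
        tests = peaks.scan_windows(ip, input_)
        peaks.attach_fdr(tests)
        called = peaks.call_peaks(tests)
        all_windows[chrom] = tests
        all_peaks[chrom] = called
        bed_frames.append(peaks.peaks_bed(called, chrom))

    # per-chromosome interval Jaccard of called vs planted regions
    jaccards = {}
    for chrom, called in all_peaks.items():
        jaccards[chrom] = interval_jaccard(
            [(p.start, p.end) for p in called], planted[chrom]
        )

    # short internal exon census (genomic coordinates, per chromosome)
    census = {"with_m6a": 0, "without_m6a": 0, "with_rac": 0, "without_rac": 0}
    for chrom in sorted(fixture.genome):
        exon_ivs, exon_seqs = [], []
        for g, tx in fixture.transcripts.items():
            if tx.chrom != chrom:
                continue
            roles = tx.exon_roles()
            for exon, role in zip(tx.exons, roles):
                if role == "internal":
                    exon_ivs.append((exon.start, exon.end))
                    exon_seqs.append(fixture.genome[chrom][exon.start:exon.end])
        c = peaks.exon_methylation_census(
            all_peaks[chrom], exon_ivs, exon_seqs, max_len=200
        )
        for k in census:
            census[k] += c[k]

    result = {
        "windows": all_windows,
        "peaks": all_peaks,
        "jaccard": jaccards,
        "census": census,
    }
    if outdir is not None:
        out = Path(outdir)
        pd.concat(
            [peaks.windows_frame(t).assign(chrom=c) for c, t in all_windows.items()],
            ignore_index=True,
        ).to_csv(out / "ip_windows.tsv", sep="\t", index=False)
        pd.concat(bed_frames, ignore_index=True).to_csv(
            out / "ip_peaks.bed", sep="\t", index=False, header=False
        )
        with open(out / "exon_census.json", "w") as fh:
            json.dump({**census, "jaccard": jaccards}, fh, indent=2, default=float)
    return result


def assay_stage(
    fixture: simulate.GenomeFixture,
    records: list[delta.DeltaRecord],
    n_sites: int = 19,
    outdir: str | Path | None = None,
) -> dict:
    """SELECT + decay assay emulation on the strongest latent sites.

    Planted relative levels mirror the minigene experiment: the
    intron-containing construct carries the pre-edit methylation level, the
    intron-deleted construct the post-edit level (scaled to a unit baseline).
    """
    inc = sorted(
        (r for r in records if r.category == delta.CAT_INCREASED),
        key=lambda r: -r.delta,
    )[:n_sites]
    if not inc:
        raise ValueError("no latent sites available for the assay stage")
    # planted relative level = 1 + methylation probability: an unmethylated
    # site amplifies like the non-RAC controls (level 1); m6A delays
    # amplification in proportion to the methylated fraction
    site_levels = pd.DataFrame(
        {
            "site_id": [f"{r.gene_id}:{r.position}" for r in inc],
            "level_containing": [1.0 + r.p_before for r in inc],
            "level_deleted": [1.0 + r.p_after for r in inc],
        }
    )
    select_df, decay_df = simulate.generate_assay_tables(
        site_levels,
        decay_constants={
            "intron_containing": np.log(2) / 6.0,   # T1/2 6 h: fewer m6A, stabler
            "intron_deleted": np.log(2) / 3.0,      # T1/2 3 h: methylated, less stable
        },
        ct_noise_sd=fixture.config.ct_noise_sd,
        decay_noise_sd=fixture.config.decay_noise_sd,
        seed=fixture.config.seed + 4,
    )

    levels = {}
    for construct, grp in select_df.groupby("construct"):
        controls = grp.loc[grp["is_control"], "ct"].to_numpy()
        per_site = {}
        for site_id, sgrp in grp[~grp["is_control"]].groupby("site_id"):
            m = assays.SelectMeasurement(construct, site_id, sgrp["ct"].tolist(), controls.tolist())
            per_site[site_id] = assays.select_relative_level(m)
        levels[construct] = per_site
    site_ids = site_levels["site_id"].tolist()
    changes = assays.relative_level_change(
        [levels["intron_deleted"][s] for s in site_ids],
        [levels["intron_containing"][s] for s in site_ids],
    )
    t_stat, p_one_sided = assays.one_sample_t(changes, mu=0.0, alternative="greater")

    fits = {}
    for construct, grp in decay_df.groupby("construct"):
        mean_levels = grp.groupby("time_h")["level_pct"].mean()
        fits[construct] = assays.fit_first_order_decay(
            mean_levels.index.to_numpy(), mean_levels.to_numpy()
        )

    result = {
        "select": select_df,
        "decay": decay_df,
        "levels": levels,
        "changes": changes,
        "mean_change": float(np.mean(changes)),
        "t": t_stat,
        "p": p_one_sided,
        "decay_fits": fits,
    }
    if outdir is not None:
        out = Path(outdir)
        select_df.to_csv(out / "select_ct.tsv", sep="\t", index=False)
        decay_df.to_csv(out / "decay_timecourse.tsv", sep="\t", index=False)
        with open(out / "assay_summary.json", "w") as fh:
            json.dump(
                {
                    "mean_relative_level_change": float(np.mean(changes)),
                    "t": t_stat, "p_one_sided": p_one_sided,
                    "half_life_h": {c: f.half_life_h for c, f in fits.items()},
                },
                fh, indent=2, default=float,
            )
    return result


def interval_jaccard(called, truth) -> float:
    """Jaccard index of two interval sets (union of base coverage)."""
    def _cover(ivs):
        s = set()
        for a, b in ivs:
            s.update(range(a, b))
        return s

    ca, tr = _cover(called), _cover(truth)
    if not ca and not tr:
        return float("nan")
    return len(ca & tr) / len(ca | tr)


def run_all(seed: int = 0, outdir: str | Path | None = None, n_genes: int = 300) -> dict:
    """Full pipeline: simulate -> predict -> edit -> delta -> cluster ->
    stats -> peaks -> assays; returns the per-stage results."""
    config = simulate.GeneratorConfig(seed=seed, n_genes=n_genes)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
    fixture = simulate_stage(config, outdir)
    profiles = predict_stage(fixture, outdir)
    records, frame = delta_stage(fixture, profiles, "all", outdir)
    clusters = cluster_stage(fixture, records, "internal", seed=seed, outdir=outdir)
    usage = codon_stage(fixture, clusters["assignment"], "internal", outdir)
    stat_res = stats_stage(fixture, profiles, records, seed=seed, outdir=outdir)
    peak_res = peaks_stage(fixture, outdir)
    assay_res = assay_stage(fixture, records, outdir=outdir)
    return {
        "fixture": fixture,
        "profiles": profiles,
        "records": records,
        "delta_frame": frame,
        "clusters": clusters,
        "codon_usage": usage,
        "stats": stat_res,
        "peaks": peak_res,
        "assays": assay_res,
    }
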