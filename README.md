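# boundary-m6a

Analysis pipeline for studying how exon–intron boundaries inhibit
N6-methyladenosine (m6A) deposition on pre-mRNA, by *in-silico intron
mutagenesis*: delete or truncate introns from a gene model, rescore the
edited sequence with a per-nucleotide methylation predictor, and quantify
the probability change (ΔProbability) at every RAC site (R = A/G; the
methylated base is the central A).

The package is written for epitranscriptomics researchers who want to run —
and stress-test — the full analysis chain without access to a trained deep
methylation model or raw sequencing data. Everything runs on a seeded
synthetic world whose planted ground truth makes each stage falsifiable.

## What it computes

Given a gene annotation (GTF), a genome (FASTA) and a methylation predictor
(a pluggable contract; a transparent synthetic predictor ships with the
package), the pipeline:

1. selects the longest transcript per gene and extracts pre-mRNA/mRNA
   sequences with strand-aware 5'→3' coordinates (`gene_models`);
2. performs sequence surgeries with exact coordinate liftover: intron
   deletion, truncation to mini-introns (keep 100 nt per end), and
   splice-site point mutation GT→CA / AG→TC with a cryptic-site guard
   (`edits`);
3. scores RAC sites before and after the edit and categorizes each site by
   ΔProbability: increased (> 0.1), decreased (< −0.1), no change
   (|Δ| ≤ 0.1) (`predictor`, `delta`);
4. bins the first 200 nt of each exon into 40 × 5 nt intervals of signed-max
   ΔValues and k-means-clusters exons into C1 (strong boundary inhibition)
   vs C2 (`clustering`);
5. runs the downstream comparisons: positional enhancer/silencer pentamer
   frequencies, pentamer enrichment volcanoes (Fisher exact), conservation
   of latent vs unchanged sites (Wilcoxon), m6A/RAC-ratio vs exon-count and
   half-life correlations (Pearson + t), codon usage of C1 vs C2 exons
   (`motifs`, `stats`);
6. calls m6A-IP peaks from per-base coverage: 20-nt window Fisher tests
   against the input library, Benjamini–Hochberg FDR, concatenation of
   significant windows (fold > 2, FDR < 0.05) into ≥ 40 nt peaks, FPKM ≥ 1
   expression gating (`peaks`);
7. quantifies SELECT qPCR tables (relative m6A level `2^ΔCt` against two
   non-RAC control sites) and first-order decay fits
   (T½ = ln 2 / k) (`assays`).

The synthetic predictor scores each RAC site as
`p = logistic(β0 + βe·E − βs·S)` where E and S count enhancer and silencer
pentamers inside a two-sided ±100 nt window. The synthetic genome plants
silencers in intron terminal segments, so boundary inhibition *emerges*:
deleting an intron swaps silencers out of the window and junction-proximal
probabilities rise. Nothing tells the pipeline where the inhibition is — it
has to find the ~100 nt localization itself.

## Worked example

```bash
python analysis/01_simulate.py --seed 0 --n-genes 120 --out results
python analysis/03_delta.py    --seed 0 --n-genes 120 --out results
python analysis/04_cluster.py  --seed 0 --n-genes 120 --out results
```

prints (numbers from this exact invocation):

```
generated 120 genes on 2 chromosomes (0.65 Mb)
exons: 724 total, 163 C1 / 441 C2 labelled
planted sites: {'latent': 489, 'first_exon_dense': 141, 'constitutive': 116}

[all-intron deletion] 5224 exonic RAC sites: 30.5% increased, 0.0% decreased
  increased sites within 100 nt of the exon start: 67.6%
[last-intron deletion] 5224 exonic RAC sites: 5.8% increased, 0.0% decreased

[internal exons, all-intron deletion] 481 exons clustered; ARI vs planted labels = 1.000
  latent-site fraction: C1 0.77, C2 0.15
```

Reading: deleting every intron flips 30.5% of exonic RAC sites to
"increased" (latent sites, repressed by the boundary in the full-length
gene); deleting only the last intron flips far fewer, and only near that
junction. k-means on the binned ΔValues recovers the planted C1/C2 exon
labels perfectly, and C1 exons carry ~5× the latent-site fraction of C2 —
the heterogeneity structure the clustering is meant to expose.

The remaining drivers (`02_predict`, `05_motifs`, `06_stats`, `07_peaks`,
`08_assays`) cover predictor scoring, cis-element enrichment, conservation/
half-life/codon statistics, IP peak calling and assay quantification; each
writes its tables under `results/` and prints a short summary.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on the default 300-gene world
(simulate → predict → edit → delta → cluster → stats → peaks → assays,
about a minute on one CPU), writes every documented table under
`results/pipeline/`, and writes the results manifest to `--out`.

## Layout

```
src/boundary_m6a/   library: gene_models, edits, predictor, delta, motifs,
                    clustering, stats, peaks, assays, simulate, pipeline
analysis/           numbered narrative drivers (01_simulate … 08_assays)
scripts/            acceptance.py
tests/              pytest suite incl. test_acceptance.py
docs/methods.md     model assumptions, parameter rationale, limitations
```
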