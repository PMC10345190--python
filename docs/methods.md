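# Methods

## The question and the modeling strategy

m6A is deposited co-transcriptionally on pre-mRNA at RAC consensus sites,
yet methylation is depleted near exon–intron boundaries. The analysis
implemented here probes that inhibition by *in-silico mutagenesis*: edit the
gene model (delete introns, truncate them to mini-introns, kill splice
sites), rescore the edited sequence with a per-nucleotide methylation
predictor, and ask which RAC sites gain probability once the boundary is
gone. A site whose probability rises by more than 0.1 is called *latent*
(boundary-repressed); drops below −0.1 are *decreased*; the closed interval
[−0.1, 0.1] is *no change*. A site is *called* methylated when its
probability exceeds 0.05. Both cutoffs are strict inequalities.

The deep methylation model used in the original genome-wide analyses enters
only through a contract (`sequence → per-nucleotide probability, nonzero
only at RAC A positions`). External score tables can be adapted through
`predictor.load_external_scores`, which masks off-RAC rows. Everything
downstream of the contract — editing, liftover, ΔProbability, clustering,
statistics, peak calling — is exercised against a synthetic predictor whose
mechanism is fully transparent, so every stage has checkable ground truth.

## The synthetic predictor

At each RAC site the methylation log-odds are linear in local cis-element
content:

    p(site) = logistic(β0 + βe·E − βs·S)

E and S count *enhancer* and *silencer* pentamers lying fully inside the
two-sided window [site − W_up, site + W_down]; pentamers containing N are
neutral, and N never matches RAC. Defaults:

| parameter | default | rationale |
|---|---|---|
| β0 (intercept) | −3.2 | background RAC probability 0.039, just below the 0.05 calling threshold, so being "methylated" requires enhancer support and being silenced is visible |
| βe (enhancer weight) | 0.3 | a typical planted site (E ≈ 4–6) reaches p ≈ 0.2–0.4 |
| βs (silencer weight) | 0.6 | 2 silencers in the window suppress a site below threshold |
| W_up, W_down | 100 nt each | functional elements concentrate within ~50 nt downstream of a site while the boundary inhibition reaches ~100 nt; a two-sided 100-nt window lets both behaviors operate and sets the inhibition reach |

The enhancer/silencer sets are the top/bottom 50 of 1024 pentamers by a
seeded random weight ranking — a stand-in for a predictor-derived ranking;
a real ranking can be supplied as a TSV (`pentamer, weight, class`).

Inhibition is **not** a distance rule. It emerges because intron terminal
segments are silencer-rich: before the edit a junction-proximal site sees
those silencers inside its window; after intron deletion the window spans
the neighboring exon instead. Sites farther than the window reach from every
junction see identical windows before and after, so their Δ is exactly 0 —
which is both the mechanism's signature and a sharp test of the liftover.

## The stated synthetic world

`simulate.GeneratorConfig` defaults (one seed → byte-identical output):

- 300 genes on 2 chromosomes (~1.6 Mb), exon count 1 + Poisson(5),
  exon lengths LogNormal(ln 180, 0.35) clipped to [90, 600] nt, intron
  lengths LogNormal(ln 700, 0.30) clipped to [250, 2000] nt, both strands.
- Introns are canonical (GT…AG) and carry 11 silencer pentamers in each
  terminal 100 nt.
- 30% of exons draw a *dense start*: RAC sites at offsets 10/33/56 with two
  enhancer pentamers planted downstream of each. Dense internal/last exons
  are labelled C1 (their planted sites are the latent truth); non-dense
  internal/last exons are C2. First/single exons draw dense starts at the
  same rate but stay unlabelled — this keeps per-exon composition
  independent of exon count, so the exon-count correlation below cannot be
  a planting artifact.
- Exons of ≥ 250 nt carry one *constitutive* mid-exon site (RAC plus three
  enhancers, > 100 nt from any junction): methylated regardless of splicing,
  the source of between-gene methylation differences.
- Exons are additionally sprinkled with ~0.7 enhancers per 100 nt (exonic
  sequence is enhancer-enriched relative to introns).
- Background sequence is *scrubbed*: every accidental enhancer/silencer
  pentamer outside a planted footprint is mutated away, iterating to a
  fixpoint; the same clean-up removes RAC sites whose purine would be an
  intron's trailing G (they would vanish on deletion, confounding Δ with
  context loss) and weighted pentamers that would span any exon–exon
  junction of an intron-deleted sequence. After clean-up, every E/S count
  the predictor ever sees traces to a deliberate plant — with planting rates
  at zero, all deltas are exactly 0, not approximately.

Companion generators (all parameters in the config):

- **Conservation**: N(0,1) per base, +1.0 at planted latent sites.
- **Half-life**: T½(WT) = 8 h · exp(−0.15 · m6A count) · LogNormal(0, 0.25);
  T½(KO) uses β = 0 (methylation dependence removed).
- **IP coverage**: per-base Poisson(30) input; IP Poisson(30·4) over 60-nt
  intervals centred on constitutive sites and snapped to the 20-nt window
  grid (grid alignment avoids partial-window edge dilution and makes the
  planted/called comparison exact), Poisson(30) elsewhere.
- **Assays**: site Ct = 25 + log2(level) + N(0, 0.15), level = 1 + p
  (unmethylated sites amplify like the two non-RAC controls); decay series
  100·exp(−kt) at t = 0/3/6/9 h with 2% multiplicative noise, renormalized
  to 100% at t = 0.

What the generator does **not** emulate: realistic base composition
(isochores, repeats, codon bias beyond what planting induces), alternative
isoforms, read-level noise (coverage is consumed as bedGraph, alignment is
upstream of scope), branch points or spliceosome kinetics. A green test
therefore establishes that the *analysis machinery* recovers planted
structure — not that the effect exists in any real genome.

## Analysis conventions and numerical choices

- Coordinates are 0-based half-open internally; the GTF reader converts from
  1-based closed. One transcript per gene: maximal summed exon length, ties
  broken by lexicographically smallest transcript id.
- "m6A density" in metagene profiles is the arithmetic mean probability per
  offset (the called-site fraction is available as an alternative);
  unsmoothed by default.
- ΔValue binning takes the *signed* maximum ΔProbability per 5-nt interval
  (the analysis targets increases; an absolute-max flag exists); empty
  intervals are 0, keeping the fixed 40-column geometry.
- k-means: k = 2, squared Euclidean on raw (unstandardized) ΔValues, best of
  10 restarts, seeded; C1 is the cluster with the larger grand-mean ΔValue.
  All-identical rows are flagged degenerate and assigned C2.
- Fisher tests are exact; odds ratios get a Haldane–Anscombe +0.5 correction
  only when a cell is zero, and only for display — p-values always come from
  the uncorrected table. Wilcoxon rank-sum is exact for tie-free samples
  with both n ≤ 25, otherwise the tie-corrected normal approximation.
- Splice-site mutation mutates the literal terminal dinucleotides when an
  intron is non-canonical (with a warning), runs exactly one cryptic-
  mutation round plus one verification pass (configurable), and scans the
  window from the upstream exon start to the downstream exon end.
- The cryptic-site guard treats its predictor as a black box; any site with
  probability > 0.1 surviving verification rejects the gene.
- IP window tests use the 2×2 table [window counts vs library remainder] for
  IP and input; windows tile the genome without overlap (step = width, an
  overlapping step is available). A window with zero reads in both tracks
  has p = 1; zero input with nonzero IP adds a 1-read pseudocount to both
  window sums for the enrichment fold only. BH FDR is an own step-up
  implementation (validated against brute force and statsmodels).
- Decay fits are OLS on ln(level) vs time — identical to nonlinear LSQ on
  noise-free data, deterministic and closed-form; k ≤ 0 is flagged
  non-decaying. SELECT direction: higher Ct ⇒ more m6A (2^+ΔCt), flippable.
- Degenerate synonymous positions are computed from the standard genetic
  code (any position where ≥ 1 single-base substitution is synonymous) —
  broader than "third positions only", flagged as such.
- Matched-group comparisons match exactly on RAC count, or by nearest value
  within a 10% caliper for cDNA length, greedily without replacement in
  seeded random order. ΔT½ is reported as KO − WT.

## Known limitations

- The synthetic predictor is linear in pentamer counts; it cannot express
  saturation or cooperative effects a trained model would learn.
- Latent-site localization is inherited from the window reach (sites beyond
  W from every junction cannot change), so the "≥ 80% within 100 nt"
  property tests the machinery end-to-end but is structurally guaranteed in
  this world; the informative part is that the *fractions and clusters*
  match the planted truth.
- Exact-RAC-count matching yields few pairs when the groups' RAC
  distributions barely overlap (they scale with exon count); the caliper
  mode trades exactness for coverage.
- Fisher window tests over a whole genome are exact but slow (~1 ms per
  distinct count pair; repeated tables are cached).
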