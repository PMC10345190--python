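"""Seeded synthetic-data generators for the full pipeline.

The genome fixture is a *stated world* with the statistical structure the
boundary-inhibition analyses assume:

- multi-exon genes on both strands with realistic exon/intron lengths;
- intron terminal segments planted with m6A-silencer pentamers;
- a subpopulation of "C1-like" internal/last exons whose first ~60 nt carry
  dense RAC sites with enhancer pentamers planted just downstream;
- constitutively methylated mid-exon sites (RAC + enhancers, > 100 nt from
  any junction) so transcripts differ in methylation level;
- background sequence *scrubbed* of accidental enhancer/silencer pentamers,
  so every E/S count the predictor sees traces back to a deliberate plant.

Boundary inhibition is therefore emergent, not hard-coded: deleting an
intron swaps its silencer-rich ends out of the predictor's two-sided window,
raising the probability of junction-proximal exonic sites only.  Companion
generators emit conservation tracks, half-life tables, IP/input coverage and
SELECT/decay assay tables with planted ground truth.

All generators are pure functions of (config, seed): one seed, byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .edits import write_fasta
from .gene_models import (
    GenomicInterval,
    SequenceRecord,
    TranscriptModel,
    pre_mrna_sequence,
    write_gtf,
)
from .peaks import CoverageTrack
from .predictor import PentamerWeightTable, SyntheticPredictorConfig

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GeneratorConfig:
    """Parameters of the stated synthetic world (see docs for rationale)."""

    seed: int = 0
    n_genes: int = 300
    mean_exons: float = 6.0                 # exon count ~ 1 + Poisson(mean - 1)
    exon_len_log_mean: float = math.log(180.0)
    exon_len_log_sd: float = 0.35
    exon_len_min: int = 90
    exon_len_max: int = 600
    intron_len_log_mean: float = math.log(700.0)
    intron_len_log_sd: float = 0.30
    intron_len_min: int = 250
    intron_len_max: int = 2000
    c1_fraction: float = 0.30               # of internal + last exons
    c1_site_offsets: tuple[int, ...] = (10, 33, 56)
    enhancers_per_site: int = 2             # planted downstream of each C1 site
    silencers_per_intron_end: int = 12      # within each terminal 100 nt
    silencer_end_nt: int = 100
    constitutive_min_exon_len: int = 250
    constitutive_site_prob: float = 1.0     # per eligible exon
    enhancers_per_constitutive: int = 3
    exon_enhancer_per_100nt: float = 0.7    # random exonic enhancer sprinkling
    n_chromosomes: int = 2
    intergenic_min: int = 300
    intergenic_max: int = 800
    # companion-table defaults
    halflife_base_h: float = 8.0
    halflife_beta_wt: float = 0.15
    halflife_beta_ko: float = 0.0
    halflife_noise_sd: float = 0.25         # sd of log-normal noise
    conservation_shift: float = 1.0
    ip_background_rate: float = 30.0        # per-base Poisson rate
    ip_peak_fold: float = 4.0
    ip_peak_len: int = 60                   # snapped to the 20-nt window grid
    ct_base: float = 25.0
    ct_noise_sd: float = 0.15
    decay_noise_sd: float = 0.02            # 2% multiplicative

    def __post_init__(self) -> None:
        if not 0 <= self.c1_fraction <= 1:
            raise ValueError("c1_fraction must lie in [0,1]")
        for name in ("enhancers_per_site", "silencers_per_intron_end"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.exon_len_min < 90:
            raise ValueError("exon_len_min < 90 cannot host the C1 plant layout")
        if self.intron_len_min < 2 * self.silencer_end_nt + 10:
            raise ValueError("introns too short for disjoint terminal plants")


@dataclass
class GenomeFixture:
    """A generated genome plus its planted ground truth."""

    config: GeneratorConfig
    weights: PentamerWeightTable
    predictor_config: SyntheticPredictorConfig
    genome: dict[str, str]
    transcripts: dict[str, TranscriptModel]
    genes: pd.DataFrame          # gene_id, chrom, strand, n_exons, start, end
    exons: pd.DataFrame          # gene_id, exon_index, role, label, tx_start, tx_end, length
    sites: pd.DataFrame          # gene_id, exon_index, tx_position, dist_to_exon_start, kind

    def pre_mrna(self, gene_id: str) -> SequenceRecord:
        return pre_mrna_sequence(self.transcripts[gene_id], self.genome)

    def latent_sites(self, gene_id: str | None = None) -> pd.DataFrame:
        df = self.sites[self.sites["kind"] == "latent"]
        if gene_id is not None:
            df = df[df["gene_id"] == gene_id]
        return df

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(
            (SequenceRecord(c, s) for c, s in self.genome.items()),
            str(out / "genome.fa"),
        )
        write_gtf(
            [self.transcripts[g] for g in sorted(self.transcripts)],
            str(out / "annotation.gtf"),
        )
        self.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.exons.to_csv(out / "truth_exons.tsv", sep="\t", index=False)
        self.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        self.weights.to_tsv(str(out / "pentamer_weights.tsv"))


# ---------------------------------------------------------------------------
# sequence-level helpers (code space: A=0 C=1 G=2 T=3)
# ---------------------------------------------------------------------------

def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(s: str) -> np.ndarray:
    lookup = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lookup[ord(b)] = i
    return lookup[np.frombuffer(s.encode(), dtype=np.uint8)]


def _pentamer_codes_from_codes(codes: np.ndarray) -> np.ndarray:
    n = max(len(codes) - 4, 0)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for k in range(5):
        out = out * 4 + codes[k:k + n].astype(np.int64)
    return out


def _motif_code(motif: str) -> int:
    code = 0
    for b in motif:
        code = code * 4 + "ACGT".index(b)
    return code


def _plant(arr: np.ndarray, fp: np.ndarray, pos: int, motif: str) -> None:
    arr[pos:pos + len(motif)] = _str_to_codes(motif)
    fp[pos:pos + len(motif)] = True


def _scrub_weighted(
    arr: np.ndarray, fp: np.ndarray, weighted_codes: np.ndarray, rng: np.random.Generator,
    max_passes: int = 30,
) -> None:
    """Mutate background bases until no enhancer/silencer pentamer survives
    outside planted footprints.

    Fast passes break each weighted window by mutating one free (non-
    footprint) base at random; windows wedged between plants, where few free
    bases serve several overlapping constraints, fall back to an exhaustive
    local search over the free-base assignments.  Fully-footprinted windows
    are the plants themselves and stay.
    """
    n = len(arr)
    if n < 5:
        return
    wset = frozenset(int(c) for c in weighted_codes)
    for pass_no in range(max_passes):
        pcodes = _pentamer_codes_from_codes(arr)
        bad = np.nonzero(np.isin(pcodes, weighted_codes))[0]
        if len(bad) == 0:
            return
        fp_cum = np.concatenate([[0], np.cumsum(fp.astype(np.int64))])
        n_fp = fp_cum[bad + 5] - fp_cum[bad]
        todo = bad[n_fp < 5]
        if len(todo) == 0:
            return
        if pass_no < 8:
            last = -10
            for j in todo:
                if j < last + 5:      # overlaps a window already broken this pass
                    continue
                free = [k for k in range(j, j + 5) if not fp[k]]
                if not free:
                    continue
                pos = free[int(rng.integers(len(free)))]
                arr[pos] = (arr[pos] + rng.integers(1, 4)) % 4
                last = j
        else:
            for j in todo:
                _repair_window(arr, fp, wset, int(j), rng)
    pcodes = _pentamer_codes_from_codes(arr)
    bad = np.nonzero(np.isin(pcodes, weighted_codes))[0]
    fp_cum = np.concatenate([[0], np.cumsum(fp.astype(np.int64))])
    if (fp_cum[bad + 5] - fp_cum[bad] < 5).any():
        raise RuntimeError("weighted-pentamer scrub did not converge")


def _fix_junction_pentamers(
    arr: np.ndarray,
    fp: np.ndarray,
    weighted_codes: np.ndarray,
    junctions: list[tuple[int, int]],
    rng: np.random.Generator,
) -> bool:
    """Break weighted pentamers that would span an exon-exon junction after
    intron deletion.

    Each junction is (exon_end, next_exon_start) in pre-mRNA coordinates; the
    virtual 8-mer is the last 4 exon bases joined to the next exon's first 4.
    Mutates free bases among those 8 until none of the four junction-spanning
    pentamer windows is weighted.  Returns True when anything was mutated.
    """
    wset = frozenset(int(c) for c in weighted_codes)
    changed = False
    for left_end, right_start in junctions:
        positions = list(range(left_end - 4, left_end)) + list(
            range(right_start, right_start + 4)
        )
        for _ in range(40):
            octamer = arr[positions]
            bad = [
                k for k in range(4)
                if _codes_weighted(octamer[k:k + 5], wset)
            ]
            if not bad:
                break
            k = bad[int(rng.integers(len(bad)))]
            free = [i for i in range(k, k + 5) if not fp[positions[i]]]
            if not free:
                break
            i = free[int(rng.integers(len(free)))]
            arr[positions[i]] = (arr[positions[i]] + rng.integers(1, 4)) % 4
            changed = True
        else:
            raise RuntimeError("junction pentamer fix did not converge")
    return changed


def _codes_weighted(codes: np.ndarray, wset: frozenset) -> bool:
    code = 0
    for c in codes:
        code = code * 4 + int(c)
    return code in wset


def _window_weighted(arr: np.ndarray, wset: frozenset, start: int) -> bool:
    code = 0
    for k in range(start, start + 5):
        code = code * 4 + int(arr[k])
    return code in wset


def _repair_window(
    arr: np.ndarray, fp: np.ndarray, wset: frozenset, j: int, rng: np.random.Generator
) -> None:
    """Exhaustively search assignments of the free bases of window j for one
    that leaves every overlapping window unweighted; keep the best found."""
    from itertools import product as _product

    if not _window_weighted(arr, wset, j):
        return
    if not any(not fp[k] for k in range(j, j + 5)):
        return
    # vary all free bases near the window (a plant-gap base just outside the
    # window can be essential to a jointly clean assignment), capped at 6
    free = [k for k in range(max(j - 4, 0), min(j + 9, len(arr))) if not fp[k]]
    free.sort(key=lambda k: (abs(k - (j + 2)), k))
    free = sorted(free[:6])
    lo = max(min(free) - 4, 0)
    hi = min(max(free), len(arr) - 5)
    # planted (fully-footprinted) windows are legitimately weighted; skip them
    affected = [s for s in range(lo, hi + 1) if not fp[s:s + 5].all()]
    original = arr[free].copy()
    best = None
    best_bad = None
    assignments = list(_product(range(4), repeat=len(free)))
    rng.shuffle(assignments)
    for assign in assignments:
        arr[free] = assign
        n_bad = sum(_window_weighted(arr, wset, s) for s in affected)
        if n_bad == 0:
            return
        if best_bad is None or n_bad < best_bad:
            best_bad = n_bad
            best = assign
    arr[free] = best if best is not None else original


# ---------------------------------------------------------------------------
# the genome fixture
# ---------------------------------------------------------------------------

def generate_genome_fixture(config: GeneratorConfig | None = None) -> GenomeFixture:
    """Generate the genome, annotation and planted truth tables."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    weights = PentamerWeightTable.generate(int(rng.integers(2**31)))
    enh_list = sorted(weights.enhancers)
    sil_list = sorted(weights.silencers)
    weighted_codes = np.array(
        sorted(_motif_code(m) for m in (*enh_list, *sil_list)), dtype=np.int64
    )

    gene_rows, exon_rows, site_rows = [], [], []
    gene_seqs: list[tuple[str, np.ndarray, list[int], list[int]]] = []

    for gi in range(cfg.n_genes):
        gene_id = f"g{gi:04d}"
        n_ex = 1 + int(rng.poisson(max(cfg.mean_exons - 1, 0)))
        exon_lens = np.clip(
            np.round(rng.lognormal(cfg.exon_len_log_mean, cfg.exon_len_log_sd, n_ex)),
            cfg.exon_len_min, cfg.exon_len_max,
        ).astype(int)
        intron_lens = np.clip(
            np.round(rng.lognormal(cfg.intron_len_log_mean, cfg.intron_len_log_sd, max(n_ex - 1, 0))),
            cfg.intron_len_min, cfg.intron_len_max,
        ).astype(int)

        total = int(exon_lens.sum() + intron_lens.sum())
        arr = rng.integers(0, 4, total, dtype=np.int8)
        fp = np.zeros(total, dtype=bool)

        # segment offsets in transcript (pre-mRNA) coordinates
        exon_starts, intron_starts = [], []
        pos = 0
        for i in range(n_ex):
            exon_starts.append(pos)
            pos += int(exon_lens[i])
            if i < n_ex - 1:
                intron_starts.append(pos)
                pos += int(intron_lens[i])

        # introns: canonical GT..AG ends plus silencer plants in the terminal ends
        for i, s in enumerate(intron_starts):
            L = int(intron_lens[i])
            _plant(arr, fp, s, "GT")
            _plant(arr, fp, s + L - 2, "AG")
            for r in _silencer_offsets(cfg):
                _plant(arr, fp, s + r, sil_list[int(rng.integers(len(sil_list)))])
                _plant(arr, fp, s + L - cfg.silencer_end_nt + r,
                       sil_list[int(rng.integers(len(sil_list)))])

        # every exon draws its RAC/enhancer-dense start with equal probability
        # so that per-exon composition does not depend on exon count; only
        # internal/last dense exons carry the C1 truth label (their sites are
        # the boundary-repressed, latent ones)
        roles = _roles(n_ex)
        labels = []
        dense = []
        for i in range(n_ex):
            eligible = roles[i] in ("internal", "last")
            is_dense = rng.random() < cfg.c1_fraction
            dense.append(is_dense)
            if eligible:
                labels.append("C1" if is_dense else "C2")
            else:
                labels.append("none")

        for i in range(n_ex):
            es, L = exon_starts[i], int(exon_lens[i])
            if dense[i]:
                kind = "latent" if labels[i] == "C1" else "first_exon_dense"
                for d in cfg.c1_site_offsets:
                    _plant(arr, fp, es + d - 1, "GAC")
                    for e_k in range(cfg.enhancers_per_site):
                        off = d + 6 + 8 * e_k
                        _plant(arr, fp, es + off,
                               enh_list[int(rng.integers(len(enh_list)))])
                    site_rows.append((gene_id, i, es + d, d, kind))
            if (
                L >= cfg.constitutive_min_exon_len
                and rng.random() < cfg.constitutive_site_prob
            ):
                d = L // 2
                _plant(arr, fp, es + d - 1, "GAC")
                for e_k in range(cfg.enhancers_per_constitutive):
                    _plant(arr, fp, es + d + 6 + 8 * e_k,
                           enh_list[int(rng.integers(len(enh_list)))])
                site_rows.append((gene_id, i, es + d, d, "constitutive"))
            # random exonic enhancer sprinkling (exons are enhancer-enriched
            # relative to introns); kept clear of exon edges and other plants
            n_extra = int(rng.poisson(L * cfg.exon_enhancer_per_100nt / 100.0))
            for _ in range(n_extra):
                for _try in range(4):
                    p = es + int(rng.integers(8, max(L - 13, 9)))
                    if not fp[p - 3:p + 8].any():
                        _plant(arr, fp, p, enh_list[int(rng.integers(len(enh_list)))])
                        break
            exon_rows.append(
                (gene_id, i, roles[i], labels[i], es, es + L, L)
            )

        # Iterate three clean-up constraints to a joint fixpoint:
        # 1. no accidental weighted pentamer in the pre-mRNA (scrub);
        # 2. no exon starting "AC" (such an exon would host a RAC site whose
        #    purine is the upstream intron's trailing G — the site would vanish
        #    on intron deletion, confounding deltas with context loss);
        # 3. no weighted pentamer spanning any potential exon-exon junction of
        #    an intron-deleted sequence (junction 8-mers are new sequence the
        #    pre-mRNA scrub never sees).
        junctions = [
            (exon_starts[i] + int(exon_lens[i]), exon_starts[i + 1])
            for i in range(n_ex - 1)
        ]
        for _ in range(25):
            _scrub_weighted(arr, fp, weighted_codes, rng)
            changed = False
            for es in exon_starts[1:]:
                if arr[es] == 0 and arr[es + 1] == 1 and not fp[es + 1]:
                    arr[es + 1] = int(rng.choice([2, 3]))
                    changed = True
            changed |= _fix_junction_pentamers(arr, fp, weighted_codes, junctions, rng)
            if not changed:
                break
        else:
            raise RuntimeError("fixture sequence clean-up did not converge")
        gene_seqs.append((gene_id, arr, exon_starts, [int(x) for x in exon_lens]))

    # --- place genes on chromosomes ---------------------------------------
    chrom_parts: dict[str, list[np.ndarray]] = {
        f"chr{c + 1}": [] for c in range(cfg.n_chromosomes)
    }
    chrom_pos = {c: 0 for c in chrom_parts}
    transcripts: dict[str, TranscriptModel] = {}
    for gi, (gene_id, arr, exon_starts, exon_lens) in enumerate(gene_seqs):
        chrom = f"chr{(gi % cfg.n_chromosomes) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(cfg.intergenic_min, cfg.intergenic_max + 1))
        chrom_parts[chrom].append(rng.integers(0, 4, gap, dtype=np.int8))
        gstart = chrom_pos[chrom] + gap
        placed = arr if strand == "+" else (3 - arr)[::-1]   # revcomp in code space
        chrom_parts[chrom].append(placed)
        gend = gstart + len(arr)
        chrom_pos[chrom] = gend

        exons = []
        for es, L in zip(exon_starts, exon_lens):
            if strand == "+":
                exons.append(GenomicInterval(chrom, gstart + es, gstart + es + L, "+"))
            else:
                exons.append(GenomicInterval(chrom, gend - es - L, gend - es, "-"))
        transcripts[gene_id] = TranscriptModel(gene_id, f"{gene_id}.t1", exons)
        gene_rows.append(
            (gene_id, f"{gene_id}.t1", chrom, strand, len(exons), gstart, gend)
        )

    genome = {
        c: _codes_to_str(np.concatenate(parts) if parts else np.empty(0, dtype=np.int8))
        for c, parts in chrom_parts.items()
    }
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "transcript_id", "chrom", "strand", "n_exons", "start", "end"],
    )
    exons_df = pd.DataFrame(
        exon_rows,
        columns=["gene_id", "exon_index", "role", "label", "tx_start", "tx_end", "length"],
    )
    sites_df = pd.DataFrame(
        site_rows,
        columns=["gene_id", "exon_index", "tx_position", "dist_to_exon_start", "kind"],
    )
    return GenomeFixture(
        cfg, weights, SyntheticPredictorConfig(), genome, transcripts,
        genes, exons_df, sites_df,
    )


def _silencer_offsets(cfg: GeneratorConfig) -> list[int]:
    n = cfg.silencers_per_intron_end
    if n == 0:
        return []
    # >= 3 free bases between consecutive plants and from the GT/AG ends, so
    # the background scrub always has room to break junction-spanning
    # pentamers without touching a plant
    span = cfg.silencer_end_nt - 10
    step = max(span // max(n, 1), 8)
    return [5 + step * k for k in range(n) if 5 + step * k + 5 <= cfg.silencer_end_nt - 5]


def _roles(n_ex: int) -> list[str]:
    if n_ex == 1:
        return ["single"]
    return ["first"] + ["internal"] * (n_ex - 2) + ["last"]


def neutral_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A fixture config with no weighted-pentamer planting anywhere: every
    RAC site then scores the bare intercept and all edit deltas are exactly 0."""
    return GeneratorConfig(
        seed=seed, enhancers_per_site=0, silencers_per_intron_end=0,
        constitutive_site_prob=0.0, exon_enhancer_per_100nt=0.0, **overrides,
    )


# ---------------------------------------------------------------------------
# companion generators
# ---------------------------------------------------------------------------

def generate_conservation_track(
    length: int, latent_positions, shift: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Per-position conservation scores: N(0,1) baseline, +shift at latent
    sites (shift 0 makes the groups exchangeable)."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=length)
    idx = np.asarray(list(latent_positions), dtype=int)
    if len(idx):
        scores[idx] += shift
    return scores


def generate_conservation_tracks(
    fixture: GenomeFixture, shift: float | None = None, seed: int | None = None
) -> dict[str, np.ndarray]:
    """One conservation track per gene over its pre-mRNA, elevated at the
    planted latent sites."""
    cfg = fixture.config
    shift = cfg.conservation_shift if shift is None else shift
    master = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    tracks = {}
    latent = fixture.latent_sites()
    for gene_id, tx in sorted(fixture.transcripts.items()):
        pos = latent.loc[latent["gene_id"] == gene_id, "tx_position"].to_numpy()
        tracks[gene_id] = generate_conservation_track(
            tx.pre_mrna_length, pos, shift, int(master.integers(2**31))
        )
    return tracks


def generate_halflife_tables(
    m6a_counts: pd.DataFrame,
    base_h: float = 8.0,
    beta_wt: float = 0.15,
    beta_ko: float = 0.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Half-life table: T1/2 = base * exp(-beta * m6A count) * lognormal noise.

    ``m6a_counts`` needs columns gene_id and m6a_count (extra columns pass
    through).  The WT condition uses ``beta_wt``; the KO condition uses
    ``beta_ko`` (0 = methylation dependence removed).
    """
    rng = np.random.default_rng(seed)
    out = m6a_counts.copy()
    counts = out["m6a_count"].to_numpy(dtype=float)
    out["t12_wt"] = base_h * np.exp(-beta_wt * counts) * np.exp(
        rng.normal(0, noise_sd, len(out))
    )
    out["t12_ko"] = base_h * np.exp(-beta_ko * counts) * np.exp(
        rng.normal(0, noise_sd, len(out))
    )
    return out


def generate_ip_coverage(
    length: int,
    peak_intervals,
    background_rate: float = 30.0,
    fold: float = 4.0,
    seed: int = 0,
) -> tuple[CoverageTrack, CoverageTrack]:
    """(IP, input) per-base Poisson coverage with planted enrichment.

    Input is Poisson(background_rate) everywhere; IP is
    Poisson(background_rate * fold) inside the planted intervals and
    Poisson(background_rate) elsewhere.  Library sizes are the summed
    coverage.
    """
    rng = np.random.default_rng(seed)
    input_cov = rng.poisson(background_rate, length).astype(float)
    ip_cov = rng.poisson(background_rate, length).astype(float)
    for s, e in peak_intervals:
        ip_cov[s:e] = rng.poisson(background_rate * fold, e - s)
    return CoverageTrack(ip_cov), CoverageTrack(input_cov)


def fixture_methylated_intervals(
    fixture: GenomeFixture, window_nt: int = 20
) -> dict[str, list[tuple[int, int]]]:
    """Genomic intervals (per chromosome) around planted constitutive m6A
    sites, snapped to the window grid and spanning ``ip_peak_len`` nt."""
    cfg = fixture.config
    half_windows = cfg.ip_peak_len // window_nt // 2
    out: dict[str, list[tuple[int, int]]] = {c: [] for c in fixture.genome}
    const = fixture.sites[fixture.sites["kind"] == "constitutive"]
    gene_info = fixture.genes.set_index("gene_id")
    for gene_id, grp in const.groupby("gene_id"):
        info = gene_info.loc[gene_id]
        for tx_pos in grp["tx_position"]:
            gpos = (
                info["start"] + tx_pos
                if info["strand"] == "+"
                else info["end"] - 1 - tx_pos
            )
            w0 = (int(gpos) // window_nt - half_windows) * window_nt
            s = max(w0, 0)
            e = min(s + cfg.ip_peak_len, len(fixture.genome[info["chrom"]]))
            if e > s:
                out[info["chrom"]].append((s, e))
    for c in out:
        out[c].sort()
    return out


def generate_fixture_ip_coverage(
    fixture: GenomeFixture, seed: int | None = None
) -> dict[str, tuple[CoverageTrack, CoverageTrack]]:
    """IP/input coverage per chromosome, enriched over the methylated
    intervals of the fixture."""
    cfg = fixture.config
    master = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    intervals = fixture_methylated_intervals(fixture)
    return {
        chrom: generate_ip_coverage(
            len(seq), intervals[chrom], cfg.ip_background_rate, cfg.ip_peak_fold,
            int(master.integers(2**31)),
        )
        for chrom, seq in sorted(fixture.genome.items())
    }


def generate_assay_tables(
    site_levels: pd.DataFrame,
    decay_constants: dict[str, float],
    ct_base: float = 25.0,
    ct_noise_sd: float = 0.15,
    n_replicates: int = 3,
    times_h: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0),
    decay_noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SELECT Ct tables and decay time courses with planted truth.

    ``site_levels`` has columns site_id, level_containing, level_deleted
    (planted relative m6A levels per construct).  Site Ct values are
    ``ct_base + log2(level) + noise``; each construct also carries two
    control (non-RAC) sites at ``ct_base + noise``.  Decay series follow
    ``100 * exp(-k t)`` with multiplicative log-normal noise, renormalized to
    100% at t = 0 per replicate.
    """
    rng = np.random.default_rng(seed)
    select_rows = []
    for construct, col in (
        ("intron_containing", "level_containing"),
        ("intron_deleted", "level_deleted"),
    ):
        for _, row in site_levels.iterrows():
            for rep in range(n_replicates):
                ct = ct_base + math.log2(row[col]) + rng.normal(0, ct_noise_sd)
                select_rows.append((construct, row["site_id"], rep, ct, False))
        for ctrl in ("ctrl_1", "ctrl_2"):
            for rep in range(n_replicates):
                ct = ct_base + rng.normal(0, ct_noise_sd)
                select_rows.append((construct, ctrl, rep, ct, True))
    select_df = pd.DataFrame(
        select_rows, columns=["construct", "site_id", "replicate", "ct", "is_control"]
    )

    decay_rows = []
    times = np.asarray(times_h, dtype=float)
    for construct, k in decay_constants.items():
        for rep in range(n_replicates):
            noise = np.exp(rng.normal(0, decay_noise_sd, len(times)))
            levels = 100.0 * np.exp(-k * times) * noise
            levels *= 100.0 / levels[0]
            for t, lv in zip(times, levels):
                decay_rows.append((construct, rep, t, lv))
    decay_df = pd.DataFrame(
        decay_rows, columns=["construct", "replicate", "time_h", "level_pct"]
    )
    return select_df, decay_df


# ---------------------------------------------------------------------------
# light-weight random transcripts (for liftover stress tests)
# ---------------------------------------------------------------------------

def random_transcript(
    rng: np.random.Generator,
    gene_id: str = "toy",
    max_exons: int = 8,
    exon_len_range: tuple[int, int] = (20, 300),
    intron_len_range: tuple[int, int] = (30, 500),
) -> tuple[TranscriptModel, SequenceRecord]:
    """A random transcript with its pre-mRNA, for structural property tests
    (no planting, no genome placement)."""
    n_ex = int(rng.integers(1, max_exons + 1))
    exon_lens = rng.integers(*exon_len_range, n_ex)
    intron_lens = rng.integers(*intron_len_range, max(n_ex - 1, 0))
    strand = "+" if rng.random() < 0.5 else "-"
    total = int(exon_lens.sum() + intron_lens.sum())
    seq = _codes_to_str(rng.integers(0, 4, total, dtype=np.int8))
    exons = []
    pos = 0
    gstart = int(rng.integers(0, 1000))
    for i in range(n_ex):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    if strand == "+":
        ivs = [GenomicInterval("chrT", gstart + s, gstart + e, "+") for s, e in exons]
    else:
        gend = gstart + total
        ivs = [GenomicInterval("chrT", gend - e, gend - s, "-") for s, e in exons]
    tx = TranscriptModel(gene_id, f"{gene_id}.t1", ivs)
    return tx, SequenceRecord(f"{gene_id}.t1", seq)
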