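"""Synthetic bisulfite and RNA data with fully recorded ground truth.

The generator emulates the structure of a holometabolous-insect
(wasp-like) developmental methylome: five stages (embryo, larva,
prepupa, pupa, adult) with three replicates each, a sparse CpG methylome
(~1% of CpGs methylated) dominated by a large always-methylated core plus
small stage-specific site sets, an unmethylated lambda-phage spike whose
apparent methylation comes only from bisulfite non-conversion, a sequence
context bias (one CpG-centered 6-mer over-represented among methylated
sites), and negative-binomial RNA counts whose mean is log-linearly
coupled to gene-body methylation percentage.

Defaults mirror the study conditions: non-conversion rate 0.005, mean
coverage 30, 3 replicates, true level ~0.9 at methylated sites, and an
enlarged first-stage-specific set so the embryo→larva transition carries
the largest differential-methylation truth set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import (
    STAGES,
    CytosineRecord,
    Exon,
    Gene,
    GenomeAnnotation,
)
from .kmers import extract_kmer

Site = tuple[str, int]  # (chrom, 1-based position of the + strand C)


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    annotation: GenomeAnnotation

    def cpg_sites(self) -> list[Site]:
        """All CpG dyads, as the 1-based position of the + strand C."""
        out: list[Site] = []
        for chrom in sorted(self.sequences):
            seq = self.sequences[chrom]
            for i in range(len(seq) - 1):
                if seq[i] == "C" and seq[i + 1] == "G":
                    out.append((chrom, i + 1))
        return out


@dataclass
class SimulationTruth:
    """Ground truth of one simulated methylome, the estimand of every test."""

    nonconversion_rate: float
    stages: tuple[str, ...]
    cpg_sites: list[Site]
    levels: dict[str, np.ndarray]  # per stage, aligned with cpg_sites
    always_methylated_sites: set[Site]
    stage_unique_sites: dict[str, set[Site]]
    dms_truth: dict[tuple[str, str], dict[Site, float]]  # site -> true delta (pct)
    expression_coupling: dict[str, float]  # gene -> beta1 (log-count per meth %)
    stage_offsets: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def methylated_sites(self, stage: str, threshold: float = 0.5) -> set[Site]:
        lv = self.levels[stage]
        return {s for s, l in zip(self.cpg_sites, lv) if l >= threshold}

    def level_at(self, stage: str, site: Site) -> float:
        return float(self.levels[stage][self._index[site]])

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.cpg_sites)}


def _random_seq(rng: np.random.Generator, length: int, gc_frac: float) -> str:
    p = [
        (1 - gc_frac) / 2,  # A
        gc_frac / 2,        # C
        gc_frac / 2,        # G
        (1 - gc_frac) / 2,  # T
    ]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def make_genome(
    n_chrom: int = 2,
    chrom_len: int = 50_000,
    gc_frac: float = 0.4,
    n_genes: int = 20,
    seed: int = 0,
) -> SyntheticGenome:
    """Random genome with non-overlapping genes of 2–6 exons each.

    Deterministic given ``seed``. Genes are laid out left to right with
    random intergenic gaps; raises ``ValueError`` when ``n_genes`` genes
    cannot be packed into the available sequence.
    """
    if not (0 <= gc_frac <= 1):
        raise ValueError("gc_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sequences = {
        f"chr{c + 1}": _random_seq(rng, chrom_len, gc_frac) for c in range(n_chrom)
    }

    genes: list[Gene] = []
    exons: list[Exon] = []
    per_chrom = [n_genes // n_chrom + (1 if c < n_genes % n_chrom else 0)
                 for c in range(n_chrom)]
    gid = 0
    for c, n_here in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        cursor = 1
        for _ in range(n_here):
            gap = int(rng.integers(200, 1001))
            glen = int(rng.integers(900, 2401))
            start = cursor + gap
            end = start + glen - 1
            if end > chrom_len:
                raise ValueError(
                    f"infeasible packing: cannot place {n_genes} genes of "
                    f"~1–2.4 kb into {n_chrom}×{chrom_len} bp"
                )
            gid += 1
            gene_id = f"g{gid:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gene_id, chrom, start, end, strand))
            exons.extend(_make_exons(rng, gene_id, chrom, start, end, strand))
            cursor = end + 1
    return SyntheticGenome(sequences, GenomeAnnotation(genes=genes, exons=exons))


def _make_exons(
    rng: np.random.Generator, gene_id: str, chrom: str, start: int, end: int, strand: str
) -> list[Exon]:
    glen = end - start + 1
    n_ex = int(rng.integers(2, 7))
    # alternating exon/intron blocks, each at least 60 bp
    n_blocks = 2 * n_ex - 1
    while n_blocks * 60 > glen and n_ex > 1:
        n_ex -= 1
        n_blocks = 2 * n_ex - 1
    cuts = np.sort(rng.choice(glen - n_blocks * 60, size=n_blocks - 1, replace=True)) \
        if n_blocks > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [glen - n_blocks * 60]])) + 60
    exons: list[Exon] = []
    pos = start
    for b, size in enumerate(sizes):
        if b % 2 == 0:  # exon block
            exons.append(Exon(gene_id, 0, chrom, pos, pos + int(size) - 1))
        pos += int(size)
    if strand == "-":
        exons = exons[::-1]
    return [Exon(e.gene_id, rank, e.chrom, e.start, e.end)
            for rank, e in enumerate(exons, start=1)]


def _fold_stratified_sample(
    rng: np.random.Generator, idx: np.ndarray, matches: np.ndarray, n: int, fold: float
) -> np.ndarray:
    """Sample ``n`` of ``idx`` so the match rate in the sample over the
    match rate in the complement equals ``fold`` (up to integer rounding).

    Solving (n_m/n) / ((M−n_m)/(N−n)) = fold for the number of matching
    sites n_m gives n_m = fold·n·M / (N − n + fold·n); the two strata are
    then sampled uniformly without replacement. A fold too large for the
    available matches is clamped with a warning.
    """
    N = len(idx)
    if n >= N:
        return idx
    M = int(matches.sum())
    n_m = int(round(fold * n * M / (N - n + fold * n)))
    if n_m > min(n, M):
        import warnings

        warnings.warn(f"requested enrichment fold {fold} not achievable; clamping")
        n_m = min(n, M)
    match_idx = idx[matches]
    other_idx = idx[~matches]
    pick_m = rng.choice(match_idx, size=n_m, replace=False)
    pick_o = rng.choice(other_idx, size=n - n_m, replace=False)
    return np.concatenate([pick_m, pick_o])


def simulate_methylome(
    genome: SyntheticGenome,
    stages: tuple[str, ...] = STAGES,
    pct_always: float = 0.01,
    pct_stage_unique: float = 0.002,
    enriched_kmer: str = "TACGTA",
    enrichment_fold: float = 3.0,
    meth_level: float = 0.9,
    first_stage_boost: float = 3.0,
    nonconversion_rate: float = 0.005,
    expression_coupling: float = 0.02,
    seed: int = 0,
) -> SimulationTruth:
    """Plant an always-methylated core plus disjoint stage-specific sets.

    Core sites are drawn so CpGs whose centered 6-mer equals
    ``enriched_kmer`` occur at ``enrichment_fold`` times the background
    rate (rate ratio planted exactly up to rounding), giving the k-mer
    enrichment module a recoverable target. True levels are ``meth_level``
    at methylated sites and 0 elsewhere. The first stage's unique set is
    ``first_stage_boost`` times larger than the others', so the first
    transition carries the largest differential-methylation truth set.
    """
    k = len(enriched_kmer)
    if k % 2 != 0 or enriched_kmer[k // 2 - 1 : k // 2 + 1] != "CG":
        raise ValueError(f"enriched k-mer {enriched_kmer!r} must have CG at its center")
    unique_budget = pct_stage_unique * (first_stage_boost + len(stages) - 1)
    if pct_always + unique_budget > 1:
        raise ValueError("pct_always + stage-unique budget exceeds 1")

    rng = np.random.default_rng(seed)
    sites = genome.cpg_sites()
    n = len(sites)
    idx = np.arange(n)

    matches = np.array(
        [extract_kmer(genome.sequences, s, k=k) == enriched_kmer for s in sites]
    )
    n_always = int(round(pct_always * n))
    always_idx = _fold_stratified_sample(rng, idx, matches, n_always, enrichment_fold)
    always = {sites[i] for i in always_idx}

    remaining = np.array(sorted(set(idx) - set(always_idx)))
    rng.shuffle(remaining)
    stage_unique: dict[str, set[Site]] = {}
    cursor = 0
    for s_i, stage in enumerate(stages):
        boost = first_stage_boost if s_i == 0 else 1.0
        n_uni = int(round(pct_stage_unique * boost * n))
        chunk = remaining[cursor : cursor + n_uni]
        cursor += n_uni
        stage_unique[stage] = {sites[i] for i in chunk}

    site_index = {s: i for i, s in enumerate(sites)}
    levels: dict[str, np.ndarray] = {}
    for stage in stages:
        lv = np.zeros(n)
        for s in always:
            lv[site_index[s]] = meth_level
        for s in stage_unique[stage]:
            lv[site_index[s]] = meth_level
        levels[stage] = lv

    dms_truth: dict[tuple[str, str], dict[Site, float]] = {}
    for a, b in zip(stages[:-1], stages[1:]):
        delta = 100.0 * (levels[b] - levels[a])
        dms_truth[(a, b)] = {
            sites[i]: float(delta[i]) for i in np.nonzero(delta != 0)[0]
        }

    coupling = {g.gene_id: expression_coupling for g in genome.annotation.genes}
    offsets = {
        stage: float(off)
        for stage, off in zip(stages, np.random.default_rng(seed + 1).normal(0, 0.3, len(stages)))
    }
    return SimulationTruth(
        nonconversion_rate=nonconversion_rate,
        stages=tuple(stages),
        cpg_sites=sites,
        levels=levels,
        always_methylated_sites=always,
        stage_unique_sites=stage_unique,
        dms_truth=dms_truth,
        expression_coupling=coupling,
        stage_offsets=offsets,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# WGBS count simulation
# ---------------------------------------------------------------------------

@dataclass
class WGBSSim:
    """Simulated per-replicate CpG reports plus the lambda spike report."""

    reports: dict[str, list[list[CytosineRecord]]]  # stage -> replicate reports
    lambda_report: list[CytosineRecord]
    lambda_sequence: str


def _dyad_records(
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    tri_plus: str,
    tri_minus: str,
    level: float,
    rate: float,
    mean_cov: float,
) -> list[CytosineRecord]:
    p_obs = min(1.0, level + (1.0 - level) * rate)
    out = []
    for strand, p_, tri in (("+", pos, tri_plus), ("-", pos + 1, tri_minus)):
        cov = int(rng.poisson(mean_cov / 2.0))
        meth = int(rng.binomial(cov, p_obs)) if cov > 0 else 0
        out.append(CytosineRecord(chrom, p_, strand, meth, cov - meth, "CpG", tri))
    return out


def simulate_wgbs(
    truth: SimulationTruth,
    genome: SyntheticGenome,
    mean_cov: float = 30.0,
    n_reps: int = 3,
    seed: int = 0,
    lambda_len: int = 20_000,
) -> WGBSSim:
    """Simulate destrandable CpG count reports and the lambda spike.

    Each CpG dyad gets per-strand coverage ~ Poisson(mean_cov/2) and
    methylated counts ~ Binomial(cov, level + (1-level)·rate). The lambda
    spike is a separate random chromosome whose every cytosine (all
    contexts, both strands) has true level 0, so its methylated calls arise
    only from non-conversion.
    """
    if mean_cov <= 0:
        raise ValueError("mean_cov must be positive")
    rng = np.random.default_rng(seed)
    rate = truth.nonconversion_rate

    reports: dict[str, list[list[CytosineRecord]]] = {}
    for stage in truth.stages:
        reps = []
        for _ in range(n_reps):
            rep: list[CytosineRecord] = []
            for (chrom, pos), level in zip(truth.cpg_sites, truth.levels[stage]):
                seq = genome.sequences[chrom]
                i = pos - 1
                tri_plus = seq[i : i + 3].ljust(3, "N")
                tri_minus = "CG" + (seq[i - 1] if i >= 1 else "N")
                rep.extend(
                    _dyad_records(rng, chrom, pos, tri_plus, tri_minus,
                                  float(level), rate, mean_cov)
                )
            reps.append(rep)
        reports[stage] = reps

    lam_seq = _random_seq(np.random.default_rng(seed + 7919), lambda_len, 0.5)
    lam: list[CytosineRecord] = []
    for i, base in enumerate(lam_seq):
        for strand, is_c in (("+", base == "C"), ("-", base == "G")):
            if not is_c:
                continue
            cov = int(rng.poisson(mean_cov))
            meth = int(rng.binomial(cov, rate)) if cov > 0 else 0
            ctx = _context(lam_seq, i, strand)
            lam.append(
                CytosineRecord("lambda", i + 1, strand, meth, cov - meth, ctx)
            )
    return WGBSSim(reports=reports, lambda_report=lam, lambda_sequence=lam_seq)


def _context(seq: str, i: int, strand: str) -> str:
    if strand == "+":
        nxt = seq[i + 1 : i + 3]
        if nxt[:1] == "G":
            return "CpG"
        if len(nxt) == 2 and nxt[1] == "G":
            return "CHG"
        return "CHH"
    nxt = seq[max(0, i - 2) : i][::-1]  # reverse-complement direction
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    nxt = "".join(comp.get(b, "N") for b in nxt)
    if nxt[:1] == "G":
        return "CpG"
    if len(nxt) == 2 and nxt[1] == "G":
        return "CHG"
    return "CHH"


# ---------------------------------------------------------------------------
# RNA count simulation
# ---------------------------------------------------------------------------

def gene_truth_methylation(
    truth: SimulationTruth, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """True gene-body methylation percentage per gene × stage.

    The percentage is the mean true level (×100) over CpGs inside the gene
    body; genes with no CpGs get 0.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for c, _ in truth.cpg_sites}:
        idx = np.array([i for i, (c, _) in enumerate(truth.cpg_sites) if c == chrom])
        pos = np.array([truth.cpg_sites[i][1] for i in idx])
        order = np.argsort(pos)
        by_chrom[chrom] = (pos[order], idx[order])

    rows = {}
    for g in annotation.genes:
        pos, idx = by_chrom.get(g.chrom, (np.array([]), np.array([], dtype=int)))
        lo, hi = np.searchsorted(pos, [g.start, g.end + 1])
        in_gene = idx[lo:hi]
        rows[g.gene_id] = {
            stage: (100.0 * float(np.mean(truth.levels[stage][in_gene]))
                    if len(in_gene) else 0.0)
            for stage in truth.stages
        }
    return pd.DataFrame(rows).T


def simulate_expression(
    truth: SimulationTruth,
    annotation: GenomeAnnotation,
    n_reps: int = 3,
    nb_dispersion: float = 0.1,
    seed: int = 0,
    base_log_mean: float = math.log(100.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial gene and exon counts coupled to methylation.

    Mean model: log μ_gs = base + stage_offset_s + β_g · meth%_gs, with
    counts ~ NB(μ, dispersion) (gamma–Poisson mixture; dispersion → 0
    recovers Poisson). Exon counts partition each gene count multinomially
    with exon-length weights. Returns (gene counts, exon counts) with
    ``stage_rep`` sample columns.
    """
    rng = np.random.default_rng(seed)
    meth = gene_truth_methylation(truth, annotation)
    samples = [f"{stage}_{r + 1}" for stage in truth.stages for r in range(n_reps)]

    gene_rows = {}
    exon_rows: dict[str, dict[str, int]] = {}
    for g in annotation.genes:
        beta = truth.expression_coupling[g.gene_id]
        exons = annotation.exons_of(g.gene_id)
        lens = np.array([e.end - e.start + 1 for e in exons], dtype=float)
        w = lens / lens.sum() if len(lens) else np.array([])
        counts = {}
        for stage in truth.stages:
            mu = math.exp(
                base_log_mean + truth.stage_offsets[stage] + beta * meth.loc[g.gene_id, stage]
            )
            for r in range(n_reps):
                if nb_dispersion > 1e-8:
                    lam = rng.gamma(1.0 / nb_dispersion, mu * nb_dispersion)
                else:
                    lam = mu
                c = int(rng.poisson(lam))
                counts[f"{stage}_{r + 1}"] = c
                if len(w):
                    parts = rng.multinomial(c, w)
                    for e, pc in zip(exons, parts):
                        exon_rows.setdefault(
                            f"{g.gene_id}:exon{e.exon_rank}", {}
                        )[f"{stage}_{r + 1}"] = int(pc)
        gene_rows[g.gene_id] = counts

    genes_df = pd.DataFrame(gene_rows).T.reindex(columns=samples).astype(int)
    exons_df = pd.DataFrame(exon_rows).T.reindex(columns=samples).fillna(0).astype(int)
    return genes_df, exons_df


def simulate_lfc_table(
    n_genes: int = 500,
    slope: float = 0.15,
    comparisons: tuple[str, ...] = (
        "embryo_vs_larva", "larva_vs_prepupa", "prepupa_vs_pupa", "pupa_vs_adult",
    ),
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene × comparison table with LFC linear in the number of DMS.

    lfc = comparison offset + slope · n_dms + Gaussian noise; gives the
    Gaussian GLMs a known recoverable slope.
    """
    rng = np.random.default_rng(seed)
    offs = {c: o for c, o in zip(comparisons, rng.normal(0, 0.2, len(comparisons)))}
    rows = []
    for comp in comparisons:
        n_dms = rng.poisson(3.0, n_genes)
        lfc = offs[comp] + slope * n_dms + rng.normal(0, noise_sd, n_genes)
        for g in range(n_genes):
            rows.append(
                {"gene_id": f"g{g + 1:04d}", "comparison": comp,
                 "n_dms": int(n_dms[g]), "lfc": float(lfc[g])}
            )
    return pd.DataFrame(rows)
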