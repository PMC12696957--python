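"""Spike-calibrated binomial methylation calling and feature aggregation.

The pipeline: estimate the bisulfite non-conversion (false-positive) rate
from an unmethylated lambda spike, destrand CpG dyads to pool strand
counts, drop sites below a minimum coverage (default 10 reads), test each
site against Binomial(coverage, rate) one-sided, control the FDR with
Benjamini–Hochberg at 0.05, and aggregate calls to genomic features,
genes, methylation classes, stage-overlap regions and exon-rank profiles.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import CytosineRecord, GenomeAnnotation

Site = tuple[str, int]

METH_CLASSES = ("unmethylated", "low", "medium", "high")


@dataclass(frozen=True)
class CpGSite:
    """Destranded CpG dyad; ``pos`` is the + strand C of the dyad."""

    chrom: str
    pos: int
    count_meth: int
    count_unmeth: int

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth

    @property
    def meth_pct(self) -> float:
        cov = self.coverage
        return 100.0 * self.count_meth / cov if cov else float("nan")

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class MethCall:
    site: CpGSite
    p_value: float
    q_value: float
    methylated: bool


@dataclass(frozen=True)
class FeatureAssignment:
    site: Site
    category: str  # exon / intron / promoter / intergenic
    gene_id: str | None = None
    exon_rank: int | None = None


@dataclass(frozen=True)
class GeneMethylation:
    gene_id: str
    meth_pct: float  # coverage-weighted
    n_sites: int
    meth_class: str
    n_methylated: int | None = None


@dataclass(frozen=True)
class NonconversionEstimate:
    rate: float
    total_coverage: int
    n_methylated: int

    @property
    def se(self) -> float:
        return math.sqrt(self.rate * (1 - self.rate) / self.total_coverage)


def estimate_nonconversion(
    lambda_records: Sequence[CytosineRecord],
) -> NonconversionEstimate:
    """Pooled methylated fraction over all lambda cytosines (all contexts).

    The lambda genome is fully unmethylated, so every context informs the
    error rate. A zero estimate is replaced by the pseudo-rate
    1/(total coverage + 1), with a warning, so the downstream binomial
    test does not degenerate at p = 0.
    """
    total = sum(r.coverage for r in lambda_records)
    meth = sum(r.count_meth for r in lambda_records)
    if total == 0:
        raise ValueError("lambda spike has zero total coverage")
    rate = meth / total
    if rate == 0.0:
        rate = 1.0 / (total + 1)
        warnings.warn(
            f"no methylated lambda calls; using pseudo-rate 1/{total + 1}"
        )
    return NonconversionEstimate(rate=rate, total_coverage=total, n_methylated=meth)


def destrand(
    records: Iterable[CytosineRecord], genome: Mapping[str, str]
) -> list[CpGSite]:
    """Merge the two strands of each CpG dyad into one site.

    A + strand C at position i and the − strand C at i+1 are pooled and
    reported at i. Unpaired strand records pass through with their own
    counts (a − strand singleton over a genuine dyad is reported at i; one
    without a dyad in the genome is kept at its own position with a
    warning). Total methylated and unmethylated counts are conserved
    exactly.
    """
    merged: dict[Site, list[int]] = {}
    order: list[Site] = []

    def _add(key: Site, meth: int, unmeth: int) -> None:
        if key not in merged:
            merged[key] = [0, 0]
            order.append(key)
        merged[key][0] += meth
        merged[key][1] += unmeth

    for r in records:
        if r.context != "CpG":
            continue
        if r.strand == "+":
            _add((r.chrom, r.pos), r.count_meth, r.count_unmeth)
        else:
            seq = genome.get(r.chrom, "")
            i = r.pos - 1
            if i >= 1 and seq[i - 1 : i + 1].upper() == "CG":
                _add((r.chrom, r.pos - 1), r.count_meth, r.count_unmeth)
            else:
                warnings.warn(
                    f"- strand CpG record at {r.chrom}:{r.pos} has no dyad in "
                    "the genome; kept as singleton"
                )
                _add((r.chrom, r.pos), r.count_meth, r.count_unmeth)
    return [CpGSite(chrom, pos, m, u) for (chrom, pos), (m, u) in
            ((k, merged[k]) for k in order)]


def filter_coverage(sites: Sequence[CpGSite], min_cov: int = 10) -> list[CpGSite]:
    """Keep sites with coverage >= min_cov, preserving order."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    return [s for s in sites if s.coverage >= min_cov]


def binomial_tail_p(count_meth: int, coverage: int, rate: float) -> float:
    """One-sided upper-tail p: P(X >= count_meth), X ~ Binomial(cov, rate)."""
    if count_meth <= 0:
        return 1.0
    return float(stats.binom.sf(count_meth - 1, coverage, rate))


def call_methylated(
    sites: Sequence[CpGSite], rate: float, alpha: float = 0.05
) -> list[MethCall]:
    """Binomial test per site against the non-conversion rate, BH at alpha.

    Methylation can only inflate the methylated count above the error
    rate, so the test is one-sided (upper tail). A site is called
    methylated when its BH q-value is below ``alpha``.
    """
    if not (0 < rate < 1):
        raise ValueError(f"rate must be in (0, 1), got {rate}")
    if not sites:
        return []
    p = np.array([binomial_tail_p(s.count_meth, s.coverage, rate) for s in sites])
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    # flag strictly from the q-value so the invariant methylated <=> q < alpha holds
    return [
        MethCall(site=s, p_value=float(pi), q_value=float(qi), methylated=bool(qi < alpha))
        for s, pi, qi in zip(sites, p, q)
    ]


def pool_replicates(reports: Sequence[Sequence[CytosineRecord]]) -> list[CytosineRecord]:
    """Sum counts across replicate reports position-by-position.

    Used for the per-stage "merged" calling track; differential analysis
    keeps replicates separate.
    """
    acc: dict[tuple[str, int, str], list] = {}
    order = []
    for rep in reports:
        for r in rep:
            key = (r.chrom, r.pos, r.strand)
            if key not in acc:
                acc[key] = [0, 0, r.context, r.tri_context]
                order.append(key)
            acc[key][0] += r.count_meth
            acc[key][1] += r.count_unmeth
    return [
        CytosineRecord(chrom, pos, strand, acc[k][0], acc[k][1], acc[k][2], acc[k][3])
        for k in order
        for chrom, pos, strand in [k]
    ]


# ---------------------------------------------------------------------------
# Feature assignment
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Per-chromosome interval lookup with exon > intron > promoter precedence."""

    def __init__(self, annotation: GenomeAnnotation, promoter_bp: int = 1000):
        self.promoter_bp = promoter_bp
        self.genes = annotation.genes
        self.exons_by_gene = {
            g.gene_id: annotation.exons_of(g.gene_id) for g in annotation.genes
        }

    def assign(self, site: Site) -> FeatureAssignment:
        chrom, pos = site
        intron_hit: FeatureAssignment | None = None
        promoter_hit: FeatureAssignment | None = None
        for g in self.genes:
            if g.chrom != chrom:
                continue
            if g.start <= pos <= g.end:
                for e in self.exons_by_gene.get(g.gene_id, []):
                    if e.start <= pos <= e.end:
                        return FeatureAssignment(site, "exon", g.gene_id, e.exon_rank)
                if intron_hit is None:
                    intron_hit = FeatureAssignment(site, "intron", g.gene_id)
            elif promoter_hit is None:
                if g.strand == "+" and g.start - self.promoter_bp <= pos < g.start:
                    promoter_hit = FeatureAssignment(site, "promoter", g.gene_id)
                elif g.strand == "-" and g.end < pos <= g.end + self.promoter_bp:
                    promoter_hit = FeatureAssignment(site, "promoter", g.gene_id)
        if intron_hit is not None:
            return intron_hit
        if promoter_hit is not None:
            return promoter_hit
        return FeatureAssignment(site, "intergenic")


def assign_feature(
    site: Site | CpGSite, annotation: GenomeAnnotation, promoter_bp: int = 1000
) -> FeatureAssignment:
    """Assign one site to exon/intron/promoter/intergenic (that precedence).

    Promoter = within ``promoter_bp`` upstream of a TSS (strand-aware) and
    not inside any gene body.
    """
    if isinstance(site, CpGSite):
        site = site.site
    return FeatureIndex(annotation, promoter_bp).assign(site)


def assign_features(
    sites: Sequence[Site | CpGSite],
    annotation: GenomeAnnotation,
    promoter_bp: int = 1000,
) -> list[FeatureAssignment]:
    index = FeatureIndex(annotation, promoter_bp)
    return [index.assign(s.site if isinstance(s, CpGSite) else s) for s in sites]


# ---------------------------------------------------------------------------
# Gene-level aggregation
# ---------------------------------------------------------------------------

def classify_gene(meth_pct: float) -> str:
    """Methylation class: unmethylated [0,0.5), low [0.5,30), medium
    [30,70), high [70,100]. Boundaries are lower-inclusive."""
    if not (0 <= meth_pct <= 100):
        raise ValueError(f"meth_pct must be in [0, 100], got {meth_pct}")
    if meth_pct < 0.5:
        return "unmethylated"
    if meth_pct < 30:
        return "low"
    if meth_pct < 70:
        return "medium"
    return "high"


def gene_methylation(
    sites: Sequence[CpGSite],
    annotation: GenomeAnnotation,
    calls: Sequence[MethCall] | None = None,
) -> list[GeneMethylation]:
    """Coverage-weighted gene-body methylation percentage per gene.

    gene % = 100 · Σ count_meth / Σ coverage over covered CpGs inside the
    gene body; genes with no covered CpGs are omitted. When ``calls`` are
    given, the number of methylated sites per gene is reported too.
    """
    called = (
        {c.site.site for c in calls if c.methylated} if calls is not None else None
    )
    out = []
    for g in annotation.genes:
        meth = cov = n = n_meth = 0
        for s in sites:
            if s.chrom == g.chrom and g.start <= s.pos <= g.end:
                meth += s.count_meth
                cov += s.coverage
                n += 1
                if called is not None and s.site in called:
                    n_meth += 1
        if cov == 0:
            continue
        pct = 100.0 * meth / cov
        out.append(
            GeneMethylation(
                gene_id=g.gene_id,
                meth_pct=pct,
                n_sites=n,
                meth_class=classify_gene(pct),
                n_methylated=n_meth if called is not None else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stage overlaps and exon profiles
# ---------------------------------------------------------------------------

def stage_overlap(
    per_stage_sets: Mapping[str, set[Site]]
) -> tuple[dict[frozenset, int], dict[str, set[Site]]]:
    """Venn-region counts for all 2^n − 1 stage combinations.

    Returns (region counts keyed by the exact stage combination, per-stage
    unique site sets). Region counts sum to the size of the union.
    """
    stages = list(per_stage_sets)
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    regions: dict[frozenset, int] = {}
    for r in range(1, len(stages) + 1):
        for combo in itertools.combinations(stages, r):
            inside = set.intersection(*(per_stage_sets[s] for s in combo))
            outside = set.union(
                *(per_stage_sets[s] for s in stages if s not in combo), set()
            )
            regions[frozenset(combo)] = len(inside - outside)
    uniques = {
        s: per_stage_sets[s]
        - set.union(*(per_stage_sets[t] for t in stages if t != s), set())
        for s in stages
    }
    return regions, uniques


def exon_number_profile(
    calls: Sequence[MethCall],
    annotation: GenomeAnnotation,
    max_rank: int = 10,
) -> dict[int, float]:
    """Mean site methylation percentage per exon rank (1..max_rank).

    Averages site-level percentages over CpGs falling in exons of each
    rank; a rank with no sites maps to NaN (missing, not 0).
    """
    index = FeatureIndex(annotation)
    acc: dict[int, list[float]] = {r: [] for r in range(1, max_rank + 1)}
    for c in calls:
        fa = index.assign(c.site.site)
        if fa.category == "exon" and fa.exon_rank is not None and fa.exon_rank <= max_rank:
            acc[fa.exon_rank].append(c.site.meth_pct)
    return {
        r: (float(np.mean(v)) if v else float("nan")) for r, v in acc.items()
    }
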