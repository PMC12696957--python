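"""End-to-end synthetic-study driver.

Wires the generator and the analysis modules together the way the
analysis scripts and the acceptance checks use them: simulate a genome,
methylome, bisulfite counts and RNA counts; estimate the non-conversion
rate from the lambda spike; call methylated CpGs per stage from pooled
replicates; run pairwise differential methylation on replicate-level
counts; scan k-mer enrichment of the always-methylated core; and fit the
methylation–expression GLMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import pandas as pd

from . import calling, diffmeth, kmers, synthetic
from .calling import CpGSite, MethCall
from .diffmeth import DMSRecord
from .formats import STAGES
from .synthetic import SimulationTruth, SyntheticGenome, WGBSSim

Site = tuple[str, int]


@dataclass
class PipelineResult:
    genome: SyntheticGenome
    truth: SimulationTruth
    wgbs: WGBSSim
    nonconversion: calling.NonconversionEstimate
    stage_sites: dict[str, list[CpGSite]]  # pooled, coverage-filtered
    stage_calls: dict[str, list[MethCall]]
    methylated_sets: dict[str, set[Site]]
    dms: dict[tuple[str, str], list[DMSRecord]]
    tested_order: dict[tuple[str, str], dict[str, list[int]]] = field(default_factory=dict)


def simulate_study(
    seed: int = 0,
    n_chrom: int = 2,
    chrom_len: int = 50_000,
    gc_frac: float = 0.4,
    n_genes: int = 20,
    mean_cov: float = 30.0,
    n_reps: int = 3,
    stages: tuple[str, ...] = STAGES,
    **methylome_kwargs,
) -> tuple[SyntheticGenome, SimulationTruth, WGBSSim]:
    genome = synthetic.make_genome(
        n_chrom=n_chrom, chrom_len=chrom_len, gc_frac=gc_frac,
        n_genes=n_genes, seed=seed,
    )
    truth = synthetic.simulate_methylome(genome, stages=stages, seed=seed + 1,
                                         **methylome_kwargs)
    wgbs = synthetic.simulate_wgbs(
        truth, genome, mean_cov=mean_cov, n_reps=n_reps, seed=seed + 2
    )
    return genome, truth, wgbs


def run_methylation_pipeline(
    genome: SyntheticGenome,
    truth: SimulationTruth,
    wgbs: WGBSSim,
    min_cov: int = 10,
    alpha: float = 0.05,
    p_threshold: float = diffmeth.P_THRESHOLD_DEFAULT,
    diff_threshold: float = diffmeth.DIFF_THRESHOLD_DEFAULT,
    with_dms: bool = True,
) -> PipelineResult:
    """Calling + (optionally) differential methylation on simulated reports."""
    est = calling.estimate_nonconversion(wgbs.lambda_report)

    stage_sites: dict[str, list[CpGSite]] = {}
    stage_calls: dict[str, list[MethCall]] = {}
    methylated_sets: dict[str, set[Site]] = {}
    rep_sites: dict[str, list[list[CpGSite]]] = {}
    for stage in truth.stages:
        pooled = calling.pool_replicates(wgbs.reports[stage])
        sites = calling.filter_coverage(
            calling.destrand(pooled, genome.sequences), min_cov=min_cov
        )
        calls = calling.call_methylated(sites, est.rate, alpha=alpha)
        stage_sites[stage] = sites
        stage_calls[stage] = calls
        methylated_sets[stage] = {c.site.site for c in calls if c.methylated}
        if with_dms:
            rep_sites[stage] = [
                calling.destrand(rep, genome.sequences) for rep in wgbs.reports[stage]
            ]

    dms: dict[tuple[str, str], list[DMSRecord]] = {}
    tested_order: dict[tuple[str, str], dict[str, list[int]]] = {}
    for a, b in zip(truth.stages[:-1], truth.stages[1:]) if with_dms else []:
        map_a = diffmeth.replicate_site_map(rep_sites[a], min_cov=min_cov)
        map_b = diffmeth.replicate_site_map(rep_sites[b], min_cov=min_cov)
        records = diffmeth.compare_stages(
            map_a, map_b, p_threshold=p_threshold, diff_threshold=diff_threshold
        )
        dms[(a, b)] = records
        shared = sorted(set(map_a) & set(map_b))
        order: dict[str, list[int]] = {}
        for chrom, pos in shared:
            order.setdefault(chrom, []).append(pos)
        tested_order[(a, b)] = order

    return PipelineResult(
        genome=genome, truth=truth, wgbs=wgbs, nonconversion=est,
        stage_sites=stage_sites, stage_calls=stage_calls,
        methylated_sets=methylated_sets, dms=dms, tested_order=tested_order,
    )


def empirical_call_fdr(result: PipelineResult) -> tuple[int, int]:
    """(false calls, total calls) pooled over stages, judged against truth."""
    fp = total = 0
    for stage in result.truth.stages:
        true_meth = result.truth.methylated_sites(stage)
        for call in result.stage_calls[stage]:
            if call.methylated:
                total += 1
                if call.site.site not in true_meth:
                    fp += 1
    return fp, total


def dms_detection_power(
    result: PipelineResult, min_true_delta: float = 30.0
) -> tuple[int, int]:
    """(detected, testable planted DMS with |true Δ| >= min_true_delta).

    Only planted sites actually tested (covered in every replicate of
    both stages) count toward the denominator.
    """
    detected = testable = 0
    for (a, b), records in result.dms.items():
        tested = {r.site: r for r in records}
        for site, delta in result.truth.dms_truth[(a, b)].items():
            if abs(delta) < min_true_delta or site not in tested:
                continue
            testable += 1
            if tested[site].significant:
                detected += 1
    return detected, testable


def kmer_scan_always_methylated(
    result: PipelineResult, k: int = 6
) -> pd.DataFrame:
    """Enrichment of CpG-centered k-mers among CpGs methylated in every
    stage, against all other tested CpGs."""
    fg = set.intersection(*(result.methylated_sets[s] for s in result.truth.stages))
    universe = {s.site for s in result.stage_sites[result.truth.stages[0]]}
    return kmers.enrichment_table(
        result.genome.sequences, fg, all_sites=sorted(universe | fg), k=k
    )
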