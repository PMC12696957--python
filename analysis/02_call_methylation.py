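#!/usr/bin/env python
"""Spike-calibrated methylation calling per developmental stage.

Reads the simulated cytosine reports back from results/data/, estimates
the bisulfite non-conversion rate from the lambda spike, pools replicates
per stage, destrands, filters to coverage >= 10, runs the binomial test
with BH FDR < 0.05, and summarises: per-stage methylated fractions,
genomic feature distribution, the all-stage overlap, and the exon-rank
methylation profile. Tables go to results/.
"""

from pathlib import Path

import pandas as pd

from methylmorph import calling, formats

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent
STAGES = formats.STAGES


def main() -> None:
    genome = formats.read_fasta(DATA / "genome.fa")
    annotation = formats.read_gff3(DATA / "annotation.gff3")
    est = calling.estimate_nonconversion(
        formats.read_cytosine_report(DATA / "lambda.cx.tsv")
    )
    print(f"non-conversion rate: {est.rate:.5f} "
          f"(+-{est.se:.5f}, {est.total_coverage} lambda calls)")

    methylated: dict[str, set] = {}
    rows = []
    for stage in STAGES:
        reps = [
            formats.read_cytosine_report(DATA / f"{stage}_{i}.cx.tsv")
            for i in (1, 2, 3)
        ]
        pooled = calling.pool_replicates(reps)
        sites = calling.filter_coverage(calling.destrand(pooled, genome), min_cov=10)
        calls = calling.call_methylated(sites, est.rate, alpha=0.05)
        meth_sites = [c for c in calls if c.methylated]
        methylated[stage] = {c.site.site for c in meth_sites}
        feats = calling.assign_features([c.site for c in meth_sites], annotation)
        dist = pd.Series([f.category for f in feats]).value_counts()
        rows.append(
            {"stage": stage, "tested": len(sites), "methylated": len(meth_sites),
             "pct": 100 * len(meth_sites) / len(sites),
             **{cat: int(dist.get(cat, 0))
                for cat in ("exon", "intron", "promoter", "intergenic")}}
        )
        if stage == STAGES[0]:
            prof = calling.exon_number_profile(calls, annotation, max_rank=6)
            pd.Series(prof, name="mean_meth_pct").rename_axis("exon_rank").to_csv(
                OUT / "exon_profile_embryo.tsv", sep="\t"
            )
    summary = pd.DataFrame(rows).set_index("stage")
    summary.to_csv(OUT / "stage_methylation_summary.tsv", sep="\t")
    print(summary.to_string())

    regions, uniques = calling.stage_overlap(methylated)
    core = regions[frozenset(STAGES)]
    print(f"\nCpGs methylated in all {len(STAGES)} stages: {core} "
          f"(union {sum(regions.values())}); "
          f"stage-unique: { {s: len(u) for s, u in uniques.items()} }")
    overlap = pd.DataFrame(
        [{"stages": "+".join(sorted(k)), "n_sites": v} for k, v in regions.items()]
    ).sort_values("n_sites", ascending=False)
    overlap.to_csv(OUT / "stage_overlap.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": c, "pos": p, "stage": s} for s, sites in methylated.items()
         for c, p in sorted(sites)]
    ).to_csv(OUT / "methylated_sites.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
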