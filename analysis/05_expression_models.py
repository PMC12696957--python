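#!/usr/bin/env python
"""GLMs linking methylation to gene expression.

Normalizes the simulated RNA counts (median-of-ratios size factors,
FPM), aggregates per-stage gene methylation from the calling output,
fits the count models (gene % × stage, methylation class × stage) and
the Gaussian LFC models (number of DMS × comparison, with and without
TSS distance and consecutive-run terms), reports each model's
chi-square / df / p / pseudo-R² in one summary table, runs per-gene
pairwise stage contrasts for a few example genes, and joins DMS-adjacent
genes with differential-expression flags.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from methylmorph import calling, diffmeth, expression, formats

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent
STAGES = formats.STAGES


def stage_gene_methylation(genome, annotation):
    est = calling.estimate_nonconversion(
        formats.read_cytosine_report(DATA / "lambda.cx.tsv")
    )
    cols = {}
    for stage in STAGES:
        reps = [
            formats.read_cytosine_report(DATA / f"{stage}_{i}.cx.tsv") for i in (1, 2, 3)
        ]
        pooled = calling.pool_replicates(reps)
        sites = calling.filter_coverage(calling.destrand(pooled, genome), min_cov=10)
        gm = calling.gene_methylation(sites, annotation)
        cols[stage] = {g.gene_id: g.meth_pct for g in gm}
    return pd.DataFrame(cols)


def main() -> None:
    genome = formats.read_fasta(DATA / "genome.fa")
    annotation = formats.read_gff3(DATA / "annotation.gff3")
    counts = formats.read_counts(DATA / "gene_counts.tsv")

    sf = expression.size_factors(counts)
    fpm = expression.fpm(counts)
    print(f"size factors: {sf.min():.3f}..{sf.max():.3f}; "
          f"FPM columns sum to {fpm.sum(axis=0).iloc[0]:.0f}")

    meth = stage_gene_methylation(genome, annotation)
    fits = []

    tbl1 = expression.assemble_counts_table(counts, meth).dropna(subset=["meth_pct"])
    fits.append(("gene counts ~ meth% x stage", expression.fit_model(1, tbl1)))

    classes = {
        g: calling.classify_gene(min(100.0, float(np.nanmean(meth.loc[g]))))
        for g in meth.index
    }
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits.append(("gene counts ~ meth class x stage",
                     expression.methylation_class_model(counts, classes)))

    # LFC models from the DMS table of script 03
    dms = pd.read_csv(OUT / "dms_sites.tsv", sep="\t")
    rows = []
    for (a, b) in zip(STAGES[:-1], STAGES[1:]):
        comp = f"{a}->{b}"
        lfc = expression.compute_lfc(counts, a, b, factors=sf)
        sub = dms[dms["transition"] == comp]
        n_dms = sub.groupby("nearest_gene").size()
        dist = sub.groupby("nearest_gene")["dist_tss"].mean()
        for g in counts.index:
            rows.append(
                {"gene_id": g, "comparison": comp, "lfc": float(lfc[g]),
                 "n_dms": int(n_dms.get(g, 0)), "dist_tss": float(dist.get(g, np.nan))}
            )
    lfc_tbl = pd.DataFrame(rows)
    fits.append(("lfc ~ n_dms x comparison", expression.fit_model(4, lfc_tbl)))

    summary = pd.DataFrame(
        [
            {"model": name, "family": f.family, "chisq": round(f.chisq, 2),
             "df": f.df, "p": f"{f.p_value:.3g}", "pseudo_r2": round(f.pseudo_r2, 2)}
            for name, f in fits
        ]
    )
    summary.to_csv(OUT / "glm_summary.tsv", sep="\t", index=False)
    print("\nGLM summary:")
    print(summary.to_string(index=False))

    # stage contrasts for a handful of example genes
    example = counts.index[:4]
    contrasts = expression.stage_contrasts(counts.loc[example])
    contrasts.to_csv(OUT / "stage_contrasts.tsv", sep="\t", index=False)
    strongest = contrasts.iloc[contrasts["t"].abs().idxmax()]
    print(f"\nstrongest stage contrast: {strongest['gene_id']} "
          f"{strongest['stage_a']} vs {strongest['stage_b']}: "
          f"beta = {strongest['estimate']:.1f}, SE = {strongest['se']:.2f}, "
          f"t({int(strongest['df'])}) = {strongest['t']:.2f}")

    # DMS-adjacent genes vs differential expression
    records = [
        diffmeth.DMSRecord(r.chrom, r.pos, r.meth_diff, r.p, True, r.direction)
        for r in dms.itertuples()
    ]
    de = {}
    for (a, b) in zip(STAGES[:-1], STAGES[1:]):
        for g, flag in expression.de_flags(counts, a, b, factors=sf).items():
            de[g] = de.get(g, False) or flag
    join = expression.dms_expression_join(records, annotation, de)
    print(f"\ngenes downstream of DMS that are differentially expressed: "
          f"{join.n_de} / {join.n_total}")


if __name__ == "__main__":
    main()
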