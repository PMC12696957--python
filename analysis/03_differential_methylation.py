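#!/usr/bin/env python
"""Pairwise differential methylation across stage transitions.

Reads the per-replicate reports, destrands each replicate separately,
keeps CpGs covered >= 10 in every replicate of both stages, runs the
per-site logistic likelihood-ratio test (DMS: p < 0.0125 and |delta| >
10 points), summarises hyper/hypo counts per transition, finds runs of
consecutive DMS, and computes the sample PCA. Tables go to results/.
"""

from pathlib import Path

import pandas as pd

from methylmorph import calling, diffmeth, formats

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent
STAGES = formats.STAGES


def main() -> None:
    genome = formats.read_fasta(DATA / "genome.fa")
    annotation = formats.read_gff3(DATA / "annotation.gff3")
    rep_sites = {
        stage: [
            calling.destrand(
                formats.read_cytosine_report(DATA / f"{stage}_{i}.cx.tsv"), genome
            )
            for i in (1, 2, 3)
        ]
        for stage in STAGES
    }

    # PCA over CpGs covered in every sample
    maps = {
        f"{stage}_{i+1}": {s.site: s.meth_pct for s in reps if s.coverage >= 10}
        for stage, repl in rep_sites.items()
        for i, reps in enumerate(repl)
    }
    shared = sorted(set.intersection(*(set(m) for m in maps.values())))
    matrix = pd.DataFrame({k: [m[s] for s in shared] for k, m in maps.items()})
    scores, var_frac = diffmeth.pca_samples(matrix)
    scores[["PC1", "PC2"]].to_csv(OUT / "pca_samples.tsv", sep="\t")
    print(f"PCA over {len(shared)} shared CpGs: "
          f"PC1 {100 * var_frac[0]:.1f}%, PC2 {100 * var_frac[1]:.1f}% of variance")

    rows, all_records = [], {}
    for a, b in zip(STAGES[:-1], STAGES[1:]):
        map_a = diffmeth.replicate_site_map(rep_sites[a], min_cov=10)
        map_b = diffmeth.replicate_site_map(rep_sites[b], min_cov=10)
        records = diffmeth.compare_stages(map_a, map_b)
        all_records[(a, b)] = records
        n, h1, h2 = diffmeth.transition_summary(records)
        order: dict[str, list[int]] = {}
        for chrom, pos in sorted(set(map_a) & set(map_b)):
            order.setdefault(chrom, []).append(pos)
        runs = diffmeth.consecutive_runs(records, order, annotation)
        rows.append(
            {"transition": f"{a}->{b}", "tested": sum(len(v) for v in order.values()),
             "dms": n, f"hyper_{a}": h1, f"hyper_{b}": h2, "runs_ge2": len(runs)}
        )
        print(f"{a}->{b}: {n} DMS ({h1} hyper in {a}, {h2} hyper in {b}), "
              f"{len(runs)} consecutive runs")
    pd.DataFrame(rows).to_csv(OUT / "dms_transitions.tsv", sep="\t", index=False)

    dms_rows = [
        {"transition": f"{a}->{b}", "chrom": r.chrom, "pos": r.pos,
         "meth_diff": r.meth_diff, "p": r.p_value, "significant": r.significant,
         "direction": r.direction,
         **dict(zip(("nearest_gene", "dist_tss"),
                    diffmeth.distance_to_tss(r.site, annotation) or (None, None)))}
        for (a, b), records in all_records.items()
        for r in records
        if r.significant
    ]
    pd.DataFrame(dms_rows).to_csv(OUT / "dms_sites.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
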