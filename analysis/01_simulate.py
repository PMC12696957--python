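#!/usr/bin/env python
"""Generate the synthetic developmental-methylome study data.

Writes a toy genome (FASTA + GFF3), per-stage × replicate CpG cytosine
reports, the lambda-spike report, gene/exon RNA count tables and the full
ground truth under results/data/. All downstream analysis scripts read
from that directory, so the whole analysis is reproducible from here.
"""

import json
from pathlib import Path

from methylmorph import formats, pipeline, synthetic

SEED = 1
DATA = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    genome, truth, wgbs = pipeline.simulate_study(
        seed=SEED, n_chrom=2, chrom_len=50_000, gc_frac=0.4, n_genes=16,
        mean_cov=30.0, n_reps=3,
    )

    formats.write_fasta(genome.sequences, DATA / "genome.fa")
    formats.write_gff3(genome.annotation, DATA / "annotation.gff3")
    for stage, reps in wgbs.reports.items():
        for i, rep in enumerate(reps, start=1):
            formats.write_cytosine_report(rep, DATA / f"{stage}_{i}.cx.tsv")
    formats.write_cytosine_report(wgbs.lambda_report, DATA / "lambda.cx.tsv")

    gene_counts, exon_counts = synthetic.simulate_expression(
        truth, genome.annotation, n_reps=3, nb_dispersion=0.1, seed=SEED + 3
    )
    formats.write_table(gene_counts.rename_axis("gene_id"), DATA / "gene_counts.tsv")
    formats.write_table(exon_counts.rename_axis("exon_id"), DATA / "exon_counts.tsv")

    truth_json = {
        "seed": SEED,
        "nonconversion_rate": truth.nonconversion_rate,
        "stages": list(truth.stages),
        "always_methylated_sites": sorted(map(list, truth.always_methylated_sites)),
        "stage_unique_sites": {
            s: sorted(map(list, v)) for s, v in truth.stage_unique_sites.items()
        },
        "dms_truth": {
            f"{a}__{b}": {f"{c}:{p}": d for (c, p), d in sites.items()}
            for (a, b), sites in truth.dms_truth.items()
        },
        "expression_coupling": truth.expression_coupling,
        "stage_offsets": truth.stage_offsets,
    }
    (DATA / "truth.json").write_text(json.dumps(truth_json, indent=1))

    n_cpg = len(truth.cpg_sites)
    print(f"wrote study to {DATA}")
    print(f"  genome: {len(genome.sequences)} chromosomes, {n_cpg} CpG dyads, "
          f"{len(genome.annotation.genes)} genes")
    print(f"  methylome: {len(truth.always_methylated_sites)} always-methylated CpGs "
          f"({100 * len(truth.always_methylated_sites) / n_cpg:.2f}%), "
          f"stage-unique sets "
          f"{ {s: len(v) for s, v in truth.stage_unique_sites.items()} }")
    print(f"  bisulfite: 5 stages x 3 replicates at mean coverage 30, "
          f"non-conversion rate {truth.nonconversion_rate}")


if __name__ == "__main__":
    main()
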