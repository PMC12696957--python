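"""CpG-centered k-mer extraction and Fisher-test enrichment.

A CpG-centered k-mer is the plus-strand window of even length ``k`` whose
central two bases are the C and G of the dyad. Enrichment of a k-mer among
a foreground site set (e.g. CpGs methylated in every stage) relative to a
background set is summarised by the fold change of per-site rates, its
log2, the Haldane–Anscombe-corrected odds ratio (0.5 added to every cell),
a two-sided Fisher exact p-value and Benjamini–Hochberg q-values across
all k-mers tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

Site = tuple[str, int]


@dataclass(frozen=True)
class KmerEnrichment:
    kmer: str
    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    fold: float  # NaN when the background rate is 0
    log2_fold: float
    or_h: float
    p_value: float
    q_value: float = float("nan")


def extract_kmer(
    genome: Mapping[str, str], site: Site, k: int = 6
) -> str | None:
    """Plus-strand k-mer centered on the CpG dyad at ``site``.

    ``site`` is (chrom, 1-based position of the + strand C); positions
    k/2-1 and k/2 (0-based) of the returned string are the C and G.
    Returns None when the window runs off the chromosome or contains a
    base outside ACGT. Raises ValueError when the site is not a CpG in the
    genome.
    """
    if k < 2 or k % 2 != 0:
        raise ValueError("k must be an even integer >= 2")
    chrom, pos = site
    seq = genome[chrom]
    i = pos - 1
    if seq[i : i + 2].upper() != "CG":
        raise ValueError(f"site {chrom}:{pos} is not a CpG dyad in the genome")
    flank = k // 2 - 1
    lo, hi = i - flank, i + 2 + flank
    if lo < 0 or hi > len(seq):
        return None
    kmer = seq[lo:hi].upper()
    if any(b not in "ACGT" for b in kmer):
        return None
    return kmer


def count_contexts(
    genome: Mapping[str, str],
    fg_sites: Iterable[Site],
    bg_sites: Iterable[Site],
    k: int = 6,
) -> tuple[dict[str, tuple[int, int]], int, int]:
    """Per-k-mer (foreground, background) site counts plus totals.

    Totals count sites with a valid window; each such site contributes
    exactly one occurrence. Raises ValueError on an empty foreground or
    background.
    """
    fg_sites, bg_sites = list(fg_sites), list(bg_sites)
    if not fg_sites or not bg_sites:
        raise ValueError("foreground and background site sets must be non-empty")
    counts: dict[str, list[int]] = {}
    totals = [0, 0]
    for slot, sites in enumerate((fg_sites, bg_sites)):
        for site in sites:
            kmer = extract_kmer(genome, site, k=k)
            if kmer is None:
                continue
            totals[slot] += 1
            counts.setdefault(kmer, [0, 0])[slot] += 1
    return (
        {kmer: (c[0], c[1]) for kmer, c in counts.items()},
        totals[0],
        totals[1],
    )


def enrich(fg_count: int, fg_total: int, bg_count: int, bg_total: int) -> KmerEnrichment:
    """Enrichment statistics for one k-mer's 2×2 table.

    fold = (fg rate)/(bg rate), NaN if the background rate is 0; the
    Haldane odds ratio and Fisher p remain defined in that case.
    """
    if fg_total <= 0 or bg_total <= 0:
        raise ValueError("totals must be positive")
    if bg_count > 0:
        fold = (fg_count / fg_total) / (bg_count / bg_total)
        log2_fold = math.log2(fold) if fold > 0 else float("-inf")
    else:
        fold = float("nan")
        log2_fold = float("nan")
    or_h = ((fg_count + 0.5) * (bg_total - bg_count + 0.5)) / (
        (fg_total - fg_count + 0.5) * (bg_count + 0.5)
    )
    table = [[fg_count, fg_total - fg_count], [bg_count, bg_total - bg_count]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return KmerEnrichment("", fg_count, fg_total, bg_count, bg_total,
                          fold, log2_fold, or_h, p)


def enrichment_table(
    genome: Mapping[str, str],
    fg_sites: Iterable[Site],
    bg_sites: Iterable[Site] | None = None,
    all_sites: Iterable[Site] | None = None,
    k: int = 6,
) -> pd.DataFrame:
    """Full enrichment scan, sorted by p-value, with BH q-values.

    The default background is the complement: every site in ``all_sites``
    not in the foreground. Pass ``bg_sites`` explicitly to override.
    """
    fg = set(fg_sites)
    if bg_sites is None:
        if all_sites is None:
            raise ValueError("provide bg_sites or all_sites")
        bg_sites = [s for s in all_sites if s not in fg]
    counts, fg_total, bg_total = count_contexts(genome, fg, bg_sites, k=k)
    rows = []
    for kmer, (fgc, bgc) in sorted(counts.items()):
        e = enrich(fgc, fg_total, bgc, bg_total)
        rows.append(
            {"kmer": kmer, "fg_count": fgc, "fg_total": fg_total,
             "bg_count": bgc, "bg_total": bg_total, "fold": e.fold,
             "log2_fold": e.log2_fold, "or_h": e.or_h, "p": e.p_value}
        )
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("p", kind="stable").reset_index(drop=True)
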