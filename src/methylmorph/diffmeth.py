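"""Stage-pairwise differential methylation of individual CpGs.

Each coverage-filtered CpG is tested with a per-site logistic regression
on replicate-level (methylated, coverage) observations — a binomial GLM
with a group indicator — using a likelihood-ratio chi-square (1 df)
against the intercept-only null. A site is a differentially methylated
site (DMS) when p < 0.0125 (0.05 Bonferroni-corrected across the four
stage transitions) and the pooled methylation difference exceeds 10
percentage points, both strict. Helpers classify hyper/hypo direction,
summarise transitions, find runs of consecutive DMS, compute distances to
the nearest transcription start site, and run a sample PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .calling import CpGSite
from .formats import GenomeAnnotation

Site = tuple[str, int]

P_THRESHOLD_DEFAULT = 0.05 / 4  # 0.0125: Bonferroni over the 4 stage transitions
DIFF_THRESHOLD_DEFAULT = 10.0


@dataclass(frozen=True)
class DiffResult:
    chrom: str
    pos: int
    meth_a: float  # pooled % in stage A
    meth_b: float  # pooled % in stage B
    meth_diff: float  # meth_b - meth_a, percentage points
    p_value: float


@dataclass(frozen=True)
class DMSRecord:
    chrom: str
    pos: int
    meth_diff: float
    p_value: float
    significant: bool
    direction: str  # hyper_stage1 / hyper_stage2

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class DMSRun:
    chrom: str
    positions: tuple[int, ...]
    nearest_gene: str | None = None
    dist_tss: int | None = None

    @property
    def run_length(self) -> int:
        return len(self.positions)


def _pooled_pct(obs: Sequence[tuple[int, int]]) -> float:
    meth = sum(m for m, _ in obs)
    cov = sum(c for _, c in obs)
    return 100.0 * meth / cov if cov else float("nan")


def _binomial_deviance(obs: np.ndarray, p: np.ndarray) -> float:
    """Deviance of binomial observations (meth, cov) at fitted probs p."""
    meth, cov = obs[:, 0], obs[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(meth > 0, meth * np.log(meth / (cov * p)), 0.0)
        fail = cov - meth
        t2 = np.where(fail > 0, fail * np.log(fail / (cov * (1 - p))), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _irls_logistic(
    meth: np.ndarray, cov: np.ndarray, X: np.ndarray,
    tol: float = 1e-10, max_iter: int = 50,
) -> float:
    """Binomial-logit IRLS; returns the model deviance.

    Under complete separation the coefficients diverge but the deviance
    converges, which is all the likelihood-ratio test needs; iteration
    stops on a relative deviance change below ``tol``.
    """
    beta = np.zeros(X.shape[1])
    prev = np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = cov * p * (1 - p)
        if np.all(w < 1e-12):
            break
        z = eta + (meth - cov * p) / np.maximum(w, 1e-12)
        WX = X * w[:, None]
        beta = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)[0]
        dev = _binomial_deviance(
            np.column_stack([meth, cov]),
            np.clip(1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30))), 1e-15, 1 - 1e-15),
        )
        if abs(prev - dev) <= tol * (abs(dev) + 0.1):
            return dev
        prev = dev
    return prev if np.isfinite(prev) else float("nan")


def logistic_diff(
    obs_a: Sequence[tuple[int, int]],
    obs_b: Sequence[tuple[int, int]],
) -> tuple[float, float]:
    """Per-site logistic regression between two stages.

    ``obs_a``/``obs_b`` are replicate-level (count_meth, coverage) pairs.
    Fits logit(π) = β0 + β1·group by IRLS and tests β1 = 0 by the
    likelihood-ratio chi-square with 1 df; with one replicate per group
    this equals the 2×2 G-test. Returns (meth_diff = pooled %B − pooled
    %A, p).

    Degenerate inputs (all-zero or all-full counts in both groups) give
    p = 1. If the IRLS fit fails, falls back to a chi-square test on the
    pooled 2×2 table with a warning.
    """
    obs_a = [(m, c) for m, c in obs_a if c > 0]
    obs_b = [(m, c) for m, c in obs_b if c > 0]
    if not obs_a or not obs_b:
        raise ValueError("need at least one covered replicate per stage")
    diff = _pooled_pct(obs_b) - _pooled_pct(obs_a)

    arr = np.array(obs_a + obs_b, dtype=float)
    meth, cov = arr[:, 0], arr[:, 1]
    group = np.array([0.0] * len(obs_a) + [1.0] * len(obs_b))

    total_meth = meth.sum()
    if total_meth == 0 or total_meth == cov.sum():
        return diff, 1.0  # no information against the null
    p_null = total_meth / cov.sum()
    dev_null = _binomial_deviance(arr, np.full(len(arr), p_null))

    X = np.column_stack([np.ones_like(group), group])
    dev_full = _irls_logistic(meth, cov, X)
    if not np.isfinite(dev_full):
        warnings.warn("logistic IRLS failed; falling back to pooled 2x2 chi-square")
        table = np.array(
            [
                [sum(m for m, _ in obs_a), sum(c - m for m, c in obs_a)],
                [sum(m for m, _ in obs_b), sum(c - m for m, c in obs_b)],
            ]
        )
        return diff, float(stats.chi2_contingency(table, correction=False)[1])

    lr = max(0.0, dev_null - dev_full)
    return diff, float(stats.chi2.sf(lr, df=1))


def logistic_diff_glm(
    obs_a: Sequence[tuple[int, int]],
    obs_b: Sequence[tuple[int, int]],
) -> tuple[float, float]:
    """Same contract as :func:`logistic_diff` via an explicit IRLS GLM fit.

    Kept as an independently-routed implementation; used for
    cross-checking. Falls back to a chi-square test on the pooled 2×2
    table when the IRLS fit fails to converge.
    """
    obs_a = [(m, c) for m, c in obs_a if c > 0]
    obs_b = [(m, c) for m, c in obs_b if c > 0]
    diff = _pooled_pct(obs_b) - _pooled_pct(obs_a)
    endog = np.array(
        [[m, c - m] for m, c in obs_a] + [[m, c - m] for m, c in obs_b], dtype=float
    )
    group = np.array([0.0] * len(obs_a) + [1.0] * len(obs_b))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.GLM(endog, sm.add_constant(group), family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((len(group), 1)), family=sm.families.Binomial()).fit()
        lr = max(0.0, null.deviance - full.deviance)
        return diff, float(stats.chi2.sf(lr, df=1))
    except Exception:
        warnings.warn("logistic fit failed; falling back to pooled 2x2 chi-square")
        table = np.array(
            [
                [sum(m for m, _ in obs_a), sum(c - m for m, c in obs_a)],
                [sum(m for m, _ in obs_b), sum(c - m for m, c in obs_b)],
            ]
        )
        return diff, float(stats.chi2_contingency(table, correction=False)[1])


def diff_site(
    chrom: str,
    pos: int,
    obs_a: Sequence[tuple[int, int]],
    obs_b: Sequence[tuple[int, int]],
) -> DiffResult:
    diff, p = logistic_diff(obs_a, obs_b)
    return DiffResult(chrom, pos, _pooled_pct(obs_a), _pooled_pct(obs_b), diff, p)


def call_dms(
    results: Sequence[DiffResult],
    p_threshold: float = P_THRESHOLD_DEFAULT,
    diff_threshold: float = DIFF_THRESHOLD_DEFAULT,
) -> list[DMSRecord]:
    """Flag DMS: p strictly below threshold AND |Δ| strictly above threshold.

    Direction follows the sign of Δ = %(stage2) − %(stage1):
    hyper_stage2 for positive Δ, hyper_stage1 for negative.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    if not (0 < diff_threshold < 100):
        raise ValueError("diff_threshold must be in (0, 100)")
    out = []
    for r in results:
        sig = (r.p_value < p_threshold) and (abs(r.meth_diff) > diff_threshold)
        direction = "hyper_stage2" if r.meth_diff > 0 else "hyper_stage1"
        out.append(DMSRecord(r.chrom, r.pos, r.meth_diff, r.p_value, sig, direction))
    return out


def compare_stages(
    sites_a: Mapping[Site, Sequence[tuple[int, int]]],
    sites_b: Mapping[Site, Sequence[tuple[int, int]]],
    p_threshold: float = P_THRESHOLD_DEFAULT,
    diff_threshold: float = DIFF_THRESHOLD_DEFAULT,
) -> list[DMSRecord]:
    """Test every site covered in both stages; returns DMS-flagged records
    sorted by (chrom, pos)."""
    shared = sorted(set(sites_a) & set(sites_b))
    results = [
        diff_site(chrom, pos, sites_a[(chrom, pos)], sites_b[(chrom, pos)])
        for chrom, pos in shared
    ]
    return call_dms(results, p_threshold, diff_threshold)


def transition_summary(dms_records: Sequence[DMSRecord]) -> tuple[int, int, int]:
    """(n significant, n hyper in stage 1, n hyper in stage 2)."""
    sig = [r for r in dms_records if r.significant]
    h1 = sum(1 for r in sig if r.direction == "hyper_stage1")
    h2 = sum(1 for r in sig if r.direction == "hyper_stage2")
    return len(sig), h1, h2


def consecutive_runs(
    dms_records: Sequence[DMSRecord],
    tested_site_order: Mapping[str, Sequence[int]],
    annotation: GenomeAnnotation | None = None,
) -> list[DMSRun]:
    """Maximal runs of >= 2 significant sites adjacent in the tested order.

    "Consecutive" means adjacency among the tested (coverage-filtered)
    CpGs of one chromosome, position-sorted; runs never span chromosomes.
    When an annotation is supplied, each run is annotated with the gene
    whose TSS is nearest to the run's first position.
    """
    sig = {r.site for r in dms_records if r.significant}
    runs: list[DMSRun] = []
    for chrom, positions in tested_site_order.items():
        current: list[int] = []
        for pos in list(positions) + [None]:  # sentinel flushes the last run
            if pos is not None and (chrom, pos) in sig:
                current.append(pos)
            else:
                if len(current) >= 2:
                    runs.append(_annotate_run(chrom, current, annotation))
                current = []
    return runs


def _annotate_run(
    chrom: str, positions: list[int], annotation: GenomeAnnotation | None
) -> DMSRun:
    gene = dist = None
    if annotation is not None:
        hit = distance_to_tss((chrom, positions[0]), annotation)
        if hit is not None:
            gene, dist = hit
    return DMSRun(chrom, tuple(positions), gene, dist)


def distance_to_tss(
    site: Site, annotation: GenomeAnnotation
) -> tuple[str, int] | None:
    """Nearest TSS on the same chromosome by absolute distance.

    Ties break toward the lexicographically lower gene id. Returns None
    when the chromosome has no genes.
    """
    chrom, pos = site
    best: tuple[int, str] | None = None
    for g in annotation.genes:
        if g.chrom != chrom:
            continue
        d = abs(pos - g.tss)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    if best is None:
        return None
    return best[1], best[0]


def pca_samples(meth_matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples from a sites × samples methylation-percentage matrix.

    Columns are samples; rows are CpGs covered in every sample. Scores are
    computed by SVD of the sample × site matrix after centering each site.
    Returns (scores on PC1..PCm indexed by sample, variance fractions).
    """
    if meth_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = meth_matrix.T.to_numpy(dtype=float)  # samples x sites
    X = X - X.mean(axis=0, keepdims=True)
    nonconst = np.ptp(X, axis=0) > 0
    if nonconst.sum() < 2:
        raise ValueError("need at least 2 non-constant sites")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    var_frac = S**2 / np.sum(S**2)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=meth_matrix.columns, columns=cols), var_frac


# ---------------------------------------------------------------------------
# Convenience: replicate-level site maps from destranded reports
# ---------------------------------------------------------------------------

def replicate_site_map(
    replicate_sites: Sequence[Sequence[CpGSite]], min_cov: int = 10
) -> dict[Site, list[tuple[int, int]]]:
    """Sites covered >= min_cov in *every* replicate, with per-replicate
    (meth, coverage) observations."""
    maps = []
    for rep in replicate_sites:
        maps.append(
            {s.site: (s.count_meth, s.coverage) for s in rep if s.coverage >= min_cov}
        )
    shared = set.intersection(*(set(m) for m in maps)) if maps else set()
    return {site: [m[site] for m in maps] for site in sorted(shared)}
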