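"""GLMs linking methylation to expression, plus count normalization.

Six model families relate methylation summaries to RNA counts or to
log2 fold changes (LFC) between consecutive developmental stages:

1. gene counts ~ gene methylation % × stage        (quasi-Poisson)
2. exon counts ~ exon methylation % × stage        (quasi-Poisson)
3. gene counts ~ methylation class × stage         (quasi-Poisson)
4. LFC ~ number of DMS × comparison                (Gaussian)
5. LFC ~ TSS distance × TF × comparison            (Gaussian)
6. LFC ~ TSS distance × comparison × consecutive   (Gaussian)

Count models use a log link with a Pearson-estimated dispersion; the
model test is the dispersion-scaled deviance difference against the
intercept-only null (chi-square). Goodness of fit is reported as the
deviance-explained percentage, 100·(1 − D_full/D_null).

Normalization helpers re-implement median-of-ratios size factors,
fragments per million (FPM), and pseudocounted LFCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .diffmeth import DMSRecord, distance_to_tss
from .formats import GenomeAnnotation, sample_stage

FORMULAS: dict[int, tuple[str, str]] = {
    1: ("counts ~ meth_pct * stage", "quasipoisson"),
    2: ("counts ~ meth_pct * stage", "quasipoisson"),
    3: ("counts ~ meth_class * stage", "quasipoisson"),
    4: ("lfc ~ n_dms * comparison", "gaussian"),
    5: ("lfc ~ dist_tss * tf * comparison", "gaussian"),
    6: ("lfc ~ dist_tss * comparison * n_consecutive", "gaussian"),
}


@dataclass
class GLMFit:
    formula_id: int
    formula: str
    family: str  # quasipoisson / gaussian
    params: pd.Series
    bse: pd.Series
    dispersion: float
    chisq: float
    df: int
    p_value: float
    pseudo_r2: float  # percent of deviance explained
    n_obs: int


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with nonzero counts in every sample, each sample's factor is
    the median of count/geometric-mean ratios. Raises when no gene is
    nonzero everywhere.
    """
    pos = counts[(counts > 0).all(axis=1)]
    if pos.empty:
        raise ValueError("no gene has nonzero counts in all samples")
    geo_mean = np.exp(np.log(pos).mean(axis=1))
    ratios = pos.div(geo_mean, axis=0)
    return ratios.median(axis=0).rename("size_factor")


def fpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per million mapped reads.

    Plain variant (factors=None): counts scaled so each column sums to
    1e6. Robust variant: divides by a size-factor-scaled library size,
    sf_s · mean_s(lib_s / sf_s), so factor-adjusted columns share one
    effective library size.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    if factors is None:
        denom = lib
    else:
        denom = factors * float((lib / factors).mean())
    return counts.div(denom, axis=1) * 1e6


def compute_lfc(
    counts: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 fold change stage_b over stage_a.

    lfc = log2((mean normalized count in b + pc) / (mean in a + pc)).
    Antisymmetric in the two stages by construction.
    """
    norm = counts.div(factors, axis=1) if factors is not None else counts.astype(float)
    cols_a = [c for c in counts.columns if sample_stage(c) == stage_a]
    cols_b = [c for c in counts.columns if sample_stage(c) == stage_b]
    if not cols_a or not cols_b:
        raise ValueError(f"stages {stage_a!r}/{stage_b!r} missing from count matrix")
    mean_a = norm[cols_a].mean(axis=1)
    mean_b = norm[cols_b].mean(axis=1)
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount)).rename("lfc")


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

def fit_model(formula_id: int, table: pd.DataFrame) -> GLMFit:
    """Fit one of the six methylation–expression models.

    Quasi-Poisson models: log-link Poisson IRLS with Pearson dispersion;
    the model chi-square is (D_null − D_full)/dispersion on the model df.
    Gaussian models: least squares, chi-square from the residual-sum
    difference scaled by the full model's mean squared error. Categorical
    predictors are dummy-coded against the alphabetically first level.
    """
    if formula_id not in FORMULAS:
        raise ValueError(f"unknown formula id {formula_id}")
    formula, family = FORMULAS[formula_id]
    missing = [
        v for v in _formula_vars(formula) if v not in table.columns
    ]
    if missing:
        raise ValueError(f"table lacks columns {missing} for model {formula_id}")

    if family == "quasipoisson":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.glm(formula, data=table, family=sm.families.Poisson()).fit(
                maxiter=100, tol=1e-8
            )
            null = smf.glm(
                formula.split("~")[0] + "~ 1", data=table, family=sm.families.Poisson()
            ).fit()
        if not full.converged:
            raise RuntimeError(
                f"quasi-Poisson IRLS did not converge in {full.fit_history['iteration']} iterations"
            )
        dispersion = float(full.pearson_chi2 / full.df_resid)
        dev_full, dev_null = float(full.deviance), float(null.deviance)
        df = int(full.df_model - null.df_model)
        chisq = (dev_null - dev_full) / dispersion if dispersion > 0 else float("inf")
        bse = full.bse * np.sqrt(dispersion)  # quasi-likelihood SEs
    else:
        full = smf.ols(formula, data=table).fit()
        null = smf.ols(formula.split("~")[0] + "~ 1", data=table).fit()
        dev_full, dev_null = float(full.ssr), float(null.ssr)
        dispersion = dev_full / full.df_resid if full.df_resid > 0 else float("nan")
        df = int(full.df_model - null.df_model)
        chisq = (dev_null - dev_full) / dispersion if dispersion > 0 else float("inf")
        bse = full.bse

    p = float(stats.chi2.sf(chisq, df)) if np.isfinite(chisq) else 0.0
    pseudo_r2 = 100.0 * (1.0 - dev_full / dev_null) if dev_null > 0 else float("nan")
    return GLMFit(
        formula_id=formula_id,
        formula=formula,
        family=family,
        params=full.params,
        bse=bse,
        dispersion=dispersion,
        chisq=float(chisq),
        df=df,
        p_value=p,
        pseudo_r2=float(pseudo_r2),
        n_obs=int(full.nobs),
    )


def _formula_vars(formula: str) -> list[str]:
    rhs = formula.split("~")[1]
    lhs = formula.split("~")[0]
    names = set()
    for part in rhs.replace("*", "+").replace(":", "+").split("+"):
        part = part.strip()
        if part and part != "1":
            names.add(part)
    names.add(lhs.strip())
    return sorted(names)


def methylation_class_model(
    counts: pd.DataFrame, classes: Mapping[str, str]
) -> GLMFit:
    """Model 3: counts ~ methylation class × stage, quasi-Poisson.

    ``classes`` maps gene id → class from the calling module; genes
    without a class are dropped, and absent class levels simply do not
    appear in the design (with a warning).
    """
    table = assemble_counts_table(counts, {g: np.nan for g in counts.index})
    table["meth_class"] = table["gene_id"].map(dict(classes))
    table = table.dropna(subset=["meth_class"])
    present = set(table["meth_class"])
    from .calling import METH_CLASSES

    absent = [c for c in METH_CLASSES if c not in present]
    if absent:
        warnings.warn(f"methylation classes absent from data: {absent}")
    return fit_model(3, table)


def assemble_counts_table(
    counts: pd.DataFrame, meth_pct: Mapping[str, float] | pd.DataFrame
) -> pd.DataFrame:
    """Long gene × sample table with counts, stage and methylation %.

    ``meth_pct`` is either one percentage per gene or a gene × stage
    DataFrame (stage-specific percentages).
    """
    rows = []
    for gene in counts.index:
        for sample in counts.columns:
            stage = sample_stage(sample)
            if isinstance(meth_pct, pd.DataFrame):
                m = float(meth_pct.loc[gene, stage]) if gene in meth_pct.index else np.nan
            else:
                m = float(meth_pct.get(gene, np.nan))
            rows.append(
                {"gene_id": gene, "sample": sample, "stage": stage,
                 "counts": int(counts.loc[gene, sample]), "meth_pct": m}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage contrasts for selected genes (methylation-machinery expression)
# ---------------------------------------------------------------------------

def stage_contrasts(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise stage contrasts per gene from the full-interaction linear
    model counts ~ condition × gene.

    The cell-mean parameterisation makes each contrast a difference of
    stage means within a gene; the standard error uses the pooled residual
    variance of the full model, t on the residual df, unadjusted p.
    Returns rows (gene_id, stage_a, stage_b, estimate, se, t, df, p).
    """
    stages = sorted({sample_stage(c) for c in counts.columns})
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    cells: dict[tuple[str, str], np.ndarray] = {}
    for gene in counts.index:
        for stage in stages:
            cols = [c for c in counts.columns if sample_stage(c) == stage]
            vals = counts.loc[gene, cols].to_numpy(dtype=float)
            if len(vals) < 2:
                raise ValueError("need >= 2 replicates per stage per gene")
            cells[(gene, stage)] = vals
    n_total = sum(len(v) for v in cells.values())
    df_resid = n_total - len(cells)
    if df_resid <= 0:
        raise ValueError("singular fit: no residual degrees of freedom")
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in cells.values())
    mse = sse / df_resid

    rows = []
    for gene in counts.index:
        for i, a in enumerate(stages):
            for b in stages[i + 1 :]:
                va, vb = cells[(gene, a)], cells[(gene, b)]
                est = float(va.mean() - vb.mean())
                se = float(np.sqrt(mse * (1 / len(va) + 1 / len(vb))))
                t = est / se if se > 0 else float("inf")
                p = 2 * float(stats.t.sf(abs(t), df_resid)) if se > 0 else (1.0 if est == 0 else 0.0)
                if se == 0 and est == 0:
                    t, p = 0.0, 1.0
                rows.append(
                    {"gene_id": gene, "stage_a": a, "stage_b": b,
                     "estimate": est, "se": se, "t": t, "df": df_resid, "p": p}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Differential-expression flags and the DMS/DE join
# ---------------------------------------------------------------------------

def de_flags(
    counts: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    factors: pd.Series | None = None,
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Simple per-gene differential-expression call between two stages.

    Wald t-test on log2(normalized count + 1) replicate values; a gene is
    flagged when p < alpha. A deliberately plain screen used only to
    label genes for the DMS/expression join.
    """
    norm = counts.div(factors, axis=1) if factors is not None else counts.astype(float)
    cols_a = [c for c in counts.columns if sample_stage(c) == stage_a]
    cols_b = [c for c in counts.columns if sample_stage(c) == stage_b]
    la = np.log2(norm[cols_a] + 1.0)
    lb = np.log2(norm[cols_b] + 1.0)
    out = {}
    for gene in counts.index:
        a, b = la.loc[gene].to_numpy(), lb.loc[gene].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            out[gene] = False
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        out[gene] = bool(p < alpha)
    return out


@dataclass
class DmsExpressionJoin:
    n_de: int
    n_total: int
    table: pd.DataFrame

    @property
    def fraction(self) -> float:
        return self.n_de / self.n_total


def dms_expression_join(
    dms_records: Sequence[DMSRecord],
    annotation: GenomeAnnotation,
    de: Mapping[str, bool],
) -> DmsExpressionJoin:
    """Fraction of genes downstream of significant DMS that are
    differentially expressed.

    "Downstream" gene = the gene whose TSS is nearest to the DMS. Raises
    on an empty denominator (no significant DMS maps to a gene).
    """
    genes: set[str] = set()
    for r in dms_records:
        if not r.significant:
            continue
        hit = distance_to_tss(r.site, annotation)
        if hit is not None:
            genes.add(hit[0])
    if not genes:
        raise ValueError("no genes downstream of significant DMS (empty denominator)")
    rows = [{"gene_id": g, "differentially_expressed": bool(de.get(g, False))}
            for g in sorted(genes)]
    table = pd.DataFrame(rows)
    return DmsExpressionJoin(
        n_de=int(table["differentially_expressed"].sum()),
        n_total=len(table),
        table=table,
    )
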