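"""qPCR reference-gene selection and relative quantification.

Implements the full normalization workflow: standard-curve efficiency
(E% from the slope of Cq vs log10 template amount), global-mean screening
with Spearman rank correlation, a from-scratch geNorm (pairwise-variation
M values, iterative exclusion ranking, V_{n/n+1} series), normalization
factors (geometric mean of Cq — the study's rule — or of relative
quantities, the classic geNorm rule), and ddCq fold changes against a
calibrator sample.

Cq matrices are pandas DataFrames with genes as rows and samples as columns.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StandardCurveFit:
    slope: float
    intercept: float
    efficiency_pct: float | None
    r_squared: float


@dataclass
class GlobalMeanResult:
    global_mean: pd.Series          # per-sample mean Cq
    table: pd.DataFrame             # gene, rs, p, retained
    dropped: list = field(default_factory=list)


@dataclass
class GeNormResult:
    final_m: dict                   # gene -> M at exclusion (final pair: 2-gene M)
    exclusion_order: list           # least stable first
    ranking: list                   # most stable first; ranking[0] is the tied final pair
    m_trajectory: list              # per stage: {gene: M}
    v_series: dict | None = None    # n -> V_{n/n+1}
    recommended_n: int | None = None
    recommended_genes: list | None = None


def standard_curve(series) -> StandardCurveFit:
    """Least-squares fit of Cq against log10(relative amount).

    E% = (10^(-1/slope) - 1) x 100.  A non-negative slope leaves the
    efficiency undefined (None).
    """
    amounts = np.asarray(series.amounts, dtype=float)
    cq = np.asarray(series.cq, dtype=float)
    if len(amounts) < 3:
        raise ValueError("at least 3 dilution points are required")
    fit = stats.linregress(np.log10(amounts), cq)
    if fit.slope >= 0:
        eff = None
    else:
        eff = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    return StandardCurveFit(float(fit.slope), float(fit.intercept),
                            eff, float(fit.rvalue ** 2))


def global_mean(cq: pd.DataFrame) -> pd.Series:
    """Mean Cq of all assayed sRNAs per sample."""
    if cq.empty:
        raise ValueError("empty Cq matrix")
    return cq.mean(axis=0)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, chunk: int = 100_000) -> float:
    """Two-sided exact permutation p for the Spearman correlation.

    All n! permutations of one rank vector are enumerated (chunked matrix
    products keep n = 10 tractable); ties are handled by average ranks.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = np.sqrt((cx ** 2).sum() * (cy ** 2).sum())
    if denom == 0:
        return np.nan
    r_obs = float(np.dot(cx, cy) / denom)
    count = total = 0
    perm_iter = itertools.permutations(ry)
    while True:
        block = np.array(list(itertools.islice(perm_iter, chunk)))
        if block.size == 0:
            break
        r_perm = (block - ry.mean()) @ cx / denom
        count += int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        total += block.shape[0]
    return count / total


def spearman_screen(cq: pd.DataFrame, exact_max_n: int = 10):
    """Rank candidate reference genes by correlation with the global mean.

    Returns ``(GlobalMeanResult, retained)``: rs per gene against the
    per-sample global mean Cq (average-rank ties), a two-tailed p (exact
    permutation for <= ``exact_max_n`` samples, t-approximation otherwise),
    and the genes with rs > 0 ordered by descending rs.  Constant genes are
    dropped with a warning.
    """
    if cq.shape[1] < 5:
        warnings.warn("fewer than 5 samples: rank correlations are weakly informative")
    gm = global_mean(cq)
    rows = []
    dropped = []
    for gene, values in cq.iterrows():
        v = values.to_numpy(dtype=float)
        if np.all(v == v[0]):
            dropped.append(gene)
            warnings.warn(f"gene {gene!r} is constant; Spearman rs undefined, dropped")
            continue
        rs = float(stats.spearmanr(v, gm.to_numpy()).statistic)
        if cq.shape[1] <= exact_max_n:
            p = _spearman_exact_p(v, gm.to_numpy())
        else:
            p = float(stats.spearmanr(v, gm.to_numpy()).pvalue)
        rows.append({"gene": gene, "rs": rs, "p": p, "retained": rs > 0})
    table = (pd.DataFrame(rows)
             .sort_values("rs", ascending=False)
             .reset_index(drop=True))
    retained = table.loc[table["retained"], "gene"].tolist()
    return GlobalMeanResult(gm, table, dropped), retained


def relative_quantity(cq: pd.DataFrame) -> pd.DataFrame:
    """Linear-scale quantities Q = 2^(minCq - Cq), per gene (row max = 1)."""
    return cq.apply(lambda row: 2.0 ** (row.min() - row), axis=1)


def _m_values(q: pd.DataFrame) -> pd.Series:
    """geNorm M per gene: mean SD of pairwise log2 quantity ratios."""
    log_q = np.log2(q.to_numpy(dtype=float))
    genes = list(q.index)
    m = {}
    for j, gene in enumerate(genes):
        sds = [np.std(log_q[j] - log_q[k], ddof=1)
               for k in range(len(genes)) if k != j]
        m[gene] = float(np.mean(sds))
    return pd.Series(m)


def genorm_rank(quantities: pd.DataFrame) -> GeNormResult:
    """geNorm stability ranking by iterative exclusion of the highest-M gene.

    The final two genes cannot be separated by the method and are reported
    as a tied most-stable pair.
    """
    if quantities.shape[0] < 3:
        raise ValueError("geNorm requires at least 3 genes")
    if quantities.shape[1] < 2:
        raise ValueError("geNorm requires at least 2 samples")
    if (quantities.to_numpy() <= 0).any():
        raise ValueError("relative quantities must be positive")
    remaining = quantities.copy()
    exclusion = []
    final_m = {}
    trajectory = []
    while remaining.shape[0] > 2:
        m = _m_values(remaining)
        trajectory.append(m.to_dict())
        worst = max(m.index, key=lambda g: (m[g], g))
        final_m[worst] = float(m[worst])
        exclusion.append(worst)
        remaining = remaining.drop(index=worst)
    m = _m_values(remaining)
    trajectory.append(m.to_dict())
    pair = sorted(remaining.index)
    for g in pair:
        final_m[g] = float(m[g])
    ranking = [tuple(pair)] + list(reversed(exclusion))
    return GeNormResult(final_m, exclusion, ranking, trajectory)


def ranked_gene_list(result: GeNormResult) -> list:
    """Flat most-to-least-stable gene list (tied pair first, in name order)."""
    out = list(result.ranking[0])
    out.extend(result.ranking[1:])
    return out


def genorm_v(quantities: pd.DataFrame, ranking=None, threshold: float = 0.15,
             result: GeNormResult | None = None) -> GeNormResult:
    """Pairwise-variation series V_{n/n+1} and the recommended reference set.

    NF_n per sample is the geometric mean of the top-n genes' quantities;
    V_{n/n+1} is the SD over samples of log2(NF_n / NF_{n+1}).  The
    recommended set size is the smallest n >= 2 with V < ``threshold``
    (all genes when no n qualifies).
    """
    if result is None:
        result = genorm_rank(quantities)
    genes = list(ranking) if ranking is not None else ranked_gene_list(result)
    if len(genes) < 3:
        raise ValueError("the V series needs at least 3 ranked genes")
    log_q = np.log2(quantities.loc[genes].to_numpy(dtype=float))
    v_series = {}
    for n in range(2, len(genes)):
        log_nf_n = log_q[:n].mean(axis=0)
        log_nf_n1 = log_q[:n + 1].mean(axis=0)
        v_series[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    recommended = next((n for n, v in sorted(v_series.items()) if v < threshold),
                       len(genes))
    result.v_series = v_series
    result.recommended_n = recommended
    result.recommended_genes = genes[:recommended]
    return result


def normalization_factor(cq_refs: pd.DataFrame, mode: str = "cq-geomean") -> pd.Series:
    """Per-sample normalization factor from the chosen reference genes.

    ``mode='cq-geomean'`` (the study's rule) takes the geometric mean of the
    reference Cq values themselves; ``mode='quantity-geomean'`` (classic
    geNorm) takes the geometric mean of the 2^(-dCq) relative quantities.
    A single reference reduces to that gene.
    """
    if cq_refs.shape[0] < 1:
        raise ValueError("at least one reference gene is required")
    if mode == "cq-geomean":
        return pd.Series(stats.gmean(cq_refs.to_numpy(dtype=float), axis=0),
                         index=cq_refs.columns)
    if mode == "quantity-geomean":
        q = relative_quantity(cq_refs)
        return pd.Series(stats.gmean(q.to_numpy(dtype=float), axis=0),
                         index=cq_refs.columns)
    raise ValueError(f"unknown normalization mode {mode!r}")


def ddcq_expression(target_cq, nf: pd.Series, calibrator: str) -> pd.DataFrame:
    """ddCq fold changes of a target gene against a calibrator sample.

    ``target_cq`` holds the target's Cq per sample, replicates as rows
    (a Series is treated as a single replicate).  dCq = Cq_target - NF per
    sample; ddCq subtracts the calibrator's replicate-mean dCq; fold =
    2^(-ddCq).  Returns per-sample mean fold and its standard error.
    """
    if isinstance(target_cq, pd.Series):
        target_cq = target_cq.to_frame().T
    if calibrator not in target_cq.columns:
        raise ValueError(f"calibrator sample {calibrator!r} not present")
    missing = [s for s in target_cq.columns if s not in nf.index]
    if missing:
        raise ValueError(f"normalization factor missing for samples: {missing}")
    dcq = target_cq.sub(nf[target_cq.columns], axis=1)
    ddcq = dcq - dcq[calibrator].mean()
    fold = 2.0 ** (-ddcq)
    n_rep = fold.shape[0]
    se = fold.std(axis=0, ddof=1) / np.sqrt(n_rep) if n_rep > 1 else pd.Series(
        0.0, index=fold.columns)
    return pd.DataFrame({"fold_mean": fold.mean(axis=0), "fold_se": se})
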