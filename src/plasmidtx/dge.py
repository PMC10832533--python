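"""Plasmid-carriage differential expression.

TPM matrix, k-means clustering with SSE-elbow model selection, per-gene
Welch tests on log2(TPM+1), Benjamini-Hochberg FDR and fold-change/p/FDR
filtering (fc >= 2, p < 0.05, q < 0.1), plus functional-class-scoring
enrichment on the log2 fold changes of all genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .quantify import tpm

DEFAULT_KMEANS_SEED = 20240111


def tpm_matrix(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Per-sample TPM (columns each sum to 1e6)."""
    lengths = lengths.reindex(counts.index)
    return pd.DataFrame(
        {s: tpm(counts[s].to_numpy(), lengths.to_numpy()) for s in counts.columns},
        index=counts.index,
    )


@dataclass
class ClusterModel:
    k: int
    sse_by_k: dict
    assignments: np.ndarray | None
    seed: int


def zscore_rows(matrix: np.ndarray) -> np.ndarray:
    """Row-wise z-score of log2(x+1); constant rows map to zero."""
    lg = np.log2(np.asarray(matrix, dtype=float) + 1.0)
    mu = lg.mean(axis=1, keepdims=True)
    sd = lg.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (lg - mu) / sd


def elbow_k(sse_by_k: dict) -> int:
    """k maximising the second difference of SSE; smaller k wins ties."""
    ks = sorted(sse_by_k)
    best_k, best_curv = ks[0], -np.inf
    for j in range(1, len(ks) - 1):
        k = ks[j]
        curv = sse_by_k[ks[j - 1]] - 2 * sse_by_k[k] + sse_by_k[ks[j + 1]]
        if curv > best_curv + 1e-12:
            best_k, best_curv = k, curv
    return best_k


def select_k(
    matrix_z: np.ndarray,
    k_range=range(1, 9),
    seed: int = DEFAULT_KMEANS_SEED,
    n_init: int = 10,
) -> ClusterModel:
    """k-means over a z-scored expression matrix with SSE-elbow selection."""
    X = np.asarray(matrix_z, dtype=float)
    if X.shape[0] < 2 or np.allclose(X, X[0]):
        return ClusterModel(k=1, sse_by_k={1: 0.0}, assignments=np.zeros(X.shape[0], int), seed=seed)
    sse: dict[int, float] = {}
    fits = {}
    for k in k_range:
        if k > X.shape[0]:
            break
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
        km.fit(X)
        sse[k] = float(km.inertia_)
        fits[k] = km
    k = elbow_k(sse)
    return ClusterModel(k=k, sse_by_k=sse, assignments=fits[k].labels_, seed=seed)


def gene_test(
    tpm_a: np.ndarray,
    tpm_b: np.ndarray,
    mean_floor: float = 0.5,
    var_floor: float = 1e-3,
) -> tuple[float, float]:
    """Per-gene (log2fc, p) between two replicate groups of TPMs.

    log2fc is the ratio of condition means (floored at `mean_floor` TPM);
    p is a Welch t-test on log2(TPM+1) with a pooled-variance floor.
    """
    a = np.asarray(tpm_a, dtype=float)
    b = np.asarray(tpm_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    lfc = float(np.log2(max(b.mean(), mean_floor) / max(a.mean(), mean_floor)))
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    va, vb = la.var(ddof=1), lb.var(ddof=1)
    se2 = va / len(a) + vb / len(b)
    se2_f = max(se2, var_floor)
    diff = lb.mean() - la.mean()
    t = diff / np.sqrt(se2_f)
    if va > 0 and vb > 0:
        df = se2**2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
    else:
        df = len(a) + len(b) - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return lfc, float(min(p, 1.0))


def _fit_variance_prior(
    variances: np.ndarray, df: float, mean_expr: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Fit a scaled inverse chi-square prior (d0, s0^2) to gene variances.

    Method of moments on log variances: with residual df `df`,
    log s^2 - digamma(df/2) + log(df/2) scatters with variance
    trigamma(df/2) + trigamma(d0/2) around log s0^2.  When `mean_expr` is
    given, log s0^2 follows a quadratic trend in mean expression
    (mean-variance trend of count data) instead of a single constant.
    """
    from scipy.special import digamma, polygamma

    z = np.log(variances)
    e = z - digamma(df / 2) + np.log(df / 2)
    if mean_expr is None:
        center = np.full_like(e, e.mean())
    else:
        coef = np.polyfit(mean_expr, e, deg=2)
        center = np.polyval(coef, mean_expr)
    resid = e - center
    target = resid.var(ddof=1) - polygamma(1, df / 2)
    if target <= 0:
        return np.inf, np.exp(center)
    # invert trigamma(d0/2) = target by Newton iteration
    x = 0.5 + 1.0 / target
    for _ in range(50):
        tri = polygamma(1, x)
        delta = tri * (1 - tri / target) / polygamma(2, x)
        x = max(x - delta, 1e-8)
        if abs(delta) < 1e-10:
            break
    d0 = 2 * x
    s0_sq = np.exp(center + digamma(x) - np.log(x))
    return float(d0), s0_sq


def moderated_tests(
    log_a: np.ndarray, log_b: np.ndarray, var_floor: float = 1e-3,
    offset: float = 0.0, trend: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical-Bayes moderated t-tests per gene (rows) between two groups.

    Per-gene pooled residual variances are squeezed toward a fitted
    inverse-chi-square prior (trended in mean expression by default),
    adding the prior's degrees of freedom to the residual ones; this
    recovers power lost to noisy few-replicate variance estimates without
    letting noisy low-expression genes borrow an unrealistically small
    variance.  Returns (t, p, total df).
    """
    na, nb = log_a.shape[1], log_b.shape[1]
    df_res = na + nb - 2
    va = log_a.var(axis=1, ddof=1)
    vb = log_b.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / df_res
    pooled = np.maximum(pooled, var_floor)
    mean_expr = np.hstack([log_a, log_b]).mean(axis=1) if trend else None
    d0, s0_sq = _fit_variance_prior(pooled, df_res, mean_expr)
    if np.isinf(d0):
        var_mod = s0_sq
        df_tot = 1e6
    else:
        var_mod = (d0 * s0_sq + df_res * pooled) / (d0 + df_res)
        df_tot = d0 + df_res
    se = np.sqrt(var_mod * (1.0 / na + 1.0 / nb))
    t = (log_b.mean(axis=1) - log_a.mean(axis=1) - offset) / se
    p = 2.0 * stats.t.sf(np.abs(t), df_tot)
    return t, p, df_tot, se


def shrink_lfc(lfc: np.ndarray, se: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Adaptive empirical-Bayes shrinkage of log2 fold-change estimates.

    Fits a two-component prior by EM across genes — a spike (true effect 0,
    observed lfc ~ N(0, se^2)) and a slab of genuine effects
    (lfc ~ N(0, se^2 + tau^2)) — and returns the posterior-mean effect
    w * lfc * tau^2 / (tau^2 + se^2), with w the posterior slab
    probability.  Chance fold changes of null genes are damped toward zero
    while large real effects pass almost unshrunk.
    """
    lfc = np.asarray(lfc, dtype=float)
    se_sq = np.asarray(se, dtype=float) ** 2
    pi1, tau_sq = 0.1, max(float(np.var(lfc) - np.mean(se_sq)), 0.01)
    for _ in range(max_iter):
        f0 = stats.norm.pdf(lfc, scale=np.sqrt(se_sq))
        f1 = stats.norm.pdf(lfc, scale=np.sqrt(se_sq + tau_sq))
        w = pi1 * f1 / ((1 - pi1) * f0 + pi1 * f1 + 1e-300)
        new_pi1 = float(np.clip(w.mean(), 1e-4, 1 - 1e-4))
        wsum = w.sum()
        new_tau = max(float((w * (lfc**2 - se_sq)).sum() / max(wsum, 1e-12)), 0.01)
        done = abs(new_pi1 - pi1) < 1e-8 and abs(new_tau - tau_sq) < 1e-8
        pi1, tau_sq = new_pi1, new_tau
        if done:
            break
    return w * lfc * tau_sq / (tau_sq + se_sq)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DgeThresholds:
    min_mean_tpm: float = 1.0
    min_abs_log2fc: float = 1.0  # fc >= 2
    max_p: float = 0.05
    max_q: float = 0.1


@dataclass
class DgeResult:
    table: pd.DataFrame
    clusters: ClusterModel
    n_up: int = 0
    n_down: int = 0

    def __post_init__(self) -> None:
        self.n_up = int((self.table["call"] == "up").sum())
        self.n_down = int((self.table["call"] == "down").sum())


def call_degs(
    counts: pd.DataFrame,
    lengths: pd.Series,
    cond_a_cols: list,
    cond_b_cols: list,
    thresholds: DgeThresholds | None = None,
    cluster_seed: int = DEFAULT_KMEANS_SEED,
    moderate: bool = True,
) -> DgeResult:
    """Full differential-expression call between condition A and B samples.

    With `moderate` (default), per-gene variances are empirical-Bayes
    moderated across genes before testing; otherwise each gene gets an
    independent Welch test.
    """
    th = thresholds or DgeThresholds()
    mat = tpm_matrix(counts, lengths)
    A = mat[cond_a_cols].to_numpy()
    B = mat[cond_b_cols].to_numpy()
    mean_tpm = mat.mean(axis=1).to_numpy()
    testable = (mean_tpm >= th.min_mean_tpm) & ~(
        (A.sum(axis=1) == 0) & (B.sum(axis=1) == 0)
    )

    lfc = np.full(len(mat), np.nan)
    p = np.full(len(mat), np.nan)
    idx = np.flatnonzero(testable)
    floored = np.maximum
    lfc[idx] = np.log2(
        floored(B[idx].mean(axis=1), 0.5) / floored(A[idx].mean(axis=1), 0.5)
    )
    # median-ratio recentring: TPM is compositional, so an asymmetric set of
    # true changes shifts every null gene's ratio; assuming most genes are
    # unchanged, the median log-ratio estimates that shift
    shift = float(np.median(lfc[idx])) if len(idx) else 0.0
    lfc[idx] -= shift
    la, lb = np.log2(A[idx] + 1.0), np.log2(B[idx] + 1.0)
    lfc_raw = lfc.copy()
    if moderate:
        test_shift = float(np.median(lb.mean(axis=1) - la.mean(axis=1)))
        _, p[idx], _, se = moderated_tests(la, lb, offset=test_shift)
        lfc[idx] = shrink_lfc(lfc[idx], se)
    else:
        for i, j in enumerate(idx):
            _, p[j] = gene_test(A[j] / 2.0**shift, B[j])
    q = np.full(len(mat), np.nan)
    q[testable] = bh_fdr(p[testable])

    call = np.full(len(mat), "not_de", dtype=object)
    sig = testable & (p < th.max_p) & (q < th.max_q)
    call[sig & (lfc >= th.min_abs_log2fc)] = "up"
    call[sig & (lfc <= -th.min_abs_log2fc)] = "down"

    clusters = select_k(zscore_rows(mat.to_numpy()), seed=cluster_seed)
    table = pd.DataFrame(
        {
            "mean_tpm_a": A.mean(axis=1),
            "mean_tpm_b": B.mean(axis=1),
            "log2fc": lfc,
            "log2fc_raw": lfc_raw,
            "p_value": p,
            "q_value": q,
            "cluster": clusters.assignments,
            "call": call,
            "tested": testable,
        },
        index=mat.index,
    )
    return DgeResult(table=table, clusters=clusters)


def fcs_enrichment(
    log2fc_all: pd.Series,
    gene_set,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Functional-class-scoring enrichment of a gene set's log2 fold changes.

    Mann-Whitney rank test of the set against its complement; exact
    enumeration for small problems (|set| <= 8, background <= 25),
    otherwise the tie-corrected normal approximation.
    """
    gene_set = set(gene_set)
    background = set(log2fc_all.index)
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    if not 1 <= len(gene_set) < len(background):
        raise ValueError("gene set must be non-empty and a proper subset")
    in_set = log2fc_all.loc[sorted(gene_set)].to_numpy()
    out_set = log2fc_all.loc[sorted(background - gene_set)].to_numpy()
    method = "exact" if (len(in_set) <= 8 and len(log2fc_all) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(in_set, out_set, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
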