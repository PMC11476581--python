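"""Differential expression, preranked GSEA and over-representation.

The differential-expression step is a deliberately lightweight
stand-in for a count-model fit: median-of-ratios size factors, a Welch
t-test on log2(normalized + 1) values, and Benjamini-Hochberg
correction.  Its job is to produce a defensible per-gene ranking
statistic for preranked GSEA, not to replicate a negative-binomial GLM.

Preranked GSEA follows the classic convention: the enrichment score is
the signed extreme deviation of a weighted Kolmogorov-Smirnov walk
(hit increments proportional to |stat|^weight), the null is built by
gene-label permutation, and the normalized enrichment score divides by
the mean magnitude of same-sign null scores.  Note this intentionally
differs from the per-sample scoring walk in :mod:`mhcscreen.scoring`,
which uses the difference-of-extremes form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection, MhcScreenError


# ---------------------------------------------------------------------------
# normalization and differential expression


def median_of_ratios_size_factors(counts: ExpressionMatrix) -> np.ndarray:
    """Per-sample size factors: the median, over genes positive in all
    samples, of the ratio of the gene's count to its geometric mean."""
    if counts.scale != "counts":
        raise MhcScreenError("size factors require a counts-scale matrix")
    X = counts.values
    positive = (X > 0).all(axis=1)
    if not positive.any():
        raise MhcScreenError(
            "no gene is positive in every sample; supply a pseudo-reference or filter samples"
        )
    logX = np.log(X[positive])
    log_geomean = logX.mean(axis=1)
    factors = np.exp(np.median(logX - log_geomean[:, None], axis=0))
    return factors


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene; columns log2fc, p, q, mean_a, mean_b, filtered

    def significant(self, q_max: float = 0.05, lfc_min: float = 1.0) -> list[str]:
        t = self.table
        keep = (~t["filtered"]) & (t["q"] < q_max) & (t["log2fc"].abs() >= lfc_min)
        return list(t.index[keep])


def differential_expression(
    counts: ExpressionMatrix,
    group: np.ndarray,
    min_count: int = 10,
) -> DEResult:
    """Two-group differential expression on count data.

    Genes with total count below ``min_count`` are flagged filtered and
    not tested.  Counts are normalized by median-of-ratios size
    factors; a Welch t-test is applied on log2(normalized + 1), and
    log2FC is the difference of group means on that scale (group B
    minus group A, where B is the second label in sorted order).
    """
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise MhcScreenError("differential expression requires exactly 2 groups")
    a_mask = group == labels[0]
    b_mask = group == labels[1]
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise MhcScreenError("each group needs at least 2 samples")
    factors = median_of_ratios_size_factors(counts)
    norm = counts.values / factors[None, :]
    logn = np.log2(norm + 1.0)
    total = counts.values.sum(axis=1)
    filtered = total < min_count
    mean_a = logn[:, a_mask].mean(axis=1)
    mean_b = logn[:, b_mask].mean(axis=1)
    log2fc = mean_b - mean_a
    p = np.ones(counts.n_genes)
    testable = ~filtered
    if testable.any():
        res = stats.ttest_ind(logn[testable][:, b_mask], logn[testable][:, a_mask],
                              axis=1, equal_var=False)
        pvals = np.nan_to_num(res.pvalue, nan=1.0)
        p[testable] = np.clip(pvals, np.finfo(float).tiny, 1.0)
    q = np.ones(counts.n_genes)
    if testable.any():
        q[testable] = bh_fdr(p[testable])
    table = pd.DataFrame({
        "log2fc": log2fc, "p": p, "q": q,
        "mean_a": mean_a, "mean_b": mean_b, "filtered": filtered,
    }, index=pd.Index(counts.gene_ids, name="gene"))
    return DEResult(table=table)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, mapped
    back to input order; enforces q >= p and q <= 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise MhcScreenError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclass
class GseaSetResult:
    name: str
    es: float
    nes: float
    p_value: float
    q_value: float
    size: int
    leading_edge: list[str]


@dataclass
class GseaResult:
    sets: dict[str, GseaSetResult]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "set": r.name, "es": r.es, "nes": r.nes, "p": r.p_value, "q": r.q_value,
            "size": r.size, "leading_edge": ",".join(r.leading_edge),
        } for r in self.sets.values()]
        return pd.DataFrame(rows).set_index("set")


def _gsea_walk(stat_sorted: np.ndarray, hit_mask: np.ndarray, weight: float) -> tuple[float, int]:
    """Signed extreme deviation of the GSEA walk over genes sorted by
    decreasing statistic; returns (ES, index of the extreme)."""
    w = np.abs(stat_sorted) ** weight
    hit_total = w[hit_mask].sum()
    n_miss = (~hit_mask).sum()
    if n_miss == 0:
        raise MhcScreenError("gene set equals the full universe; miss increments undefined")
    if hit_total == 0:
        hit_steps = np.where(hit_mask, 1.0 / max(hit_mask.sum(), 1), 0.0)
    else:
        hit_steps = np.where(hit_mask, w / hit_total, 0.0)
    steps = np.where(hit_mask, hit_steps, -1.0 / n_miss)
    walk = np.cumsum(steps)
    i_max = int(np.argmax(walk))
    i_min = int(np.argmin(walk))
    if walk[i_max] >= -walk[i_min]:
        return float(walk[i_max]), i_max
    return float(walk[i_min]), i_min


def preranked_gsea(
    ranking: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA over a gene -> statistic ranking.

    The null distribution per set size is built by drawing ``n_perm``
    random gene subsets (gene-label permutation); NES divides ES by the
    mean |null ES| of matching sign, and the permutation p-value is
    (1 + #{same-sign null at least as extreme}) / (1 + #same-sign null).
    Fixed seeds make results bit-reproducible.
    """
    if ranking.isna().any():
        raise MhcScreenError("ranking statistic contains missing values")
    if ranking.index.duplicated().any():
        raise MhcScreenError("duplicate gene ids in ranking")
    order = np.argsort(-ranking.to_numpy(float), kind="stable")
    genes_sorted = ranking.index.to_numpy()[order]
    stat_sorted = ranking.to_numpy(float)[order]
    n = genes_sorted.size
    pos = {g: i for i, g in enumerate(genes_sorted)}
    rng = np.random.default_rng(seed)

    results: dict[str, GseaSetResult] = {}
    null_cache: dict[int, np.ndarray] = {}
    for name in sets.names():
        members = [g for g in sets[name] if g in pos]
        k = len(members)
        if k == 0 or k >= n:
            raise MhcScreenError(f"set {name!r} has invalid effective size {k} of {n}")
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[[pos[g] for g in members]] = True
        es, i_ext = _gsea_walk(stat_sorted, hit_mask, weight)
        if k not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                idx = rng.choice(n, size=k, replace=False)
                mask = np.zeros(n, dtype=bool)
                mask[idx] = True
                null[b], _ = _gsea_walk(stat_sorted, mask, weight)
            null_cache[k] = null
        null = null_cache[k]
        same_sign = null[null >= 0] if es >= 0 else -null[null < 0]
        if same_sign.size and same_sign.mean() > 0:
            nes = es / same_sign.mean() if es >= 0 else -abs(es) / same_sign.mean()
        else:
            nes = 0.0
        p = (1.0 + np.sum(same_sign >= abs(es))) / (1.0 + same_sign.size)
        if es >= 0:
            leading = [g for g in genes_sorted[: i_ext + 1] if hit_mask[pos[g]]]
        else:
            leading = [g for g in genes_sorted[i_ext:] if hit_mask[pos[g]]]
        results[name] = GseaSetResult(name, es, float(nes), float(p), 1.0, k, leading)
    if results:
        names = list(results)
        q = bh_fdr(np.array([results[s].p_value for s in names]))
        for s, qv in zip(names, q):
            results[s].q_value = float(qv)
    return GseaResult(sets=results)


# ---------------------------------------------------------------------------
# over-representation


def overrepresentation_test(
    hits: set[str], pathway: set[str], universe: set[str]
) -> tuple[float, int, float]:
    """Upper-tail hypergeometric test of pathway over-representation
    among the hits; returns (p, overlap, fold enrichment)."""
    if not universe:
        raise MhcScreenError("empty universe")
    if not hits <= universe:
        raise MhcScreenError("hits must be a subset of the universe")
    pathway_in = pathway & universe
    if not pathway_in:
        raise MhcScreenError("pathway shares no genes with the universe")
    M = len(universe)
    K = len(pathway_in)
    n = len(hits)
    k = len(hits & pathway_in)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    expected = K * n / M
    fold = k / expected if expected > 0 else float("inf")
    return p, k, fold


def ora_over_collection(
    hits: set[str], sets: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """ORA across a collection with BH correction over pathways."""
    rows = []
    for name in sets.names():
        pathway = set(sets[name]) & universe
        if not pathway:
            continue
        p, overlap, fold = overrepresentation_test(hits, pathway, universe)
        rows.append({"set": name, "p": p, "overlap": overlap, "fold": fold, "size": len(pathway)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p", kind="stable").set_index("set")
    return df
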