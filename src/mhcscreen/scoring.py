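"""Single-sample gene-set scoring and correlation utilities.

Two scoring schemes are provided:

* a GSVA-style score: per-gene cross-sample expression statistics
  (Gaussian kernel CDF for continuous data, mid-ranks for counts) feed a
  weighted Kolmogorov-Smirnov random walk within each sample; the
  enrichment score is the difference of the maximum positive and maximum
  negative walk deviations, so it lies in (-1, 1);
* a UCell-style score: the Mann-Whitney U statistic on clipped
  within-unit expression ranks, mapped to [0, 1].

Spearman correlation is computed as Pearson on mid-ranks with the
t-distribution p-value approximation, matching the convention used
throughout the screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .io import DegenerateStratumError, ExpressionMatrix, GeneSetCollection, MhcScreenError, logger


@dataclass
class SignatureScores:
    """Per-unit enrichment scores for one gene set."""

    unit_ids: list[str]
    scores: np.ndarray
    method: str  # "gsva" | "ucell"
    gene_set: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.unit_ids),):
            raise MhcScreenError("score vector length does not match unit ids")
        if not np.all(np.isfinite(self.scores)):
            raise MhcScreenError("scores must be finite")
        if self.method == "ucell" and not self.normalized:
            if self.scores.min() < -1e-12 or self.scores.max() > 1 + 1e-12:
                raise MhcScreenError("raw UCell scores must lie in [0, 1]")


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _gaussian_kcdf(values: np.ndarray) -> np.ndarray:
    """Cross-sample Gaussian-kernel CDF statistic for one gene.

    For sample j: mean over k of Phi((x_j - x_k) / h), with bandwidth
    h = sd / 4.  Returns mid-ranks scaled to (0, 1) when the gene has
    zero variance (the kernel bandwidth degenerates).
    """
    sd = values.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero variance")
    h = sd / 4.0
    diff = (values[:, None] - values[None, :]) / h
    return special.ndtr(diff).mean(axis=1)


def _per_gene_statistic(expr: ExpressionMatrix, kcdf: str) -> np.ndarray:
    X = expr.values
    n_genes, n_samples = X.shape
    Z = np.empty_like(X)
    if kcdf == "rank":
        for i in range(n_genes):
            Z[i] = stats.rankdata(X[i], method="average")
        return Z
    if kcdf != "gaussian":
        raise MhcScreenError(f"unknown kcdf {kcdf!r}; expected 'gaussian' or 'rank'")
    fell_back = 0
    for i in range(n_genes):
        try:
            Z[i] = _gaussian_kcdf(X[i])
        except ZeroDivisionError:
            Z[i] = stats.rankdata(X[i], method="average")
            fell_back += 1
    if fell_back:
        logger.warning("gaussian kcdf fell back to ranks for %d zero-variance gene(s)", fell_back)
    return Z


def _ks_walk_es(stat_column: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Weighted KS walk for one sample; ES = v+ - v- (each floored at 0).

    Genes are ordered by decreasing statistic (ties broken by input
    order); hit increments are |stat|^tau normalized over the set, miss
    increments are uniform over the complement.
    """
    order = np.argsort(-stat_column, kind="stable")
    hits = in_set[order]
    w = np.abs(stat_column[order]) ** tau
    hit_total = w[hits].sum()
    n_miss = (~hits).sum()
    if n_miss == 0:
        raise MhcScreenError("gene set equals the whole matrix; walk undefined")
    steps = np.where(hits, (w / hit_total if hit_total > 0 else 1.0 / hits.sum()), -1.0 / n_miss)
    walk = np.cumsum(steps)
    v_pos = max(walk.max(), 0.0)
    v_neg = max(-walk.min(), 0.0)
    return v_pos - v_neg


def gsva_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    kcdf: str | None = None,
    tau: float = 1.0,
) -> dict[str, SignatureScores]:
    """GSVA-style per-sample enrichment scores, one vector per gene set.

    ``kcdf`` defaults to ``gaussian`` for log2-TPM / log-normalized data
    and ``rank`` for counts.  Sets with no gene in the matrix are
    skipped with a warning.
    """
    if expr.n_samples < 2:
        raise MhcScreenError("GSVA scoring needs at least 2 samples")
    if kcdf is None:
        kcdf = "rank" if expr.scale == "counts" else "gaussian"
    Z = _per_gene_statistic(expr, kcdf)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    out: dict[str, SignatureScores] = {}
    for name in sets.names():
        members = [g for g in sets[name] if g in gene_pos]
        if not members:
            logger.warning("gene set %r shares no genes with the matrix; skipped", name)
            continue
        in_set = np.zeros(expr.n_genes, dtype=bool)
        in_set[[gene_pos[g] for g in members]] = True
        scores = np.array([_ks_walk_es(Z[:, j], in_set, tau) for j in range(expr.n_samples)])
        out[name] = SignatureScores(list(expr.sample_ids), scores, "gsva", name)
    return out


def ucell_score(
    expr: ExpressionMatrix,
    gene_set: list[str],
    max_rank: int = 1500,
    set_name: str = "signature",
) -> SignatureScores:
    """UCell score per unit (cell, sample or cell line).

    Genes are ranked within each unit by decreasing expression with
    mid-ranks for ties; ranks beyond ``max_rank`` are clipped to
    ``max_rank + 1``.  With R_sum the summed ranks of the n set genes
    present in the data, U = R_sum - n(n+1)/2 and
    score = 1 - U / (n * max_rank), clipped to [0, 1].
    """
    present = [g for g in dict.fromkeys(gene_set) if g in set(expr.gene_ids)]
    n = len(present)
    if n == 0:
        raise MhcScreenError("gene set shares no genes with the matrix")
    if n > max_rank:
        raise MhcScreenError(f"set size {n} exceeds max_rank {max_rank}; score undefined")
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    set_idx = np.array([gene_pos[g] for g in present])
    X = expr.values
    scores = np.empty(expr.n_samples)
    for j in range(expr.n_samples):
        ranks = stats.rankdata(-X[:, j], method="average")
        ranks = np.where(ranks > max_rank, max_rank + 1, ranks)
        u = ranks[set_idx].sum() - n * (n + 1) / 2.0
        scores[j] = 1.0 - u / (n * max_rank)
    np.clip(scores, 0.0, 1.0, out=scores)
    return SignatureScores(list(expr.sample_ids), scores, "ucell", set_name)


def zscore_normalize(scores: SignatureScores) -> SignatureScores:
    """Z-normalize scores across units (population sd)."""
    if len(scores.unit_ids) < 2:
        raise MhcScreenError("z-normalization needs at least 2 units")
    sd = scores.scores.std(ddof=0)
    if sd == 0:
        raise MhcScreenError("cannot z-normalize a constant score vector")
    z = (scores.scores - scores.scores.mean()) / sd
    return SignatureScores(list(scores.unit_ids), z, scores.method, scores.gene_set, normalized=True)


def spearman(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation: Pearson on mid-ranks, p from the
    t-approximation with n - 2 degrees of freedom.

    Pairs with a missing value in either vector are dropped.  |rho| = 1
    yields the smallest representable positive p rather than 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MhcScreenError("vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise MhcScreenError("Spearman correlation needs >= 3 complete pairs")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    sx = rx.std(ddof=0)
    sy = ry.std(ddof=0)
    if sx == 0 or sy == 0:
        raise MhcScreenError("zero rank variance; correlation undefined")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if 1.0 - abs(rho) < 1e-12:  # perfectly monotone up to rounding
        rho = 1.0 if rho > 0 else -1.0
    if abs(rho) == 1.0:
        p = np.finfo(float).tiny
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p = max(p, np.finfo(float).tiny)
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n)


def score_by_expression_stratum(
    cell_scores: SignatureScores,
    cell_expression: np.ndarray,
    threshold: float = 0.0,
) -> tuple[float, float, float]:
    """Mean signature score among units expressing a gene (value >
    threshold) vs not, and the difference (non-expressing - expressing).

    Raises :class:`DegenerateStratumError` when either stratum is empty,
    e.g. when every cell expresses the gene.
    """
    expr = np.asarray(cell_expression, dtype=float)
    if expr.shape != cell_scores.scores.shape:
        raise MhcScreenError("expression vector length does not match scores")
    expressing = expr > threshold
    if expressing.all() or not expressing.any():
        raise DegenerateStratumError(
            "all units fall in one stratum "
            f"({'expressing' if expressing.all() else 'non-expressing'})"
        )
    mean_expr = float(cell_scores.scores[expressing].mean())
    mean_non = float(cell_scores.scores[~expressing].mean())
    return mean_expr, mean_non, mean_non - mean_expr
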