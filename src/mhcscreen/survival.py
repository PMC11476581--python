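"""Survival models behind the prognostic screen.

The module implements, from the partial likelihood up:

* univariate Cox proportional hazards with the Efron tie correction,
  maximized by Newton-Raphson with step halving;
* the Kaplan-Meier product-limit estimator;
* the two-group log-rank test;
* administrative-censoring truncation of follow-up at a horizon;
* the multi-endpoint, multi-horizon prognostic score: for each
  (endpoint, horizon) cell, follow-up is truncated, a univariate Cox
  model is fitted on z-scored expression, and the fit contributes -1
  (risky: beta > 0, p < alpha), +1 (protective: beta < 0, p < alpha) or
  0; the per-cohort score is the sum of contributions, so a strongly
  and consistently risky gene approaches -(endpoints x horizons).

Scores are signed unit counts rather than p-value weights: the point of
the construction is an intuitive integer that can be thresholded (the
shipped focal-cohort cutoff is a score below -12 out of a 4x5 grid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix, MhcScreenError, RunConfig, logger

MAX_ITER = 50
GRAD_TOL = 1e-9
STEP_TOL = 1e-10
BETA_BOUND = 50.0  # |beta| beyond this signals monotone likelihood


@dataclass
class CoxFit:
    beta: float
    se: float
    z: float
    p_value: float
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    iterations: int
    message: str = ""


def _validate_surv(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape:
        raise MhcScreenError("time and event must have equal length")
    if (time < 0).any():
        raise MhcScreenError("negative survival time")
    if not np.isin(event, (0.0, 1.0)).all():
        raise MhcScreenError("event indicator outside {0,1}")
    return time, event.astype(int)


class _EfronPartialLikelihood:
    """Efron-corrected log partial likelihood for one covariate, with
    the tie-group structure precomputed so each evaluation is a handful
    of vectorized O(n) passes.

    Samples must be pre-sorted by ascending time.  For an event time
    with d tied events, the l-th tied term (l = 0..d-1) uses the
    risk-set sums minus l/d times the tied-event sums.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, x: np.ndarray) -> None:
        self.x = x
        n = time.size
        # distinct-time group of each sample
        new_time = np.r_[True, time[1:] != time[:-1]]
        starts = np.flatnonzero(new_time)
        grp_per_sample = np.cumsum(new_time) - 1
        ev_idx = np.flatnonzero(event == 1)
        grp_of_ev = grp_per_sample[ev_idx]
        uniq_grp, counts = np.unique(grp_of_ev, return_counts=True)
        offsets = np.r_[0, np.cumsum(counts[:-1])]
        within = np.arange(ev_idx.size) - np.repeat(offsets, counts)
        self.ev_idx = ev_idx
        self.ev_group_starts = offsets
        self.term_f = within / np.repeat(counts, counts)
        self.term_grp = np.repeat(np.arange(uniq_grp.size), counts)
        self.grp_risk_start = starts[uniq_grp]
        self.sum_x_events = float(x[ev_idx].sum())

    def derivatives(self, beta: float) -> tuple[float, float, float]:
        x = self.x
        eta = np.clip(beta * x, -700, 700)  # overflow guard during line search
        w = np.exp(eta)
        wx = w * x
        wxx = wx * x
        # suffix sums over the risk set (time >= t)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum(wx[::-1])[::-1]
        s2 = np.cumsum(wxx[::-1])[::-1]
        t0 = np.add.reduceat(w[self.ev_idx], self.ev_group_starts)
        t1 = np.add.reduceat(wx[self.ev_idx], self.ev_group_starts)
        t2 = np.add.reduceat(wxx[self.ev_idx], self.ev_group_starts)
        g = self.term_grp
        rs = self.grp_risk_start[g]
        a0 = s0[rs] - self.term_f * t0[g]
        a1 = s1[rs] - self.term_f * t1[g]
        a2 = s2[rs] - self.term_f * t2[g]
        with np.errstate(divide="ignore", invalid="ignore"):
            m = a1 / a0
            ll = beta * self.sum_x_events - float(np.log(a0).sum())
            grad = self.sum_x_events - float(m.sum())
            hess = -float((a2 / a0 - m * m).sum())
        return ll, grad, hess


def _efron_derivatives(beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray):
    return _EfronPartialLikelihood(time, event, x).derivatives(beta)


def fit_cox_univariate(time, event, x) -> CoxFit:
    """Newton-Raphson maximization of the Efron partial likelihood for a
    single continuous covariate.

    Monotone likelihood (perfect separation) is reported through the
    ``converged`` flag and message, never as a silent finite estimate.
    """
    time, event = _validate_surv(time, event)
    x = np.asarray(x, dtype=float)
    if x.shape != time.shape:
        raise MhcScreenError("covariate length does not match survival data")
    n_events = int(event.sum())
    if n_events < 1:
        raise MhcScreenError("Cox fit requires at least one event")
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    # variance among at-risk subjects; a constant covariate is degenerate
    if np.ptp(x) == 0:
        raise MhcScreenError("covariate has zero variance")

    lik = _EfronPartialLikelihood(time, event, x)
    beta = 0.0
    ll, grad, hess = lik.derivatives(beta)
    it = 0
    converged = False
    message = ""
    for it in range(1, MAX_ITER + 1):
        if abs(grad) < GRAD_TOL:
            converged = True
            break
        if hess >= 0 or not np.isfinite(hess):
            message = "non-concave step"
            break
        step = -grad / hess
        # step halving to ensure the likelihood does not decrease
        new_beta = beta + step
        new = lik.derivatives(new_beta)
        halvings = 0
        while (not np.isfinite(new[0]) or new[0] < ll - 1e-12) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new = lik.derivatives(new_beta)
            halvings += 1
        if abs(step) < STEP_TOL:
            beta, (ll, grad, hess) = new_beta, new
            converged = abs(grad) < 1e-6
            break
        beta, (ll, grad, hess) = new_beta, new
        if abs(beta) > BETA_BOUND:
            message = "monotone likelihood (perfect separation suspected)"
            break
    else:
        message = "maximum iterations reached"
    if abs(grad) < GRAD_TOL:
        converged = True
    if abs(beta) > BETA_BOUND or -hess < 1e-8:
        # the partial likelihood flattens out as beta runs away: the
        # gradient criterion can trigger even though no maximum exists
        converged = False
        message = message or "monotone likelihood (perfect separation suspected)"
    if converged and hess < 0:
        se = float(1.0 / math.sqrt(-hess))
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = max(p, np.finfo(float).tiny)
    else:
        se, z, p = float("nan"), float("nan"), 1.0
        converged = False
        message = message or "did not converge"
    return CoxFit(
        beta=float(beta), se=se, z=float(z), p_value=p, log_likelihood=float(ll),
        n=int(time.size), n_events=n_events, converged=converged, iterations=it,
        message=message,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KMEstimate:
    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(time, event) -> KMEstimate:
    """Product-limit estimator; tied events at a time are handled
    jointly, and subjects censored at that same time count as at risk
    for its factor."""
    time, event = _validate_surv(time, event)
    if time.size == 0:
        raise MhcScreenError("empty survival data")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq = np.unique(time[event == 1])
    surv = []
    at_risk = []
    d_list = []
    s = 1.0
    for t in uniq:
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        d_list.append(d)
    return KMEstimate(
        times=uniq, survival=np.array(surv), at_risk=np.array(at_risk), n_events=np.array(d_list)
    )


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic with 1 df from the
    observed-minus-expected events in group 1, with the hypergeometric
    variance summed over distinct event times."""
    time, event = _validate_surv(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise MhcScreenError(f"log-rank requires exactly 2 groups, got {labels.size}")
    if event.sum() < 1:
        raise MhcScreenError("log-rank requires at least one event")
    g1 = group == labels[1]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def truncate_followup(time, event, horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring at ``horizon`` (years): follow-up beyond
    the horizon becomes censoring at the horizon; events at exactly the
    horizon remain events."""
    if not horizon > 0:
        raise MhcScreenError("horizon must be positive")
    time, event = _validate_surv(time, event)
    if math.isinf(horizon):
        return time.copy(), event.copy()
    over = time > horizon
    return np.where(over, horizon, time), np.where(over, 0, event)


# ---------------------------------------------------------------------------
# prognostic score


@dataclass
class FitRecord:
    endpoint: str
    horizon: float
    beta: float
    p_value: float
    contribution: int
    n: int
    n_events: int
    skipped: bool = False
    reason: str = ""


@dataclass
class GeneCohortScore:
    gene: str
    cohort: str
    score: int | None          # None when every fit was skipped
    records: list[FitRecord] = field(default_factory=list)
    risky: bool = False

    @property
    def available(self) -> bool:
        return self.score is not None


@dataclass
class PrognosticTable:
    """Per gene x cohort prognostic scores with a full per-fit audit trail."""

    entries: dict[tuple[str, str], GeneCohortScore]
    genes: list[str]
    cohorts: list[str]
    risky_threshold: float

    def score(self, gene: str, cohort: str) -> int | None:
        return self.entries[(gene, cohort)].score

    def n_cohorts_risky(self, gene: str) -> int:
        return sum(1 for c in self.cohorts if self.entries[(gene, c)].risky)

    def to_frame(self) -> pd.DataFrame:
        data = {c: [self.entries[(g, c)].score for g in self.genes] for c in self.cohorts}
        df = pd.DataFrame(data, index=pd.Index(self.genes, name="gene"))
        df["n_cohorts_risky"] = [self.n_cohorts_risky(g) for g in self.genes]
        return df

    def audit_frame(self) -> pd.DataFrame:
        rows = []
        for (g, c), entry in self.entries.items():
            for r in entry.records:
                rows.append({
                    "gene": g, "cohort": c, "endpoint": r.endpoint, "horizon": r.horizon,
                    "beta": r.beta, "p_value": r.p_value, "contribution": r.contribution,
                    "n": r.n, "n_events": r.n_events, "skipped": r.skipped, "reason": r.reason,
                })
        return pd.DataFrame(rows)


MIN_SAMPLES_PER_FIT = 20
MIN_EVENTS_PER_FIT = 5


def prognostic_score_gene(
    expr_g: pd.Series,
    clinical: ClinicalTable,
    samples: list[str],
    cohort: str,
    endpoints: list[str] | tuple[str, ...],
    horizons: list[float] | tuple[float, ...],
    alpha: float = 0.05,
    risky_threshold: float = -12.0,
    dichotomize: bool = False,
    gene: str = "",
) -> GeneCohortScore:
    """Prognostic score of one gene in one cohort.

    ``expr_g`` is indexed by sample id.  For every (endpoint, horizon)
    cell with at least 20 usable samples and 5 events after truncation,
    a univariate Cox fit on z-scored (or median-dichotomized) expression
    contributes -1/+1/0; cells below the data floor are recorded as
    skipped with contribution 0.  If every cell is skipped the score is
    reported unavailable (None), never 0.
    """
    records: list[FitRecord] = []
    any_fit = False
    total = 0
    for endpoint in endpoints:
        if endpoint not in clinical.endpoints:
            for h in horizons:
                records.append(FitRecord(endpoint, h, float("nan"), 1.0, 0, 0, 0, True, "endpoint absent"))
            continue
        surv = clinical.available(endpoint, samples)
        usable = surv.index[surv.index.isin(expr_g.index)]
        surv = surv.loc[usable]
        xv = expr_g.loc[usable].to_numpy(float)
        for h in horizons:
            t, e = truncate_followup(surv["time"].to_numpy(float), surv["event"].to_numpy(float), h)
            n, n_events = t.size, int(e.sum())
            if n < MIN_SAMPLES_PER_FIT or n_events < MIN_EVENTS_PER_FIT:
                records.append(FitRecord(endpoint, h, float("nan"), 1.0, 0, n, n_events, True, "too few samples/events"))
                continue
            if dichotomize:
                x = (xv > np.median(xv)).astype(float)
            else:
                sd = xv.std(ddof=0)
                if sd == 0:
                    records.append(FitRecord(endpoint, h, float("nan"), 1.0, 0, n, n_events, True, "constant expression"))
                    continue
                x = (xv - xv.mean()) / sd
            try:
                fit = fit_cox_univariate(t, e, x)
            except MhcScreenError as exc:
                records.append(FitRecord(endpoint, h, float("nan"), 1.0, 0, n, n_events, True, str(exc)))
                continue
            any_fit = True
            if fit.converged and fit.p_value < alpha:
                contribution = -1 if fit.beta > 0 else 1
            else:
                contribution = 0
            total += contribution
            records.append(FitRecord(endpoint, h, fit.beta, fit.p_value, contribution, n, n_events,
                                     skipped=False, reason="" if fit.converged else fit.message))
    if not any_fit:
        return GeneCohortScore(gene=gene, cohort=cohort, score=None, records=records, risky=False)
    return GeneCohortScore(
        gene=gene, cohort=cohort, score=total, records=records,
        risky=total <= risky_threshold,
    )


def batch_prognostic_scores(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    genes: list[str] | None = None,
    cohorts: list[str] | None = None,
    config: RunConfig | None = None,
) -> PrognosticTable:
    """Prognostic scores for many genes across cohorts.

    ``n_cohorts_risky`` counts cohorts whose per-cohort score is at or
    below the risky threshold; the pan-cohort screen criterion is the
    strict ``> k`` comparison applied downstream.
    """
    config = config or RunConfig()
    genes = list(genes) if genes is not None else list(expr.gene_ids)
    if cohorts is None:
        cohorts = sorted(set(clinical.cohort.loc[clinical.sample_ids]))
    entries: dict[tuple[str, str], GeneCohortScore] = {}
    frame = expr.to_frame()
    for cohort in cohorts:
        samples = [s for s in clinical.samples_in_cohort(cohort) if s in frame.columns]
        for gene in genes:
            expr_g = frame.loc[gene, samples]
            entries[(gene, cohort)] = prognostic_score_gene(
                expr_g, clinical, samples, cohort,
                endpoints=config.endpoints, horizons=config.horizons,
                alpha=config.alpha, risky_threshold=config.risky_threshold,
                dichotomize=config.dichotomize_expression, gene=gene,
            )
    return PrognosticTable(entries=entries, genes=genes, cohorts=list(cohorts),
                           risky_threshold=config.risky_threshold)
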