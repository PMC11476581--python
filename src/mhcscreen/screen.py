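"""The screening cascade.

Stages, in order: MHC-I signature scoring of the focal cohort, the
signature-correlation filter (Spearman rho <= -0.15 and p < 0.05), the
multi-cohort prognostic filter (focal score < -12 and risky in more
than three cohorts), the expression filter (mean log2(TPM + 0.001)
>= 1), their intersection (the candidate set), the TIL-correlation
filter (rho < -0.1 with both CD8 T and activated NK fractions) and the
cell-line dual-effector filter (expression negatively correlated with
the cell-line MHC-I score and median dependency < -0.5).

Boundary semantics follow the printed thresholds literally: the
signature-correlation bound is inclusive, every other comparison is
strict.  Each stage records its input and output sets so reports are
fully auditable and byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolution import FractionMatrix, correlate_expression_with_fractions
from .io import (
    ClinicalTable,
    DegenerateStratumError,
    ExpressionMatrix,
    MhcScreenError,
    RunConfig,
    logger,
)
from .scoring import (
    CorrelationResult,
    SignatureScores,
    score_by_expression_stratum,
    spearman,
    ucell_score,
    zscore_normalize,
    gsva_score,
)
from .simulate import TIL_TYPES, CellLinePanel, SingleCellSample, SyntheticCohort
from .survival import PrognosticTable, batch_prognostic_scores


@dataclass
class ScreenStage:
    name: str
    n_in: int
    passed: set[str]
    detail: pd.DataFrame | None = None


@dataclass
class ScreenResult:
    stages: list[ScreenStage]
    candidates: list[str]
    dual_effectors: list[str]
    thresholds: dict
    seed: int
    extras: dict = field(default_factory=dict)

    def stage(self, name: str) -> ScreenStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)


def correlation_filter(
    expr: ExpressionMatrix,
    scores: SignatureScores,
    config: RunConfig,
    genes: list[str] | None = None,
) -> tuple[set[str], dict[str, CorrelationResult]]:
    """Genes whose expression is Spearman-anticorrelated with the
    signature score: rho <= rho_signature_max (inclusive) and
    p < p_max."""
    genes = list(genes) if genes is not None else list(expr.gene_ids)
    sample_pos = {s: i for i, s in enumerate(scores.unit_ids)}
    idx = [sample_pos[s] for s in expr.sample_ids if s in sample_pos]
    shared = [s for s in expr.sample_ids if s in sample_pos]
    sub = expr.subset_samples(shared)
    y = scores.scores[idx]
    passed: set[str] = set()
    results: dict[str, CorrelationResult] = {}
    for gene in genes:
        try:
            r = spearman(sub.gene_values(gene), y)
        except MhcScreenError as exc:
            logger.warning("correlation undefined for gene %r: %s", gene, exc)
            continue
        results[gene] = r
        if r.rho <= config.rho_signature_max and r.p_value < config.p_max:
            passed.add(gene)
    return passed, results


def expression_filter(expr: ExpressionMatrix, config: RunConfig,
                      genes: list[str] | None = None) -> set[str]:
    """Genes with mean expression >= expr_min on the log2(TPM + 0.001)
    scale (inclusive)."""
    if expr.scale != "log2_tpm":
        raise MhcScreenError(f"expression filter requires log2_tpm scale, got {expr.scale!r}")
    genes = list(genes) if genes is not None else list(expr.gene_ids)
    means = expr.to_frame().loc[genes].mean(axis=1)
    return set(means.index[means >= config.expr_min])


def prognostic_filter(
    table: PrognosticTable, focal_cohort: str, config: RunConfig
) -> set[str]:
    """Genes with focal-cohort score < prognostic_max (strict) that are
    risky in more than min_risky_cohorts cohorts (strict).  Genes whose
    focal score is unavailable are excluded with a logged reason."""
    if focal_cohort not in table.cohorts:
        raise MhcScreenError(f"prognostic table lacks focal cohort {focal_cohort!r}")
    passed: set[str] = set()
    for gene in table.genes:
        score = table.score(gene, focal_cohort)
        if score is None:
            logger.warning("gene %r has no available prognostic score in %s; excluded", gene, focal_cohort)
            continue
        if score < config.prognostic_max and table.n_cohorts_risky(gene) > config.min_risky_cohorts:
            passed.add(gene)
    return passed


def intersect_candidates(stage_sets: list[set[str]]) -> list[str]:
    """Exact intersection, listed lexicographically."""
    if len(stage_sets) < 2:
        raise MhcScreenError("need at least two stage sets to intersect")
    common = set(stage_sets[0])
    for s in stage_sets[1:]:
        common &= set(s)
    return sorted(common)


def til_filter(
    candidates: list[str] | set[str],
    rho_matrix: pd.DataFrame,
    config: RunConfig,
    cell_types: tuple[str, str] = TIL_TYPES,
) -> set[str]:
    """Candidates negatively correlated (rho < rho_til_max, strict) with
    BOTH named cell-type fractions."""
    for ct in cell_types:
        if ct not in rho_matrix.columns:
            raise MhcScreenError(f"TIL correlation matrix lacks cell type {ct!r}")
    passed: set[str] = set()
    for gene in candidates:
        if gene not in rho_matrix.index:
            raise MhcScreenError(f"TIL correlation matrix lacks gene {gene!r}")
        if all(rho_matrix.loc[gene, ct].rho < config.rho_til_max for ct in cell_types):
            passed.add(gene)
    return passed


def cellline_dual_effector_filter(
    candidates: list[str] | set[str],
    panel: CellLinePanel,
    panel_scores: SignatureScores,
    config: RunConfig,
) -> tuple[set[str], pd.DataFrame]:
    """Candidates whose cell-line expression anticorrelates with the
    (z-normalized) MHC-I score (rho < cellline_rho_max, strict) and
    whose median dependency score across lines is < dependency_max
    (strict) — essential for survival AND suppressing the signature."""
    if not panel_scores.normalized:
        panel_scores = zscore_normalize(panel_scores)
    rows = []
    passed: set[str] = set()
    gene_set = set(panel.expression.gene_ids)
    for gene in sorted(candidates):
        if gene not in gene_set or gene not in panel.dependency.index:
            logger.warning("gene %r absent from the cell-line panel; excluded", gene)
            continue
        r = spearman(panel.expression.gene_values(gene), panel_scores.scores)
        med_dep = float(panel.dependency.loc[gene].median())
        ok = r.rho < config.cellline_rho_max and med_dep < config.dependency_max
        rows.append({"gene": gene, "rho": r.rho, "p": r.p_value, "median_dependency": med_dep,
                     "passed": ok})
        if ok:
            passed.add(gene)
    detail = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
    return passed, detail


def single_cell_validation(
    samples: list[SingleCellSample],
    genes: list[str],
    signature_genes: list[str],
    config: RunConfig,
    max_rank: int = 1500,
) -> pd.DataFrame:
    """Single-cell check of the screen's candidates.

    Excludes samples whose annotated tumor-cell proportion falls below
    10% or above 90%; per gene, compares mean tumor-cell MHC-I (UCell)
    scores between expressing (count > 0) and non-expressing cells
    within each sample, and correlates per-sample mean tumor expression
    with immune-cell-type proportions across samples.
    """
    usable: list[SingleCellSample] = []
    for s in samples:
        frac = float((s.cell_types == "Cancer_epithelial").mean())
        if frac < config.sc_tumor_frac_min or frac > config.sc_tumor_frac_max:
            logger.info("sample %s excluded (tumor proportion %.3f)", s.sample_id, frac)
            continue
        usable.append(s)
    if len(usable) < 3:
        raise MhcScreenError(f"only {len(usable)} samples survive the tumor-fraction exclusion")

    immune_types = sorted({t for s in usable for t in s.cell_types.unique() if t != "Cancer_epithelial"})
    per_sample_rows = []
    diffs: dict[str, list[float]] = {g: [] for g in genes}
    mean_expr: dict[str, list[float]] = {g: [] for g in genes}
    for s in usable:
        tumor_cells = list(s.cell_types.index[s.cell_types == "Cancer_epithelial"])
        sub = s.expression.subset_samples(tumor_cells)
        eff_rank = min(max_rank, sub.n_genes - 1)
        scores = ucell_score(sub, signature_genes, max_rank=eff_rank)
        props = {ct: float((s.cell_types == ct).mean()) for ct in immune_types}
        per_sample_rows.append({"sample": s.sample_id, **props})
        for g in genes:
            x = sub.gene_values(g)
            mean_expr[g].append(float(x.mean()))
            try:
                _, _, diff = score_by_expression_stratum(scores, x)
            except DegenerateStratumError:
                diff = float("nan")
            diffs[g].append(diff)
    props_df = pd.DataFrame(per_sample_rows).set_index("sample")

    rows = []
    for g in genes:
        d = np.asarray(diffs[g], dtype=float)
        valid = np.isfinite(d)
        row: dict = {
            "gene": g,
            "n_samples": int(valid.sum()),
            "mean_score_diff": float(np.nanmean(d)) if valid.any() else float("nan"),
            "frac_positive_diff": float((d[valid] > 0).mean()) if valid.any() else float("nan"),
        }
        for ct in immune_types:
            try:
                r = spearman(np.asarray(mean_expr[g]), props_df[ct].to_numpy())
                row[f"rho_{ct}"] = r.rho
            except MhcScreenError:
                row[f"rho_{ct}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def run_full_screen(
    cohort: SyntheticCohort,
    config: RunConfig,
    panel: CellLinePanel | None = None,
    fractions: FractionMatrix | None = None,
    signature_genes: list[str] | None = None,
) -> ScreenResult:
    """Execute the cascade on a cohort (synthetic or assembled from real
    inputs) and, if a cell-line panel is supplied, the dual-effector
    stage.  The TIL filter uses the supplied fraction source (e.g.
    deconvolution output); by default the cohort's own fraction matrix.
    Deterministic given config and inputs."""
    signature_genes = signature_genes or cohort.signature[cohort.signature.names()[0]]
    fractions = fractions or cohort.fractions
    focal_samples = cohort.clinical.samples_in_cohort(config.focal_cohort)
    if not focal_samples:
        raise MhcScreenError(f"no samples in focal cohort {config.focal_cohort!r}")
    focal_expr = cohort.expression.subset_samples(focal_samples)
    screen_genes = [g for g in cohort.expression.gene_ids if g not in set(signature_genes)]

    # stage 0: signature scoring of the focal cohort
    scores = gsva_score(focal_expr, cohort.signature)[cohort.signature.names()[0]]

    # stage 1: signature-correlation filter
    corr_pass, corr_detail = correlation_filter(focal_expr, scores, config, genes=screen_genes)
    stages = [ScreenStage("signature_correlation", len(screen_genes), corr_pass,
                          pd.DataFrame({"rho": {g: r.rho for g, r in corr_detail.items()},
                                        "p": {g: r.p_value for g, r in corr_detail.items()}}))]

    # stage 2: prognostic filter across cohorts (cascaded: fits run only
    # on stage-1 survivors, matching the flow chart)
    prog_genes = sorted(corr_pass)
    if prog_genes:
        table = batch_prognostic_scores(cohort.expression, cohort.clinical,
                                        genes=prog_genes, config=config)
        prog_pass = prognostic_filter(table, config.focal_cohort, config)
        prog_detail = table.to_frame()
    else:
        prog_pass, prog_detail, table = set(), None, None
    stages.append(ScreenStage("prognostic", len(prog_genes), prog_pass, prog_detail))

    # stage 3: expression filter on the focal cohort
    expr_pass = expression_filter(focal_expr, config, genes=screen_genes)
    stages.append(ScreenStage("expression", len(screen_genes), expr_pass))

    # candidates: intersection of the three criteria
    candidates = intersect_candidates([corr_pass, prog_pass, expr_pass])
    stages.append(ScreenStage("intersection", len(screen_genes), set(candidates)))

    # stage 4: TIL-correlation filter
    if candidates:
        rho_matrix = correlate_expression_with_fractions(
            focal_expr, fractions, genes=candidates, cell_types=list(TIL_TYPES))
        til_pass = til_filter(candidates, rho_matrix, config)
    else:
        til_pass = set()
    stages.append(ScreenStage("til_correlation", len(candidates), til_pass))
    final_candidates = sorted(til_pass)

    # stage 5: cell-line dual-effector filter
    dual: list[str] = []
    if panel is not None and final_candidates:
        panel_scores = zscore_normalize(
            ucell_score(panel.expression, signature_genes,
                        max_rank=min(1500, panel.expression.n_genes - 1)))
        dual_pass, dual_detail = cellline_dual_effector_filter(final_candidates, panel, panel_scores, config)
        stages.append(ScreenStage("cellline_dual_effector", len(final_candidates), dual_pass, dual_detail))
        dual = sorted(dual_pass)
    elif panel is not None:
        stages.append(ScreenStage("cellline_dual_effector", 0, set()))

    return ScreenResult(
        stages=stages,
        candidates=final_candidates,
        dual_effectors=dual,
        thresholds=config.thresholds_dict(),
        seed=config.seed,
    )


def screen_metrics(result: ScreenResult, truth) -> dict[str, float]:
    """Recall/precision of the final candidate set against planted
    ground truth, plus the decoy pass rate the recall must beat."""
    planted = set(truth.planted_negative)
    decoys = set(truth.decoys)
    final = set(result.candidates)
    recall = len(final & planted) / len(planted) if planted else math.nan
    precision = len(final & planted) / len(final) if final else math.nan
    decoy_rate = len(final & decoys) / len(decoys) if decoys else math.nan
    dual_recall = (len(set(result.dual_effectors) & set(truth.planted_dual)) / len(truth.planted_dual)
                   if truth.planted_dual else math.nan)
    return {"recall": recall, "precision": precision, "decoy_pass_rate": decoy_rate,
            "dual_recall": dual_recall, "n_candidates": len(final),
            "n_dual": len(result.dual_effectors)}
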