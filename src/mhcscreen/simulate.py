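"""Synthetic cohorts with the statistical structure the screen assumes.

The generator emulates TCGA-like bulk tumor cohorts, a CCLE-like cell
line panel with knockout dependency scores, and per-patient single-cell
samples:

* a latent per-sample interferon-activity variable ``a ~ N(0, 1)``
  drives the expression of the MHC-I signature genes upward and the
  expression of planted negative-regulator genes downward (strength
  ``b``), while decoy genes are independent of it;
* immune-cell fractions come from a Dirichlet whose CD8 T and
  activated-NK log-weights are tilted by ``c * a`` before
  renormalization, so infiltration co-varies with the latent activity;
* survival times per endpoint follow an exponential proportional-hazards
  model whose linear predictor sums the (centered) planted-gene
  expressions, with independent exponential censoring calibrated to the
  configured censoring fraction;
* cell-line dependency scores are ~N(-0.8, 0.1) for planted
  dual-effectors and ~N(0, 0.15) otherwise, so the printed -0.5
  essentiality cutoff separates the two cleanly;
* single-cell samples carry cell-type annotations, a tumor-cell
  proportion drawn uniformly, zero-inflated planted-gene expression in
  tumor cells, and an MHC-I program that is lower in cells expressing a
  planted gene.

All randomness flows from one seed through named sub-streams, so every
component is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .deconvolution import FractionMatrix, SignatureMatrix
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection, MhcScreenError

# the eight signature genes as printed in the source signature
MHC1_SIGNATURE = ["HLA-A", "HLA-B", "HLA-C", "HLA-D", "HLA-E", "HLA-F", "HLA-H", "B2M"]

CELL_TYPES = ["CD8_T", "NK_activated", "CD4_T", "T_reg", "B_cell", "Monocyte", "Cancer_epithelial"]
TIL_TYPES = ("CD8_T", "NK_activated")

ENDPOINTS = ("OS", "DSS", "PFS", "TTE")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults describe a mid-sized TCGA-like cohort: 500 samples per
    cohort, 2,000 genes of which 8 form the MHC-I signature, 25 are
    planted negative regulators (the first 5 doubling as essential
    dual-effectors in the cell-line panel) and the rest are decoys.
    """

    n_samples: int = 500
    n_genes: int = 2000
    n_signature_genes: int = 8
    n_planted_negative: int = 25
    n_planted_dual: int = 5
    noise_sd: float = 1.0                 # per-gene expression noise, log2-TPM units
    signature_strength: float = 1.0       # latent-activity loading of signature genes
    anticorr_strength: float = 0.8        # b > 0: planted genes get mu - b*a + noise
    hazard_beta: dict[str, float] | float = 0.15   # per planted gene, per endpoint
    baseline_hazard: float = 0.15         # events per year at lp = 0 (median ~4.6 y)
    censoring_rate: float = 0.3
    dirichlet_alpha: tuple[float, ...] = (2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 8.0)
    fraction_coupling: float = 0.7        # c: tilt of CD8/NK log-weights by c*a
    n_cohorts: int = 6
    focal_cohort: str = "BRCA"
    # cell-line panel
    n_cell_lines: int = 40
    dependency_dual_mean: float = -0.8
    dependency_dual_sd: float = 0.1
    dependency_null_sd: float = 0.15
    # single-cell samples
    n_sc_samples: int = 15
    cells_per_sample: int = 250
    tumor_prop_range: tuple[float, float] = (0.05, 0.95)
    sc_dropout: float = 0.3               # extra dropout of planted genes in tumor cells
    sc_effect: float = 1.5                # log-odds of expressing a planted gene per unit latent
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_signature_genes, self.n_cohorts) <= 0:
            raise MhcScreenError("counts must be positive")
        if self.n_planted_negative + self.n_signature_genes > self.n_genes:
            raise MhcScreenError("more planted + signature genes than total genes")
        if self.n_planted_dual > self.n_planted_negative:
            raise MhcScreenError("dual-effectors must be a subset of planted negatives")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise MhcScreenError("censoring rate must lie in [0, 1)")
        if self.anticorr_strength < 0:
            raise MhcScreenError("anti-correlation strength b must be >= 0")
        if len(self.dirichlet_alpha) != len(CELL_TYPES):
            raise MhcScreenError(f"dirichlet_alpha needs {len(CELL_TYPES)} components")

    def beta_for(self, endpoint: str) -> float:
        if isinstance(self.hazard_beta, dict):
            return float(self.hazard_beta.get(endpoint, 0.0))
        return float(self.hazard_beta)


@dataclass
class GroundTruth:
    planted_negative: list[str]
    planted_dual: list[str]
    decoys: list[str]
    signature_genes: list[str]
    hazard_beta: dict[str, float]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    fractions: FractionMatrix
    latent_activity: pd.Series
    truth: GroundTruth
    signature: GeneSetCollection

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.fractions.sample_ids:
            raise MhcScreenError("expression and fractions must share sample ids")
        missing = set(self.truth.planted_negative) - set(self.expression.gene_ids)
        if missing:
            raise MhcScreenError("planted ids must be a subset of gene ids")


@dataclass
class CellLinePanel:
    expression: ExpressionMatrix        # cell lines as samples
    dependency: pd.DataFrame            # genes x cell lines
    truth: GroundTruth


@dataclass
class SingleCellSample:
    sample_id: str
    expression: ExpressionMatrix        # genes x cells, counts
    cell_types: pd.Series               # cell id -> type label
    tumor_proportion: float             # realized proportion of annotated tumor cells


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    n_sig = config.n_signature_genes
    signature = list(MHC1_SIGNATURE[:n_sig])
    if n_sig > len(MHC1_SIGNATURE):
        signature += [f"SIG{i:03d}" for i in range(len(MHC1_SIGNATURE), n_sig)]
    planted = [f"NEG{i + 1:03d}" for i in range(config.n_planted_negative)]
    dual = planted[: config.n_planted_dual]
    n_decoy = config.n_genes - n_sig - config.n_planted_negative
    decoys = [f"DEC{i + 1:05d}" for i in range(n_decoy)]
    return signature, planted, dual, decoys


def _expression_block(
    config: SimulationConfig,
    a: np.ndarray,
    rng: np.random.Generator,
    mu_sig: np.ndarray,
    mu_neg: np.ndarray,
    mu_dec: np.ndarray,
) -> np.ndarray:
    """Gene x sample log2-TPM values given the latent activity vector."""
    n = a.size
    s, b, sd = config.signature_strength, config.anticorr_strength, config.noise_sd
    sig = mu_sig[:, None] + s * a[None, :] + rng.normal(0, sd, (mu_sig.size, n))
    neg = mu_neg[:, None] - b * a[None, :] + rng.normal(0, sd, (mu_neg.size, n))
    dec = mu_dec[:, None] + rng.normal(0, sd, (mu_dec.size, n))
    return np.vstack([sig, neg, dec])


def _calibrate_censor_rate(lams: np.ndarray, target: float) -> float:
    """Rate of an independent exponential censor such that the expected
    censored fraction E[mu / (mu + lambda_j)] equals the target."""
    if target <= 0:
        return 0.0

    def f(log_mu: float) -> float:
        mu = math.exp(log_mu)
        return float(np.mean(mu / (mu + lams))) - target

    return math.exp(brentq(f, -30, 30, xtol=1e-10))


def simulate_bulk_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate ``n_cohorts`` bulk cohorts sharing gene identities and
    planted structure, concatenated into one cohort object with
    per-sample cohort labels (the first label is the focal cohort)."""
    signature, planted, dual, decoys = _gene_ids(config)
    gene_ids = signature + planted + decoys
    streams = _streams(config.seed, ["means", "latent", "expr", "fractions", "survival"])

    # gene means on the log2(TPM + 0.001) scale, shared across cohorts:
    # signature genes are well expressed, planted genes sit above the
    # downstream expression cutoff, decoys span a broad realistic range
    mu_sig = streams["means"].normal(5.0, 1.0, len(signature))
    mu_neg = np.clip(streams["means"].normal(3.5, 1.0, len(planted)), 2.0, None)
    mu_dec = streams["means"].normal(1.5, 2.0, len(decoys))
    mu_all = np.concatenate([mu_sig, mu_neg, mu_dec])

    cohort_names = [config.focal_cohort] + [f"C{i + 1:02d}" for i in range(1, config.n_cohorts)]
    beta = {e: config.beta_for(e) for e in ENDPOINTS}

    all_samples: list[str] = []
    cohort_labels: list[str] = []
    blocks: list[np.ndarray] = []
    latent_parts: list[np.ndarray] = []
    frac_parts: list[np.ndarray] = []
    endpoint_frames: dict[str, list[pd.DataFrame]] = {e: [] for e in ENDPOINTS}

    alpha = np.asarray(config.dirichlet_alpha, dtype=float)
    til_idx = [CELL_TYPES.index(t) for t in TIL_TYPES]

    for cohort in cohort_names:
        n = config.n_samples
        samples = [f"{cohort}_S{i + 1:04d}" for i in range(n)]
        a = streams["latent"].normal(0.0, 1.0, n)
        X = _expression_block(config, a, streams["expr"], mu_sig, mu_neg, mu_dec)

        w = streams["fractions"].dirichlet(alpha, size=n)
        logw = np.log(np.clip(w, 1e-300, None))
        logw[:, til_idx] += config.fraction_coupling * a[:, None]
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)

        # exponential PH survival per endpoint with shared expression
        planted_rows = X[len(signature): len(signature) + len(planted)]
        centered = planted_rows - mu_neg[:, None]
        for endpoint in ENDPOINTS:
            lp = beta[endpoint] * centered.sum(axis=0)
            lam = config.baseline_hazard * np.exp(lp)
            t_event = streams["survival"].exponential(1.0 / lam)
            if config.censoring_rate > 0:
                mu_c = _calibrate_censor_rate(lam, config.censoring_rate)
                t_cens = streams["survival"].exponential(1.0 / mu_c, size=n)
            else:
                t_cens = np.full(n, np.inf)
            time = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
            endpoint_frames[endpoint].append(pd.DataFrame({"time": time, "event": event}, index=samples))

        all_samples.extend(samples)
        cohort_labels.extend([cohort] * n)
        blocks.append(X)
        latent_parts.append(a)
        frac_parts.append(w)

    expr = ExpressionMatrix(gene_ids, all_samples, np.hstack(blocks), scale="log2_tpm")
    clinical = ClinicalTable(
        sample_ids=all_samples,
        endpoints={e: pd.concat(endpoint_frames[e]) for e in ENDPOINTS},
        cohort=pd.Series(cohort_labels, index=all_samples),
        subtype=pd.Series(
            np.where(np.concatenate(latent_parts) > 0, "LumA", "LumB"), index=all_samples
        ),
        er_status=pd.Series(["positive"] * len(all_samples), index=all_samples),
    )
    fractions = FractionMatrix(all_samples, list(CELL_TYPES), np.vstack(frac_parts))
    truth = GroundTruth(planted, dual, decoys, signature, beta)
    sig_collection = GeneSetCollection(sets={"MHC1": signature},
                                       descriptions={"MHC1": "MHC-I signature"})
    return SyntheticCohort(
        expression=expr,
        clinical=clinical,
        fractions=fractions,
        latent_activity=pd.Series(np.concatenate(latent_parts), index=all_samples),
        truth=truth,
        signature=sig_collection,
    )


def simulate_cellline_panel(config: SimulationConfig) -> CellLinePanel:
    """A small cell-line panel mirroring the bulk expression structure,
    plus knockout dependency scores: planted dual-effectors essential
    (~N(-0.8, 0.1)), every other gene near zero (~N(0, 0.15))."""
    signature, planted, dual, decoys = _gene_ids(config)
    gene_ids = signature + planted + decoys
    streams = _streams(config.seed, ["means", "latent", "expr", "fractions", "survival",
                                     "panel_latent", "panel_expr", "dependency"])
    mu_sig = streams["means"].normal(5.0, 1.0, len(signature))
    mu_neg = np.clip(streams["means"].normal(3.5, 1.0, len(planted)), 2.0, None)
    mu_dec = streams["means"].normal(1.5, 2.0, len(decoys))

    n = config.n_cell_lines
    lines = [f"LINE{i + 1:03d}" for i in range(n)]
    a = streams["panel_latent"].normal(0.0, 1.0, n)
    X = _expression_block(config, a, streams["panel_expr"], mu_sig, mu_neg, mu_dec)
    expr = ExpressionMatrix(gene_ids, lines, X, scale="log2_tpm")

    dep = streams["dependency"].normal(0.0, config.dependency_null_sd, (len(gene_ids), n))
    dual_rows = [gene_ids.index(g) for g in dual]
    dep[dual_rows] = streams["dependency"].normal(
        config.dependency_dual_mean, config.dependency_dual_sd, (len(dual), n)
    )
    dependency = pd.DataFrame(dep, index=gene_ids, columns=lines)
    truth = GroundTruth(planted, dual, decoys, signature,
                        {e: config.beta_for(e) for e in ENDPOINTS})
    return CellLinePanel(expression=expr, dependency=dependency, truth=truth)


# immune-type sampling weights for non-tumor cells in single-cell samples
_SC_IMMUNE_BASE = {"CD8_T": 2.0, "NK_activated": 1.0, "CD4_T": 2.0, "T_reg": 1.0,
                   "B_cell": 1.5, "Monocyte": 1.5}


def simulate_single_cell(config: SimulationConfig) -> list[SingleCellSample]:
    """Per-patient single-cell count matrices with cell-type labels.

    Each sample carries a latent activity ``A_s``; tumor cells inherit a
    per-cell latent centered on it that drives the MHC-I program up and
    planted-gene expression down (zero-inflated; extra dropout
    ``sc_dropout``), and the CD8 T / activated-NK share of immune cells
    increases with ``A_s`` — so per-sample planted expression
    anti-correlates with both the MHC-I score and TIL proportions.
    """
    signature, planted, dual, decoys = _gene_ids(config)
    gene_ids = signature + planted + decoys
    streams = _streams(config.seed, ["sc_sample", "sc_cells"])
    lo, hi = config.tumor_prop_range
    if not 0.0 <= lo < hi <= 1.0:
        raise MhcScreenError("tumor_prop_range must satisfy 0 <= lo < hi <= 1")
    immune_types = list(_SC_IMMUNE_BASE)
    base_w = np.array([_SC_IMMUNE_BASE[t] for t in immune_types])
    til_cols = [immune_types.index(t) for t in TIL_TYPES]

    samples: list[SingleCellSample] = []
    for s in range(config.n_sc_samples):
        sid = f"P{s + 1:03d}"
        rng = streams["sc_cells"]
        tumor_prop = streams["sc_sample"].uniform(lo, hi)
        A = streams["sc_sample"].normal(0.0, 1.0)
        n_cells = config.cells_per_sample
        is_tumor = rng.random(n_cells) < tumor_prop
        w = base_w.copy().astype(float)
        w_til = w.copy()
        w_til[til_cols] *= math.exp(config.fraction_coupling * A)
        w_til /= w_til.sum()
        types = np.where(
            is_tumor, "Cancer_epithelial", rng.choice(immune_types, size=n_cells, p=w_til)
        )
        cells = [f"{sid}_c{i + 1:04d}" for i in range(n_cells)]
        counts = rng.poisson(0.2, (len(gene_ids), n_cells)).astype(float)

        tumor_idx = np.nonzero(is_tumor)[0]
        if tumor_idx.size:
            m = rng.normal(A, 1.0, tumor_idx.size)
            sig_rate = np.exp(0.5 + 0.7 * m)
            for i, g in enumerate(signature):
                counts[i, tumor_idx] = rng.poisson(sig_rate)
            p_expr = 1.0 / (1.0 + np.exp(-( -config.sc_effect * m )))
            p_expr *= 1.0 - config.sc_dropout
            for k, g in enumerate(planted):
                gi = len(signature) + k
                expressed = rng.random(tumor_idx.size) < p_expr
                counts[gi, tumor_idx] = np.where(expressed, 1.0 + rng.poisson(1.0, tumor_idx.size), 0.0)
        expr = ExpressionMatrix(gene_ids, cells, counts, scale="counts")
        samples.append(SingleCellSample(
            sample_id=sid,
            expression=expr,
            cell_types=pd.Series(types, index=cells),
            tumor_proportion=float(is_tumor.mean()),
        ))
    return samples


def make_signature_matrix(seed: int = 0, markers_per_type: int = 10) -> SignatureMatrix:
    """Synthetic deconvolution reference: each cell type over-expresses
    its own block of marker genes on the linear scale."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n_types = len(CELL_TYPES)
    genes = [f"MRK_{t}_{i + 1:02d}" for t in CELL_TYPES for i in range(markers_per_type)]
    base = rng.uniform(0.5, 2.0, (markers_per_type * n_types, n_types))
    for t in range(n_types):
        rows = slice(t * markers_per_type, (t + 1) * markers_per_type)
        base[rows, t] += rng.uniform(8.0, 15.0, markers_per_type)
    return SignatureMatrix(genes, list(CELL_TYPES), base)


def mix_fractions(
    signature: SignatureMatrix,
    fractions: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_prefix: str = "MIX",
) -> ExpressionMatrix:
    """Linear mixtures of the signature columns with the given fractions
    (samples x types), optionally with Gaussian noise proportional to
    the mean signal — the forward model the deconvolver inverts."""
    rng = np.random.default_rng(seed)
    fractions = np.asarray(fractions, dtype=float)
    M = signature.values @ fractions.T
    if noise_sd > 0:
        M = M + rng.normal(0.0, noise_sd * M.mean(), M.shape)
        M = np.clip(M, 0.0, None)
    samples = [f"{sample_prefix}{i + 1:04d}" for i in range(fractions.shape[0])]
    return ExpressionMatrix(list(signature.gene_ids), samples, M, scale="linear")
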