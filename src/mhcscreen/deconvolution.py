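"""Immune-cell fraction estimation from bulk mixtures.

A simplex-constrained least-squares deconvolution against a marker-gene
signature matrix: per sample, non-negative least squares followed by
renormalization to the simplex.  It is deterministic, exact on
noiseless mixtures, and scale-invariant per sample, which is all the
TIL-correlation filter downstream requires.  A real reference matrix
(e.g. LM22) can be supplied as a TSV in place of the synthetic one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import ExpressionMatrix, MhcScreenError, logger
from .scoring import CorrelationResult, spearman


@dataclass
class SignatureMatrix:
    """Marker genes x cell types, non-negative reference expression."""

    gene_ids: list[str]
    cell_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise MhcScreenError("signature matrix shape mismatch")
        if np.any(self.values < 0):
            raise MhcScreenError("signature matrix must be non-negative")
        if np.any(self.values.sum(axis=0) == 0):
            raise MhcScreenError("signature matrix has an all-zero cell-type column")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_types)

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(float))


@dataclass
class FractionMatrix:
    """Samples x cell types; rows on the simplex."""

    sample_ids: list[str]
    cell_types: list[str]
    values: np.ndarray
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.cell_types)):
            raise MhcScreenError("fraction matrix shape mismatch")
        if np.any(self.values < -1e-12):
            raise MhcScreenError("fractions must be non-negative")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise MhcScreenError("fractions must sum to 1 per sample")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cell_types)

    def column(self, cell_type: str) -> np.ndarray:
        return self.values[:, self.cell_types.index(cell_type)]


def estimate_fractions(mixture: ExpressionMatrix, signature: SignatureMatrix) -> FractionMatrix:
    """Per-sample NNLS against the signature columns, renormalized to
    the simplex.

    Deconvolution operates on the linear scale; log2-TPM input is
    exponentiated (2**x) with a warning before fitting.
    """
    shared = [g for g in signature.gene_ids if g in set(mixture.gene_ids)]
    if not shared:
        raise MhcScreenError("mixture and signature share no marker genes")
    S = signature.to_frame().loc[shared].to_numpy(float)
    M = mixture.to_frame().loc[shared].to_numpy(float)
    if mixture.scale == "log2_tpm":
        logger.warning("deconvolution needs linear-scale input; exponentiating log2 values")
        M = np.power(2.0, M)
    elif mixture.scale == "lognorm":
        logger.warning("deconvolution needs linear-scale input; applying expm1 to log-normalized values")
        M = np.expm1(M)
    fractions = np.empty((mixture.n_samples, len(signature.cell_types)))
    residuals = np.empty(mixture.n_samples)
    for j in range(mixture.n_samples):
        m = M[:, j]
        if np.all(m == 0):
            raise MhcScreenError(f"all-zero mixture column for sample {mixture.sample_ids[j]!r}")
        coef, rnorm = nnls(S, m)
        total = coef.sum()
        if total == 0:
            raise MhcScreenError(f"deconvolution returned all-zero weights for sample {mixture.sample_ids[j]!r}")
        fractions[j] = coef / total
        residuals[j] = rnorm
    return FractionMatrix(list(mixture.sample_ids), list(signature.cell_types), fractions, residuals)


def correlate_expression_with_fractions(
    expr: ExpressionMatrix,
    fractions: FractionMatrix,
    genes: list[str] | None = None,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each gene's expression with each
    cell-type fraction over shared samples.

    Returns a genes x cell-types DataFrame of
    :class:`~mhcscreen.scoring.CorrelationResult`.
    """
    genes = list(genes) if genes is not None else list(expr.gene_ids)
    cell_types = list(cell_types) if cell_types is not None else list(fractions.cell_types)
    shared = [s for s in expr.sample_ids if s in set(fractions.sample_ids)]
    if len(shared) < 3:
        raise MhcScreenError("fewer than 3 shared samples")
    frac_df = fractions.to_frame().loc[shared]
    expr_df = expr.to_frame().loc[genes, shared]
    out: dict[str, list[CorrelationResult]] = {ct: [] for ct in cell_types}
    for ct in cell_types:
        if ct not in frac_df.columns:
            raise MhcScreenError(f"cell type {ct!r} not in fraction matrix")
        f = frac_df[ct].to_numpy(float)
        for gene in genes:
            out[ct].append(spearman(expr_df.loc[gene].to_numpy(float), f))
    return pd.DataFrame(out, index=pd.Index(genes, name="gene"))
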