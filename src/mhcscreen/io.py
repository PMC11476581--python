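"""Readers, writers and core containers for the screening pipeline.

All external formats are plain text: TSV/CSV expression matrices
(genes in rows, samples in columns — the UCSC Xena convention), GMT
gene-set collections, TSV clinical tables, YAML/JSON run configuration
and JSON provenance reports.

Gene and sample identifiers are opaque strings; no symbol mapping is
performed.  Survival times are stored internally in years; a declared
``days`` unit on load is converted with the Julian-year factor 365.25.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mhcscreen")

DAYS_PER_YEAR = 365.25

VALID_SCALES = ("log2_tpm", "counts", "lognorm", "linear")


class MhcScreenError(Exception):
    """Base class for hard errors raised by the pipeline."""


class ParseError(MhcScreenError):
    """Malformed input file."""


class DegenerateStratumError(MhcScreenError):
    """A stratified comparison has an empty stratum (e.g. every cell
    expresses the gene, or none does)."""


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with a declared value scale.

    ``scale`` is one of ``log2_tpm`` (log2(TPM + 0.001) bulk values),
    ``counts`` (non-negative integers) or ``lognorm`` (log-normalized
    counts, e.g. single-cell log1p values).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "log2_tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in VALID_SCALES:
            raise MhcScreenError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise MhcScreenError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MhcScreenError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise MhcScreenError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            raise MhcScreenError("expression values must be finite")
        if self.scale == "counts":
            if np.any(self.values < 0) or not np.allclose(self.values, np.round(self.values)):
                raise MhcScreenError("counts scale requires non-negative integers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx], self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, idx], self.scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets; within-set duplicates are removed on construction."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            if not genes:
                raise MhcScreenError(f"gene set {name!r} is empty")
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g, None)
            clean[name] = list(seen)
        self.sets = clean

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample survival records over one or more endpoints.

    ``endpoints`` maps endpoint name -> DataFrame indexed by sample id
    with columns ``time`` (years, >= 0) and ``event`` (0/1); samples
    with a missing time or event for an endpoint are simply absent from
    that endpoint's frame but remain in ``sample_ids``.
    """

    sample_ids: list[str]
    endpoints: dict[str, pd.DataFrame]
    cohort: pd.Series  # sample id -> cohort label
    subtype: pd.Series | None = None
    er_status: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MhcScreenError("duplicate sample identifiers in clinical table")
        missing = set(self.sample_ids) - set(self.cohort.index)
        if missing:
            raise MhcScreenError(f"samples without a cohort label: {sorted(missing)[:5]}")
        for name, df in self.endpoints.items():
            if not {"time", "event"} <= set(df.columns):
                raise MhcScreenError(f"endpoint {name!r} lacks time/event columns")
            if (df["time"] < 0).any():
                raise MhcScreenError(f"negative survival time in endpoint {name!r}")
            if not df["event"].isin((0, 1)).all():
                bad = df.index[~df["event"].isin((0, 1))][0]
                raise MhcScreenError(f"event value outside {{0,1}} in endpoint {name!r}, sample {bad!r}")

    def endpoint_names(self) -> list[str]:
        return list(self.endpoints)

    def available(self, endpoint: str, samples: Sequence[str]) -> pd.DataFrame:
        """Endpoint records restricted to the given samples, dropping
        samples unavailable for this endpoint."""
        df = self.endpoints[endpoint]
        keep = [s for s in samples if s in df.index]
        return df.loc[keep]

    def samples_in_cohort(self, cohort: str) -> list[str]:
        return [s for s in self.sample_ids if self.cohort.get(s) == cohort]


@dataclass
class RunConfig:
    """All thresholds the screening cascade consumes, with the shipped
    defaults, plus run plumbing (seed, endpoint list, horizon grid)."""

    # cascade thresholds
    rho_signature_max: float = -0.15   # inclusive (<=)
    p_max: float = 0.05                # strict (<)
    expr_min: float = 1.0              # inclusive, on log2(tpm + 0.001)
    prognostic_max: float = -12.0      # strict (<) for the focal cohort
    risky_threshold: float = -12.0     # per-cohort risky flag (<=)
    min_risky_cohorts: int = 3         # strict (> k cohorts)
    rho_til_max: float = -0.1          # strict (<), both CD8 T and activated NK
    dependency_max: float = -0.5       # strict (<), median across lines
    cellline_rho_max: float = 0.0      # strict (<)
    # single-cell exclusion bounds on tumor-cell proportion
    sc_tumor_frac_min: float = 0.10
    sc_tumor_frac_max: float = 0.90
    # survival model grid
    alpha: float = 0.05
    horizons: tuple[float, ...] = (1.0, 3.0, 5.0, 10.0, math.inf)
    endpoints: tuple[str, ...] = ("OS", "DSS", "PFS", "TTE")
    dichotomize_expression: bool = False
    # plumbing
    focal_cohort: str = "BRCA"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_signature_max", "rho_til_max", "cellline_rho_max"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise MhcScreenError(f"{name}={v} outside [-1, 1]")
        if not 0.0 < self.p_max <= 1.0:
            raise MhcScreenError("p_max must lie in (0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise MhcScreenError("alpha must lie in (0, 1]")
        if int(self.seed) != self.seed:
            raise MhcScreenError("seed must be an integer")

    def thresholds_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["horizons"] = ["inf" if math.isinf(h) else h for h in self.horizons]
        d["endpoints"] = list(self.endpoints)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if "horizons" in data:
            data["horizons"] = tuple(math.inf if h in ("inf", ".inf") else float(h) for h in data["horizons"])
        if "endpoints" in data:
            data["endpoints"] = tuple(data["endpoints"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise MhcScreenError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# readers


def read_expression_matrix(path: str | Path, scale: str = "log2_tpm") -> ExpressionMatrix:
    """Read a TSV/CSV matrix with gene ids in the first column and
    sample ids in the header.

    Duplicate gene rows are collapsed by their mean with a logged
    warning; a duplicate sample id or a non-numeric cell is a hard
    error naming the offending row/column.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise ParseError(f"duplicate sample id {col!r} in {path}")
        seen.add(col)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any() or df.isna().any().any():
        mask = numeric.isna()
        r = mask.any(axis=1).idxmax()
        c = mask.loc[r].idxmax()
        raise ParseError(f"non-numeric value at gene {r!r}, sample {c!r} in {path}")
    if numeric.index.duplicated().any():
        dups = sorted(set(numeric.index[numeric.index.duplicated()]))
        logger.warning("collapsing %d duplicated gene row(s) by mean: %s", len(dups), dups[:5])
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(
        gene_ids=[str(g) for g in numeric.index],
        sample_ids=[str(s) for s in numeric.columns],
        values=numeric.to_numpy(dtype=float),
        scale=scale,
    )


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # default (shortest-repr) float formatting round-trips doubles exactly
    expr.to_frame().to_csv(path, sep=sep, index_label="gene")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        return GeneSetCollection(sets={}, descriptions={})
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_clinical_table(
    path: str | Path,
    endpoint_spec: Mapping[str, tuple[str, str]],
    time_unit: str = "years",
    sample_col: str = "sample_id",
    cohort_col: str = "cohort",
    subtype_col: str | None = None,
    er_col: str | None = None,
) -> ClinicalTable:
    """Read a TSV clinical table.

    ``endpoint_spec`` maps endpoint name -> (time column, event column).
    Rows with a missing time or event for an endpoint are retained in the
    table but flagged unavailable for that endpoint.  Negative times and
    event values outside {0, 1} are hard errors.
    """
    if time_unit not in ("years", "days"):
        raise MhcScreenError(f"time_unit must be 'years' or 'days', got {time_unit!r}")
    df = pd.read_csv(path, sep="\t", dtype={sample_col: str})
    for col in (sample_col, cohort_col):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r} in {path}")
    samples = df[sample_col].tolist()
    df = df.set_index(sample_col)
    endpoints: dict[str, pd.DataFrame] = {}
    for name, (tcol, ecol) in endpoint_spec.items():
        for col in (tcol, ecol):
            if col not in df.columns:
                raise ParseError(f"missing column {col!r} for endpoint {name!r} in {path}")
        sub = df[[tcol, ecol]].apply(pd.to_numeric, errors="coerce")
        avail = sub.notna().all(axis=1)
        sub = sub.loc[avail]
        times = sub[tcol].to_numpy(float)
        events = sub[ecol].to_numpy(float)
        if (times < 0).any():
            bad = sub.index[times < 0][0]
            raise ParseError(f"negative {name} time for sample {bad!r}")
        if not np.isin(events, (0.0, 1.0)).all():
            bad = sub.index[~np.isin(events, (0.0, 1.0))][0]
            raise ParseError(f"{name} event outside {{0,1}} for sample {bad!r}")
        if time_unit == "days":
            times = times / DAYS_PER_YEAR
        frame = pd.DataFrame({"time": times, "event": events.astype(int)}, index=sub.index)
        frame.index.name = None
        endpoints[name] = frame
    return ClinicalTable(
        sample_ids=samples,
        endpoints=endpoints,
        cohort=df[cohort_col].astype(str),
        subtype=df[subtype_col].astype(str) if subtype_col and subtype_col in df.columns else None,
        er_status=df[er_col].astype(str) if er_col and er_col in df.columns else None,
    )


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    """Write a clinical table in the layout ``read_clinical_table`` expects
    (times in years, one ``<endpoint>_time`` / ``<endpoint>_event`` pair per
    endpoint)."""
    out = pd.DataFrame(index=pd.Index(clinical.sample_ids, name="sample_id"))
    out["cohort"] = clinical.cohort.reindex(clinical.sample_ids)
    if clinical.subtype is not None:
        out["subtype"] = clinical.subtype.reindex(clinical.sample_ids)
    if clinical.er_status is not None:
        out["er_status"] = clinical.er_status.reindex(clinical.sample_ids)
    for name, df in clinical.endpoints.items():
        out[f"{name}_time"] = df["time"].reindex(clinical.sample_ids)
        out[f"{name}_event"] = df["event"].reindex(clinical.sample_ids)
    out.to_csv(path, sep="\t", float_format="%.17g")


def endpoint_spec_for(clinical_or_names) -> dict[str, tuple[str, str]]:
    """Endpoint spec matching :func:`write_clinical_table` column names."""
    names = clinical_or_names.endpoint_names() if isinstance(clinical_or_names, ClinicalTable) else list(clinical_or_names)
    return {n: (f"{n}_time", f"{n}_event") for n in names}


# ---------------------------------------------------------------------------
# screen report


def write_screen_report(result, out_dir: str | Path) -> list[Path]:
    """Write per-stage gene lists (TSV) and a provenance JSON.

    Deterministic given identical input: gene lists are sorted, JSON keys
    are sorted, and no timestamps are recorded.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for stage in result.stages:
        p = out_dir / f"stage_{stage.name}.tsv"
        with open(p, "w") as fh:
            fh.write("gene\n")
            for g in sorted(stage.passed):
                fh.write(g + "\n")
        written.append(p)
    for fname, genes in (("candidates.tsv", result.candidates), ("dual_effectors.tsv", result.dual_effectors)):
        p = out_dir / fname
        with open(p, "w") as fh:
            fh.write("gene\n")
            for g in sorted(genes):
                fh.write(g + "\n")
        written.append(p)
    provenance = {
        "thresholds": result.thresholds,
        "seed": result.seed,
        "stages": [{"name": s.name, "n_in": s.n_in, "n_out": len(s.passed)} for s in result.stages],
        "stage_cardinalities": [len(s.passed) for s in result.stages],
        "n_candidates": len(result.candidates),
        "n_dual_effectors": len(result.dual_effectors),
        "package": "mhcscreen 0.1.0",
    }
    p = out_dir / "provenance.json"
    p.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written
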