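"""Signed gene co-expression network construction.

Builds a condition-specific gene co-expression network (GCN) from a genes ×
samples abundance matrix by thresholding the Pearson correlation coefficient
(PCC): an edge is kept iff ``|r|`` strictly exceeds the threshold (default
0.8), and its sign (positive/negative co-expression) is recorded.

Correlations are computed on ``log2(x + 1)``-transformed abundances by
default, the standard variance-stabilising choice for RNA-Seq-derived
tables; pass ``transform="raw"`` to correlate the abundances as given.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(
    r"^(?P<cultivar>.+?)_(?P<stage>stage\d+|[^_]+)_(?P<rep>rep\d+)$"
)


@dataclass
class ExpressionMatrix:
    """Genes × samples abundance table with a parsed sample design.

    ``data`` holds nonnegative abundances (FPKM-like units), indexed by gene
    id with sample ids as columns. Sample ids of the form
    ``<cultivar>_<stage>_rep<k>`` are parsed into a design table; other ids
    are kept with a null design.
    """

    data: pd.DataFrame
    design: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if not np.issubdtype(np.asarray(self.data.values).dtype, np.number):
            bad = self._first_non_numeric()
            raise ValueError(f"non-numeric expression value at {bad}")
        finite_per_row = np.isfinite(self.data.values.astype(float)).sum(axis=1)
        if len(self.data.columns) and (finite_per_row < 3).any():
            genes = self.data.index[finite_per_row < 3].tolist()
            raise ValueError(f"genes with fewer than 3 finite values: {genes}")
        if self.design is None:
            self.design = parse_sample_design(list(self.data.columns))

    def _first_non_numeric(self) -> str:
        for j, col in enumerate(self.data.columns):
            for i, gid in enumerate(self.data.index):
                try:
                    float(self.data.iat[i, j])
                except (TypeError, ValueError):
                    return f"row {gid!r}, column {col!r}"
        return "unknown cell"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def stage_means(self) -> pd.DataFrame:
        """Per-gene mean abundance within each stage of the design."""
        if self.design["stage"].isna().all():
            raise ValueError("sample design has no stage labels")
        groups = self.data.T.groupby(self.design["stage"].values)
        return groups.mean().T

    def subset(self, gene_ids: list[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            logger.warning("subset: %d gene ids absent from matrix", len(missing))
        keep = [g for g in gene_ids if g in self.data.index]
        return ExpressionMatrix(self.data.loc[keep].copy())

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def parse_sample_design(sample_ids: list[str]) -> pd.DataFrame:
    """Parse ``cultivar_stage_rep`` sample ids into a design table."""
    rows = []
    for sid in sample_ids:
        m = _SAMPLE_RE.match(sid)
        if m:
            rows.append((sid, m["cultivar"], m["stage"], m["rep"]))
        else:
            rows.append((sid, None, None, None))
    return pd.DataFrame(
        rows, columns=["sample_id", "cultivar", "stage", "replicate"]
    ).set_index("sample_id")


def load_expression(path, sep: str | None = None) -> ExpressionMatrix:
    """Load a genes × samples TSV/CSV (first column = gene id, header row).

    The delimiter is inferred from the filename (.csv → comma, else tab)
    unless given. Duplicate gene ids and non-numeric cells raise ValueError
    naming the offender.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0)
    dup = raw.index[raw.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene ids in {path}: {dup}")
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in {path} at row {bad[0]!r}, column {col!r}"
            )
        raw[col] = coerced
    return ExpressionMatrix(raw.astype(float))


@dataclass
class NetworkConfig:
    """Parameters of GCN construction; houses the |PCC| cutoff (default 0.8)."""

    pcc_threshold: float = 0.8
    min_variance: float = 0.0
    transform: str = "log2"  # "log2" -> log2(x+1); "raw"

    def __post_init__(self) -> None:
        if not 0.0 < self.pcc_threshold <= 1.0:
            raise ValueError(
                f"pcc_threshold must be in (0, 1], got {self.pcc_threshold}"
            )
        if self.transform not in ("log2", "raw"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass(frozen=True)
class CoexpressionEdge:
    """One unordered co-expression edge; sign follows sign(r)."""

    gene_a: str
    gene_b: str
    r: float
    sign: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self edge on {self.gene_a}")


def filter_dynamic_genes(m: ExpressionMatrix, rule: dict) -> ExpressionMatrix:
    """Restrict the matrix to developmentally dynamic genes.

    ``rule`` is one of::

        {"kind": "genes", "genes": [...]}            explicit gene list
        {"kind": "fold_change", "min_fold": f}       max/min of stage means >= f
        {"kind": "cv", "min_cv": c}                  coefficient of variation >= c

    An empty result is allowed (warning, not error). The applied rule is
    logged.
    """
    kind = rule.get("kind")
    if kind == "genes":
        wanted = [g for g in rule["genes"] if g in m.data.index]
        missing = set(rule["genes"]) - set(wanted)
        if missing:
            logger.warning("filter: %d listed genes absent", len(missing))
        kept = m.data.loc[wanted]
    elif kind == "fold_change":
        means = m.stage_means()
        lo = means.min(axis=1).clip(lower=1e-9)
        fold = means.max(axis=1) / lo
        kept = m.data.loc[fold >= rule["min_fold"]]
    elif kind == "cv":
        mu = m.data.mean(axis=1)
        cv = m.data.std(axis=1, ddof=1) / mu.replace(0.0, np.nan)
        kept = m.data.loc[cv.fillna(0.0) >= rule["min_cv"]]
    else:
        raise ValueError(f"unknown filter rule {kind!r}")
    logger.info("filter_dynamic_genes(%s): %d -> %d genes", kind, len(m.data), len(kept))
    if kept.empty:
        logger.warning("filter_dynamic_genes produced an empty matrix")
    return ExpressionMatrix(kept.copy())


def compute_pcc_matrix(
    m: ExpressionMatrix, transform: str = "log2", min_shared: int = 3
) -> pd.DataFrame:
    """All-pairs Pearson correlation of (transformed) expression profiles.

    Pairwise-complete over finite values with a minimum of ``min_shared``
    shared samples (fewer ⇒ NaN ⇒ no edge). Zero-variance genes get NaN
    against all partners and are thereby excluded from edges; the diagonal
    is 1 for all genes. Raises if the matrix has fewer than 3 samples.
    """
    if m.data.shape[1] < 3:
        raise ValueError("need at least 3 samples to compute correlations")
    x = m.data.astype(float)
    if transform == "log2":
        x = np.log2(x + 1.0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    xt = x.T  # samples × genes, as pandas .corr expects
    corr = xt.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    zero_var = xt.std(ddof=0) == 0.0
    if zero_var.any():
        logger.info(
            "compute_pcc_matrix: %d zero-variance genes excluded from edges",
            int(zero_var.sum()),
        )
        ids = corr.index[zero_var.values]
        corr.loc[ids, :] = np.nan
        corr.loc[:, ids] = np.nan
        for g in ids:
            corr.loc[g, g] = 1.0
    return corr


def build_network(corr: pd.DataFrame, config: NetworkConfig) -> list[CoexpressionEdge]:
    """Threshold the correlation matrix into a signed edge list.

    An edge is emitted iff ``|r|`` is strictly greater than the cutoff, so
    r equal to the threshold yields no edge. Each unordered pair appears
    once (gene_a < gene_b lexicographically); NaN correlations never edge.
    """
    t = config.pcc_threshold
    genes = list(corr.index)
    vals = corr.values
    iu, ju = np.triu_indices(len(genes), k=1)
    edges: list[CoexpressionEdge] = []
    for i, j in zip(iu, ju):
        r = vals[i, j]
        if np.isfinite(r) and abs(r) > t:
            a, b = sorted((genes[i], genes[j]))
            edges.append(
                CoexpressionEdge(a, b, float(r), "positive" if r > 0 else "negative")
            )
    return edges


def edges_to_frame(edges: list[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.gene_a, e.gene_b, e.r, e.sign) for e in edges],
        columns=["gene_a", "gene_b", "r", "sign"],
    )
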