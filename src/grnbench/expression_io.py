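"""Expression / sensitivity matrix containers, readers and wrangling filters.

Expression values are assumed to sit on a log2(TPM+1)-like scale: nonnegative,
with 0 meaning "not detected". Sensitivity values are CHRONOS-like gene-effect
scores: unbounded, more negative meaning a stronger growth defect on knockout.

Two different zero conventions apply, mirroring how bulk-cohort (TCGA-style)
and cell-line (CCLE-style) data are treated:

* cell-line path (:func:`filter_zero_genes`): zeros are legitimate values and
  genes are dropped only when zeros are too frequent;
* bulk-cohort path (:func:`half_zero_filter_and_knn_impute`): zeros in retained
  genes are treated as missing and imputed from the k nearest gene rows.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError, InsufficientDataError

logger = logging.getLogger(__name__)

_DEPMAP_HEADER = re.compile(r"^\s*(?P<symbol>\S+)\s*\((?P<entrez>\d+)\)\s*$")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with a cancer-type label per sample.

    ``values``: DataFrame indexed by gene symbol, columns = sample ids.
    ``sample_types``: Series mapping sample id -> cancer-type label ("pan" when
    the cohort is not stratified).
    """

    values: pd.DataFrame
    sample_types: pd.Series | None = None

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicated gene symbols in expression matrix: {dupes[:5]}")
        if self.sample_types is None:
            self.sample_types = pd.Series("pan", index=self.values.columns)
        else:
            self.sample_types = self.sample_types.reindex(self.values.columns).fillna("pan")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_type(self, cancer_type: str) -> "ExpressionMatrix":
        keep = self.sample_types.index[self.sample_types == cancer_type]
        return ExpressionMatrix(self.values[keep], self.sample_types[keep])


@dataclass
class SensitivityMatrix:
    """Genes x cell-lines gene-effect matrix (negative = sensitising).

    May contain missing entries prior to alignment; ``line_types`` labels each
    cell line with a cancer type.
    """

    values: pd.DataFrame
    line_types: pd.Series | None = None

    def __post_init__(self):
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicated cell-line identifiers: {dupes[:5]}")
        if self.line_types is None:
            self.line_types = pd.Series("pan", index=self.values.columns)
        else:
            self.line_types = self.line_types.reindex(self.values.columns).fillna("pan")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def lines(self) -> pd.Index:
        return self.values.columns

    def subset_type(self, cancer_type: str) -> "SensitivityMatrix":
        keep = self.line_types.index[self.line_types == cancer_type]
        return SensitivityMatrix(self.values[keep], self.line_types[keep])


def read_expression(path, annotation_path=None, sep=None) -> ExpressionMatrix:
    """Read a genes x samples delimited table, optionally with a sample sidecar.

    The sidecar is a two-column table (sample_id, cancer_type).
    """
    values = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    sample_types = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep=None, engine="python")
        if ann.shape[1] < 2:
            raise FormatError("sample annotation sidecar needs (sample_id, cancer_type) columns")
        sample_types = pd.Series(ann.iloc[:, 1].values, index=ann.iloc[:, 0].astype(str))
    return ExpressionMatrix(values, sample_types)


def read_depmap_gene_effect(path, plain_symbols: bool = False,
                            line_types: pd.Series | None = None) -> SensitivityMatrix:
    """Read a DepMap-layout gene-effect CSV (cell lines x "SYMBOL (Entrez)").

    Columns are reduced to bare symbols and the matrix transposed to
    genes x cell lines. With ``plain_symbols=True`` headers that are not in
    "SYMBOL (digits)" form are accepted verbatim instead of raising.
    """
    raw = pd.read_csv(path, index_col=0)
    symbols = []
    for i, col in enumerate(raw.columns):
        m = _DEPMAP_HEADER.match(str(col))
        if m:
            symbols.append(m.group("symbol"))
        elif plain_symbols:
            symbols.append(str(col).strip())
        else:
            raise FormatError(
                f"column {i} ({col!r}) does not match 'SYMBOL (EntrezID)'; "
                "pass plain_symbols=True to accept bare symbols"
            )
    counts = pd.Series(symbols).value_counts()
    clashes = counts[counts > 1].index.tolist()
    if clashes:
        raise FormatError(f"columns collapse to duplicate gene symbols: {clashes}")
    out = raw.T
    out.index = symbols
    return SensitivityMatrix(out, line_types)


def filter_zero_genes(expr: ExpressionMatrix, max_zero_fraction: float = 0.20) -> ExpressionMatrix:
    """Drop genes whose fraction of zero entries strictly exceeds the threshold.

    A gene with exactly the threshold fraction of zeros is retained.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise DataError("max_zero_fraction must lie in [0, 1]")
    frac = (expr.values == 0).mean(axis=1)
    keep = frac <= max_zero_fraction
    dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise DataError("zero-fraction filter removed every gene")
    if dropped:
        logger.info("filter_zero_genes: dropped %d of %d genes (> %.0f%% zeros)",
                    dropped, len(keep), 100 * max_zero_fraction)
    return ExpressionMatrix(expr.values.loc[keep], expr.sample_types)


def _knn_impute_rows(mat: np.ndarray, k: int) -> np.ndarray:
    """Impute NaNs in each row from the mean of the k nearest rows (by Euclidean
    distance over mutually observed columns, scaled to the full column count).

    Candidate neighbours for a missing cell are rows observing that cell. When a
    row with missing values has fewer than k fully observed candidate rows, its
    gaps fall back to the row mean (with a warning), matching the documented
    degenerate-input contract.
    """
    out = mat.copy()
    obs = ~np.isnan(mat)
    n_rows, n_cols = mat.shape
    complete = obs.all(axis=1)
    for i in range(n_rows):
        miss = ~obs[i]
        if not miss.any():
            continue
        # rows that observe every column this row also observes are usable for
        # a distance; a candidate must additionally observe the missing cell
        if complete.sum() - (1 if complete[i] else 0) < k:
            fallback = np.nanmean(mat[i])
            warnings.warn("knn imputation: fewer than k complete rows; "
                          "falling back to row-mean imputation", stacklevel=3)
            out[i, miss] = fallback
            continue
        shared = obs[i] & obs  # (n_rows, n_cols) mask of mutually observed cols
        diff = mat - mat[i]
        with np.errstate(invalid="ignore"):
            sq = np.where(shared, diff ** 2, 0.0)
        n_shared = shared.sum(axis=1)
        dist = np.sqrt(sq.sum(axis=1) * (n_cols / np.maximum(n_shared, 1)))
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for j in np.where(miss)[0]:
            cand = obs[:, j] & np.isfinite(dist)
            if cand.sum() == 0:
                out[i, j] = np.nanmean(mat[i])
                continue
            order = np.argsort(dist[cand], kind="stable")
            idx = np.where(cand)[0][order[:k]]
            out[i, j] = mat[idx, j].mean()
    return out


def half_zero_filter_and_knn_impute(expr: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Bulk-cohort cleanup: drop genes with zeros in more than half the samples,
    then treat the remaining zeros as missing and kNN-impute them over gene rows.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    frac = (expr.values == 0).mean(axis=1)
    keep = frac <= 0.5
    if keep.sum() == 0:
        raise DataError("half-zero filter removed every gene")
    vals = expr.values.loc[keep].to_numpy(dtype=float).copy()
    vals[vals == 0] = np.nan
    if np.isnan(vals).any():
        vals = _knn_impute_rows(vals, k)
    out = pd.DataFrame(vals, index=expr.values.index[keep], columns=expr.values.columns)
    return ExpressionMatrix(out, expr.sample_types)


def align_datasets(expr: ExpressionMatrix, sens: SensitivityMatrix):
    """Restrict both matrices to shared genes and shared sample/line ids.

    Shared axes are sorted lexicographically so repeated runs produce identical
    layouts; the operation is idempotent.
    """
    genes = expr.genes.intersection(sens.genes).sort_values()
    samples = expr.samples.intersection(sens.lines).sort_values()
    if len(genes) == 0:
        raise AlignmentError(
            f"no shared genes (expression {len(expr.genes)}, sensitivity {len(sens.genes)})")
    if len(samples) == 0:
        raise AlignmentError(
            f"no shared samples (expression {len(expr.samples)}, sensitivity {len(sens.lines)})")
    e = ExpressionMatrix(expr.values.loc[genes, samples], expr.sample_types[samples])
    s = SensitivityMatrix(sens.values.loc[genes, samples], sens.line_types[samples])
    return e, s
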