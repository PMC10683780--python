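"""Parsing and normalisation of regulon tables from three source dialects.

All dialects are reduced to one internal edge table with columns
``regulator, target, weight, mor`` where ``weight`` is a nonnegative magnitude
(ARACNe likelihood, GENIE3 weight, or 1.0 for curated edges) and ``mor`` is the
signed mode of regulation in [-1, 1] (-1 inhibition, +1 activation). The
effective signed weight used by every activity method is ``weight * mor``.

Recognised dialects and their column names:

==============  =============================================
aracne-like     regulator, target, mor, likelihood
grndb-like      TF, gene, weight           (no sign; inferred later)
dorothea-like   tf, target, mor [, confidence]
synthetic       regulator, target, weight, mor
==============  =============================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, FormatError, InsufficientDataError
from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

DIALECTS = {
    "aracne-like": {"regulator": "regulator", "target": "target",
                    "mor": "mor", "likelihood": "likelihood"},
    "grndb-like": {"regulator": "TF", "target": "gene", "weight": "weight"},
    "dorothea-like": {"regulator": "tf", "target": "target", "mor": "mor"},
    "synthetic": {"regulator": "regulator", "target": "target",
                  "weight": "weight", "mor": "mor"},
}

EDGE_COLUMNS = ["regulator", "target", "weight", "mor"]


@dataclass
class RegulonSet:
    """A weighted, signed regulator->target edge collection from one source.

    ``edges`` has columns regulator, target, weight, mor (plus bookkeeping
    columns such as ``zero_mor``). ``needs_sign`` marks grndb-like sets whose
    mor is a +1 placeholder until :func:`infer_mor_sign` runs. ``log`` records
    row counts dropped or merged during parsing and normalisation.
    """

    edges: pd.DataFrame
    source: str
    cancer_type: str = "pan"
    confidence: frozenset | None = None
    needs_sign: bool = False
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise FormatError(f"edge table lacks columns {missing}")
        if (self.edges["weight"] < 0).any():
            raise DataError("edge weights must be nonnegative magnitudes")
        if (self.edges["mor"].abs() > 1).any():
            raise DataError("mor must lie in [-1, 1]")
        dup = self.edges.duplicated(subset=["regulator", "target"])
        if dup.any():
            raise DataError("duplicate (regulator, target) pairs in edge table")
        self_edges = int((self.edges["regulator"] == self.edges["target"]).sum())
        if self_edges:
            self.log.setdefault("self_edges", self_edges)

    @property
    def regulators(self) -> pd.Index:
        return pd.Index(self.edges["regulator"].unique())

    def targets_of(self, regulator: str) -> pd.Index:
        return pd.Index(self.edges.loc[self.edges["regulator"] == regulator, "target"])

    def signed_weights(self) -> pd.Series:
        """Effective signed weight per edge: weight * mor."""
        return self.edges["weight"] * self.edges["mor"]

    def to_table(self) -> pd.DataFrame:
        """Canonical long table: regulator, target, weight, mor, source, cancer_type."""
        out = self.edges[EDGE_COLUMNS].copy()
        out["source"] = self.source
        out["cancer_type"] = self.cancer_type
        return out


def _dedup_max_weight(df: pd.DataFrame, log: dict) -> pd.DataFrame:
    """Resolve duplicate (regulator, target) rows by keeping the max-|weight| one."""
    n = len(df)
    order = df.assign(_absw=df["weight"].abs()).sort_values(
        ["regulator", "target", "_absw"], kind="stable")
    out = order.drop_duplicates(subset=["regulator", "target"], keep="last")
    out = out.drop(columns="_absw").sort_index()
    collisions = n - len(out)
    if collisions:
        log["duplicate_edges_merged"] = collisions
        logger.warning("resolved %d duplicate (regulator, target) rows (kept max |weight|)",
                       collisions)
    return out.reset_index(drop=True)


def parse_regulons(path, dialect: str, confidence_levels=None, sep=None,
                   cancer_type: str = "pan") -> RegulonSet:
    """Parse a delimited regulon table into the internal representation.

    ``confidence_levels`` (a subset of {"A".."E"}) is only valid for the
    dorothea-like dialect and keeps rows at those curation levels. grndb-like
    edges get mor = +1 as a placeholder and the returned set is flagged
    ``needs_sign`` until :func:`infer_mor_sign` is applied.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    if confidence_levels is not None and dialect != "dorothea-like":
        raise ConfigurationError("confidence_levels only applies to dorothea-like tables")
    cols = DIALECTS[dialect]
    raw = pd.read_csv(path, sep=sep, engine="python")
    for role, name in cols.items():
        if name not in raw.columns:
            raise FormatError(f"{dialect} table is missing required column {name!r}")
    log: dict = {}

    df = pd.DataFrame({
        "regulator": raw[cols["regulator"]],
        "target": raw[cols["target"]],
    })
    if dialect == "aracne-like":
        df["weight"] = pd.to_numeric(raw[cols["likelihood"]])
        df["raw_mor"] = pd.to_numeric(raw[cols["mor"]])
        # keep a bounded placeholder until update_mor_aracne computes sign(raw_mor)
        df["mor"] = np.sign(df["raw_mor"]).astype(float)
    elif dialect == "grndb-like":
        df["weight"] = pd.to_numeric(raw[cols["weight"]])
        df["mor"] = 1.0
    elif dialect == "dorothea-like":
        df["weight"] = 1.0
        mor = pd.to_numeric(raw[cols["mor"]]) if cols["mor"] in raw.columns else 1.0
        df["mor"] = np.sign(mor).astype(float)
        df.loc[df["mor"] == 0, "mor"] = 1.0  # unsigned curated edges default to activation
        if "confidence" in raw.columns and confidence_levels is not None:
            levels = frozenset(confidence_levels)
            keep = raw["confidence"].isin(levels).to_numpy()
            log["confidence_filtered"] = int((~keep).sum())
            df = df.loc[keep]
        elif confidence_levels is not None:
            raise FormatError("dorothea-like table has no 'confidence' column to filter on")
    else:  # synthetic
        df["weight"] = pd.to_numeric(raw[cols["weight"]])
        df["mor"] = pd.to_numeric(raw[cols["mor"]])

    bad = df["regulator"].isna() | df["target"].isna()
    if bad.any():
        log["rows_missing_ids"] = int(bad.sum())
        logger.warning("dropped %d rows with missing regulator or target", int(bad.sum()))
        df = df.loc[~bad]
    if (df["weight"] < 0).any():
        raise DataError("negative weight magnitude in regulon table")
    df = _dedup_max_weight(df.reset_index(drop=True), log)
    if len(df) == 0:
        logger.warning("parsed regulon table %s contains no edges", path)
    return RegulonSet(df, source=dialect, cancer_type=cancer_type,
                      confidence=frozenset(confidence_levels) if confidence_levels else None,
                      needs_sign=(dialect == "grndb-like"), log=log)


def update_mor_aracne(rs: RegulonSet) -> RegulonSet:
    """Apply the ARACNe sign update: signed weight = likelihood x sign(raw mor).

    Stored as (weight=likelihood, mor=sign(raw mor)); sign(0) = 0, so an edge
    with raw mor exactly 0 contributes nothing to activity — it is flagged in a
    ``zero_mor`` column rather than dropped, leaving regulon sizes unchanged.
    """
    if rs.source != "aracne-like":
        raise ConfigurationError("update_mor_aracne requires an aracne-like set")
    if (rs.edges["weight"] < 0).any():
        raise DataError("negative likelihood")
    edges = rs.edges.copy()
    raw = edges["raw_mor"] if "raw_mor" in edges.columns else edges["mor"]
    edges["mor"] = np.sign(raw).astype(float)
    edges["zero_mor"] = raw == 0
    log = dict(rs.log)
    n_zero = int(edges["zero_mor"].sum())
    if n_zero:
        log["zero_mor_edges"] = n_zero
    return RegulonSet(edges, source=rs.source, cancer_type=rs.cancer_type,
                      confidence=rs.confidence, needs_sign=False, log=log)


def infer_mor_sign(rs: RegulonSet, reference_expression: ExpressionMatrix) -> RegulonSet:
    """Assign each unsigned edge the sign of the Spearman correlation between
    regulator and target expression across reference samples.

    Edges whose regulator or target is absent from the reference matrix, or
    whose expression is constant (rank correlation undefined), are dropped and
    counted. Rank correlation uses midranks for ties, so the result is
    invariant under strictly monotone transforms of either vector.
    """
    if not rs.needs_sign:
        raise ConfigurationError("infer_mor_sign expects a set flagged needs_sign")
    if reference_expression.values.shape[1] < 3:
        raise InsufficientDataError("need >= 3 reference samples for Spearman sign inference")
    expr = reference_expression.values
    genes = set(expr.index)
    edges = rs.edges.copy()
    present = edges["regulator"].isin(genes) & edges["target"].isin(genes)
    log = dict(rs.log)
    if (~present).any():
        log["edges_missing_in_expression"] = int((~present).sum())
    edges = edges.loc[present].reset_index(drop=True)

    ranks = pd.DataFrame(
        stats.rankdata(expr.to_numpy(dtype=float), axis=1),
        index=expr.index, columns=expr.columns)
    reg_r = ranks.loc[edges["regulator"]].to_numpy()
    tgt_r = ranks.loc[edges["target"]].to_numpy()
    reg_sd = reg_r.std(axis=1)
    tgt_sd = tgt_r.std(axis=1)
    degenerate = (reg_sd == 0) | (tgt_sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rc = ((reg_r - reg_r.mean(axis=1, keepdims=True))
              * (tgt_r - tgt_r.mean(axis=1, keepdims=True))).mean(axis=1)
        rho = rc / (reg_sd * tgt_sd)
    if degenerate.any():
        log["edges_zero_variance"] = int(degenerate.sum())
        logger.warning("dropped %d edges with zero-variance expression", int(degenerate.sum()))
    edges = edges.loc[~degenerate].reset_index(drop=True)
    edges["mor"] = np.sign(rho[~degenerate]).astype(float)
    return RegulonSet(edges, source=rs.source, cancer_type=rs.cancer_type,
                      confidence=rs.confidence, needs_sign=False, log=log)


_SIZE_BINS = [(20, "small"), (100, "medium"), (np.inf, "large")]


def stratify_regulons(sets) -> pd.DataFrame:
    """Assign each regulon a size class and a unique-target class.

    Size: small (<=20 targets), medium (21-100), large (>100). A target is
    unique to a regulon when no other regulon among the supplied sets contains
    it; the unique fraction 0 maps to class "none", (0, 0.10] to "low" and
    > 0.10 to "high". Returns one row per (source, cancer_type, regulator).
    """
    sets = list(sets)
    if not sets:
        raise ConfigurationError("stratify_regulons needs at least one regulon set")
    records = []
    target_lists = []
    for si, rs in enumerate(sets):
        for reg, grp in rs.edges.groupby("regulator", sort=True):
            target_lists.append((si, rs.source, rs.cancer_type, reg, set(grp["target"])))
    # multiplicity of each target across all tested regulons
    from collections import Counter
    counts: Counter = Counter()
    for _, _, _, _, tgts in target_lists:
        counts.update(tgts)
    for _, source, cancer_type, reg, tgts in target_lists:
        n = len(tgts)
        n_unique = sum(1 for t in tgts if counts[t] == 1)
        frac = n_unique / n if n else 0.0
        size_class = next(lbl for bound, lbl in _SIZE_BINS if n <= bound)
        if frac == 0:
            uniq_class = "none"
        elif frac <= 0.10:
            uniq_class = "low"
        else:
            uniq_class = "high"
        records.append({"source": source, "cancer_type": cancer_type, "regulator": reg,
                        "n_targets": n, "size_class": size_class,
                        "unique_fraction": frac, "unique_class": uniq_class})
    return pd.DataFrame.from_records(records)
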