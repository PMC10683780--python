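"""Regulon-based activity inference: ULM, MLM, aREA (VIPER-style), weighted
sum/mean and their consensus.

All methods consume a paired (expression matrix, regulon weight matrix) and
produce regulators x samples activity scores. The linear-model scores are
t-statistics of regression slopes; the aREA score is a normalised enrichment
score over within-sample expression midranks; the weighted sum/mean are plain
signed-weight projections. Consensus is the per-sample mean of z-scored method
outputs.

Normative definitions used here:

* ULM: per (sample, regulator), regress the sample's expression profile across
  genes on the regulator's signed weight vector with intercept; the activity is
  the slope t-value with G-2 degrees of freedom.
* MLM: per sample, one multiple regression of expression on all regulators'
  weight vectors jointly plus intercept; activity(r, s) is coefficient r's
  t-value with G-(p+1) degrees of freedom.
* aREA (single-layer, no pleiotropy/shadow correction): genes receive midranks
  r_i within the sample; two-tail quantiles q2_i = Phi^-1(r_i/(G+1)), one-tail
  quantiles q1_i = Phi^-1(0.5 + |r_i/(G+1) - 0.5|);
  ES = [sum w_i mor_i q2_i + sum w_i (1-|mor_i|) q1_i] / sum w_i and
  NES = ES * sqrt(sum_i w_i / max_j w_j).
* wsum(r, s) = sum_i signedweight_i x_is; wmean divides by sum_i |signedweight_i|.

Perfect-fit t-values (zero residual variance) are capped at +/-1e6 and flagged
so downstream correlations stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, DataError, InsufficientDataError
from .expression_io import ExpressionMatrix
from .regulons import RegulonSet

logger = logging.getLogger(__name__)

T_CAP = 1e6
METHODS = ("ulm", "mlm", "viper", "wsum", "wmean")


@dataclass
class ActivityMatrix:
    """Regulators x samples activity scores for one (regulon, method) pair."""

    values: pd.DataFrame
    method: str
    source: str = "unknown"
    cancer_type: str = "pan"
    log: dict = field(default_factory=dict)

    @property
    def regulators(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename("score").reset_index()
        long.columns = ["regulator", "sample", "score"]
        long["method"] = self.method
        long["source"] = self.source
        return long


@dataclass
class RegulonWeights:
    """Dense per-regulator weight vectors over the genes of a paired expression
    matrix: ``signed`` = weight*mor (the quantity the linear methods use),
    ``weight`` = nonnegative magnitudes and ``mor`` the signed mode of
    regulation (kept separately because aREA weighs its one-tail term by
    w*(1-|mor|)). All frames are genes x regulators; non-target entries are 0.
    """

    signed: pd.DataFrame
    weight: pd.DataFrame
    mor: pd.DataFrame
    source: str = "unknown"
    cancer_type: str = "pan"
    log: dict = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.signed.index

    @property
    def regulators(self) -> pd.Index:
        return self.signed.columns


def build_weight_matrix(reg: RegulonSet, expr: ExpressionMatrix,
                        min_targets: int = 5) -> RegulonWeights:
    """Pair a regulon set with an expression matrix.

    Edges whose target is absent from the expression matrix are discarded;
    regulators left with fewer than ``min_targets`` targets are dropped with a
    logged count. Raises if no regulator survives.
    """
    if min_targets < 1:
        raise DataError("min_targets must be >= 1")
    genes = expr.genes
    edges = reg.edges
    present = edges["target"].isin(set(genes))
    kept = edges.loc[present]
    counts = kept.groupby("regulator", sort=True).size()
    keep_regs = counts.index[counts >= min_targets]
    log = {"regulators_in": int(edges["regulator"].nunique()),
           "regulators_kept": int(len(keep_regs)),
           "edges_outside_expression": int((~present).sum())}
    if len(keep_regs) == 0:
        raise DataError(
            f"no regulator has >= {min_targets} targets in the expression matrix")
    dropped = log["regulators_in"] - log["regulators_kept"]
    if dropped:
        logger.info("build_weight_matrix: dropped %d regulators below min_targets=%d",
                    dropped, min_targets)
    kept = kept.loc[kept["regulator"].isin(set(keep_regs))]
    gi = pd.Index(genes)
    rows = gi.get_indexer(kept["target"])
    cols = pd.Index(keep_regs).get_indexer(kept["regulator"])
    shape = (len(gi), len(keep_regs))
    weight = np.zeros(shape)
    mor = np.zeros(shape)
    weight[rows, cols] = kept["weight"].to_numpy(dtype=float)
    mor[rows, cols] = kept["mor"].to_numpy(dtype=float)
    signed = weight * mor
    mk = lambda a: pd.DataFrame(a, index=gi, columns=pd.Index(keep_regs))
    return RegulonWeights(mk(signed), mk(weight), mk(mor),
                          source=reg.source, cancer_type=reg.cancer_type, log=log)


def _activity(values, weights: RegulonWeights, expr: ExpressionMatrix, method: str,
              log=None) -> ActivityMatrix:
    vals = pd.DataFrame(values, index=weights.regulators, columns=expr.samples)
    return ActivityMatrix(vals, method=method, source=weights.source,
                          cancer_type=weights.cancer_type, log=log or {})


def ulm_activity(expr: ExpressionMatrix, weights: RegulonWeights) -> ActivityMatrix:
    """Univariate linear model activity: slope t-value of expression ~ weights.

    Computed via the correlation identity t = r sqrt(G-2)/sqrt(1-r^2), which is
    algebraically the slope/SE of the simple regression with intercept. A
    zero-variance weight vector yields a missing score (reason logged); perfect
    fits are capped at +/-1e6.
    """
    X = expr.values.to_numpy(dtype=float)  # genes x samples
    W = weights.signed.to_numpy(dtype=float)  # genes x regulators
    G = X.shape[0]
    if G < 3:
        raise InsufficientDataError("ULM needs at least 3 genes")
    Xc = X - X.mean(axis=0, keepdims=True)
    Wc = W - W.mean(axis=0, keepdims=True)
    xsd = np.sqrt((Xc ** 2).sum(axis=0))
    wsd = np.sqrt((Wc ** 2).sum(axis=0))
    log: dict = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Wc.T @ Xc) / np.outer(wsd, xsd)  # regulators x samples
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((G - 2) / (1.0 - r ** 2))
    perfect = np.isclose(np.abs(r), 1.0)
    if perfect.any():
        t[perfect] = np.sign(r[perfect]) * T_CAP
        log["capped_perfect_fit"] = int(perfect.sum())
    degenerate_w = wsd == 0
    if degenerate_w.any():
        t[degenerate_w, :] = np.nan
        log["zero_variance_weight_vectors"] = int(degenerate_w.sum())
    degenerate_x = xsd == 0
    if degenerate_x.any():
        # constant expression profile: slope 0 by convention
        t[:, degenerate_x] = 0.0
    return _activity(t, weights, expr, "ulm", log)


def _collinear_report(W: np.ndarray, regulators) -> list:
    """Pairwise max-correlation report for a rank-deficient design."""
    Wc = W - W.mean(axis=0, keepdims=True)
    sd = np.sqrt((Wc ** 2).sum(axis=0))
    sd[sd == 0] = 1.0
    C = (Wc / sd).T @ (Wc / sd)
    np.fill_diagonal(C, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(C)), C.shape)
    return [(regulators[i], regulators[j], float(C[i, j]))]


def mlm_activity(expr: ExpressionMatrix, weights: RegulonWeights) -> ActivityMatrix:
    """Multivariate linear model activity: joint regression per sample; the
    activity of regulator r in sample s is the t-value of coefficient r."""
    X = expr.values.to_numpy(dtype=float)
    W = weights.signed.to_numpy(dtype=float)
    G, p = W.shape
    if G <= p + 1:
        raise InsufficientDataError(
            f"MLM needs more genes ({G}) than regulators + 1 ({p + 1})")
    M = np.column_stack([np.ones(G), W])
    MtM = M.T @ M
    rank = np.linalg.matrix_rank(MtM)
    if rank < p + 1:
        pairs = _collinear_report(W, list(weights.regulators))
        raise CollinearityError(
            "rank-deficient weight matrix; most correlated regulators: "
            + ", ".join(f"{a}~{b} (r={c:.3f})" for a, b, c in pairs), pairs=pairs)
    MtM_inv = np.linalg.inv(MtM)
    beta = MtM_inv @ (M.T @ X)  # (p+1) x samples
    resid = X - M @ beta
    dof = G - (p + 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(MtM_inv), sigma2))
    log: dict = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    perfect = se == 0
    if perfect.any():
        t[perfect] = np.sign(beta[perfect]) * T_CAP
        log["capped_perfect_fit"] = int(perfect.sum())
    return _activity(t[1:, :], weights, expr, "mlm", log)


def viper_activity(expr: ExpressionMatrix, weights: RegulonWeights) -> ActivityMatrix:
    """Single-layer analytic rank-based enrichment (aREA) activity.

    Per sample, genes get midranks over the G genes; the enrichment score
    combines a signed two-tail term with a mode-of-regulation-discounted
    one-tail term, and is scaled by sqrt(sum w / max w) into a normalised
    enrichment score. All-tied expression in a sample yields activity 0 for
    every regulator.
    """
    X = expr.values.to_numpy(dtype=float)
    G = X.shape[0]
    if G < 5:
        raise InsufficientDataError("aREA needs at least 5 genes")
    Wabs = weights.weight.to_numpy(dtype=float)
    mor = weights.mor.to_numpy(dtype=float)
    ranks = stats.rankdata(X, axis=0)  # midranks, genes x samples
    u = ranks / (G + 1)
    q2 = stats.norm.ppf(u)
    q1 = stats.norm.ppf(0.5 + np.abs(u - 0.5))
    signed = Wabs * mor
    onetail_w = Wabs * (1.0 - np.abs(mor))
    wsum = Wabs.sum(axis=0)
    wmax = Wabs.max(axis=0)
    es = (signed.T @ q2 + onetail_w.T @ q1) / wsum[:, None]
    nes_factor = np.sqrt(wsum / wmax)
    return _activity(es * nes_factor[:, None], weights, expr, "viper")


def wsum_activity(expr: ExpressionMatrix, weights: RegulonWeights) -> ActivityMatrix:
    """Weighted sum: projection of each sample's expression on signed weights."""
    W = weights.signed.to_numpy(dtype=float)
    X = expr.values.to_numpy(dtype=float)
    return _activity(W.T @ X, weights, expr, "wsum")


def wmean_activity(expr: ExpressionMatrix, weights: RegulonWeights) -> ActivityMatrix:
    """Weighted mean: weighted sum divided by the total absolute signed weight.

    Differs from wsum by a positive per-regulator constant, so any sample-wise
    correlation computed from the two is identical.
    """
    W = weights.signed.to_numpy(dtype=float)
    X = expr.values.to_numpy(dtype=float)
    denom = np.abs(W).sum(axis=0)
    return _activity((W.T @ X) / denom[:, None], weights, expr, "wmean")


def consensus_activity(per_method) -> ActivityMatrix:
    """Consensus: per method and sample, z-score activities across regulators
    (sd = 0 gives all zeros), then average the z-scores across methods.

    Missing scores are excluded cell-wise; the effective number of contributing
    methods per cell is tracked in the log.
    """
    mats = list(per_method)
    if len(mats) < 2:
        raise DataError("consensus needs at least two method matrices")
    ref = mats[0].values
    for m in mats[1:]:
        if not (m.values.index.equals(ref.index) and m.values.columns.equals(ref.columns)):
            raise DataError("activity matrices disagree on the regulator x sample grid")
    zs = []
    for m in mats:
        v = m.values.to_numpy(dtype=float)
        mu = np.nanmean(v, axis=0, keepdims=True)
        sd = np.nanstd(v, axis=0, ddof=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (v - mu) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        zs.append(z)
    stack = np.stack(zs)
    with np.errstate(invalid="ignore"):
        cons = np.nanmean(stack, axis=0)
    n_eff = (~np.isnan(stack)).sum(axis=0)
    log = {"methods": [m.method for m in mats],
           "min_effective_n": int(n_eff.min()), "max_effective_n": int(n_eff.max())}
    first = mats[0]
    vals = pd.DataFrame(cons, index=ref.index, columns=ref.columns)
    return ActivityMatrix(vals, method="consensus", source=first.source,
                          cancer_type=first.cancer_type, log=log)


def compute_activities(expr: ExpressionMatrix, weights: RegulonWeights,
                       methods=("ulm", "mlm", "viper", "wsum", "wmean", "consensus")):
    """Run the requested activity methods; "consensus" averages whichever base
    methods were requested (all five if only consensus was asked for).
    Returns {method: ActivityMatrix}."""
    fns = {"ulm": ulm_activity, "mlm": mlm_activity, "viper": viper_activity,
           "wsum": wsum_activity, "wmean": wmean_activity}
    want = list(methods)
    base = [m for m in want if m != "consensus"]
    if "consensus" in want and not base:
        base = list(METHODS)
    out = {}
    for m in base:
        if m not in fns:
            raise DataError(f"unknown activity method {m!r}")
        out[m] = fns[m](expr, weights)
    if "consensus" in want:
        out["consensus"] = consensus_activity([out[m] for m in base])
    return out
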