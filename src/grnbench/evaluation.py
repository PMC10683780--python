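"""The statistical comparison layer.

Per-gene Pearson correlations between a predictor (activity scores or the
regulator's own mRNA) and gene-effect scores; |R| binning and sign splits;
common-language effect size (CLES, numerically the AUROC) for binary
essentiality; matched-vs-mismatched regulon ranking; sequential adjusted-R^2
variance decomposition; and Fisher's-exact gene-set enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import ConfigurationError, DataError, InsufficientDataError
from .essentiality import EssentialityCalls

ABS_R_EDGES = (0.2, 0.4, 0.6, 0.8, 1.0)


def pearson_with_p(x, y):
    """Pearson R with a two-sided p-value from the t transform
    t = R sqrt(n-2)/sqrt(1-R^2) with n-2 degrees of freedom.

    Pairwise-complete: entries missing in either vector are dropped. Returns
    (nan, nan) when fewer than 3 complete pairs remain or either vector is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _bin_abs_r(abs_r: float) -> str:
    if np.isnan(abs_r) or abs_r <= ABS_R_EDGES[0]:
        return "below-threshold"
    for lo, hi in zip(ABS_R_EDGES[:-1], ABS_R_EDGES[1:]):
        if lo < abs_r <= hi:
            return f"({lo},{hi}]"
    return f"({ABS_R_EDGES[-2]},{ABS_R_EDGES[-1]}]"


def correlate_all(pred_values: pd.DataFrame, sens_values: pd.DataFrame, genes,
                  predictor: str = "predictor", alpha: float = 0.05,
                  cancer_type: str = "pan", source: str = "unknown") -> pd.DataFrame:
    """One correlation record per gene: Pearson R and p between the predictor
    row and the gene-effect row, the p < alpha significance flag, the |R| bin
    and the sign of R. Per-gene failures (constant vectors, too few pairs)
    produce records with missing statistics rather than raising.
    """
    records = []
    for g in genes:
        if g not in pred_values.index or g not in sens_values.index:
            records.append((g, np.nan, np.nan, 0))
            continue
        x = pred_values.loc[g].to_numpy(dtype=float)
        y = sens_values.loc[g].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        r, p = pearson_with_p(x, y)
        records.append((g, r, p, int(ok.sum())))
    df = pd.DataFrame(records, columns=["gene", "r", "p", "n"])
    df["abs_r"] = df["r"].abs()
    df["significant"] = df["p"] < alpha
    df["bin"] = [_bin_abs_r(a) for a in df["abs_r"]]
    df["sign"] = np.where(df["r"] >= 0, "positive", "negative")
    df.loc[df["r"].isna(), "sign"] = "missing"
    df["predictor"] = predictor
    df["cancer_type"] = cancer_type
    df["source"] = source
    return df


def cles(essential_scores, nonessential_scores) -> float:
    """Common-language effect size: the probability that a random draw from the
    essential group scores higher than one from the non-essential group, ties
    counted half. Numerically identical to the AUROC of the scores against the
    essential/non-essential labels.
    """
    e = np.asarray(essential_scores, dtype=float)
    n = np.asarray(nonessential_scores, dtype=float)
    if len(e) == 0 or len(n) == 0:
        raise DataError("both groups must be non-empty")
    combined = np.concatenate([e, n])
    ranks = stats.rankdata(combined)  # midranks make ties count half
    u = ranks[: len(e)].sum() - len(e) * (len(e) + 1) / 2.0
    return float(u / (len(e) * len(n)))


def rank_sum_test(a, b, alternative: str = "two-sided") -> float:
    """Unpaired Wilcoxon / Mann-Whitney rank-sum p-value.

    Exact enumeration when the pooled size is <= 12 and tie-free; otherwise the
    normal approximation with tie and continuity corrections. ``alternative``
    follows scipy semantics ("two-sided", "greater", "less") with "greater"
    meaning a tends to exceed b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.pvalue)


def cles_table(pred_values: pd.DataFrame, calls: EssentialityCalls, eligible,
               thresholds=(0.7, 0.8, 0.9), alpha: float = 0.05,
               predictor: str = "predictor") -> tuple[pd.DataFrame, dict]:
    """Per-gene CLES of predictor scores in essential vs non-essential lines,
    with the rank-sum p-value, plus counts of genes clearing each CLES
    threshold at p < alpha.
    """
    records = []
    for g in sorted(eligible):
        if g not in pred_values.index or g not in calls.calls.index:
            continue
        call_row = calls.calls.loc[g]
        scores = pred_values.loc[g].reindex(call_row.index)
        ok = call_row.notna() & scores.notna()
        e = scores[ok & (call_row == 1.0)].to_numpy()
        n = scores[ok & (call_row == 0.0)].to_numpy()
        if len(e) == 0 or len(n) == 0:
            continue
        c = cles(e, n)
        p = rank_sum_test(e, n)
        records.append((g, c, p, len(e), len(n)))
    df = pd.DataFrame(records, columns=["gene", "cles", "p", "n_essential", "n_nonessential"])
    df["predictor"] = predictor
    counts = {}
    for thr in thresholds:
        if df.empty:
            counts[thr] = 0
        else:
            counts[thr] = int(((df["cles"] > thr) & (df["p"] < alpha)).sum())
    return df, counts


def matched_vs_mismatched(mean_abs_r: pd.DataFrame, alternative: str = "two-sided"):
    """Rank regulon sources within each cancer type (rank 1 = highest mean |R|,
    midranks on ties) and compare matched-cell ranks against mismatched ones
    with the rank-sum test.

    ``mean_abs_r`` is a cancer_type x regulon-source table whose matched cells
    are those where the row label equals the column label. Rows with a missing
    matched cell are excluded from the test. Returns (ranks table, p-value).
    """
    tab = mean_abs_r.astype(float)
    ranks = tab.apply(lambda row: pd.Series(
        stats.rankdata(-row.to_numpy()), index=row.index), axis=1)
    matched, mismatched = [], []
    for ct in tab.index:
        if ct not in tab.columns or np.isnan(tab.loc[ct, ct]):
            continue
        row = ranks.loc[ct]
        matched.append(row[ct])
        mismatched.extend(row.drop(ct).tolist())
    if not matched or not mismatched:
        raise InsufficientDataError("need at least one matched and one mismatched cell")
    # lower rank = better, so "matched better" corresponds to matched < mismatched
    p = rank_sum_test(np.asarray(matched), np.asarray(mismatched),
                      alternative=alternative)
    return ranks, float(p)


def variance_decomposition(df: pd.DataFrame, response: str, terms,
                           categorical=None) -> pd.DataFrame:
    """Sequential adjusted-R^2 decomposition of ``response`` over an ordered
    term list.

    Fits the nested OLS sequence response ~ t1, response ~ t1 + t2, ... with
    categorical terms dummy-encoded (first level as reference) and numeric
    terms standardised; the share of term j is the adjusted R^2 gained when it
    enters. Shares are order-dependent; the output preserves the order used.
    """
    terms = list(terms)
    if categorical is None:
        categorical = [t for t in terms if not pd.api.types.is_numeric_dtype(df[t])]
    work = df[[response] + terms].copy()
    for t in terms:
        if t not in categorical:
            v = work[t].astype(float)
            sd = v.std()
            work[t] = (v - v.mean()) / sd if sd > 0 else 0.0
    n_params = 1 + sum(
        (work[t].nunique() - 1) if t in categorical else 1 for t in terms)
    if len(work) <= n_params:
        raise InsufficientDataError(
            f"{len(work)} rows cannot support {n_params} parameters")
    import statsmodels.formula.api as smf
    work = work.rename(columns={c: c.replace(" ", "_") for c in work.columns})
    resp = response.replace(" ", "_")
    shares = []
    prev_adj = 0.0
    included = []
    for t in terms:
        tn = t.replace(" ", "_")
        included.append(f"C({tn})" if t in categorical else tn)
        model = smf.ols(f"{resp} ~ {' + '.join(included)}", data=work).fit()
        adj = float(model.rsquared_adj)
        shares.append({"term": t, "share": adj - prev_adj, "cumulative_adj_r2": adj})
        prev_adj = adj
    out = pd.DataFrame(shares)
    out.attrs["full_model_adj_r2"] = prev_adj
    out.attrs["term_order"] = terms
    return out


def per_gene_variance(values: pd.DataFrame) -> pd.Series:
    """Unbiased (n-1) variance of each gene/regulator row across samples."""
    if values.shape[1] < 2:
        raise InsufficientDataError("variance needs at least 2 samples")
    return values.var(axis=1, ddof=1)


def gene_set_enrichment(hits, universe, annotation):
    """One-sided (greater) Fisher's exact test of hit/annotation overlap.

    ``hits`` and ``annotation`` are intersected with ``universe`` before the
    2x2 table is formed. Returns (odds ratio, p).
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    hits = set(hits) & universe
    annotation = set(annotation) & universe
    a = len(hits & annotation)
    b = len(hits - annotation)
    c = len(annotation - hits)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)
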