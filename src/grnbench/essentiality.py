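"""Binarisation of gene-effect scores and sometimes-essential filters.

A gene is called essential in a cell line when its CHRONOS-like score falls
strictly below the threshold (default -0.6). Only genes that vary — essential
in some lines, non-essential in others — carry information for across-line
correlation, hence the "sometimes essential" filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .expression_io import SensitivityMatrix


@dataclass
class EssentialityCalls:
    """Binary essentiality calls: 1.0 essential, 0.0 non-essential, NaN missing."""

    calls: pd.DataFrame
    threshold: float
    line_types: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def lines(self) -> pd.Index:
        return self.calls.columns

    def counts(self) -> pd.DataFrame:
        """Per-gene counts of essential and non-essential (non-missing) lines."""
        ess = (self.calls == 1.0).sum(axis=1)
        non = (self.calls == 0.0).sum(axis=1)
        return pd.DataFrame({"essential": ess, "non_essential": non})


def binarize(sens: SensitivityMatrix, threshold: float = -0.6) -> EssentialityCalls:
    """Strict-less-than essentiality calls; missing scores stay missing.

    A score exactly at the threshold is non-essential.
    """
    if not np.isfinite(threshold):
        raise DataError("threshold must be finite")
    vals = sens.values.to_numpy(dtype=float)
    calls = np.where(np.isnan(vals), np.nan, (vals < threshold).astype(float))
    return EssentialityCalls(
        pd.DataFrame(calls, index=sens.genes, columns=sens.lines),
        threshold=threshold, line_types=sens.line_types.copy())


def sometimes_essential(calls: EssentialityCalls, mode: str = "per-cancer",
                        min_fraction: float | None = None):
    """Select genes that are essential in some lines and non-essential in others.

    mode="per-cancer": within each cancer type keep genes with at least one
    essential and one non-essential call; returns {cancer_type: frozenset}.

    mode="pan-cancer": across all lines, keep genes with at least
    max(1, floor(min_fraction * N / 100)) essential AND as many non-essential
    calls, where N counts that gene's non-missing lines; returns a frozenset.
    Missing calls are excluded from both sides of the fraction.
    """
    if mode == "per-cancer":
        out = {}
        for ct in pd.unique(calls.line_types):
            cols = calls.line_types.index[calls.line_types == ct]
            sub = calls.calls[cols]
            ess = (sub == 1.0).sum(axis=1)
            non = (sub == 0.0).sum(axis=1)
            keep = (ess >= 1) & (non >= 1)
            out[ct] = frozenset(sub.index[keep])
        return out
    if mode == "pan-cancer":
        if min_fraction is None or min_fraction <= 0:
            raise ConfigurationError("pan-cancer mode needs a positive min_fraction (percent)")
        ess = (calls.calls == 1.0).sum(axis=1)
        non = (calls.calls == 0.0).sum(axis=1)
        n_obs = ess + non
        if int(n_obs.max()) == 0:
            raise DataError("no non-missing calls")
        need = np.maximum(1, np.floor(min_fraction * n_obs / 100.0)).astype(int)
        keep = (ess >= need) & (non >= need)
        return frozenset(calls.calls.index[keep])
    raise ConfigurationError(f"unknown mode {mode!r}; use 'per-cancer' or 'pan-cancer'")


def binary_eligible(calls: EssentialityCalls, min_per_group: int = 3) -> frozenset:
    """Genes with at least ``min_per_group`` lines in each of the essential and
    non-essential groups — the eligibility rule for binary (CLES) evaluation."""
    if min_per_group < 1:
        raise ConfigurationError("min_per_group must be >= 1")
    ess = (calls.calls == 1.0).sum(axis=1)
    non = (calls.calls == 0.0).sum(axis=1)
    keep = (ess >= min_per_group) & (non >= min_per_group)
    return frozenset(calls.calls.index[keep])
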