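"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure of a multi-cancer benchmark:
regulators with signed, weighted targets; per-sample latent regulator
activity; target expression driven by that activity; regulator mRNA coupled to
its own activity with a tunable coupling; and quantitative gene-effect scores
driven by either the latent activity or the regulator's mRNA plus noise.
Multiple "cancer types" carry partially rewired regulons.

Generative model, per cancer type with its own regulon:

* latent activity         A_rs ~ N(0, 1)
* target gene t           x_ts = sum_r beta_t * w_rt * mor_rt * A_rs + eps,  eps ~ N(0, sigma_e^2)
* regulator's own mRNA    x_rs = alpha * A_rs + sqrt(1 - alpha^2) * eta,     eta ~ N(0, 1)
* background genes        pure N(0, 1) noise
* gene-effect score       y_rs = -beta_s * D_rs + zeta,                      zeta ~ N(0, sigma_s^2)

where D is the standardised driver: the latent activity A (driver="activity"),
the regulator's own mRNA (driver="expression"), zero (driver="none"), or a
convex combination (driver="mixed" with ``driver_mix``). Expression is mapped
by a global affine transform onto a nonnegative log2(TPM+1)-like range (rank
and correlation structure untouched); gene-effect scores are shifted per gene
so a configurable fraction of calls falls below the -0.6 essentiality point,
guaranteeing sometimes-essential structure by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .expression_io import ExpressionMatrix, SensitivityMatrix
from .regulons import RegulonSet


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults follow the benchmark's reference conditions: ten cancer types of
    30 samples each, 2000 genes, 50 regulators with 30 targets apiece,
    unit-variance expression noise, sensitivity effect beta_s = 1 against
    noise sigma_s = 0.5, and an mRNA-activity coupling alpha = 0.6.
    """

    n_cancer_types: int = 10
    n_samples: int = 30              # per cancer type
    n_genes: int = 2000
    n_regulators: int = 50
    targets_min: int = 30
    targets_max: int = 30
    inhibitory_prob: float = 0.3
    rewiring_fraction: float = 0.0   # fraction of targets rewired per non-reference type
    beta_t: float = 1.0              # activity -> target signal strength
    alpha: float = 0.6               # corr(regulator mRNA, own activity)
    driver: str = "expression"       # {"activity", "expression", "none", "mixed"}
    driver_mix: float = 0.5          # weight on activity when driver="mixed"
    beta_s: float = 1.0              # sensitivity effect size
    sigma_e: float = 1.0             # expression noise sd
    sigma_s: float = 0.5             # sensitivity noise sd
    essential_fraction: float = 0.3  # calls planted below the -0.6 point, per gene
    zero_fraction: float = 0.0       # optional zero-inflation of expression
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cancer_types, self.n_samples, self.n_genes,
               self.n_regulators, self.targets_min, self.targets_max) < 1:
            raise ConfigurationError("all counts must be positive")
        if self.targets_min > self.targets_max:
            raise ConfigurationError("targets_min must not exceed targets_max")
        if self.n_genes <= self.n_regulators + self.targets_max:
            raise ConfigurationError(
                "n_genes must exceed n_regulators + targets_max")
        for name in ("inhibitory_prob", "rewiring_fraction", "alpha",
                     "driver_mix", "essential_fraction", "zero_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.driver not in {"activity", "expression", "none", "mixed"}:
            raise ConfigurationError(f"unknown driver {self.driver!r}")

    def cancer_types(self) -> list[str]:
        return [f"CT{i + 1:02d}" for i in range(self.n_cancer_types)]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        return cls(**json.loads(text))


@dataclass
class GroundTruth:
    """Everything planted: per-type regulons, the latent activity matrix
    (regulators x all samples), per-gene generative roles, and the config."""

    regulons: dict                     # cancer_type -> RegulonSet
    activity: pd.DataFrame             # regulators x samples (all types)
    sample_types: pd.Series
    gene_roles: pd.Series              # gene -> {"regulator", "target", "background"}
    config: SyntheticConfig


def _gene_names(cfg: SyntheticConfig):
    regulators = [f"REG{i + 1:03d}" for i in range(cfg.n_regulators)]
    others = [f"G{i + 1:05d}" for i in range(cfg.n_genes - cfg.n_regulators)]
    return regulators, others


def simulate_grn(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> dict:
    """Draw one regulon set per cancer type.

    Each regulator draws a target count uniformly from the configured range and
    samples targets without replacement from the non-regulator genes; edges are
    inhibitory (mor = -1) with the configured probability and carry weights
    uniform on (0.5, 1). Non-reference cancer types rewire the configured
    fraction of each regulator's targets to fresh random genes. Returns
    {cancer_type: RegulonSet}; fully deterministic under the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    regulators, others = _gene_names(cfg)
    pool = np.array(others)
    if cfg.targets_max > len(pool):
        raise ConfigurationError("target range infeasible: not enough non-regulator genes")
    base_edges = []
    for reg in regulators:
        n_t = int(rng.integers(cfg.targets_min, cfg.targets_max + 1))
        targets = rng.choice(pool, size=n_t, replace=False)
        mor = np.where(rng.random(n_t) < cfg.inhibitory_prob, -1.0, 1.0)
        weight = rng.uniform(0.5, 1.0, size=n_t)
        for t, m, w in zip(targets, mor, weight):
            base_edges.append((reg, t, w, m))
    base = pd.DataFrame(base_edges, columns=["regulator", "target", "weight", "mor"])
    out = {}
    types = cfg.cancer_types()
    for i, ct in enumerate(types):
        if i == 0 or cfg.rewiring_fraction == 0.0:
            edges = base.copy()
        else:
            edges = base.copy()
            for reg, grp in base.groupby("regulator", sort=True):
                n_t = len(grp)
                n_rw = int(round(cfg.rewiring_fraction * n_t))
                if n_rw == 0:
                    continue
                idx = rng.choice(grp.index.to_numpy(), size=n_rw, replace=False)
                current = set(grp["target"])
                candidates = np.array([g for g in pool if g not in current])
                new_targets = rng.choice(candidates, size=n_rw, replace=False)
                edges.loc[idx, "target"] = new_targets
        out[ct] = RegulonSet(edges.reset_index(drop=True), source="synthetic",
                             cancer_type=ct)
    return out


def simulate_expression(grns: dict, cfg: SyntheticConfig,
                        rng: np.random.Generator | None = None):
    """Generate expression for all cancer types and the planted ground truth.

    Each type's targets are driven by that type's own regulon; the returned
    matrix concatenates all types' samples and is affinely mapped onto a
    nonnegative log2(TPM+1)-like range (a global monotone map, so every
    rank- and correlation-based statistic is unaffected).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    regulators, others = _gene_names(cfg)
    genes = regulators + others
    gi = {g: i for i, g in enumerate(genes)}
    all_cols, all_types, blocks, acts = [], [], [], []
    for ct in cfg.cancer_types():
        rs = grns[ct]
        samples = [f"{ct}_S{j + 1:03d}" for j in range(cfg.n_samples)]
        A = rng.standard_normal((cfg.n_regulators, cfg.n_samples))
        X = rng.standard_normal((cfg.n_genes, cfg.n_samples)) * 1.0  # background
        # regulator mRNA coupled to own activity
        eta = rng.standard_normal((cfg.n_regulators, cfg.n_samples))
        X[: cfg.n_regulators] = cfg.alpha * A + np.sqrt(1 - cfg.alpha ** 2) * eta
        # targets: signal + noise
        edges = rs.edges
        rows = np.array([gi[t] for t in edges["target"]])
        regs = np.array([regulators.index(r) for r in edges["regulator"]])
        signal = np.zeros((cfg.n_genes, cfg.n_samples))
        sw = (edges["weight"] * edges["mor"]).to_numpy() * cfg.beta_t
        np.add.at(signal, rows, sw[:, None] * A[regs])
        target_rows = np.unique(rows)
        X[target_rows] = signal[target_rows] + \
            rng.standard_normal((len(target_rows), cfg.n_samples)) * cfg.sigma_e
        blocks.append(X)
        acts.append(A)
        all_cols.extend(samples)
        all_types.extend([ct] * cfg.n_samples)
    full = np.concatenate(blocks, axis=1)
    # global affine map onto a nonnegative log2(TPM+1)-like range
    lo, hi = full.min(), full.max()
    span = hi - lo if hi > lo else 1.0
    full = (full - lo) / span * 12.0
    if cfg.zero_fraction > 0:
        cut = np.quantile(full, cfg.zero_fraction, axis=1, keepdims=True)
        full = np.where(full <= cut, 0.0, full)
    values = pd.DataFrame(full, index=genes, columns=all_cols)
    sample_types = pd.Series(all_types, index=all_cols)
    activity = pd.DataFrame(np.concatenate(acts, axis=1),
                            index=regulators, columns=all_cols)
    roles = pd.Series("background", index=genes)
    roles[regulators] = "regulator"
    targeted = sorted({t for rs in grns.values() for t in rs.edges["target"]})
    roles[targeted] = "target"
    truth = GroundTruth(regulons=grns, activity=activity,
                        sample_types=sample_types, gene_roles=roles, config=cfg)
    return ExpressionMatrix(values, sample_types), truth


def simulate_sensitivity(truth: GroundTruth, expr: ExpressionMatrix,
                         cfg: SyntheticConfig,
                         rng: np.random.Generator | None = None) -> SensitivityMatrix:
    """Generate CHRONOS-like gene-effect scores.

    Regulator genes follow score = -beta_s * D + noise with D the standardised
    driver; all other genes are pure noise. Every gene's scores are then
    shifted so its ``essential_fraction`` quantile sits at -0.6, making the
    binarisation point meaningful by construction (a per-gene shift changes no
    correlation or rank statistic).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    genes = list(expr.genes)
    samples = list(expr.samples)
    n_s = len(samples)
    vals = rng.standard_normal((len(genes), n_s)) * cfg.sigma_s
    regulators = [g for g in genes if truth.gene_roles.get(g) == "regulator"]

    def standardize(M):
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (M - mu) / sd

    if cfg.driver != "none" and regulators:
        A = truth.activity.loc[regulators, samples].to_numpy()
        mrna = expr.values.loc[regulators, samples].to_numpy()
        if cfg.driver == "activity":
            D = standardize(A)
        elif cfg.driver == "expression":
            D = standardize(mrna)
        else:  # mixed
            D = standardize(cfg.driver_mix * standardize(A)
                            + (1 - cfg.driver_mix) * standardize(mrna))
        ridx = [genes.index(r) for r in regulators]
        vals[ridx] = -cfg.beta_s * D + rng.standard_normal(D.shape) * cfg.sigma_s
    # centre each gene so essential_fraction of its calls fall below -0.6
    q = np.quantile(vals, cfg.essential_fraction, axis=1, keepdims=True)
    vals = vals - q - 0.6
    return SensitivityMatrix(pd.DataFrame(vals, index=genes, columns=samples),
                             line_types=expr.sample_types.copy())


def simulate_cohort(cfg: SyntheticConfig):
    """Full cohort: (expression, sensitivity, ground truth). Deterministic
    under cfg.seed; the three stages draw from independent seeded streams."""
    grns = simulate_grn(cfg)
    expr, truth = simulate_expression(grns, cfg)
    sens = simulate_sensitivity(truth, expr, cfg)
    return expr, sens, truth
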