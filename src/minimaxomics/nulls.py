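"""Null distributions for the MiniMax statistic.

Two calibration modes are provided. The *theoretical* mode uses the classic
order-statistic result: if the G per-omics pathway p-values are independent
Uniform(0, 1) under the null, their r-th order statistic follows
Beta(r, G - r + 1), so for the default pairwise analysis of three omics
types the MiniMax statistic is Beta(2, 2). The *empirical* mode relaxes the
independence assumption: phenotype labels are permuted, per-omics pathway
p-values recomputed, and a Beta distribution is fitted to the resulting
null MiniMax statistics by maximum likelihood. Correlation between omics
platforms shrinks both fitted shape parameters below their theoretical
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

# clamping bounds: keep the statistic's ranking intact while avoiding
# log(0) / CDF edge cases
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16
FIT_EPS = 1e-12

__all__ = [
    "BetaNull",
    "NullSampleSet",
    "theoretical_null",
    "null_pvalue",
    "TheoreticalNullProvider",
    "EmpiricalNullProvider",
    "permutation_null_samples",
    "fit_beta",
]


@dataclass(frozen=True)
class BetaNull:
    """Beta null model for the order-r MiniMax statistic of g omics types."""

    alpha: float
    beta: float
    r: int
    g: int
    mode: str  # "theoretical" | "empirical"
    n_null: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.mode not in ("theoretical", "empirical"):
            raise ValueError(f"unknown null mode {self.mode!r}")
        if self.mode == "theoretical":
            if self.alpha != self.r or self.beta != self.g - self.r + 1:
                raise ValueError(
                    "theoretical null requires alpha = r, beta = g - r + 1"
                )


@dataclass
class NullSampleSet:
    """Null MiniMax statistics from phenotype-permutation, plus provenance."""

    values: np.ndarray
    b: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values <= 0) | (self.values >= 1)):
            raise ValueError("null statistics must lie in the open interval (0, 1)")


def theoretical_null(r: int, g: int) -> BetaNull:
    """Beta(r, g - r + 1) null for the r-th order statistic of g p-values."""
    if r < 1 or g < 1 or r > g:
        raise ValueError(f"need 1 <= r <= g, got r={r}, g={g}")
    return BetaNull(alpha=float(r), beta=float(g - r + 1), r=r, g=g, mode="theoretical")


def null_pvalue(x: float, null: BetaNull) -> float:
    """Beta CDF (regularized incomplete beta) of the statistic under *null*."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"statistic must lie in [0, 1], got {x}")
    if x == 0.0:
        return 0.0
    if x == 1.0:
        return 1.0
    xc = min(max(x, P_FLOOR), P_CEIL)
    return float(special.betainc(null.alpha, null.beta, xc))


class TheoreticalNullProvider:
    """Per-pathway theoretical null: Beta(r, g_effective - r + 1)."""

    def __init__(self, r: int = 2):
        self.r = r

    def null_for(self, g_effective: int) -> BetaNull:
        return theoretical_null(self.r, g_effective)


class EmpiricalNullProvider:
    """Fitted empirical null, falling back to the theoretical Beta when a
    pathway's effective omics count differs from the fitted one (the global
    fit only calibrates the complete-case order statistic)."""

    def __init__(self, null: BetaNull):
        if null.mode != "empirical":
            raise ValueError("EmpiricalNullProvider requires an empirical BetaNull")
        self.null = null

    def null_for(self, g_effective: int) -> BetaNull:
        if g_effective == self.null.g:
            return self.null
        return theoretical_null(self.null.r, g_effective)


def permutation_null_samples(
    omics_datasets,
    pathways,
    r: int = 2,
    b: int = 100,
    seed: int | None = None,
    share_labels: bool = False,
) -> NullSampleSet:
    """Null MiniMax statistics by phenotype-label permutation.

    For each of *b* permutations the phenotype labels are shuffled
    (independently within each omics dataset by default, since the datasets
    need not share samples), per-omics pathway p-values are recomputed with
    :func:`minimaxomics.scoring.score_all_pathways`, and the order-r MiniMax
    statistic is collected for every pathway with enough non-missing
    p-values.

    Parameters
    ----------
    omics_datasets:
        List of ``(OmicsMatrix, Phenotype)`` pairs.
    pathways:
        :class:`minimaxomics.io.PathwayCollection`.
    share_labels:
        If True, all datasets must have identical sample IDs and a single
        permutation is applied to every layer. Use this for matched designs
        where cross-omics correlation should survive into the null.
    """
    import pandas as pd

    from .core import minimax
    from .scoring import score_all_pathways

    if b < 1:
        raise ValueError(f"need at least one permutation, got b={b}")
    if not omics_datasets:
        raise ValueError("no omics datasets supplied")
    for matrix, phenotype in omics_datasets:
        if phenotype.kind == "binary" and phenotype.outcome.nunique() < 2:
            raise ValueError(
                f"degenerate phenotype for {matrix.omics_label!r}: single class"
            )
    if share_labels:
        ids = [tuple(ph.outcome.index) for _, ph in omics_datasets]
        if len(set(ids)) != 1:
            raise ValueError("share_labels requires identical sample IDs per layer")

    rng = np.random.default_rng(seed)
    values: list[float] = []
    for _ in range(b):
        if share_labels:
            n = len(omics_datasets[0][1].outcome)
            shared_perm = rng.permutation(n)
        columns = {}
        for matrix, phenotype in omics_datasets:
            perm = shared_perm if share_labels else rng.permutation(len(phenotype.outcome))
            shuffled = phenotype.with_outcome_values(
                phenotype.outcome.to_numpy()[perm]
            )
            columns[matrix.omics_label] = score_all_pathways(matrix, shuffled, pathways)
        table = pd.DataFrame(columns)
        for _, row in table.iterrows():
            vals = row.dropna().to_numpy()
            if vals.size >= r:
                values.append(minimax(vals, r))

    arr = np.clip(np.asarray(values, dtype=float), FIT_EPS, 1.0 - FIT_EPS)
    return NullSampleSet(values=arr, b=b, seed=seed)


def fit_beta(samples: NullSampleSet) -> BetaNull:
    """Fit an empirical Beta null by maximum likelihood.

    Uses a method-of-moments start and bounded L-BFGS-B on the negative
    log-likelihood, with both shape parameters constrained to [0.01, 100].
    The fitted ``r`` and ``g`` are taken from nothing -- this is a free
    two-parameter fit -- so they are recorded as r=2, g unchanged by the
    caller via the record on the sample set; here we record the shape only.
    """
    x = np.asarray(samples.values, dtype=float)
    if x.size < 50:
        raise ValueError(f"need at least 50 null samples to fit, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("degenerate null sample: all values equal")
    x = np.clip(x, FIT_EPS, 1.0 - FIT_EPS)

    m, v = float(np.mean(x)), float(np.var(x))
    common = max(m * (1.0 - m) / max(v, 1e-12) - 1.0, 0.02)
    start = np.array([max(m * common, 0.01), max((1.0 - m) * common, 0.01)])

    log_x = np.log(x).sum()
    log_1mx = np.log1p(-x).sum()
    n = x.size

    def nll(theta):
        a, bb = theta
        return -(
            (a - 1.0) * log_x + (bb - 1.0) * log_1mx - n * special.betaln(a, bb)
        )

    res = optimize.minimize(
        nll, start, method="L-BFGS-B", bounds=[(0.01, 100.0), (0.01, 100.0)]
    )
    a_hat, b_hat = (float(t) for t in res.x)
    return BetaNull(
        alpha=a_hat, beta=b_hat, r=2, g=2, mode="empirical", n_null=int(n)
    )


def empirical_null(samples: NullSampleSet, r: int, g: int) -> BetaNull:
    """Fit and attach the analysis order/omics-count metadata."""
    fitted = fit_beta(samples)
    return BetaNull(
        alpha=fitted.alpha, beta=fitted.beta, r=r, g=g,
        mode="empirical", n_null=fitted.n_null,
    )


def ks_against(null: BetaNull, values: np.ndarray):
    """Kolmogorov-Smirnov statistic and p-value of *values* vs the Beta null."""
    return stats.kstest(values, stats.beta(null.alpha, null.beta).cdf)
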