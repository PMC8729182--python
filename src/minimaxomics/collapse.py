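"""Collapse feature-level summary statistics (SNPs/CpGs) to gene scores.

A gene with many mapped features tends to have a smaller minimum p-value
purely by selection (the minimum of n uniform p-values has expectation
1/(n+1)), so the raw -log10(min p) score is biased by gene size. The
correction regresses the score on a smooth spline of the feature count
with a gamma-family GLM (log link) -- under the null the score is
chi-square-like, a special case of the gamma family -- and keeps the
residuals as size-adjusted gene scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines, GLMGam
import statsmodels.api as sm

__all__ = [
    "assign_features",
    "min_p_per_gene",
    "size_bias_correct",
    "collapse_features",
]

P_ONE_CLAMP = 1.0 - 1e-16


def assign_features(
    features: pd.DataFrame, genes: pd.DataFrame, window: int = 5000
) -> pd.DataFrame:
    """Assign each feature to every gene within *window* bp of its span.

    ``features`` needs columns feature_id, chrom, pos, p_value (positions
    1-based); ``genes`` needs gene_id, chrom, start, end (1-based
    inclusive). A feature at exactly ``start - window`` or ``end + window``
    is assigned (inclusive window). Features may map to several genes.
    """
    for col in ("feature_id", "chrom", "pos", "p_value"):
        if col not in features.columns:
            raise ValueError(f"features table missing column {col!r}")
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in genes.columns:
            raise ValueError(f"gene table missing column {col!r}")
    if window < 0:
        raise ValueError("window must be non-negative")
    bad = features[~(features["pos"] > 0)]
    if len(bad):
        raise ValueError(f"non-positive position for feature {bad['feature_id'].iloc[0]!r}")
    bad = genes[~((genes["start"] > 0) & (genes["end"] >= genes["start"]))]
    if len(bad):
        raise ValueError(f"malformed span for gene {bad['gene_id'].iloc[0]!r}")

    out = []
    for chrom, feats in features.groupby("chrom", sort=False):
        spans = genes[genes["chrom"] == chrom]
        if spans.empty:
            continue
        pos = feats["pos"].to_numpy()
        for gene_id, start, end in spans[["gene_id", "start", "end"]].itertuples(
            index=False
        ):
            hit = (pos >= start - window) & (pos <= end + window)
            if hit.any():
                sub = feats.loc[hit, ["feature_id", "p_value"]].copy()
                sub["gene_id"] = gene_id
                out.append(sub)
    if not out:
        return pd.DataFrame(columns=["feature_id", "p_value", "gene_id"])
    return pd.concat(out, ignore_index=True)


def min_p_per_gene(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per gene: smallest assigned p-value (min_p), feature count (n_links),
    and the score y = -log10(min_p). Genes with no features are absent."""
    if assignments.empty:
        raise ValueError("no feature-gene assignments")
    grouped = assignments.groupby("gene_id")["p_value"]
    out = pd.DataFrame(
        {"min_p": grouped.min(), "n_links": grouped.size()}
    ).reset_index()
    clamped = out["min_p"].clip(upper=P_ONE_CLAMP)
    out["y"] = -np.log10(clamped)
    return out


def size_bias_correct(
    scores: pd.DataFrame, df: int = 4, residual_type: str = "response"
) -> pd.DataFrame:
    """Remove the gene-size trend from y = -log10(min_p).

    Fits a gamma-family regression (log link) of y on a cubic regression
    spline of n_links and stores the fitted mean and residual. The default
    residual is "response" (y - fitted mean); "deviance" residuals are also
    available. When every gene has the same n_links the smooth degenerates
    to an intercept-only fit, so residuals are just centered scores.
    """
    for col in ("gene_id", "y", "n_links"):
        if col not in scores.columns:
            raise ValueError(f"gene score table missing column {col!r}")
    if len(scores) < 30:
        raise ValueError(f"need at least 30 genes to fit, got {len(scores)}")
    y = scores["y"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("scores must be positive after clamping p < 1")
    if residual_type not in ("response", "deviance"):
        raise ValueError(f"unknown residual type {residual_type!r}")

    n_links = scores["n_links"].to_numpy(dtype=float)
    family = sm.families.Gamma(link=sm.families.links.Log())
    if np.unique(n_links).size <= df:
        # too few distinct sizes for the spline: intercept-only gamma fit
        model = sm.GLM(y, np.ones((len(y), 1)), family=family).fit()
        fitted = model.fittedvalues
        dev_resid = model.resid_deviance
    else:
        splines = BSplines(n_links[:, None], df=[df], degree=[3])
        model = GLMGam(
            y, exog=np.ones((len(y), 1)), smoother=splines, family=family
        ).fit()
        fitted = model.fittedvalues
        dev_resid = model.resid_deviance

    out = scores.copy()
    out["fitted"] = np.asarray(fitted)
    out["residual"] = (
        y - np.asarray(fitted)
        if residual_type == "response"
        else np.asarray(dev_resid)
    )
    return out


def collapse_features(
    features: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 5000,
    df: int = 4,
    residual_type: str = "response",
) -> pd.DataFrame:
    """assign_features + min_p_per_gene + size_bias_correct in one call."""
    assignments = assign_features(features, genes, window=window)
    scores = min_p_per_gene(assignments)
    return size_bias_correct(scores, df=df, residual_type=residual_type)
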