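"""Single-omics pathway p-values from a raw omics matrix and a phenotype.

This is the built-in pathway test used when only raw data are available:
for each pathway the member genes are standardized, their first principal
component is extracted as a per-sample pathway score, and the score is
tested against the phenotype (logistic likelihood-ratio test for a binary
outcome, linear-regression slope t-test for a continuous one, proportional-
hazards score test for survival). Users with access to platform-specific
pathway tools can skip this module entirely and feed their pathway
p-values straight to the integrator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

MIN_PVALUE = 1e-300  # floor used on perfect separation

__all__ = [
    "OmicsMatrix",
    "Phenotype",
    "standardize",
    "pathway_pc1",
    "pathway_pvalue",
    "score_all_pathways",
]


@dataclass
class OmicsMatrix:
    """Genes x samples matrix for one omics data type."""

    data: pd.DataFrame  # index: gene IDs, columns: sample IDs
    omics_label: str = "omics"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicated gene IDs")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicated sample IDs")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns


@dataclass
class Phenotype:
    """Outcome variable aligned to sample IDs.

    ``kind`` is one of ``binary``, ``continuous`` or ``survival``. For
    survival, ``outcome`` holds the event time and ``event`` the 0/1 event
    indicator (1 = observed).
    """

    outcome: pd.Series
    kind: str = "binary"
    event: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous", "survival"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "binary":
            classes = pd.unique(self.outcome.dropna())
            if len(classes) != 2:
                raise ValueError(
                    f"binary phenotype needs exactly two classes, got {len(classes)}"
                )
        if self.kind == "survival":
            if self.event is None:
                raise ValueError("survival phenotype needs an event indicator")
            if not self.event.index.equals(self.outcome.index):
                raise ValueError("survival time and event indicator misaligned")

    def with_outcome_values(self, values) -> "Phenotype":
        """Same samples, new outcome values (used by permutation)."""
        return Phenotype(
            outcome=pd.Series(values, index=self.outcome.index),
            kind=self.kind,
            event=self.event,
        )


def standardize(m: OmicsMatrix) -> OmicsMatrix:
    """Center and scale each gene to mean 0, sample SD 1 (ddof=1).

    Zero-variance genes carry no information for the pathway score and are
    dropped with a log entry; an all-constant matrix is an error.
    """
    values = m.data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    dropped = m.data.index[~keep]
    if len(dropped):
        logger.info(
            "dropping %d zero-variance genes from %s: %s",
            len(dropped), m.omics_label, list(dropped[:10]),
        )
    values = values[keep]
    values = (values - values.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return OmicsMatrix(
        data=pd.DataFrame(values, index=m.data.index[keep], columns=m.data.columns),
        omics_label=m.omics_label,
    )


def pathway_pc1(m: OmicsMatrix, genes) -> pd.Series | None:
    """First-principal-component score of the samples over a pathway's genes.

    Genes are standardized before the SVD, so every gene enters with equal
    weight. The sign is fixed so the loading with the largest absolute value
    is positive. Returns None (``pathway not testable``) when fewer than two
    pathway genes are present in the matrix.
    """
    present = m.data.index.intersection(pd.Index(list(genes)))
    if len(present) < 2:
        return None
    sub = standardize(OmicsMatrix(m.data.loc[present], m.omics_label))
    if sub.data.shape[0] < 2:
        return None
    z = sub.data.to_numpy(dtype=float).T  # samples x genes, column-centered
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
        u = -u  # keep scores consistent with flipped loadings
    scores = u[:, 0] * s[0]
    return pd.Series(scores, index=m.data.columns)


def _logistic_lrt(scores: np.ndarray, y: np.ndarray) -> float:
    """Likelihood-ratio p-value of logistic regression of y on the score."""
    n = y.size
    n1 = y.sum()
    p0 = n1 / n
    ll0 = n1 * np.log(p0) + (n - n1) * np.log1p(-p0)
    exog = sm.add_constant(scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, exog).fit(disp=0, maxiter=100)
        except Exception:
            logger.warning("logistic fit failed (perfect separation?); flooring p")
            return MIN_PVALUE
    lr = 2.0 * (fit.llf - ll0)
    if not np.isfinite(lr):
        logger.warning("non-finite likelihood ratio; flooring p")
        return MIN_PVALUE
    return max(float(stats.chi2.sf(max(lr, 0.0), df=1)), MIN_PVALUE)


def _cox_score_test(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Score test of a proportional-hazards model with one covariate.

    Evaluated at beta = 0 with Breslow handling of tied event times; for a
    binary covariate this reduces to the log-rank test.
    """
    order = np.argsort(time, kind="stable")
    x, t, d = scores[order], time[order], event[order].astype(bool)
    n = x.size
    score_u = 0.0
    info = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        n_events = int(d[i:j].sum())
        if n_events:
            risk = x[i:]  # everyone with time >= t[i]
            mean_r = risk.mean()
            var_r = np.mean((risk - mean_r) ** 2)
            score_u += float(x[i:j][d[i:j]].sum() - n_events * mean_r)
            info += n_events * var_r
        i = j
    if info <= 0:
        return 1.0
    return max(float(stats.chi2.sf(score_u**2 / info, df=1)), MIN_PVALUE)


def pathway_pvalue(scores: pd.Series, ph: Phenotype) -> float:
    """Association p-value between a pathway score and the phenotype."""
    shared = scores.index.intersection(ph.outcome.index)
    if len(shared) < len(scores) or len(shared) < len(ph.outcome):
        if len(shared) == 0:
            raise ValueError("scores and phenotype share no samples")
    if len(shared) < 10:
        raise ValueError(f"need at least 10 aligned samples, got {len(shared)}")
    x = scores.loc[shared].to_numpy(dtype=float)

    if ph.kind == "binary":
        raw = ph.outcome.loc[shared]
        classes = pd.unique(raw)
        if len(classes) < 2:
            raise ValueError("binary phenotype has a single class after alignment")
        y = (raw == classes[1]).to_numpy(dtype=float)
        return _logistic_lrt(x, y)
    if ph.kind == "continuous":
        y = ph.outcome.loc[shared].to_numpy(dtype=float)
        return max(float(stats.linregress(x, y).pvalue), MIN_PVALUE)
    # survival
    time = ph.outcome.loc[shared].to_numpy(dtype=float)
    event = ph.event.loc[shared].to_numpy(dtype=float)
    return _cox_score_test(x, time, event)


def score_all_pathways(
    m: OmicsMatrix,
    ph: Phenotype,
    pathways,
    min_size: int | None = None,
    max_size: int | None = None,
) -> pd.Series:
    """One p-value per pathway; NaN where a pathway is not testable.

    ``pathways`` is a :class:`minimaxomics.io.PathwayCollection` (or any
    mapping of pathway ID to gene set). Size filters count genes in the
    set definition, before intersection with the matrix.
    """
    items = pathways.items() if hasattr(pathways, "items") else pathways
    items = list(items)
    if not items:
        raise ValueError("empty pathway collection")
    out = {}
    for pathway_id, genes in items:
        genes = getattr(genes, "genes", genes)  # PathwayEntry or bare set
        if min_size is not None and len(genes) < min_size:
            out[pathway_id] = np.nan
            continue
        if max_size is not None and len(genes) > max_size:
            out[pathway_id] = np.nan
            continue
        scores = pathway_pc1(m, genes)
        if scores is None:
            logger.info("pathway %s not testable in %s", pathway_id, m.omics_label)
            out[pathway_id] = np.nan
            continue
        out[pathway_id] = pathway_pvalue(scores, ph)
    return pd.Series(out, name=m.omics_label)
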