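"""Simulation benchmark: synthetic multi-omics data with known truth.

The generator emulates the structure of the benchmark the method was
evaluated on: several omics layers measuring the same genes on (possibly
disjoint) subject sets, with genes in the same designated pathway sharing
a latent factor (loading sqrt(rho)) so that within-pathway correlation is
realistic. Synthetic pathways are then re-derived from the data itself by
Ward clustering of the stacked standardized matrix, a fixed subset is
declared "true positive", and a location shift mu is injected into a
proportion ``prop`` of each true pathway's genes for the subjects randomly
assigned to group A. Each replicate redraws the group labels (and the
treated-gene subset); the underlying expression matrices are generated
once per scenario. Performance is summarised as the empirical type-I error
rate at a nominal level and the Mann-Whitney AUC of ranking true versus
null pathways by significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core import OmicsPValueTable, run_minimax
from .scoring import OmicsMatrix, Phenotype, score_all_pathways, standardize

__all__ = [
    "BenchmarkScenario",
    "SyntheticMultiomics",
    "generate_multiomics",
    "build_synthetic_pathways",
    "inject_effect",
    "run_benchmark",
    "summarize_benchmark",
    "type1_rate",
    "roc_auc",
]

DEFAULT_MU_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
DEFAULT_PROP_GRID = (0.2, 0.4, 0.6, 0.8)


@dataclass
class BenchmarkScenario:
    """One cell of the simulation grid.

    mu is the mean shift added to treated genes for group-A subjects (on
    the standardized-expression scale, so mu = 0.5 is half a within-group
    SD); prop is the fraction of each true pathway's genes that receive it.
    """

    mu: float = 0.0
    prop: float = 0.2
    n_pathways: int = 50
    n_true: int = 5
    n_reps: int = 100
    seed: int = 0
    n_genes: int = 300
    samples_per_omics: tuple[int, ...] = (150, 100, 80)
    rho: float = 0.3
    overlap: float = 0.0
    omics_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop <= 1.0:
            raise ValueError("prop must lie in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.n_true > self.n_pathways:
            raise ValueError("n_true cannot exceed n_pathways")


@dataclass
class SyntheticMultiomics:
    """Generated layers plus the bookkeeping the benchmark needs.

    Sample IDs are subject IDs, so matched subjects across layers share
    IDs; ``groups`` maps subject -> "A"/"B" once labels are assigned.
    """

    layers: list[OmicsMatrix]
    pathways: dict[str, tuple[str, ...]]
    truth: set[str] = field(default_factory=set)
    groups: pd.Series | None = None
    rho: float = 0.0
    seed: int | None = None

    @property
    def all_subjects(self) -> pd.Index:
        ids: list[str] = []
        seen = set()
        for layer in self.layers:
            for s in layer.sample_ids:
                if s not in seen:
                    seen.add(s)
                    ids.append(s)
        return pd.Index(ids)


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def generate_multiomics(
    n_genes: int | None = None,
    pathway_sizes: list[int] | None = None,
    samples_per_omics: tuple[int, ...] = (150, 100, 80),
    rho: float = 0.3,
    overlap: float = 0.0,
    seed: int | None = None,
    omics_labels: tuple[str, ...] | None = None,
) -> SyntheticMultiomics:
    """Correlated-Gaussian multi-omics layers with designated gene blocks.

    Each gene belongs to one block (a designated pathway); genes in the
    same block load on a shared per-subject latent factor with weight
    sqrt(rho), giving pairwise within-block correlation rho. Subjects
    shared between layers (controlled by ``overlap``) reuse the same
    latent factors, so matched designs carry cross-omics correlation too.

    Exactly one of ``n_genes`` / ``pathway_sizes`` may be left implicit:
    sizes default to an even split of ``n_genes`` into blocks of ~6 genes.
    """
    rng = np.random.default_rng(seed)
    if pathway_sizes is None:
        if n_genes is None:
            raise ValueError("give n_genes or pathway_sizes")
        n_blocks = max(n_genes // 6, 1)
        base, extra = divmod(n_genes, n_blocks)
        pathway_sizes = [base + (1 if i < extra else 0) for i in range(n_blocks)]
    pathway_sizes = [int(s) for s in pathway_sizes]
    if any(s < 1 for s in pathway_sizes):
        raise ValueError("pathway sizes must be positive")
    if n_genes is not None and sum(pathway_sizes) != n_genes:
        raise ValueError(
            f"pathway sizes sum to {sum(pathway_sizes)}, expected n_genes={n_genes}"
        )
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")

    total_genes = sum(pathway_sizes)
    gene_ids = [f"G{i:04d}" for i in range(total_genes)]
    block_of = np.repeat(np.arange(len(pathway_sizes)), pathway_sizes)
    pathways = {
        f"BLOCK{k:03d}": tuple(
            gene_ids[i] for i in np.flatnonzero(block_of == k)
        )
        for k in range(len(pathway_sizes))
    }
    if omics_labels is None:
        omics_labels = tuple(f"omics{i + 1}" for i in range(len(samples_per_omics)))
    if len(omics_labels) != len(samples_per_omics):
        raise ValueError("one label per omics layer required")

    # subject bookkeeping: the first round(overlap * min(n)) subjects are
    # measured on every layer; the rest are layer-specific
    n_shared = _round_half_away(overlap * min(samples_per_omics))
    shared_ids = [f"SUBJ{i:05d}" for i in range(n_shared)]
    next_id = n_shared
    layer_subjects: list[list[str]] = []
    for n in samples_per_omics:
        own = [f"SUBJ{i:05d}" for i in range(next_id, next_id + n - n_shared)]
        next_id += n - n_shared
        layer_subjects.append(shared_ids + own)

    # latent factors drawn once per (subject, block) so shared subjects
    # share them across layers
    all_subjects = []
    seen: set[str] = set()
    for subs in layer_subjects:
        for s in subs:
            if s not in seen:
                seen.add(s)
                all_subjects.append(s)
    factor = pd.DataFrame(
        rng.standard_normal((len(all_subjects), len(pathway_sizes))),
        index=all_subjects,
    )

    layers = []
    for label, subs in zip(omics_labels, layer_subjects):
        z = factor.loc[subs].to_numpy()  # subjects x blocks
        eps = rng.standard_normal((total_genes, len(subs)))
        values = np.sqrt(rho) * z.T[block_of] + np.sqrt(1.0 - rho) * eps
        layers.append(
            OmicsMatrix(
                data=pd.DataFrame(values, index=gene_ids, columns=subs),
                omics_label=label,
            )
        )
    return SyntheticMultiomics(
        layers=layers, pathways=pathways, rho=rho, seed=seed
    )


def build_synthetic_pathways(stacked: pd.DataFrame, k: int) -> pd.Series:
    """Partition genes into k synthetic pathways by Ward clustering.

    Uses the Lance-Williams "ward.D" update on unsquared Euclidean
    distances (the classic hclust ward variant), realised by running the
    ward linkage on the element-wise square roots of the distances --
    ward linkage squares its input internally, so merge order is exactly
    the ward.D order on the original distances. Input is a genes x samples
    matrix (standardize each data type before stacking).
    """
    n = stacked.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= {n} genes, got k={k}")
    if k == 1:
        return pd.Series(1, index=stacked.index)
    d = pdist(stacked.to_numpy(dtype=float))
    tree = linkage(np.sqrt(d), method="ward")
    labels = fcluster(tree, t=k, criterion="maxclust")
    found = len(np.unique(labels))
    if found != k:
        raise RuntimeError(f"Ward cut produced {found} clusters, wanted {k}")
    return pd.Series(labels, index=stacked.index)


def assign_groups(data: SyntheticMultiomics, rng: np.random.Generator) -> pd.Series:
    """Random A/B assignment per subject, redrawn until both groups appear
    in every layer."""
    subjects = data.all_subjects
    for _ in range(100):
        groups = pd.Series(
            np.where(rng.random(len(subjects)) < 0.5, "A", "B"), index=subjects
        )
        if all(groups.loc[l.sample_ids].nunique() == 2 for l in data.layers):
            return groups
    raise RuntimeError("could not draw labels with both groups in every layer")


def inject_effect(
    data: SyntheticMultiomics,
    scenario: BenchmarkScenario,
    rng: np.random.Generator | None = None,
) -> SyntheticMultiomics:
    """Add mu to the treated genes of true pathways for group-A subjects.

    The treated subset of each true pathway is the first
    round(prop x size) genes (round half away from zero) under a seeded
    shuffle, identical across omics layers. mu = 0 returns data unchanged
    (apart from the copy).
    """
    if data.groups is None:
        raise ValueError("assign group labels before injecting effects")
    if not data.truth and scenario.mu > 0:
        raise ValueError("no true pathways selected")
    rng = np.random.default_rng(scenario.seed) if rng is None else rng

    treated: list[str] = []
    for pw in sorted(data.truth):
        genes = list(data.pathways[pw])
        n_treat = _round_half_away(scenario.prop * len(genes))
        shuffled = list(rng.permutation(genes))
        treated.extend(shuffled[:n_treat])

    new_layers = []
    for layer in data.layers:
        frame = layer.data.copy()
        if scenario.mu > 0 and treated:
            a_samples = [
                s for s in layer.sample_ids if data.groups.loc[s] == "A"
            ]
            rows = frame.index.intersection(pd.Index(treated))
            frame.loc[rows, a_samples] += scenario.mu
        new_layers.append(OmicsMatrix(frame, layer.omics_label))
    return replace(data, layers=new_layers)


def _stack_standardized(data: SyntheticMultiomics) -> pd.DataFrame:
    parts = [standardize(layer).data for layer in data.layers]
    common = parts[0].index
    for p in parts[1:]:
        common = common.intersection(p.index)
    return pd.concat([p.loc[common] for p in parts], axis=1)


def run_benchmark(scenario: BenchmarkScenario) -> pd.DataFrame:
    """Run one simulation scenario end to end.

    Returns a tidy frame with one row per (replicate, pathway):
    replicate, pathway, truth, one p-value column per omics layer,
    minimax, p_value. Reproducible from ``scenario.seed``; replicate seeds
    do not depend on mu or prop, so scenarios at different effect sizes
    share base data and labels (common random numbers).
    """
    root = np.random.SeedSequence(scenario.seed)
    gen_seed, truth_seed, rep_root = root.spawn(3)

    data = generate_multiomics(
        n_genes=scenario.n_genes,
        samples_per_omics=scenario.samples_per_omics,
        rho=scenario.rho,
        overlap=scenario.overlap,
        seed=int(gen_seed.generate_state(1)[0] % (2**31)),
        omics_labels=scenario.omics_labels,
    )
    partition = build_synthetic_pathways(_stack_standardized(data), scenario.n_pathways)
    width = len(str(scenario.n_pathways))
    data.pathways = {
        f"SIM_PW{c:0{width}d}": tuple(partition.index[partition == c])
        for c in sorted(partition.unique())
    }
    truth_rng = np.random.default_rng(truth_seed.generate_state(1) % (2**31))
    data.truth = set(
        truth_rng.choice(sorted(data.pathways), size=scenario.n_true, replace=False)
    )

    rows = []
    rep_seeds = rep_root.spawn(scenario.n_reps)
    for rep, rep_seed in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_seed)
        data.groups = assign_groups(data, rng)
        injected = inject_effect(data, scenario, rng)
        columns = {}
        for layer in injected.layers:
            ph = Phenotype(
                outcome=data.groups.loc[layer.sample_ids], kind="binary"
            )
            columns[layer.omics_label] = score_all_pathways(layer, ph, data.pathways)
        table = OmicsPValueTable(pd.DataFrame(columns))
        result = run_minimax(table, r=2)
        by_id = {rec.pathway_id: rec for rec in result.records}
        for pw in sorted(data.pathways):
            rec = by_id.get(pw)
            row = {
                "replicate": rep,
                "pathway": pw,
                "truth": pw in data.truth,
                **{label: columns[label].get(pw, np.nan) for label in columns},
                "minimax": rec.statistic if rec else np.nan,
                "p_value": rec.p_value if rec else np.nan,
            }
            rows.append(row)
    return pd.DataFrame(rows)


def type1_rate(pvals, level: float = 0.05) -> float:
    """Fraction of p-values strictly below *level*."""
    arr = np.asarray(pvals, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no p-values supplied")
    return float(np.mean(arr < level))


def roc_auc(scores, truth) -> float:
    """Mann-Whitney AUC for ranking true positives by *smaller* score.

    Ties count half, so two identical scores across classes contribute 0.5.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    n1, n0 = int(t.sum()), int((~t).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(s)
    u_greater = float(ranks[t].sum()) - n1 * (n1 + 1) / 2.0
    return 1.0 - u_greater / (n1 * n0)


def summarize_benchmark(results: pd.DataFrame, level: float = 0.05) -> dict:
    """Overall type-I proxy (fraction below level among null pathways) and
    mean per-replicate AUC (NaN when a scenario has no true pathways)."""
    null_p = results.loc[~results["truth"], "p_value"]
    out = {"type1_rate": type1_rate(null_p, level), "n_null": int(null_p.notna().sum())}
    if results["truth"].any():
        aucs = [
            roc_auc(grp["p_value"].to_numpy(), grp["truth"].to_numpy())
            for _, grp in results.groupby("replicate")
        ]
        out["mean_auc"] = float(np.mean(aucs))
        out["auc_se"] = float(np.std(aucs, ddof=1) / np.sqrt(len(aucs)))
    else:
        out["mean_auc"] = float("nan")
        out["auc_se"] = float("nan")
    return out
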