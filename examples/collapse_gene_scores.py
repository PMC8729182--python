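"""Collapse SNP-level p-values to size-bias-corrected gene scores.

Simulates a null GWAS: genes carry between 1 and 100 SNPs, every SNP
p-value is Uniform(0,1). Taking the per-gene minimum p-value makes
gene-rich loci look artificially significant (the minimum of n uniforms
has mean 1/(n+1)). The gamma-family spline regression of
y = -log10(min p) on the SNP count removes that trend; its residuals are
size-adjusted gene scores.
"""

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

import minimaxomics as mx

rng = np.random.default_rng(11)
rows, genes, pos = [], [], 1
for g in range(1500):
    n_snps = int(rng.integers(1, 101))
    genes.append((f"GENE{g:04d}", "chr1", pos, pos + 999))
    for s in range(n_snps):
        rows.append((f"rs{g}_{s}", "chr1", int(rng.integers(pos, pos + 1000)), rng.random()))
    pos += 20_000
features = pd.DataFrame(rows, columns=["feature_id", "chrom", "pos", "p_value"])
spans = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end"])

scores = mx.collapse_features(features, spans, window=5000)
pre = spearmanr(scores["y"], scores["n_links"]).statistic
post = spearmanr(scores["residual"], scores["n_links"]).statistic
print(f"genes scored: {len(scores)}")
print(f"Spearman(score, SNP count) before correction: {pre:+.3f}")
print(f"Spearman(residual, SNP count) after correction: {post:+.3f}")
print(
    "\nThe raw minimum-p score is strongly confounded with gene size under "
    "a pure-noise GWAS; the corrected residual is not."
)
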