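"""Bundled worked example: published Alzheimer's disease pathway p-values.

The table below holds the ten most significant pathways from a published
multi-omics pathway meta-analysis of Alzheimer's disease, with single-omics
pathway p-values for genetic variants (SNP), DNA methylation (DNAm) and
brain RNA sequencing (RNAseq). It serves as a small, real worked example
for the integrator: the order-2 MiniMax statistic, its Beta(2, 2) p-value
and the pair of contributing omics types can all be recomputed from the
three input columns.
"""

from __future__ import annotations

import pandas as pd

from .core import OmicsPValueTable

# pathway, SNP p, DNAm p, RNAseq p, published MiniMax, published p-value,
# published contributing omics
_AD_ROWS = [
    ("PID_PDGFRB_PATHWAY", 6.99e-01, 1.45e-04, 1.67e-04, 1.67e-04, 8.33e-08, "DNAm,RNAseq"),
    ("WP_CHEMOKINE_SIGNALING_PATHWAY", 8.19e-01, 3.17e-04, 1.94e-05, 3.17e-04, 3.02e-07, "DNAm,RNAseq"),
    ("KEGG_HEMATOPOIETIC_CELL_LINEAGE", 3.67e-36, 3.40e-04, 7.61e-01, 3.40e-04, 3.48e-07, "SNP,DNAm"),
    ("PID_TCR_PATHWAY", 4.48e-04, 2.75e-02, 4.90e-04, 4.90e-04, 7.20e-07, "SNP,RNAseq"),
    ("WP_REGULATION_OF_TOLLLIKE_RECEPTOR_SIGNALING_PATHWAY", 3.76e-05, 3.32e-02, 6.55e-04, 6.55e-04, 1.29e-06, "SNP,RNAseq"),
    ("KEGG_CHEMOKINE_SIGNALING_PATHWAY", 7.90e-01, 6.72e-04, 2.98e-04, 6.72e-04, 1.35e-06, "DNAm,RNAseq"),
    ("PID_KIT_PATHWAY", 2.55e-01, 6.84e-04, 1.10e-04, 6.84e-04, 1.40e-06, "DNAm,RNAseq"),
    ("WP_KIT_RECEPTOR_SIGNALING_PATHWAY", 3.05e-02, 3.68e-04, 1.41e-03, 1.41e-03, 5.94e-06, "DNAm,RNAseq"),
    ("PID_CXCR4_PATHWAY", 4.87e-04, 1.50e-03, 7.29e-02, 1.50e-03, 6.76e-06, "SNP,DNAm"),
    ("REACTOME_TCR_SIGNALING", 6.06e-52, 2.07e-01, 2.16e-03, 2.16e-03, 1.40e-05, "SNP,RNAseq"),
]


def ad_example_frame() -> pd.DataFrame:
    """Full example table including the published integrated columns."""
    return pd.DataFrame(
        _AD_ROWS,
        columns=[
            "pathway_id", "SNP", "DNAm", "RNAseq",
            "published_minimax", "published_p_value", "published_contributing",
        ],
    ).set_index("pathway_id")


def ad_example_table() -> OmicsPValueTable:
    """The three single-omics p-value columns as integrator input."""
    frame = ad_example_frame()[["SNP", "DNAm", "RNAseq"]]
    return OmicsPValueTable(frame)
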