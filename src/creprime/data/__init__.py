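"""Bundled reference tables.

`reference_annotation_counts.tsv` holds published peak-annotation counts
for mouse hematopoietic ATAC-seq peak lists (one row per cell type plus
the master list; columns: total, promoter, coding, introns, intergenic).
The table is consumed as input data for arithmetic-identity checks of the
annotation partition contract.
"""
from importlib import resources

import pandas as pd


def reference_annotation_counts() -> pd.DataFrame:
    """Published per-cell-type annotation counts, indexed by cell type."""
    ref = resources.files(__package__) / "reference_annotation_counts.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="cell_type")
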