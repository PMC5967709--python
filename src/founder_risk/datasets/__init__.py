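"""Small bundled reference tables.

Currently one table: the published list of 48 ClinVar-pathogenic,
AJ-enriched variants with their printed enrichment odds ratios and the
study/maximum-reference allele frequencies. Useful for validating the
bias-corrected odds-ratio computation by reconstructing allele counts from
the printed frequencies.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Total allele numbers used when reconstructing counts from the printed AFs.
AJ_AN = 4356          # 2,178 high-ancestry non-IBD AJ samples
NFE_AN = 63804        # 31,902 ExAC NFE samples


def load_aj_clinvar_enriched() -> pd.DataFrame:
    """The 48 ClinVar-pathogenic AJ-enriched variants with printed statistics."""
    from ..data_model_io import read_table

    with resources.as_file(
        resources.files(__package__) / "aj_clinvar_enriched_variants.tsv"
    ) as path:
        return read_table(path)
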