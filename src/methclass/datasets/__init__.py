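"""Small bundled reference tables.

``immune_prognostic_screen()`` loads the published survival screen of 24
immune-related genes in cervical squamous cell carcinoma (TCGA CESC):
per-gene log-rank p-values with their published Benjamini-Hochberg
adjusted values, and the corresponding Human Protein Atlas p-values.
The raw p-value columns serve as inputs for validating the multiple-
testing machinery against the published adjusted columns.
"""

from importlib.resources import files

import pandas as pd


def immune_prognostic_screen() -> pd.DataFrame:
    """24-gene immune prognostic screen (published p-values), gene-indexed."""
    path = files(__package__).joinpath("immune_prognostic_screen.tsv")
    with path.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)
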