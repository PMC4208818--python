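"""Published soybean IQD reference tables shipped with the package.

Two small tables from the genome-wide survey of the soybean (Glycine max)
IQD family: the 67-gene inventory (coordinates, ORF length, protein
length, pI, molecular weight, exon count) and the 31 paralogous pairs with
their Ka, Ks, Ka/Ks and duplication dates.  They serve as worked-example
inputs: the dating formula, the Ka/Ks ratio arithmetic and the
ORF-to-protein-length convention can all be re-derived from them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("iqdfam.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def soybean_iqd_genes() -> pd.DataFrame:
    """The 67 soybean IQD genes and their sequence characteristics."""
    return _load("soybean_iqd_genes.tsv")


def soybean_iqd_divergence() -> pd.DataFrame:
    """The 31 soybean IQD paralogous pairs: Ka, Ks, Ka/Ks, date, type."""
    return _load("soybean_iqd_divergence.tsv")
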