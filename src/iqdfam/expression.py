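"""Expression profiling: RPKM, hierarchical clustering, tissue preference
and 2^-ddCt qPCR quantification.

RPKM = reads * 1e9 / (gene length in bp * library size).  Clustering uses
Pearson-correlation distance (d = 1 - r) with complete linkage, the
combination used for tissue expression atlases of plant gene families.
qPCR fold changes follow the 2^-ddCt convention with a reference
(housekeeping) gene and a 0-h untreated control that is normalized to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger("iqdfam")


@dataclass
class ExpressionMatrix:
    """Gene x condition abundance values (RPKM or relative expression)."""

    values: pd.DataFrame  # index: genes, columns: conditions

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("condition labels not unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundance values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class QPCRMeasurement:
    """Replicate CT values for one gene at one timepoint."""

    gene: str
    timepoint: float
    ct_target: list[float]
    ct_reference: list[float]

    def __post_init__(self) -> None:
        if not self.ct_target or not self.ct_reference:
            raise ValueError(
                f"{self.gene} @ {self.timepoint} h: missing target or reference CTs"
            )

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


def rpkm_normalize(
    counts: pd.DataFrame,
    gene_lengths: dict[str, int] | pd.Series,
    library_sizes: dict[str, int] | pd.Series,
) -> ExpressionMatrix:
    """Reads-per-kilobase-per-million normalization.

    value = count * 1e9 / (gene_length_bp * library_size); invariant under
    uniform count scaling when library sizes are recomputed.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError(f"missing gene lengths: {list(lengths[lengths.isna()].index)}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be positive for every condition")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    values = counts * 1e9
    values = values.div(lengths, axis=0).div(libs, axis=1)
    return ExpressionMatrix(values)


def correlation_distances(matrix: ExpressionMatrix) -> np.ndarray:
    """Condensed Pearson-distance matrix (d = 1 - r) over genes.

    Constant profiles have undefined correlation; they are assigned
    distance 1 to every other gene, with a warning.
    """
    values = matrix.values.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant expression profiles (distance set to 1): %s",
            [g for g, c in zip(matrix.genes, constant) if c],
        )
    n = values.shape[0]
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    ok = ~constant
    if ok.sum() >= 2:
        sub = values[ok]
        r = np.corrcoef(sub)
        d[np.ix_(ok, ok)] = 1.0 - r
        np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def cluster_genes(matrix: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage clustering on Pearson distance.

    Returns the scipy linkage matrix and the genes in deterministic
    dendrogram leaf order.
    """
    if len(matrix.genes) < 2 or len(matrix.conditions) < 2:
        raise ValueError("clustering needs at least 2 genes and 2 conditions")
    linkage = hierarchy.linkage(
        correlation_distances(matrix), method="complete"
    )
    order = hierarchy.leaves_list(linkage)
    return linkage, [matrix.genes[i] for i in order]


def cut_groups(linkage: np.ndarray, genes: list[str], k: int) -> dict[str, int]:
    """Flat group assignment by cutting the dendrogram into k clusters."""
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return dict(zip(genes, (int(c) for c in flat)))


@dataclass
class TissuePreference:
    gene: str
    top_condition: str  # "not detected" for an all-zero profile
    single_tissue: bool


def tissue_preference(
    matrix: ExpressionMatrix, dominance_ratio: float = 2.0
) -> dict[str, TissuePreference]:
    """Per gene, the condition of highest abundance.

    Ties are broken alphabetically by condition label.  ``single_tissue``
    flags genes whose top condition exceeds the runner-up by
    ``dominance_ratio`` (default 2x).  All-zero genes are 'not detected'.
    """
    out = {}
    for gene, row in matrix.values.iterrows():
        if (row == 0).all():
            out[gene] = TissuePreference(gene, "not detected", False)
            continue
        ordered = row.sort_values(ascending=False, kind="stable")
        top_value = ordered.iloc[0]
        top = min(c for c, v in row.items() if v == top_value)
        others = row.drop(top)
        second = others.max() if len(others) else 0.0
        single = second == 0 or top_value / second > dominance_ratio
        out[gene] = TissuePreference(gene, top, bool(single))
    return out


def relative_expression_ddct(
    meas: QPCRMeasurement, control: QPCRMeasurement
) -> float:
    """Fold change 2^-ddCt of a treatment sample against the 0-h control.

    dCt = mean(target CT) - mean(reference CT) per sample;
    ddCt = dCt_treatment - dCt_control.  The control itself evaluates to
    exactly 1.
    """
    ddct = meas.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))


def regulation_call(
    fold_series: list[float],
    down_threshold: float = 0.5,
    up_threshold: float = 2.0,
) -> str:
    """Classify a fold-change time course.

    down: every fold < down_threshold; up: some fold > up_threshold and
    none below down_threshold; unchanged: all folds within the band;
    mixed: both directions present.
    """
    if not fold_series:
        raise ValueError("empty fold series")
    any_down = any(f < down_threshold for f in fold_series)
    any_up = any(f > up_threshold for f in fold_series)
    if any_down and all(f < down_threshold for f in fold_series):
        return "down"
    if any_down and any_up:
        return "mixed"
    if any_down:
        return "mixed"
    if any_up:
        return "up"
    return "unchanged"
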