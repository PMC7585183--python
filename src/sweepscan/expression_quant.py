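"""Tissue-expression similarity summaries and 2^-ddCt relative expression.

The similarity summary reports, for a gene x tissue abundance matrix
(RPKM/TPM), the pairwise Pearson correlation between gene expression profiles
across tissues: the full r matrix, the mean off-diagonal r, and the fraction
of gene pairs with r above a cutoff (default 0.8).  An optional log2(x + 1)
transform is available because r depends on the scale; it is off by default.

qPCR relative expression uses the standard 2^-ddCt method: Ct replicates are
averaged first, the target gene is normalized to a reference gene, and the
sample of interest to a calibrator sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sweepscan.errors import DataError


@dataclass
class ExpressionMatrix:
    """Nonnegative gene x tissue abundance values."""

    values: pd.DataFrame  # index = gene ids, columns = tissue ids

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise DataError("expression values must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class CorrelationSummary:
    """Pairwise-Pearson summary over genes: r matrix, mean r, exceedance fraction."""

    r: pd.DataFrame
    mean_r: float
    fraction_above: float
    cutoff: float
    n_pairs: int
    excluded_genes: list[str]


def correlation_summary(
    em: ExpressionMatrix, cutoff: float = 0.8, log_transform: bool = False
) -> CorrelationSummary:
    """Pearson r over tissues for every unordered gene pair.

    Mean and exceedance fraction are computed over the upper triangle
    (diagonal excluded).  Genes with zero variance across tissues carry no
    correlation information and are excluded with a warning.
    """
    mat = em.values
    if log_transform:
        mat = np.log2(mat + 1.0)
    if mat.shape[1] < 3:
        raise DataError("need >= 3 tissues for a meaningful correlation")
    variances = mat.var(axis=1)
    excluded = list(mat.index[variances == 0])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} zero-variance gene(s): {excluded}")
        mat = mat.loc[variances > 0]
    g = mat.shape[0]
    if g < 2:
        raise DataError("fewer than 2 usable genes")
    r = pd.DataFrame(np.corrcoef(mat.to_numpy()), index=mat.index, columns=mat.index)
    iu = np.triu_indices(g, k=1)
    upper = r.to_numpy()[iu]
    return CorrelationSummary(
        r=r,
        mean_r=float(upper.mean()),
        fraction_above=float((upper > cutoff).mean()),
        cutoff=cutoff,
        n_pairs=len(upper),
        excluded_genes=excluded,
    )


def ddct(
    ct_target_sample: float | list[float],
    ct_ref_sample: float | list[float],
    ct_target_calibrator: float | list[float],
    ct_ref_calibrator: float | list[float],
) -> float:
    """Relative expression by the 2^-ddCt method.

    fold = 2^-[(Ct_target,sample - Ct_ref,sample)
               - (Ct_target,calibrator - Ct_ref,calibrator)]

    Each argument may be a scalar Ct or a list of technical replicates, which
    are arithmetically averaged before differencing.
    """
    vals = []
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if arr.size == 0 or not np.isfinite(arr).all():
            raise DataError("Ct values must be finite and non-empty")
        vals.append(float(arr.mean()))
    ddct_val = (vals[0] - vals[1]) - (vals[2] - vals[3])
    return float(2.0 ** (-ddct_val))
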