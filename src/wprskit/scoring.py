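"""Weighted polygenic risk scores and summed risk-allele counts.

The score for sample *i* over a panel of M variants with per-variant
log-odds weights beta_j and risk-allele dosages g_ij in {0,1,2} is

    sum mode:      PRS_i = sum_j beta_j * g_ij
    average mode:  PRS_i = sum_j beta_j * g_ij / (2 * M_i)

where M_i is the number of variants with an observed (non-missing)
genotype for sample i.  Sum mode mean-imputes missing dosages (2 * p-hat
with p-hat the in-sample counted-allele frequency) before summing;
average mode skips missing cells and shrinks the denominator instead,
matching the behaviour of the standard per-allele-average scorer.  With
complete data the two modes differ exactly by the factor 2M and induce
identical sample rankings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import MISSING, GenotypeMatrix, WeightTable
from .genotype_io import harmonize


def mean_impute(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by twice the in-sample allele frequency.

    Each missing cell at variant j becomes ``2 * p_hat_j`` where
    ``p_hat_j`` is the frequency of the counted allele among observed
    genotypes.  Returns a float-valued matrix; a no-missing input is
    returned unchanged.
    """
    miss = gm.missing_mask()
    if not miss.any():
        return gm
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        bad = [gm.variants[j].vid for j in np.flatnonzero(fully_missing)]
        raise ValueError(f"cannot impute fully missing variant(s): {bad}")
    X = gm.dosages.astype(float)
    X[miss] = np.nan
    col_means = np.nanmean(X, axis=0)  # mean dosage = 2 * p_hat
    X[miss] = np.broadcast_to(col_means, X.shape)[miss]
    return GenotypeMatrix(X, gm.variants, gm.sample_ids)


def _align(gm: GenotypeMatrix, wt: WeightTable) -> tuple[GenotypeMatrix, np.ndarray]:
    """Subset/order gm to the weight table's variants; verify alignment."""
    present = [v for v in wt.vids if v in set(gm.vids)]
    absent = sorted(set(wt.vids) - set(present))
    if absent:
        warnings.warn(
            f"{len(absent)} weight-table variant(s) absent from genotypes: {absent}",
            stacklevel=3,
        )
    if not present:
        raise ValueError("no usable variants: weight table and genotypes do not overlap")
    sub = gm.subset_variants(present)
    wrows = wt.table.set_index("vid").loc[present]
    for v, ea in zip(sub.variants, wrows["effect_allele"]):
        if v.allele_counted != ea:
            raise ValueError(
                f"{v.vid}: dosage counts {v.allele_counted} but weight table "
                f"effect allele is {ea}; run harmonize first"
            )
    return sub, wrows["weight"].to_numpy(float)


def weighted_prs(
    gm: GenotypeMatrix, wt: WeightTable, mode: str = "average"
) -> pd.DataFrame:
    """Per-sample weighted PRS over a harmonized genotype matrix.

    Requires ``gm`` already harmonized to ``wt`` (dosages count effect
    alleles).  Returns a DataFrame with columns ``sample_id``, ``wprs``,
    ``risk_allele_count``, ``n_used_variants``, ``n_imputed_cells`` and
    ``mode``.  The risk-allele count is only meaningful when weights are
    oriented so the effect allele is the risk allele (see
    :meth:`WeightTable.oriented_to_risk`).
    """
    if mode not in ("sum", "average"):
        raise ValueError(f"mode must be 'sum' or 'average', got {mode!r}")
    sub, beta = _align(gm, wt)
    miss = sub.missing_mask()
    n_missing = miss.sum(axis=1)
    observed = np.where(miss, 0, sub.dosages).astype(float)
    m_obs = sub.n_variants - n_missing
    if mode == "sum":
        imputed = mean_impute(sub)
        scores = imputed.dosages.astype(float) @ beta
    else:
        if (m_obs == 0).any():
            bad = [sub.sample_ids[i] for i in np.flatnonzero(m_obs == 0)]
            raise ValueError(f"sample(s) with no observed genotypes: {bad}")
        scores = (observed @ beta) / (2.0 * m_obs)
    risk_counts = observed.sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "sample_id": sub.sample_ids,
            "wprs": scores,
            "risk_allele_count": risk_counts,
            "n_used_variants": sub.n_variants,
            "n_imputed_cells": n_missing.astype(int),
            "mode": mode,
        }
    )


def summed_risk_alleles(gm: GenotypeMatrix, wt: WeightTable) -> pd.Series:
    """Integer count of risk alleles carried by each sample.

    ``gm`` must be harmonized so dosages count each variant's risk
    allele; missing cells contribute 0.
    """
    sub, _ = _align(gm, wt)
    counts = np.where(sub.missing_mask(), 0, sub.dosages).sum(axis=1).astype(int)
    return pd.Series(counts, index=pd.Index(sub.sample_ids, name="sample_id"), name="risk_allele_count")


class PRSScorer(BaseEstimator, TransformerMixin):
    """Transformer computing weighted PRSs from a genotype matrix.

    Wraps harmonization + scoring: the constructor takes the weight
    panel, ``fit`` re-orients it so all weights are positive (risk
    alleles) and ``transform`` harmonizes the input matrix to it and
    scores every sample.

    Parameters
    ----------
    weights : WeightTable
    mode : 'average' (per-allele average, the default) or 'sum'
    ambiguous_policy : 'drop' or 'keep', for palindromic variants

    Attributes
    ----------
    weights_ : WeightTable, risk-oriented panel used for scoring
    harmonization_report_ : report from the last transform
    """

    def __init__(
        self,
        weights: WeightTable,
        mode: str = "average",
        ambiguous_policy: str = "drop",
    ) -> None:
        self.weights = weights
        self.mode = mode
        self.ambiguous_policy = ambiguous_policy

    def fit(self, gm: GenotypeMatrix | None = None, y=None) -> "PRSScorer":
        self.weights_ = self.weights.oriented_to_risk()
        return self

    def transform(self, gm: GenotypeMatrix) -> pd.DataFrame:
        if not hasattr(self, "weights_"):
            self.fit()
        aligned, self.harmonization_report_ = harmonize(
            gm, self.weights_, ambiguous_policy=self.ambiguous_policy
        )
        return weighted_prs(aligned, self.weights_, mode=self.mode)


__all__ = ["mean_impute", "weighted_prs", "summed_risk_alleles", "PRSScorer"]
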