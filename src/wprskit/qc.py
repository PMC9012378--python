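"""Variant quality control: call rate, MAF, HWE exact test, LD pruning, PCA.

The filters mirror standard array-QC practice for case-control GWAS
panels: per-variant genotyping call rate, minor allele frequency, and an
exact Hardy-Weinberg equilibrium test, followed by greedy r^2-based LD
pruning and a within-study genotype PCA whose scores serve as ancestry
covariates in the risk models.

Defaults: call rate >= 0.95, MAF >= 0.01, HWE p >= 1e-6, pairwise
r^2 <= 0.8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .datatypes import MISSING, GenotypeMatrix

# relative slack when comparing heterozygote-count probabilities; mass
# within this factor of the observed configuration counts as tied
_HWE_REL_TOL = 1e-10


@dataclass(frozen=True)
class QCThresholds:
    """Variant-level QC thresholds (all fractions/probabilities in [0,1])."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    max_ld_r2: float = 0.8

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p", "max_ld_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# Per-variant statistics
# ---------------------------------------------------------------------------

def call_rate(gm: GenotypeMatrix, vid: str) -> float:
    """Fraction of samples with a non-missing genotype at ``vid``."""
    col = gm.column(vid)
    return float(np.count_nonzero(col != MISSING) / gm.n_samples)


def maf(gm: GenotypeMatrix, vid: str) -> float:
    """Minor allele frequency at ``vid`` among non-missing genotypes."""
    col = gm.column(vid)
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError(f"{vid}: all genotypes missing, allele frequency undefined")
    p = float(obs.sum()) / (2.0 * obs.size)
    return min(p, 1.0 - p)


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test p-value.

    Conditions on the observed allele counts and enumerates every
    attainable heterozygote count; the p-value is the total probability
    of configurations no more likely than the observed one (the
    probability-mass two-sided definition standard for this test).

    Parameters are the three genotype counts.  Returns a p-value in
    (0, 1].
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab  # copies of allele a
    rare = min(n_a, 2 * n - n_a)
    # heterozygote count shares the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    if hets.size == 0:  # rare == 0 -> only het count 0 attainable
        hets = np.array([0])
    # P(het = h | allele counts) ∝ n! / (naa! h! nbb!) * 2^h with
    # naa = (rare - h)/2 on the rare side; use log-gammas and normalise.
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        hets * np.log(2.0)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_common_hom + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs_het = n_ab
    obs_prob = probs[np.searchsorted(hets, obs_het)]
    p = float(probs[probs <= obs_prob * (1.0 + _HWE_REL_TOL)].sum())
    return min(p, 1.0)


def ld_r2(gm: GenotypeMatrix, vid1: str, vid2: str) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples non-missing at both variants; raises if either
    variant is monomorphic in that joint subset.
    """
    x = gm.column(vid1).astype(float)
    y = gm.column(vid2).astype(float)
    ok = (gm.column(vid1) != MISSING) & (gm.column(vid2) != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            f"r^2 undefined for {vid1}/{vid2}: monomorphic in the joint non-missing sample"
        )
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def qc_report(
    gm: GenotypeMatrix,
    thr: QCThresholds = QCThresholds(),
    hwe_sample_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant QC metrics and pass/fail with the first failing rule.

    ``hwe_sample_mask`` restricts the HWE test to a sample subset
    (typically controls); call rate and MAF always use all samples.
    """
    rows = []
    for v in gm.variants:
        col = gm.column(v.vid)
        cr = float(np.count_nonzero(col != MISSING) / gm.n_samples)
        sub = col if hwe_sample_mask is None else col[np.asarray(hwe_sample_mask, bool)]
        obs = col[col != MISSING]
        hwe_obs = sub[sub != MISSING]
        mafv = np.nan
        hwep = np.nan
        if obs.size:
            p = float(obs.sum()) / (2.0 * obs.size)
            mafv = min(p, 1.0 - p)
        if hwe_obs.size:
            hwep = hwe_exact_p(
                int(np.count_nonzero(hwe_obs == 0)),
                int(np.count_nonzero(hwe_obs == 1)),
                int(np.count_nonzero(hwe_obs == 2)),
            )
        # a NaN metric (undefined from all-missing data) fails its rule
        # unless that rule's threshold is 0, i.e. disabled
        fail = ""
        if cr < thr.min_call_rate:
            fail = "call_rate"
        elif (np.isnan(mafv) and thr.min_maf > 0) or mafv < thr.min_maf:
            fail = "maf"
        elif (np.isnan(hwep) and thr.min_hwe_p > 0) or hwep < thr.min_hwe_p:
            fail = "hwe"
        rows.append(
            {
                "vid": v.vid,
                "call_rate": cr,
                "maf": mafv,
                "hwe_p": hwep,
                "pass": fail == "",
                "fail_reason": fail,
            }
        )
    return pd.DataFrame(rows)


def apply_qc(
    gm: GenotypeMatrix,
    thr: QCThresholds = QCThresholds(),
    hwe_sample_mask: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter variants by call rate, MAF and HWE; return survivors + report."""
    report = qc_report(gm, thr, hwe_sample_mask)
    keep = report.loc[report["pass"], "vid"].tolist()
    if not keep:
        warnings.warn("all variants failed QC; returning empty matrix", stacklevel=2)
        return GenotypeMatrix(
            gm.dosages[:, :0], [], gm.sample_ids
        ), report
    return gm.subset_variants(keep), report


def ld_prune(gm: GenotypeMatrix, max_r2: float = 0.8) -> list[str]:
    """Greedy LD pruning in genomic order.

    Variants are scanned in input order (assumed sorted by chromosome
    and position); a variant is dropped if its r^2 with any previously
    kept variant on the same chromosome exceeds ``max_r2``.  Variants
    with undefined r^2 (monomorphic) are dropped with a warning.  Every
    kept pair satisfies r^2 <= max_r2.
    """
    kept: list[str] = []
    kept_chrom: dict[str, list[str]] = {}
    for v in gm.variants:
        ok = True
        try:
            for prev in kept_chrom.get(v.chrom, []):
                if ld_r2(gm, prev, v.vid) > max_r2:
                    ok = False
                    break
        except ValueError as exc:
            warnings.warn(f"dropping {v.vid}: {exc}", stacklevel=2)
            ok = False
        if ok:
            kept.append(v.vid)
            kept_chrom.setdefault(v.chrom, []).append(v.vid)
    return kept


class VariantQC(BaseEstimator, TransformerMixin):
    """Variant-filtering transformer: call rate, MAF, HWE, then LD pruning.

    Parameters mirror :class:`QCThresholds`; ``hwe_controls_only`` runs
    the HWE test on controls only (requires ``y`` at fit time, 1=case).
    ``ld_prune_r2=None`` disables pruning.

    Attributes (after fit): ``report_`` (per-variant metrics),
    ``kept_vids_``.
    """

    def __init__(
        self,
        min_call_rate: float = 0.95,
        min_maf: float = 0.01,
        min_hwe_p: float = 1e-6,
        ld_prune_r2: float | None = 0.8,
        hwe_controls_only: bool = False,
    ) -> None:
        self.min_call_rate = min_call_rate
        self.min_maf = min_maf
        self.min_hwe_p = min_hwe_p
        self.ld_prune_r2 = ld_prune_r2
        self.hwe_controls_only = hwe_controls_only

    def fit(self, gm: GenotypeMatrix, y: np.ndarray | None = None) -> "VariantQC":
        thr = QCThresholds(self.min_call_rate, self.min_maf, self.min_hwe_p,
                           self.ld_prune_r2 if self.ld_prune_r2 is not None else 1.0)
        mask = None
        if self.hwe_controls_only:
            if y is None:
                raise ValueError("hwe_controls_only requires case/control labels y")
            mask = np.asarray(y) == 0
        filtered, self.report_ = apply_qc(gm, thr, mask)
        if self.ld_prune_r2 is not None and filtered.n_variants:
            self.kept_vids_ = ld_prune(filtered, self.ld_prune_r2)
        else:
            self.kept_vids_ = filtered.vids
        return self

    def transform(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        return gm.subset_variants(self.kept_vids_)


# ---------------------------------------------------------------------------
# Genotype PCA
# ---------------------------------------------------------------------------

class GenotypePCA(BaseEstimator, TransformerMixin):
    """Principal components of the standardized dosage matrix.

    Missing dosages are mean-imputed per variant, columns are centred and
    scaled to unit variance (zero-variance columns scaled by 1), and the
    top ``n_components`` right singular directions are extracted.  Signs
    are fixed so each component's largest-magnitude loading is positive.

    Attributes: ``components_`` (k x m loadings), ``mean_``, ``scale_``,
    ``explained_variance_ratio_``.
    """

    def __init__(self, n_components: int = 4) -> None:
        self.n_components = n_components

    def _standardize(self, gm: GenotypeMatrix) -> np.ndarray:
        X = gm.dosages.astype(float).copy()
        miss = gm.missing_mask()
        if miss.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                col_means = np.nanmean(np.where(miss, np.nan, X), axis=0)
            col_means = np.where(np.isnan(col_means), 0.0, col_means)
            X[miss] = np.broadcast_to(col_means, X.shape)[miss]
        return X

    def fit(self, gm: GenotypeMatrix, y=None) -> "GenotypePCA":
        k = self.n_components
        if k > min(gm.n_samples, gm.n_variants):
            raise ValueError(
                f"n_components={k} exceeds min(n_samples, n_variants)="
                f"{min(gm.n_samples, gm.n_variants)}"
            )
        X = self._standardize(gm)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        if (sd == 0).all():
            raise ValueError("zero-variance dosage matrix; PCA undefined")
        self.scale_ = np.where(sd == 0, 1.0, sd)
        Z = (X - self.mean_) / self.scale_
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(Z)
        comps = pca.components_
        if k:
            signs = np.sign(comps[np.arange(k), np.abs(comps).argmax(axis=1)])
            signs[signs == 0] = 1.0
            comps = comps * signs[:, None]
        self.components_ = comps
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, gm: GenotypeMatrix) -> np.ndarray:
        Z = (self._standardize(gm) - self.mean_) / self.scale_
        return Z @ self.components_.T


def genotype_pca(gm: GenotypeMatrix, k: int = 4) -> np.ndarray:
    """Top-``k`` principal component scores (n_samples x k)."""
    if k == 0:
        return np.empty((gm.n_samples, 0))
    return GenotypePCA(n_components=k).fit(gm).transform(gm)


__all__ = [
    "QCThresholds",
    "call_rate",
    "maf",
    "hwe_exact_p",
    "ld_r2",
    "qc_report",
    "apply_qc",
    "ld_prune",
    "VariantQC",
    "GenotypePCA",
    "genotype_pca",
]
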