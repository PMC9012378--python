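"""Core containers for the PRS pipeline.

A :class:`GenotypeMatrix` is a samples x variants matrix of additive allele
dosages (0/1/2 copies of each variant's *counted* allele, with ``MISSING``
for no-calls) plus per-variant and per-sample metadata.  A
:class:`WeightTable` carries the per-variant effect allele and its
log-odds-ratio weight.  A cohort/phenotype table is an ordinary pandas
DataFrame (see :func:`wprskit.genotype_io.read_cohort_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing (no-call) genotype in integer dosage matrices.
MISSING: int = -1

_VALID_DOSAGES = frozenset({0, 1, 2, MISSING})


@dataclass(frozen=True)
class VariantMeta:
    """Metadata for one biallelic variant.

    ``allele_counted`` is the allele whose copies the dosage column counts;
    ``allele_other`` is the remaining allele.  Alleles are upper-case and
    distinct; ``pos`` is 1-based.
    """

    chrom: str
    pos: int
    vid: str
    allele_counted: str
    allele_other: str

    def __post_init__(self) -> None:
        a, b = self.allele_counted, self.allele_other
        if not a or not b:
            raise ValueError(f"{self.vid}: empty allele")
        if a != a.upper() or b != b.upper():
            raise ValueError(f"{self.vid}: alleles must be upper-case")
        if a == b:
            raise ValueError(f"{self.vid}: alleles must differ ({a}/{b})")
        if self.pos < 1:
            raise ValueError(f"{self.vid}: position must be >= 1")

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous (A/T or C/G) allele pairs."""
        return {self.allele_counted, self.allele_other} in ({"A", "T"}, {"C", "G"})


class GenotypeMatrix:
    """Samples x variants additive dosage matrix.

    Parameters
    ----------
    dosages : ndarray, shape (n_samples, n_variants)
        Integer dosages in {0, 1, 2, MISSING}, or floats after mean
        imputation (then MISSING must be absent).
    variants : sequence of VariantMeta
    sample_ids : sequence of str
    """

    def __init__(
        self,
        dosages: np.ndarray,
        variants: Sequence[VariantMeta],
        sample_ids: Sequence[str],
    ) -> None:
        dosages = np.asarray(dosages)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = dosages.shape
        if len(variants) != m:
            raise ValueError(f"{len(variants)} variant records for {m} columns")
        if len(sample_ids) != n:
            raise ValueError(f"{len(sample_ids)} sample ids for {n} rows")
        sample_ids = [str(s) for s in sample_ids]
        if len(set(sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        vids = [v.vid for v in variants]
        if len(set(vids)) != m:
            raise ValueError("variant ids must be unique")
        if np.issubdtype(dosages.dtype, np.integer):
            bad = ~np.isin(dosages, (0, 1, 2, MISSING))
            if bad.any():
                raise ValueError(f"invalid dosage values: {np.unique(dosages[bad])}")
        else:
            if not np.isfinite(dosages).all():
                raise ValueError("float dosages must be finite")
            if ((dosages < 0) | (dosages > 2)).any():
                raise ValueError("float dosages must lie in [0, 2]")
        self.dosages = dosages
        self.variants = list(variants)
        self.sample_ids = sample_ids
        self._vid_index = {v: i for i, v in enumerate(vids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def vids(self) -> list[str]:
        return [v.vid for v in self.variants]

    def column(self, vid: str) -> np.ndarray:
        """Dosage vector for one variant id."""
        return self.dosages[:, self.index_of(vid)]

    def index_of(self, vid: str) -> int:
        try:
            return self._vid_index[vid]
        except KeyError:
            raise KeyError(f"unknown variant id: {vid}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing cells (all False for float matrices)."""
        if np.issubdtype(self.dosages.dtype, np.integer):
            return self.dosages == MISSING
        return np.zeros_like(self.dosages, dtype=bool)

    def subset_variants(self, vids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.index_of(v) for v in vids]
        return GenotypeMatrix(
            self.dosages[:, idx], [self.variants[i] for i in idx], self.sample_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and np.array_equal(self.dosages, other.dosages)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"


@dataclass
class WeightTable:
    """Per-variant effect alleles and ln(OR) weights.

    Backed by a DataFrame with columns ``vid``, ``effect_allele``,
    ``other_allele``, ``weight`` and ``source`` (free-form tag such as
    ``gwas`` or ``reported``).  ``weight`` is the natural log of the
    per-allele odds ratio for the effect allele.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("vid", "effect_allele", "other_allele", "weight")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"weight table missing column {col!r}")
        if "source" not in t.columns:
            t = t.assign(source="gwas")
        t = t.copy()
        t["effect_allele"] = t["effect_allele"].str.upper()
        t["other_allele"] = t["other_allele"].str.upper()
        if t["vid"].duplicated().any():
            dups = t.loc[t["vid"].duplicated(), "vid"].tolist()
            raise ValueError(f"duplicate variant ids in weight table: {dups}")
        if not np.isfinite(t["weight"].to_numpy(float)).all():
            raise ValueError("weights must be finite")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValueError("effect_allele must differ from other_allele")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def vids(self) -> list[str]:
        return self.table["vid"].tolist()

    def weight_of(self, vid: str) -> float:
        row = self.table.loc[self.table["vid"] == vid]
        if row.empty:
            raise KeyError(f"unknown variant id: {vid}")
        return float(row["weight"].iloc[0])

    def oriented_to_risk(self) -> "WeightTable":
        """Re-orient so every weight is non-negative.

        For rows with a negative weight the effect and other alleles are
        swapped and the weight negated; the effect allele is then the risk
        allele everywhere, which makes the summed risk-allele count
        well defined.
        """
        t = self.table.copy()
        neg = t["weight"] < 0
        ea = t.loc[neg, "effect_allele"].copy()
        t.loc[neg, "effect_allele"] = t.loc[neg, "other_allele"]
        t.loc[neg, "other_allele"] = ea
        t.loc[neg, "weight"] = -t.loc[neg, "weight"]
        return WeightTable(t)


def validate_cohort_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype/covariate table and normalise dtypes.

    Requires columns ``sample_id`` and ``label`` (values ``case`` /
    ``control``); ``cohort`` tag and covariate columns are passed through.
    """
    for col in ("sample_id", "label"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table missing column {col!r}")
    bad = set(cohort["label"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"labels must be 'case'/'control'; found {sorted(bad)}")
    if cohort["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in cohort table")
    if cohort["label"].isna().any():
        raise ValueError("missing labels in cohort table")
    out = cohort.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    return out.reset_index(drop=True)


__all__ = [
    "MISSING",
    "VariantMeta",
    "GenotypeMatrix",
    "WeightTable",
    "validate_cohort_table",
]
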