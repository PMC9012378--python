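"""Genotype, weight-table and cohort-table I/O, plus allele harmonization.

PLINK 1.x bed/bim/fam triplets (SNP-major) and sites+GT VCF 4.x are
supported in both directions.  Dosages always count each variant's
*counted* allele: for PLINK that is the bim file's first-listed allele
(A1), for VCF the ALT allele.  :func:`harmonize` re-expresses a dataset's
dosages in terms of a weight table's effect alleles so that scoring is
independent of how the genotype file happened to orient each variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, VariantMeta, WeightTable, validate_cohort_table

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01
# two-bit PLINK genotype code -> dosage of the bim A1 allele
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Malformed or mutually inconsistent genotype files."""


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1.x bed/bim/fam triplet.

    Dosages count the bim file's first-listed allele (A1).  Returns
    variants in bim order and samples in fam order.
    """
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FormatError(f"missing file: {p}")

    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    sample_ids = fam_df.iloc[:, 1].tolist()
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    if bim_df.shape[1] != 6:
        raise FormatError(f"malformed bim file (expected 6 columns): {bim}")
    variants = [
        VariantMeta(
            chrom=row[0],
            pos=int(row[3]),
            vid=row[1],
            allele_counted=row[4].upper(),
            allele_other=row[5].upper(),
        )
        for row in bim_df.itertuples(index=False)
    ]

    n, m = len(sample_ids), len(variants)
    raw = bed.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError(f"bad magic bytes in bed file: {bed}")
    if raw[2] != _SNP_MAJOR:
        raise FormatError(f"only SNP-major bed files are supported: {bed}")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * m:
        raise FormatError(
            f"bed size mismatch for {bed}: {body.size} data bytes, "
            f"expected {bytes_per_variant * m} for {n} samples x {m} variants"
        )
    blocks = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, least-significant pair = first sample of each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_variant * 4)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T.copy()
    return GenotypeMatrix(dosages, variants, sample_ids)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a SNP-major PLINK 1.x bed/bim/fam triplet.

    The counted allele is written as bim A1.  Requires integer dosages.
    """
    if not np.issubdtype(gm.dosages.dtype, np.integer):
        raise ValueError("cannot write imputed (float) dosages to PLINK")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in gm.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chrom}\t{v.vid}\t0\t{v.pos}\t{v.allele_counted}\t{v.allele_other}\n")

    n = gm.n_samples
    bytes_per_variant = (n + 3) // 4
    # lookup indexed by dosage+1: MISSING(-1)->0b01, 0->0b11, 1->0b10, 2->0b00
    code_lut = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        for j in range(gm.n_variants):
            col = gm.dosages[:, j].astype(np.int64)
            codes = np.zeros(bytes_per_variant * 4, dtype=np.uint8)
            codes[:n] = code_lut[col + 1]
            packed = (
                codes[0::4]
                | (codes[1::4] << 2)
                | (codes[2::4] << 4)
                | (codes[3::4] << 6)
            )
            fh.write(packed.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF; dosage counts the ALT allele.

    Multi-allelic records are rejected by default (``split_multiallelic``
    is reserved; the target panels are biallelic SNPs).  ``./.`` becomes
    MISSING.
    """
    import cyvcf2

    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    vcf = cyvcf2.VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantMeta] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if split_multiallelic:
                raise NotImplementedError("multi-allelic splitting is not implemented")
            raise FormatError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} ({rec.ID}); "
                "split or filter the VCF first"
            )
        dos = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is the phase flag
            if len(alleles) != 2:
                raise FormatError(
                    f"non-diploid GT for sample {sample_ids[i]} at {rec.CHROM}:{rec.POS}"
                )
            if any(a < 0 for a in alleles):
                dos[i] = MISSING
            else:
                dos[i] = sum(1 for a in alleles if a == 1)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        variants.append(
            VariantMeta(
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                vid=vid,
                allele_counted=str(rec.ALT[0]).upper(),
                allele_other=str(rec.REF).upper(),
            )
        )
        cols.append(dos)
    if not cols:
        raise FormatError(f"no records in VCF: {path}")
    return GenotypeMatrix(np.column_stack(cols), variants, sample_ids)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal sites+GT VCF 4.2; the counted allele becomes ALT."""
    if not np.issubdtype(gm.dosages.dtype, np.integer):
        raise ValueError("cannot write imputed (float) dosages to VCF")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    order = range(gm.n_variants)  # preserve input order for round-tripping
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids) + "\n"
        )
        for j in order:
            v = gm.variants[j]
            calls = "\t".join(gt_str[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.allele_other}\t{v.allele_counted}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Weight and cohort tables
# ---------------------------------------------------------------------------

def read_weight_table(path: str | Path) -> WeightTable:
    """Read a TSV with columns vid, effect_allele, other_allele, weight[, source]."""
    df = pd.read_csv(path, sep="\t", dtype={"vid": str})
    return WeightTable(df)


def write_weight_table(wt: WeightTable, path: str | Path) -> None:
    wt.table.to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a phenotype/covariate CSV with sample_id and case/control label."""
    return validate_cohort_table(pd.read_csv(path, dtype={"sample_id": str}))


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationReport:
    """Outcome of aligning a dataset to a weight table's effect alleles."""

    kept: list[str] = field(default_factory=list)
    flipped: list[str] = field(default_factory=list)
    strand_flipped: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)  # vid -> reason

    def summary(self) -> str:
        return (
            f"{len(self.kept)} kept ({len(self.flipped)} dosage-flipped, "
            f"{len(self.strand_flipped)} strand-flipped), {len(self.dropped)} dropped"
        )


def harmonize(
    gm: GenotypeMatrix,
    wt: WeightTable,
    ambiguous_policy: str = "drop",
) -> tuple[GenotypeMatrix, HarmonizationReport]:
    """Align a genotype matrix to a weight table's effect alleles.

    For every variant shared with the weight table the output dosage
    counts the table's effect allele: variants whose counted allele
    already is the effect allele pass through, variants counted on the
    other allele are recoded ``2 - g`` (MISSING preserved), and alleles
    reported on the opposite strand are matched via complementation.
    Variants absent from the table, or with irreconcilable allele pairs,
    are dropped with a reason.  Palindromic (A/T, C/G) variants are
    strand-unresolvable: policy ``"drop"`` (default) removes them,
    ``"keep"`` trusts the file strand.

    Returns the aligned matrix (variants in weight-table order) and a
    :class:`HarmonizationReport`.
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ValueError(f"ambiguous_policy must be 'drop' or 'keep', got {ambiguous_policy!r}")
    report = HarmonizationReport()
    wrows = {r.vid: r for r in wt.table.itertuples(index=False)}
    keep_idx: list[int] = []
    new_variants: list[VariantMeta] = []
    flips: list[bool] = []
    for j, v in enumerate(gm.variants):
        row = wrows.get(v.vid)
        if row is None:
            continue  # not scored; silently outside the panel
        ea, oa = row.effect_allele, row.other_allele
        a, b = v.allele_counted, v.allele_other
        flip: bool | None = None
        strand = False
        if (a, b) == (ea, oa):
            flip = False
        elif (a, b) == (oa, ea):
            flip = True
        else:
            ca, cb = _complement(a), _complement(b)
            if ca is not None and (ca, cb) == (ea, oa):
                flip, strand = False, True
            elif ca is not None and (ca, cb) == (oa, ea):
                flip, strand = True, True
        if flip is None:
            report.dropped[v.vid] = (
                f"alleles {a}/{b} irreconcilable with weight table {ea}/{oa}"
            )
            continue
        if v.is_palindromic:
            if ambiguous_policy == "drop":
                report.dropped[v.vid] = f"palindromic alleles {a}/{b} (strand ambiguous)"
                continue
            strand = False  # keep-mode trusts file strand: plain match/swap only
            flip = (a, b) == (oa, ea)
        keep_idx.append(j)
        flips.append(flip)
        report.kept.append(v.vid)
        if flip:
            report.flipped.append(v.vid)
        if strand:
            report.strand_flipped.append(v.vid)
        new_variants.append(
            VariantMeta(chrom=v.chrom, pos=v.pos, vid=v.vid, allele_counted=ea, allele_other=oa)
        )
    if not keep_idx:
        raise ValueError("no variants overlap between dataset and weight table")
    if report.dropped:
        warnings.warn(
            f"harmonize dropped {len(report.dropped)} variant(s): "
            + "; ".join(f"{k} ({v})" for k, v in report.dropped.items()),
            stacklevel=2,
        )
    dosages = gm.dosages[:, keep_idx].copy()
    flip_arr = np.array(flips, dtype=bool)
    if flip_arr.any():
        cols = dosages[:, flip_arr]
        miss = cols == MISSING
        cols = 2 - cols
        cols[miss] = MISSING
        dosages[:, flip_arr] = cols
    return GenotypeMatrix(dosages, new_variants, gm.sample_ids), report


__all__ = [
    "FormatError",
    "HarmonizationReport",
    "read_plink",
    "write_plink",
    "read_vcf",
    "write_vcf",
    "read_weight_table",
    "write_weight_table",
    "read_cohort_table",
    "harmonize",
]
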