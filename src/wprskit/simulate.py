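"""Synthetic case-control cohorts for exercising the PRS pipeline.

The generator emulates a two-disease shared-control study design: one
control group reused against two case cohorts whose genetic risk is
driven by a common variant panel.  Genotypes are drawn in Hardy-Weinberg
proportions from a realistic MAF spectrum; disease status follows an
additive logistic liability

    logit P(case_i) = alpha + sum_j beta_j g_ij + gamma' x_i

with per-variant log-odds beta_j and clinical covariates x (age, sex and
four binary comorbidity/smoking flags).  The second disease shares a
configurable fraction of the first panel's non-zero effects; the
remaining panel variants have no effect on it, so cross-disease
discrimination degrades smoothly from the discovery cohort's as the
shared fraction shrinks.  The intercept alpha is tuned by bisection to a
target population case fraction and cohorts are filled by rejection
sampling, so sampled odds ratios match the generative betas (intercept
aside) by standard logistic case-control theory.

Defaults mirror the emulated study design: a 31-variant panel (29
genome-wide plus 2 previously reported variants) and cohorts of 250 /
222 cases with 296 shared controls.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .datatypes import MISSING, GenotypeMatrix, VariantMeta, WeightTable
from .genotype_io import write_plink, write_vcf, write_weight_table

#: covariate -> (population marginal, liability log-odds effect)
DEFAULT_COVARIATES = {
    "sex": (0.5, 0.30),
    "hypertension": (0.30, 0.60),
    "diabetes": (0.15, 0.30),
    "hyperlipidemia": (0.25, 0.25),
    "smoking": (0.25, 0.40),
}
DEFAULT_AGE_MEAN, DEFAULT_AGE_SD = 55.0, 15.0
DEFAULT_AGE_EFFECT = 0.03  # log-odds per year


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    ``true_weights`` may fix the per-variant log-odds explicitly;
    otherwise 29 'gwas' weights are drawn as \\|N(0.5, 0.2^2)\\| and the
    last 2 'reported' weights as \\|N(0.2, 0.1^2)\\|.
    ``shared_effect_fraction`` is the fraction of panel variants whose
    effect carries over to the second disease.
    """

    seed: int
    n_variants: int = 31
    n_reported: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_weights: np.ndarray | None = None
    n_cases_a: int = 250
    n_cases_b: int = 222
    n_controls: int = 296
    shared_effect_fraction: float = 0.7
    population_case_fraction: float = 0.25
    missing_rate: float = 0.01
    age_mean: float = DEFAULT_AGE_MEAN
    age_sd: float = DEFAULT_AGE_SD
    age_effect: float = DEFAULT_AGE_EFFECT
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    max_draw_factor: int = 500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for name in ("n_variants", "n_cases_a", "n_cases_b", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("shared_effect_fraction", "population_case_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")


# non-palindromic allele pairs so default harmonization keeps everything
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


def _panel(cfg: SimulationConfig, rng: np.random.Generator):
    """Variant metadata, MAFs and true effect sizes for both diseases."""
    m = cfg.n_variants
    mafs = rng.uniform(*cfg.maf_range, size=m)
    if cfg.true_weights is not None:
        beta_a = np.asarray(cfg.true_weights, dtype=float)
        if beta_a.shape != (m,):
            raise ValueError("true_weights must have length n_variants")
    else:
        n_gwas = m - cfg.n_reported
        beta_a = np.concatenate(
            [np.abs(rng.normal(0.5, 0.2, size=n_gwas)), np.abs(rng.normal(0.2, 0.1, size=cfg.n_reported))]
        )
    n_shared = int(round(cfg.shared_effect_fraction * m))
    shared_idx = rng.choice(m, size=n_shared, replace=False)
    beta_b = np.zeros(m)
    beta_b[shared_idx] = beta_a[shared_idx]
    variants = []
    for j in range(m):
        a, b = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        variants.append(
            VariantMeta(
                chrom=str(j % 22 + 1),
                pos=10_000 + 1_000 * j,
                vid=f"rs{1_000_000 + j}",
                allele_counted=a,
                allele_other=b,
            )
        )
    source = ["gwas"] * (m - cfg.n_reported) + ["reported"] * cfg.n_reported
    weights = WeightTable(
        pd.DataFrame(
            {
                "vid": [v.vid for v in variants],
                "effect_allele": [v.allele_counted for v in variants],
                "other_allele": [v.allele_other for v in variants],
                "weight": beta_a,
                "source": source,
            }
        )
    )
    return variants, mafs, beta_a, beta_b, weights


def simulate_genotypes(
    cfg: SimulationConfig, n: int, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw ``n`` samples of Hardy-Weinberg genotypes for the panel.

    Each variant's MAF is drawn from ``cfg.maf_range`` and genotypes are
    binomial(2, MAF); no-calls are injected at ``cfg.missing_rate``.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    variants, mafs, *_ = _panel(cfg, rng)
    dosages = rng.binomial(2, mafs, size=(n, cfg.n_variants)).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING
    ids = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages, variants, ids)


def _draw_covariates(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cov = {"age": rng.normal(cfg.age_mean, cfg.age_sd, size=n)}
    for name, (prev, _) in cfg.covariates.items():
        cov[name] = rng.binomial(1, prev, size=n)
    return pd.DataFrame(cov)


def _linear_predictor(cfg: SimulationConfig, G: np.ndarray, cov: pd.DataFrame, beta: np.ndarray) -> np.ndarray:
    lp = G @ beta + cfg.age_effect * (cov["age"].to_numpy() - cfg.age_mean)
    for name, (_, eff) in cfg.covariates.items():
        lp = lp + eff * cov[name].to_numpy()
    return lp


def _tune_intercept(lp: np.ndarray, target: float) -> float:
    """Bisection for alpha with mean(expit(alpha + lp)) = target."""
    lo, hi = -60.0, 60.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + lp).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class SimulatedStudy:
    """Genotypes, phenotypes and generative truth of one synthetic study."""

    genotypes: GenotypeMatrix
    cohort: pd.DataFrame
    weights: WeightTable
    true_beta_a: np.ndarray
    true_beta_b: np.ndarray
    mafs: np.ndarray
    intercepts: tuple[float, float]

    def __iter__(self):
        return iter((self.genotypes, self.cohort))


def simulate_case_control(cfg: SimulationConfig) -> SimulatedStudy:
    """Simulate two case cohorts with shared controls under the liability model.

    Individuals are drawn from the population (HWE genotypes +
    covariates), disease labels sampled from the two logistic
    liabilities, and assigned to the first open quota: disease-A cases,
    disease-B cases, or (neither-disease) shared controls.  Raises if
    the quotas cannot be filled within ``max_draw_factor`` times the
    total target size.
    """
    rng = np.random.default_rng(cfg.seed)
    variants, mafs, beta_a, beta_b, weights = _panel(cfg, rng)

    # intercepts from a one-off reference population
    ref_G = rng.binomial(2, mafs, size=(20_000, cfg.n_variants)).astype(float)
    ref_cov = _draw_covariates(cfg, 20_000, rng)
    alpha_a = _tune_intercept(_linear_predictor(cfg, ref_G, ref_cov, beta_a), cfg.population_case_fraction)
    alpha_b = _tune_intercept(_linear_predictor(cfg, ref_G, ref_cov, beta_b), cfg.population_case_fraction)

    quota = {"A": cfg.n_cases_a, "B": cfg.n_cases_b, "control": cfg.n_controls}
    total = sum(quota.values())
    got: dict[str, list[int]] = {"A": [], "B": [], "control": []}
    G_rows: list[np.ndarray] = []
    cov_rows: list[pd.DataFrame] = []
    drawn = 0
    batch = max(1000, total)
    while any(len(got[k]) < quota[k] for k in quota):
        if drawn >= cfg.max_draw_factor * total:
            raise RuntimeError(
                f"could not fill cohort quotas within {drawn} draws; "
                "check effect sizes and population_case_fraction"
            )
        G = rng.binomial(2, mafs, size=(batch, cfg.n_variants)).astype(np.int8)
        cov = _draw_covariates(cfg, batch, rng)
        Gf = G.astype(float)
        p_a = expit(alpha_a + _linear_predictor(cfg, Gf, cov, beta_a))
        p_b = expit(alpha_b + _linear_predictor(cfg, Gf, cov, beta_b))
        y_a = rng.random(batch) < p_a
        y_b = rng.random(batch) < p_b
        for i in range(batch):
            if y_a[i] and len(got["A"]) < quota["A"]:
                dest = "A"
            elif y_b[i] and len(got["B"]) < quota["B"]:
                dest = "B"
            elif not y_a[i] and not y_b[i] and len(got["control"]) < quota["control"]:
                dest = "control"
            else:
                continue
            got[dest].append(len(G_rows))
            G_rows.append(G[i])
            cov_rows.append(cov.iloc[[i]])
        drawn += batch

    order = got["A"] + got["B"] + got["control"]
    dosages = np.stack([G_rows[i] for i in order]).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING
    cov_df = pd.concat([cov_rows[i] for i in order], ignore_index=True)
    ids = [f"S{i:06d}" for i in range(len(order))]
    labels = ["case"] * (quota["A"] + quota["B"]) + ["control"] * quota["control"]
    tags = ["A"] * quota["A"] + ["B"] * quota["B"] + ["control"] * quota["control"]
    cohort = pd.DataFrame({"sample_id": ids, "label": labels, "cohort": tags})
    cohort = pd.concat([cohort, cov_df], axis=1)
    gm = GenotypeMatrix(dosages, variants, ids)
    return SimulatedStudy(gm, cohort, weights, beta_a, beta_b, mafs, (alpha_a, alpha_b))


# ---------------------------------------------------------------------------
# Liability-normal scores for analytic AUROC checks
# ---------------------------------------------------------------------------

def simulate_normal_scores(
    delta: float, n_cases: int, n_controls: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian scores with standardized case-control mean difference ``delta``.

    Under this equal-variance normal model the population AUROC has the
    closed form ``Phi(delta / sqrt(2))`` (see :func:`analytic_auroc`).
    Returns (labels, scores).
    """
    rng = np.random.default_rng(seed)
    scores = np.concatenate(
        [rng.normal(delta, 1.0, size=n_cases), rng.normal(0.0, 1.0, size=n_controls)]
    )
    labels = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    return labels, scores


def analytic_auroc(delta: float) -> float:
    """AUROC of the equal-variance binormal model with mean difference delta."""
    return float(norm.cdf(delta / np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

def _reference_scores(gm: GenotypeMatrix, weights: WeightTable) -> pd.DataFrame:
    """Deliberately naive double-loop scorer used for bundled expectations."""
    beta = {r.vid: r.weight for r in weights.table.itertuples(index=False)}
    rows = []
    for i, sid in enumerate(gm.sample_ids):
        s_sum = 0.0
        n_obs = 0
        risk = 0
        for j, v in enumerate(gm.variants):
            g = int(gm.dosages[i, j])
            if g == MISSING:
                continue
            s_sum += beta[v.vid] * g
            risk += g
            n_obs += 1
        rows.append(
            {
                "sample_id": sid,
                "wprs_sum_observed": s_sum,
                "wprs_average": s_sum / (2 * n_obs) if n_obs else np.nan,
                "risk_allele_count": risk,
                "n_observed": n_obs,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_bundle(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Write a complete, reproducible study fixture to ``outdir``.

    Emits a PLINK triplet, a VCF, the weight TSV, the cohort CSV, a
    tertile-count expectation TSV and per-sample expected scores from an
    independent double-loop scorer, plus ``manifest.json`` with SHA-256
    hashes of every file.  Re-running with the same config reproduces
    identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_case_control(cfg)
    write_plink(study.genotypes, outdir / "study.bed")
    write_vcf(study.genotypes, outdir / "study.vcf")
    write_weight_table(study.weights, outdir / "weights.tsv")
    study.cohort.to_csv(outdir / "cohort.csv", index=False)
    expected = _reference_scores(study.genotypes, study.weights)
    expected.to_csv(outdir / "expected_scores.tsv", sep="\t", index=False)

    files = ["study.bed", "study.bim", "study.fam", "study.vcf", "weights.tsv",
             "cohort.csv", "expected_scores.tsv"]
    manifest = {
        "seed": cfg.seed,
        "n_samples": study.genotypes.n_samples,
        "n_variants": study.genotypes.n_variants,
        "files": {f: _sha256(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_case_control",
    "simulate_normal_scores",
    "analytic_auroc",
    "make_fixture_bundle",
]
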