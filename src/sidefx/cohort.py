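"""Seeded synthetic cohort generator.

Emulates the statistical structure of a naturalistic inpatient study of
side effects under polypharmacy: ~900 subjects in two ICD-10 diagnostic
groups (F2 schizophrenic, F3 depressive), ~100 candidate genes genotyped
through 4-8 Hardy-Weinberg SNPs each (~549 SNPs in total), heavy concurrent
medication (4.50 +/- 2.68 drugs on average), longitudinal 46-item side-effect
ratings, symptom-scale trajectories, and 3-week weight series.

Side effects follow a two-part liability model:

* a *general* liability shared by the five general clusters, driven by the
  medication load (number of concurrent drugs) plus optional planted-gene
  contributions plus Gaussian noise;
* *treatment-specific* liabilities driven by two synthetic drug classes
  ("AP-like" antipsychotic-oriented, "AD-like" antidepressant-oriented) whose
  mix depends on diagnosis — F2 treatment is AP-oriented, F3 AD-oriented.
  The AP-like liability drives the neurological and cardio-vascular clusters,
  the AD-like liability the sexuality and autonomic clusters.

Liabilities map to the 0-4 ordinal item ratings through fixed thresholds on a
noisy latent (an ordinal threshold model); weight gain depends on baseline
weight, medication load and the appetite items. Ground truth (liabilities,
planted carriers) is stored separately from the observables.

All randomness flows from ``CohortConfig.seed``; identical configs give
byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genevectors import GenotypeMatrix, encode_gene_vectors
from .phenotypes import (
    ClusterRegistry,
    GENERAL_CLUSTERS,
    SPECIFIC_CLUSTERS,
    default_registry,
)

__all__ = [
    "CohortConfig",
    "PlantedGene",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "MEDICATION_COMPONENTS",
    "MEDIS_DAYS",
    "SCALE_DAYS",
    "WEIGHT_DAYS",
]

#: average medication-load decomposition (drugs per subject): psychotropic
#: drugs, medications alleviating adverse effects, other somatic medications.
MEDICATION_COMPONENTS = {
    "psychotropic": 3.30,
    "adverse_effect_relief": 0.79,
    "other_somatic": 0.41,
}

#: side-effect inventory assessment days (8 assessments over 5 weeks)
MEDIS_DAYS = (1, 3, 7, 10, 14, 21, 28, 35)

#: symptom-scale assessment days (8 assessments over 6 weeks)
SCALE_DAYS = (0, 4, 7, 14, 21, 28, 35, 42)

#: weight measurement days (baseline, week 2, week 3)
WEIGHT_DAYS = (0, 14, 21)

#: ordinal thresholds on the standardised item latent (liability + unit-noise)
#: producing ratings 1..4; calibrated once against the cohort severity
#: distribution (~15% none, ~47% mild-moderate, ~38% severe or worse globally).
ITEM_THRESHOLDS = (0.0, 0.83, 2.08, 2.85)

#: fraction of subjects with a blunted side-effect disposition and the shared
#: liability offset they receive (fattens the zero-severity stratum)
INSENSITIVE_FRACTION = 0.13
INSENSITIVE_OFFSET = -1.6

#: additive severity offset of the treatment-specific over the general
#: component (specific clusters present somewhat more severely)
SPECIFIC_OFFSET = 0.12

#: latent scale of the treatment-specific liabilities relative to thresholds
_SPECIFIC_CLUSTER_CLASS = {
    "sexuality": "AD",
    "autonomic": "AD",
    "neurological": "AP",
    "cardio_vascular": "AP",
}


@dataclass(frozen=True)
class PlantedGene:
    """A synthetic side-effect gene for parameter-recovery experiments.

    ``patterns``: gene-vector codes whose carriers receive ``effect`` on the
    stated liability ("general" or "weight"). With ``patterns=None`` the most
    frequent codes are selected at simulation time until about
    ``carrier_fraction`` of subjects carry one; the realised set is recorded
    in the cohort's ground truth.
    """

    gene_id: str
    patterns: tuple[int, ...] | None = None
    effect: float = 2.0
    target: str = "general"
    carrier_fraction: float = 0.40


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 902
    f2_fraction: float = 264 / 902
    n_genes: int = 100
    snps_per_gene: tuple[int, int] = (4, 8)
    #: probabilities over snps_per_gene range; default mean 5.49 SNPs/gene so
    #: 100 genes carry ~549 SNPs
    snp_count_probs: tuple[float, ...] = (0.30, 0.25, 0.20, 0.16, 0.09)
    allele_freq_range: tuple[float, float] = (0.10, 0.50)
    ld_rho: float = 0.0
    gene_linkage_rho: float = 0.0
    linked_gene_pairs: tuple[tuple[str, str], ...] = ()
    planted_genes: tuple[PlantedGene, ...] = ()
    mean_n_drugs: float = 4.50
    sd_n_drugs: float = 2.68
    #: male-female medication-load difference (females receive more drugs)
    gender_drug_gap: float = 0.82
    load_effect: float = 0.08
    specific_effect: float = 0.25
    #: baseline shift of the general liability; negative values model a less
    #: severity-prone cohort (used by planted-gene recovery experiments)
    liability_offset: float = 0.0
    noise_sd: float = 0.70
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("f2_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.snps_per_gene
        if not (4 <= lo <= hi <= 8):
            raise ValueError("snps_per_gene must lie within [4, 8]")
        if len(self.snp_count_probs) != hi - lo + 1 or not np.isclose(
            sum(self.snp_count_probs), 1.0
        ):
            raise ValueError("snp_count_probs must sum to 1 over the SNP-count range")
        for name in ("ld_rho", "gene_linkage_rho"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        flo, fhi = self.allele_freq_range
        if not 0 < flo <= fhi <= 0.5:
            raise ValueError("allele_freq_range must lie within (0, 0.5]")
        if self.noise_sd < 0 or self.sd_n_drugs <= 0 or self.mean_n_drugs <= 0:
            raise ValueError("scale parameters must be positive")


@dataclass
class SyntheticCohort:
    """Observable tables plus separately stored ground truth."""

    config: CohortConfig
    genotypes: GenotypeMatrix
    subjects: pd.DataFrame
    medis: pd.DataFrame          # long: subject_id, day, item_id, rating
    scale_scores: pd.DataFrame   # long: subject_id, day, score
    weights: pd.DataFrame        # long: subject_id, day, weight_kg
    truth: dict

    def to_dir(self, path: str | Path) -> None:
        """Write the pipeline's standard delimited-text files plus truth.json."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        gt = self.genotypes.values.copy()
        gt.index.name = "subject_id"
        gt.to_csv(path / "genotypes.tsv", sep="\t", na_rep="NA")
        sm = self.genotypes.snp_map.copy()
        sm.index.name = "snp_id"
        sm.to_csv(path / "snp_map.tsv", sep="\t")
        self.subjects.to_csv(path / "subjects.tsv", sep="\t", index=False)
        self.medis.to_csv(path / "medis_long.tsv", sep="\t", index=False)
        self.scale_scores.to_csv(path / "scale_scores.tsv", sep="\t", index=False)
        self.weights.to_csv(path / "weights.tsv", sep="\t", index=False)
        with open(path / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: CohortConfig) -> GenotypeMatrix:
    """Draw the subject x SNP genotype matrix.

    Per SNP, genotypes follow Hardy-Weinberg proportions at its (uniformly
    drawn) minor-allele frequency. Within a gene, adjacent-SNP correlation
    ``ld_rho`` is induced by an AR(1) Gaussian copula on the latent normals;
    designated gene pairs share latents with correlation ``gene_linkage_rho``.
    Missingness is uniform at ``missing_rate``. Coding: 0 = major homozygote,
    1 = heterozygote, 2 = minor homozygote.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_subjects
    lo, hi = config.snps_per_gene
    gene_ids = [f"G{j + 1:03d}" for j in range(config.n_genes)]
    m_per_gene = rng.choice(
        np.arange(lo, hi + 1), size=config.n_genes, p=config.snp_count_probs
    )
    latents: dict[str, np.ndarray] = {}
    for gene, m in zip(gene_ids, m_per_gene):
        eps = rng.standard_normal((n, m))
        z = np.empty((n, m))
        z[:, 0] = eps[:, 0]
        for k in range(1, m):
            z[:, k] = config.ld_rho * z[:, k - 1] + np.sqrt(1 - config.ld_rho**2) * eps[:, k]
        latents[gene] = z
    # between-gene linkage: regenerate the second gene of each designated pair
    # from the first gene's latents
    for ga, gb in config.linked_gene_pairs:
        if ga not in latents or gb not in latents:
            raise ValueError(f"linked pair ({ga}, {gb}) names unknown genes")
        za, zb = latents[ga], latents[gb]
        shared = za[:, np.arange(zb.shape[1]) % za.shape[1]]
        fresh = rng.standard_normal(zb.shape)
        r = config.gene_linkage_rho
        latents[gb] = r * shared + np.sqrt(1 - r**2) * fresh

    cols, snp_ids, map_rows = [], [], []
    from scipy.stats import norm

    for gene, m in zip(gene_ids, m_per_gene):
        freqs = rng.uniform(*config.allele_freq_range, size=m)
        u = norm.cdf(latents[gene])
        p0 = (1 - freqs) ** 2
        p1 = 2 * freqs * (1 - freqs)
        g = (u > p0).astype(float) + (u > p0 + p1)
        cols.append(g)
        for k in range(m):
            snp_ids.append(f"{gene}_S{k + 1}")
            map_rows.append((gene, k + 1))
    values = np.concatenate(cols, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan
    subjects = pd.Index([f"P{i + 1:04d}" for i in range(n)], name="subject_id")
    df = pd.DataFrame(values, index=subjects, columns=snp_ids)
    snp_map = pd.DataFrame(map_rows, index=pd.Index(snp_ids, name="snp_id"),
                           columns=["gene_id", "k"])
    return GenotypeMatrix(df, snp_map)


# ---------------------------------------------------------------------------
# phenotypes


def _truncated_negbin(rng, mean, sd, size, low=1, high=15):
    """Overdispersed drug counts: negative binomial resampled into [low, high]."""
    if sd**2 <= mean:
        raise ValueError("sd^2 must exceed mean for a negative binomial")
    r = mean**2 / (sd**2 - mean)
    p = r / (r + mean)
    out = rng.negative_binomial(r, p, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.negative_binomial(r, p, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _ordinal_ratings(latent: np.ndarray) -> np.ndarray:
    """Threshold a noisy latent into 0..4 ordinal ratings."""
    ratings = np.zeros(latent.shape, dtype=int)
    for thr in ITEM_THRESHOLDS:
        ratings += latent > thr
    return ratings


def _select_planted_patterns(codes: np.ndarray, carrier_fraction: float) -> tuple[int, ...]:
    """Most frequent vector codes until ~carrier_fraction of subjects carry one."""
    valid = codes[~np.isnan(codes)].astype(int)
    vals, counts = np.unique(valid, return_counts=True)
    order = np.lexsort((vals, -counts))
    chosen, cum = [], 0.0
    for idx in order:
        chosen.append(int(vals[idx]))
        cum += counts[idx] / len(valid)
        if cum >= carrier_fraction:
            break
    return tuple(chosen)


def simulate_phenotypes(config: CohortConfig, genotypes: GenotypeMatrix) -> SyntheticCohort:
    """Generate subject, side-effect, symptom-scale and weight tables.

    See the module docstring for the liability model. ``genotypes`` must come
    from the same config (dimension-checked).
    """
    if len(genotypes.subjects) != config.n_subjects:
        raise ValueError("genotype matrix does not match config.n_subjects")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = config.n_subjects
    sid = genotypes.subjects

    # --- demographics ----------------------------------------------------
    is_f2 = rng.random(n) < config.f2_fraction
    diagnosis = np.where(is_f2, "F2", "F3")
    p_male = np.where(is_f2, 143 / 264, 209 / 638)
    is_male = rng.random(n) < p_male
    gender = np.where(is_male, "M", "F")
    age = np.clip(np.round(rng.normal(43, 14, n)), 18, 85).astype(int)
    base_weight = np.round(
        np.clip(rng.normal(np.where(is_male, 80, 69), 14, n), 45, 140), 1
    )
    baseline_score = np.where(
        is_f2,
        np.round(np.clip(rng.normal(35, 8, n), 21, 80)),
        np.round(np.clip(rng.normal(21.5, 4, n), 15, 40)),
    ).astype(int)

    # --- medication load --------------------------------------------------
    half_gap = config.gender_drug_gap / 2
    n_drugs = np.empty(n, dtype=int)
    for male, mean in ((True, config.mean_n_drugs - half_gap),
                       (False, config.mean_n_drugs + half_gap)):
        idx = is_male == male
        n_drugs[idx] = _truncated_negbin(rng, mean, config.sd_n_drugs, int(idx.sum()))
    # drug classes: F2 antipsychotic-oriented, F3 antidepressant-oriented
    p_ap = np.where(is_f2, 0.60, 0.30)
    ap_drugs = rng.binomial(n_drugs, p_ap)
    ad_drugs = n_drugs - ap_drugs

    # --- planted genes ----------------------------------------------------
    vectors = encode_gene_vectors(genotypes)
    planted_truth = []
    planted_general = np.zeros(n)
    planted_weight = np.zeros(n)
    for pg in config.planted_genes:
        if pg.gene_id not in vectors.columns:
            raise ValueError(f"planted gene {pg.gene_id!r} not in genotype matrix")
        codes = vectors[pg.gene_id].to_numpy()
        patterns = pg.patterns
        if patterns is None:
            patterns = _select_planted_patterns(codes, pg.carrier_fraction)
        carrier = np.isin(codes, np.asarray(patterns, dtype=float))
        if pg.target == "general":
            planted_general += pg.effect * carrier
        elif pg.target == "weight":
            planted_weight += pg.effect * carrier
        else:
            raise ValueError("planted gene target must be 'general' or 'weight'")
        planted_truth.append(
            dict(gene_id=pg.gene_id, patterns=list(patterns), effect=pg.effect,
                 target=pg.target, carriers=carrier.astype(int).tolist())
        )

    # --- liabilities ------------------------------------------------------
    # shared blunted-disposition offset: a minority of subjects report next to
    # no side effects across all clusters
    insensitive = rng.random(n) < INSENSITIVE_FRACTION
    disposition = INSENSITIVE_OFFSET * insensitive
    liab_general = (
        config.liability_offset
        + config.load_effect * (n_drugs - config.mean_n_drugs)
        + planted_general
        + disposition
        + rng.normal(0, config.noise_sd, n)
    )
    mean_ap = config.mean_n_drugs * (0.60 * config.f2_fraction + 0.30 * (1 - config.f2_fraction))
    mean_ad = config.mean_n_drugs - mean_ap
    liab_class = {
        "AP": SPECIFIC_OFFSET + config.specific_effect * (ap_drugs - mean_ap)
        + disposition + rng.normal(0, config.noise_sd, n),
        "AD": SPECIFIC_OFFSET + config.specific_effect * (ad_drugs - mean_ad)
        + disposition + rng.normal(0, config.noise_sd, n),
    }

    # --- side-effect inventory ratings ------------------------------------
    registry = default_registry()
    # modest improvement of side effects after day 10
    day_shift = {d: (0.0 if d <= 10 else -0.15) for d in MEDIS_DAYS}
    # dropout: ~70% complete the 5 weeks, the rest stop at day >= 14
    dropout = np.where(
        rng.random(n) < 0.70,
        np.inf,
        rng.choice([14, 21, 28], size=n, p=(0.4, 0.35, 0.25)),
    )
    frames = []
    item_cluster = [(item, registry.cluster_of(item)) for item in registry.all_items]
    for day in MEDIS_DAYS:
        active = dropout >= day
        if not active.any():
            continue
        idx = np.where(active)[0]
        block_items, block_ratings = [], []
        for item, cluster in item_cluster:
            if cluster in GENERAL_CLUSTERS:
                liab = liab_general[idx]
            else:
                liab = liab_class[_SPECIFIC_CLUSTER_CLASS[cluster]][idx]
            latent = liab + day_shift[day] + rng.normal(0, 1.0, len(idx))
            block_items.append(item)
            block_ratings.append(_ordinal_ratings(latent))
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(sid[idx], len(block_items)),
                    "day": day,
                    "item_id": np.tile(block_items, len(idx)),
                    "rating": np.column_stack(block_ratings).ravel(),
                }
            )
        )
    medis = pd.concat(frames, ignore_index=True)

    # --- symptom-scale trajectories ---------------------------------------
    improver_class = rng.choice(3, size=n, p=(0.33, 0.34, 0.33))
    amp = np.where(
        improver_class == 0, rng.uniform(0.55, 0.90, n),
        np.where(improver_class == 1, rng.uniform(0.20, 0.50, n),
                 rng.uniform(0.00, 0.15, n)),
    )
    scale_rows = []
    for day in SCALE_DAYS:
        frac = 1 - amp * (1 - np.exp(-day / 12.0))
        score = baseline_score * frac + rng.normal(0, 1.0, n)
        score = np.maximum(np.round(score), 0)
        if day == 0:
            score = baseline_score.astype(float)
        active = (dropout >= day) | (day <= 14)  # scale follow-up kept through week 2
        scale_rows.append(
            pd.DataFrame(
                {"subject_id": sid[active], "day": day, "score": score[active]}
            )
        )
    scale_scores = pd.concat(scale_rows, ignore_index=True)

    # --- weight series ----------------------------------------------------
    appetite_items = list(registry.items_for("appetite"))
    early = medis[(medis["day"] <= 10) & (medis["item_id"].isin(appetite_items))]
    appetite = (
        early.groupby("subject_id")["rating"].mean().reindex(sid).fillna(0.0).to_numpy()
    )
    delta3 = (
        1.60
        + 0.20 * (n_drugs - config.mean_n_drugs)
        + 0.012 * (base_weight - 72)
        + 0.80 * appetite
        + planted_weight
        + rng.normal(0, 1.8, n)
    )
    # ~55% complete week 3; of the dropouts, half have a week-2 weight (LOCF)
    u = rng.random(n)
    has_wk3 = u < 0.55
    has_wk2 = u < 0.55 + 0.45 * 0.5
    w_rows = [pd.DataFrame({"subject_id": sid, "day": 0, "weight_kg": base_weight})]
    wk2 = np.round(base_weight + 0.67 * delta3 + rng.normal(0, 0.5, n), 1)
    wk3 = np.round(base_weight + delta3, 1)
    w_rows.append(pd.DataFrame({"subject_id": sid[has_wk2], "day": 14, "weight_kg": wk2[has_wk2]}))
    w_rows.append(pd.DataFrame({"subject_id": sid[has_wk3], "day": 21, "weight_kg": wk3[has_wk3]}))
    weights = pd.concat(w_rows, ignore_index=True)

    subjects = pd.DataFrame(
        {
            "subject_id": sid,
            "diagnosis": diagnosis,
            "gender": gender,
            "age": age,
            "baseline_weight_kg": base_weight,
            "baseline_scale": np.where(is_f2, "PANSSG", "HAMD17"),
            "baseline_severity_score": baseline_score,
            "n_drugs": n_drugs,
            "n_drugs_ap_like": ap_drugs,
            "n_drugs_ad_like": ad_drugs,
        }
    )
    truth = {
        "seed": config.seed,
        "liability_general": liab_general.tolist(),
        "liability_ap": liab_class["AP"].tolist(),
        "liability_ad": liab_class["AD"].tolist(),
        "planted_genes": planted_truth,
        "improver_class": improver_class.tolist(),
        "insensitive": insensitive.astype(int).tolist(),
        "weight_delta_true": delta3.tolist(),
    }
    return SyntheticCohort(
        config=config,
        genotypes=genotypes,
        subjects=subjects,
        medis=medis,
        scale_scores=scale_scores,
        weights=weights,
        truth=truth,
    )


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Genotypes plus phenotypes in one seeded call."""
    return simulate_phenotypes(config, simulate_genotypes(config))
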