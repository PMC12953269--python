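"""Synthetic cohort generator: seeding, genotype law, liability structure."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sidefx.cohort import (
    MEDICATION_COMPONENTS,
    CohortConfig,
    PlantedGene,
    simulate_cohort,
    simulate_genotypes,
    simulate_phenotypes,
)
from sidefx.genevectors import encode_gene_vectors
from sidefx.phenotypes import score_profiles


def small_config(**kw):
    base = dict(n_subjects=300, n_genes=8, seed=123)
    base.update(kw)
    return CohortConfig(**base)


class TestDeterminism:
    def test_identical_seeds_give_identical_cohorts(self, tmp_path):
        a = simulate_cohort(small_config())
        b = simulate_cohort(small_config())
        a.to_dir(tmp_path / "a")
        b.to_dir(tmp_path / "b")
        for name in ("genotypes.tsv", "snp_map.tsv", "subjects.tsv",
                     "medis_long.tsv", "scale_scores.tsv", "weights.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_cohort(small_config(seed=1))
        b = simulate_cohort(small_config(seed=2))
        assert not a.genotypes.values.equals(b.genotypes.values)


class TestGenotypeLaw:
    def test_hwe_frequencies_without_ld(self):
        cfg = CohortConfig(
            n_subjects=4000, n_genes=3, seed=5, ld_rho=0.0, missing_rate=0.0,
            allele_freq_range=(0.5, 0.5),
        )
        g = simulate_genotypes(cfg).values.to_numpy()
        freqs = np.stack([(g == c).mean(axis=0) for c in (0, 1, 2)])
        # HWE at q=0.5: (0.25, 0.5, 0.25); binomial 3-sigma at n=4000
        tol = 3 * np.sqrt(0.5 * 0.5 / 4000)
        assert np.abs(freqs - np.array([[0.25], [0.5], [0.25]])).max() < tol + 0.01

    def test_hwe_tolerance_shrinks_with_n(self):
        devs = []
        for n in (500, 8000):
            cfg = CohortConfig(n_subjects=n, n_genes=2, seed=6, missing_rate=0.0,
                               allele_freq_range=(0.3, 0.3))
            g = simulate_genotypes(cfg).values.to_numpy()
            expect = np.array([0.49, 0.42, 0.09])
            obs = np.stack([(g == c).mean(axis=0) for c in (0, 1, 2)])
            devs.append(np.abs(obs - expect[:, None]).mean())
        assert devs[1] < devs[0]

    def test_no_missing_when_rate_zero(self):
        g = simulate_genotypes(small_config(missing_rate=0.0))
        assert not g.values.isna().any().any()

    def test_missing_rate_applied(self):
        g = simulate_genotypes(small_config(n_subjects=2000, missing_rate=0.05))
        assert g.values.isna().to_numpy().mean() == pytest.approx(0.05, abs=0.005)

    def test_ld_rho_increases_within_gene_correlation(self):
        def mean_corr(rho):
            cfg = CohortConfig(n_subjects=1500, n_genes=5, seed=77, ld_rho=rho,
                               missing_rate=0.0)
            gm = simulate_genotypes(cfg)
            cs = []
            for gene in gm.genes:
                sub = gm.values[gm.snps_of(gene)].to_numpy()
                c = np.corrcoef(sub.T)
                cs.append(c[np.triu_indices_from(c, 1)].mean())
            return np.mean(cs)

        assert mean_corr(0.9) > mean_corr(0.0) + 0.2

    def test_snp_totals_near_549_at_default_scale(self):
        g = simulate_genotypes(CohortConfig(seed=0))
        assert 480 <= g.values.shape[1] <= 620
        assert g.values.shape[0] == 902


class TestPhenotypeModel:
    def test_null_load_effect_gives_null_association(self):
        cfg = small_config(n_subjects=800, load_effect=0.0)
        co = simulate_cohort(cfg)
        prof = score_profiles(co.medis, day=10)
        sub = co.subjects.set_index("subject_id").loc[prof.index]
        r, p = stats.pearsonr(prof["GSIDE"], sub["n_drugs"])
        assert abs(r) < 3 / np.sqrt(len(prof))

    def test_positive_load_effect_links_gside_to_drug_count(self):
        co = simulate_cohort(small_config(n_subjects=800))
        prof = score_profiles(co.medis, day=10)
        sub = co.subjects.set_index("subject_id").loc[prof.index]
        rho, p = stats.spearmanr(prof["GSIDE"], sub["n_drugs"])
        assert rho > 0 and p < 0.001

    def test_planted_gene_raises_carrier_gside(self):
        cfg = small_config(
            n_subjects=600,
            snps_per_gene=(4, 4), snp_count_probs=(1.0,), ld_rho=0.5,
            allele_freq_range=(0.25, 0.5),
            planted_genes=(PlantedGene("G003", effect=2.0, carrier_fraction=0.4),),
        )
        co = simulate_cohort(cfg)
        prof = score_profiles(co.medis, day=10)
        carrier = np.array(co.truth["planted_genes"][0]["carriers"], dtype=bool)
        gside = prof["GSIDE"].reindex(co.subjects["subject_id"]).to_numpy()
        t, p = stats.ttest_ind(gside[carrier], gside[~carrier])
        assert t > 0 and p < 1e-6

    def test_drug_count_moments_and_components(self):
        co = simulate_cohort(small_config(n_subjects=4000))
        nd = co.subjects["n_drugs"]
        assert nd.mean() == pytest.approx(4.50, abs=0.25)
        assert nd.std() == pytest.approx(2.68, abs=0.35)
        assert nd.min() >= 1
        by_gender = co.subjects.groupby("gender")["n_drugs"].mean()
        assert by_gender["F"] > by_gender["M"]
        assert sum(MEDICATION_COMPONENTS.values()) == pytest.approx(4.50)

    def test_f2_has_more_ap_like_drugs(self):
        co = simulate_cohort(small_config(n_subjects=2000))
        frac = co.subjects.groupby("diagnosis").apply(
            lambda d: (d["n_drugs_ap_like"] / d["n_drugs"]).mean(),
            include_groups=False,
        )
        assert frac["F2"] > 0.5 > frac["F3"]

    def test_genotype_mismatch_rejected(self):
        g = simulate_genotypes(small_config())
        with pytest.raises(ValueError):
            simulate_phenotypes(small_config(n_subjects=299), g)

    def test_type_i_error_controlled_under_null(self):
        """With all effect sizes zero, genotype-phenotype tests are null."""
        pvals = []
        for seed in (21, 22):
            cfg = CohortConfig(n_subjects=300, n_genes=30, seed=seed,
                               load_effect=0.0, missing_rate=0.0)
            co = simulate_cohort(cfg)
            prof = score_profiles(co.medis, day=10)
            gside = prof["GSIDE"].reindex(co.subjects["subject_id"]).to_numpy()
            vecs = encode_gene_vectors(co.genotypes)
            for gene in vecs.columns:
                codes = vecs[gene].to_numpy()
                top = pd.Series(codes).value_counts().index[0]
                _, p = stats.ttest_ind(gside[codes == top], gside[codes != top])
                pvals.append(p)
        rate = np.mean(np.asarray(pvals) < 0.05)
        n = len(pvals)
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(n_subjects=0), dict(f2_fraction=1.5), dict(ld_rho=1.0),
         dict(snps_per_gene=(3, 8)), dict(allele_freq_range=(0.0, 0.5)),
         dict(missing_rate=-0.1)],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)
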