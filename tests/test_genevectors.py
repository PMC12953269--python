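"""Gene-vector encoding, QC, diversity and pattern-coverage combinatorics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sidefx.genevectors import (
    GenotypeMatrix,
    decode_gene_vector,
    diversity_index,
    diversity_report,
    encode_gene_vectors,
    expected_pattern_fraction,
    gene_linkage,
    qc_filter,
    simulate_pattern_fraction,
)


def make_matrix(values, genes=None):
    """values: (n, p) array with NaN for missing; one gene unless mapped."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    snps = [f"S{i+1}" for i in range(p)]
    subj = pd.Index([f"P{i+1}" for i in range(n)], name="subject_id")
    if genes is None:
        genes = ["GA"] * p
    ks, seen = [], {}
    for g in genes:
        seen[g] = seen.get(g, 0) + 1
        ks.append(seen[g])
    snp_map = pd.DataFrame({"gene_id": genes, "k": ks}, index=pd.Index(snps, name="snp_id"))
    return GenotypeMatrix(pd.DataFrame(values, index=subj, columns=snps), snp_map)


class TestEncoding:
    def test_all_zero_genotypes_encode_to_zero(self):
        m = make_matrix(np.zeros((3, 4)))
        assert (encode_gene_vectors(m)["GA"] == 0).all()

    def test_base3_digit_example(self):
        # digits (s1..s4) = (2,1,0,1): v = 2 + 1*3 + 0*9 + 1*27 = 32
        m = make_matrix([[2, 1, 0, 1]])
        assert encode_gene_vectors(m)["GA"].iloc[0] == 32

    def test_pattern_space_size_m4(self):
        # all 81 patterns for 4 SNPs encode to distinct codes in [0, 81)
        digits = np.array(np.meshgrid(*[range(3)] * 4)).reshape(4, -1).T
        m = make_matrix(digits)
        v = encode_gene_vectors(m)["GA"]
        assert sorted(v) == list(range(81))

    def test_missing_snp_invalidates_vector(self):
        m = make_matrix([[0, 1, np.nan, 2], [0, 0, 0, 0]])
        v = encode_gene_vectors(m)["GA"]
        assert np.isnan(v.iloc[0]) and v.iloc[1] == 0

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=8))
    def test_encode_decode_round_trip(self, digits):
        v = sum(d * 3**k for k, d in enumerate(digits))
        assert list(decode_gene_vector(v, len(digits))) == digits


class TestQC:
    def test_clean_matrix_is_identity(self):
        m = make_matrix(np.ones((4, 5)))
        out, log = qc_filter(m)
        assert out.values.equals(m.values)
        assert not log.removed_subjects and not log.removed_snps

    def test_low_call_rate_subject_removed(self):
        vals = np.ones((5, 10))
        vals[0, :3] = np.nan  # 70% call rate
        out, log = qc_filter(make_matrix(vals), sample_min=0.80)
        assert log.removed_subjects == ["P1"]
        assert len(out.subjects) == 4

    def test_low_call_rate_snp_removed_and_k_compacted(self):
        vals = np.ones((40, 10))
        vals[:2, 2] = np.nan  # SNP3 call rate 95%, not strictly above threshold
        out, log = qc_filter(make_matrix(vals), snp_min=0.95)
        assert not log.removed_subjects  # affected subjects keep 90% call rate
        assert log.removed_snps == ["S3"]
        assert sorted(out.snp_map["k"]) == list(range(1, 10))
        assert len(out.snps_of("GA")) == 9

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 3, (40, 8)).astype(float)
        vals[rng.random((40, 8)) < 0.1] = np.nan
        once, _ = qc_filter(make_matrix(vals))
        twice, log2 = qc_filter(once)
        assert once.values.equals(twice.values)
        assert not log2.removed_subjects and not log2.removed_snps

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            qc_filter(make_matrix(np.ones((2, 4))), sample_min=0.0)


class TestDiversity:
    def test_identical_vectors_give_d1(self):
        assert diversity_index([5.0, 5.0, 5.0]) == 1

    def test_distinct_count(self):
        assert diversity_index([0.0, 0.0, 5.0]) == 2

    def test_d_bounded_and_monotone(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 81, 200).astype(float)
        d_small = diversity_index(v[:50])
        d_full = diversity_index(v)
        assert d_small <= d_full <= min(200, 81)

    def test_report_matches_occupancy_expectation(self):
        # equiprobable genotypes, independent SNPs: observed d near expectation
        rng = np.random.default_rng(1)
        m, n = 4, 4 * 81
        vals = rng.integers(0, 3, (n, m)).astype(float)
        gm = make_matrix(vals)
        rep = diversity_report(encode_gene_vectors(gm), gm, genotype_probs="uniform")
        row = rep.loc["GA"]
        assert row["theoretical"] == 81
        # 3 SE of the occupancy count (binomial bound per pattern)
        assert abs(row["d"] - row["expected"]) < 3 * np.sqrt(row["expected"])


class TestExpectedPatternFraction:
    def test_degenerate_sizes(self):
        assert expected_pattern_fraction(0, m=4) == 0.0
        assert expected_pattern_fraction(10**9, m=3) == pytest.approx(1.0)

    def test_equiprobable_closed_form_m5(self):
        # 1 - (1 - 3^-5)^972 = 0.9818...
        got = expected_pattern_fraction(4 * 243, m=5)
        assert got == pytest.approx(1 - (1 - 3.0**-5) ** 972, abs=1e-12)
        assert got == pytest.approx(0.982, abs=5e-4)

    def test_hwe_half_distribution_is_lower(self):
        # HWE at allele frequency 0.5 concentrates mass on heterozygotes and
        # lowers the coverage markedly below the equiprobable case
        probs = np.tile([0.25, 0.5, 0.25], (5, 1))
        got = expected_pattern_fraction(4 * 243, genotype_probs=probs)
        assert got == pytest.approx(0.892, abs=5e-3)

    def test_zero_probability_patterns_contribute_nothing(self):
        probs = np.array([[1.0, 0.0, 0.0], [0.5, 0.5, 0.0]])
        # only 2 of 9 patterns reachable
        assert expected_pattern_fraction(10**6, genotype_probs=probs) == pytest.approx(2 / 9)

    def test_analytic_agrees_with_monte_carlo(self):
        rng = np.random.default_rng(7)
        for m, n in [(4, 81), (4, 4 * 81), (5, 243)]:
            ana = expected_pattern_fraction(n, m=m)
            mc, se = simulate_pattern_fraction(n, m=m, n_reps=60, rng=rng)
            assert abs(ana - mc) < 3 * se


class TestGeneLinkage:
    def test_duplicate_gene_scores_one(self):
        rng = np.random.default_rng(3)
        v = rng.integers(0, 9, 120).astype(float)
        vecs = pd.DataFrame({"GA": v, "GB": v})
        res = gene_linkage(vecs, "GA", "GB", n_permutations=99, rng=1)
        assert res.v == pytest.approx(1.0)
        assert res.p_value <= 0.01

    def test_independent_genes_score_near_zero(self):
        rng = np.random.default_rng(4)
        vecs = pd.DataFrame(
            {"GA": rng.integers(0, 5, 400).astype(float),
             "GB": rng.integers(0, 5, 400).astype(float)}
        )
        res = gene_linkage(vecs, "GA", "GB", n_permutations=199, rng=2)
        assert res.v < 0.15
        assert res.p_value > 0.05

    def test_planted_linkage_detected(self):
        from sidefx.cohort import CohortConfig, simulate_genotypes

        cfg = CohortConfig(
            n_subjects=500, n_genes=4, seed=9, missing_rate=0.0,
            gene_linkage_rho=0.8, linked_gene_pairs=(("G001", "G002"),),
            snps_per_gene=(4, 4), snp_count_probs=(1.0,),
        )
        vecs = encode_gene_vectors(simulate_genotypes(cfg))
        linked = gene_linkage(vecs, "G001", "G002", n_permutations=199, rng=3)
        free = gene_linkage(vecs, "G003", "G004", n_permutations=199, rng=3)
        assert linked.p_value <= 0.01
        assert linked.v > free.v
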