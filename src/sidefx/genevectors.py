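"""Base-3 gene vectors, genetic diversity, and pattern-coverage combinatorics.

A gene is genotyped through m ordered polymorphic SNPs (4 <= m <= 8 in this
pipeline, but any m >= 1 works). Each SNP genotype is coded 0/1/2 (major
homozygote / heterozygote / minor homozygote), so a subject's "gene vector" is
the base-3 integer

    v = sum_k s_k * 3^(k-1),   k = 1..m,

taking one of 3^m values per gene. The number of *distinct* vectors observed
in a sample, the gene's diversity index d, measures the gene's information
content for resolving between-subject differences. The expected fraction of
the 3^m theoretically possible patterns visible in a sample of size n follows
a classical occupancy argument and is computed in closed form alongside a
Monte-Carlo estimator.

Between-gene linkage of genotypic patterns is scored with bias-corrected
Cramér's V on the pattern contingency table plus a seeded permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QCLog",
    "qc_filter",
    "encode_gene_vectors",
    "decode_gene_vector",
    "diversity_index",
    "diversity_report",
    "expected_pattern_fraction",
    "simulate_pattern_fraction",
    "gene_linkage",
    "GeneLinkage",
]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs genotype codes with a SNP -> (gene, order) map.

    ``values``: DataFrame indexed by subject id, columns are SNP ids, entries
    in {0, 1, 2} or NaN for missing. ``snp_map``: DataFrame indexed by SNP id
    with columns ``gene_id`` and ``k`` (within-gene digit order, 1..m without
    gaps). The 0/1/2 coding counts copies of the minor allele; orientation is
    fixed upstream (major homozygote = 0) so vectors are deterministic.
    """

    values: pd.DataFrame
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.values.columns) == set(self.snp_map.index):
            raise ValueError("snp_map must cover exactly the SNPs in the matrix")
        if not {"gene_id", "k"}.issubset(self.snp_map.columns):
            raise ValueError("snp_map needs columns gene_id and k")
        for gene, grp in self.snp_map.groupby("gene_id", sort=False):
            ks = sorted(grp["k"].tolist())
            if ks != list(range(1, len(ks) + 1)):
                raise ValueError(f"gene {gene!r}: k must run 1..m without gaps, got {ks}")
        vals = self.values.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> list:
        return list(dict.fromkeys(self.snp_map["gene_id"]))

    def snps_of(self, gene) -> list:
        grp = self.snp_map[self.snp_map["gene_id"] == gene]
        return list(grp.sort_values("k").index)

    def sample_call_rates(self) -> pd.Series:
        return self.values.notna().mean(axis=1)

    def snp_call_rates(self) -> pd.Series:
        return self.values.notna().mean(axis=0)


@dataclass
class QCLog:
    removed_subjects: list = field(default_factory=list)
    removed_snps: list = field(default_factory=list)
    sample_threshold: float = 0.8
    snp_threshold: float = 0.95


def qc_filter(
    matrix: GenotypeMatrix,
    sample_min: float = 0.80,
    snp_min: float = 0.95,
) -> tuple[GenotypeMatrix, QCLog]:
    """Apply genotyping quality control.

    Subjects are kept only with sample call rate strictly above ``sample_min``
    (default 80%); SNPs, evaluated on the retained subjects, only with call
    rate strictly above ``snp_min`` (default 95%). Removing SNPs changes the
    remaining subjects' call rates (and vice versa), so the two filters are
    iterated to a fixed point — this makes the operation idempotent. After SNP
    removal the within-gene digit order k is re-indexed compactly so vectors
    stay dense in [0, 3^m). Removals are returned in a log.
    """
    for name, thr in (("sample_min", sample_min), ("snp_min", snp_min)):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    log = QCLog(sample_threshold=sample_min, snp_threshold=snp_min)

    vals = matrix.values
    while True:
        keep_subj = vals.notna().mean(axis=1) > sample_min
        log.removed_subjects += list(vals.index[~keep_subj])
        vals = vals.loc[keep_subj]
        keep_snp = vals.notna().mean(axis=0) > snp_min
        log.removed_snps += list(vals.columns[~keep_snp])
        vals = vals.loc[:, keep_snp]
        if keep_subj.all() and keep_snp.all():
            break
        if vals.empty:
            break

    snp_map = matrix.snp_map.loc[vals.columns].copy()
    snp_map["k"] = (
        snp_map.sort_values("k").groupby("gene_id", sort=False).cumcount() + 1
    )
    # drop genes that lost all SNPs (no rows remain for them automatically)
    return GenotypeMatrix(vals, snp_map), log


# ---------------------------------------------------------------------------
# encoding


def encode_gene_vectors(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Encode genotypes into per-gene base-3 integer vectors.

    Returns a subjects x genes DataFrame of float codes in [0, 3^m); NaN marks
    an invalid vector (any constituent SNP missing — no imputation, since
    invented genotypes would fabricate patterns).
    """
    out = {}
    for gene in matrix.genes:
        snps = matrix.snps_of(gene)
        weights = 3.0 ** np.arange(len(snps))
        sub = matrix.values[snps].to_numpy(dtype=float)
        out[gene] = sub @ weights  # NaN propagates
    return pd.DataFrame(out, index=matrix.subjects)


def decode_gene_vector(v: int, m: int) -> tuple[int, ...]:
    """Inverse of the base-3 encoding: digits (s_1, ..., s_m) of v."""
    if not 0 <= v < 3**m:
        raise ValueError(f"v must lie in [0, 3^{m})")
    digits = []
    for _ in range(m):
        digits.append(v % 3)
        v //= 3
    return tuple(digits)


# ---------------------------------------------------------------------------
# diversity and expected pattern coverage


def _pattern_probs(genotype_probs: np.ndarray) -> np.ndarray:
    """Joint probability of each of the 3^m patterns under SNP independence.

    ``genotype_probs``: (m, 3) array of per-SNP genotype probabilities, digit
    order matching the encoding (row k-1 is SNP k). Returned vector is indexed
    by the base-3 pattern code.
    """
    gp = np.asarray(genotype_probs, dtype=float)
    if gp.ndim != 2 or gp.shape[1] != 3:
        raise ValueError("genotype_probs must have shape (m, 3)")
    if not np.allclose(gp.sum(axis=1), 1.0):
        raise ValueError("each SNP's genotype probabilities must sum to 1")
    p = np.array([1.0])
    for row in gp:  # code = sum s_k 3^(k-1): SNP k strides by 3^(k-1)
        p = (row[:, None] * p[None, :]).ravel()
    return p


def expected_pattern_fraction(
    n: int,
    genotype_probs: np.ndarray | None = None,
    m: int | None = None,
) -> float:
    """Expected fraction of the 3^m possible patterns observed in n subjects.

    Closed-form occupancy expectation under independent SNPs:

        E[d] / 3^m = (1/3^m) * sum_patterns [1 - (1 - p_pattern)^n]

    with p_pattern the product of the per-SNP genotype probabilities. Pass
    ``genotype_probs`` of shape (m, 3), or ``m`` alone for equiprobable
    genotypes (1/3, 1/3, 1/3). Patterns with zero probability contribute 0.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if genotype_probs is None:
        if m is None:
            raise ValueError("pass genotype_probs or m")
        genotype_probs = np.full((m, 3), 1.0 / 3.0)
    p = _pattern_probs(genotype_probs)
    if n == 0:
        return 0.0
    return float(np.mean(-np.expm1(n * np.log1p(-np.minimum(p, 1.0 - 1e-300)))))


def simulate_pattern_fraction(
    n: int,
    genotype_probs: np.ndarray | None = None,
    m: int | None = None,
    n_reps: int = 50,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of the observed pattern
    fraction for samples of size n, matching :func:`expected_pattern_fraction`.
    """
    rng = np.random.default_rng(rng)
    if genotype_probs is None:
        if m is None:
            raise ValueError("pass genotype_probs or m")
        genotype_probs = np.full((m, 3), 1.0 / 3.0)
    p = _pattern_probs(genotype_probs)
    total = len(p)
    fracs = np.empty(n_reps)
    for r in range(n_reps):
        counts = rng.multinomial(n, p)
        fracs[r] = np.count_nonzero(counts) / total
    se = fracs.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.nan
    return float(fracs.mean()), float(se)


def diversity_index(vectors: pd.Series | np.ndarray) -> int:
    """Number of distinct valid gene-vector values (diversity index d)."""
    arr = np.asarray(vectors, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("need at least one valid vector")
    return int(np.unique(arr).size)


def diversity_report(
    vectors: pd.DataFrame,
    matrix: GenotypeMatrix,
    genotype_probs: str = "observed",
) -> pd.DataFrame:
    """Per-gene diversity report.

    Columns: ``m`` (SNPs), ``n_valid`` subjects, ``d`` (distinct observed
    patterns), ``theoretical`` = 3^m, ``expected`` = expected distinct count
    for n_valid subjects under the stated genotype distribution
    ("observed" per-SNP sample frequencies, or "uniform" for equiprobable
    genotypes), and the ratios d/theoretical and d/expected.
    """
    if genotype_probs not in ("observed", "uniform"):
        raise ValueError("genotype_probs must be 'observed' or 'uniform'")
    rows = []
    for gene in matrix.genes:
        col = vectors[gene]
        valid = col.dropna()
        m = len(matrix.snps_of(gene))
        if len(valid) == 0:
            rows.append(
                dict(gene_id=gene, m=m, n_valid=0, d=np.nan,
                     theoretical=3**m, expected=np.nan,
                     d_over_theoretical=np.nan, d_over_expected=np.nan)
            )
            continue
        d = diversity_index(valid)
        if genotype_probs == "observed":
            gp = np.vstack([
                np.array([
                    (matrix.values[snp] == g).sum() for g in (0, 1, 2)
                ], dtype=float)
                for snp in matrix.snps_of(gene)
            ])
            gp = gp / gp.sum(axis=1, keepdims=True)
        else:
            gp = np.full((m, 3), 1.0 / 3.0)
        frac = expected_pattern_fraction(len(valid), genotype_probs=gp)
        expected = frac * 3**m
        rows.append(
            dict(gene_id=gene, m=m, n_valid=len(valid), d=d,
                 theoretical=3**m, expected=expected,
                 d_over_theoretical=d / 3**m,
                 d_over_expected=d / expected if expected > 0 else np.nan)
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# between-gene pattern linkage


@dataclass
class GeneLinkage:
    v: float
    chi2: float
    dof: int
    p_value: float
    n: int


def _cramers_v_bias_corrected(table: np.ndarray) -> tuple[float, float, int]:
    """Bias-corrected Cramér's V (Bergsma correction) and the Pearson chi2."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    chi2 = stats.chi2_contingency(table, correction=False)[0] if table.min() >= 0 else np.nan
    r, c = table.shape
    phi2 = chi2 / n
    phi2c = max(0.0, phi2 - (r - 1) * (c - 1) / (n - 1))
    rc = r - (r - 1) ** 2 / (n - 1)
    cc = c - (c - 1) ** 2 / (n - 1)
    denom = min(rc - 1, cc - 1)
    v = np.sqrt(phi2c / denom) if denom > 0 else np.nan
    return float(v), float(chi2), int((r - 1) * (c - 1))


def gene_linkage(
    vectors: pd.DataFrame,
    gene_a,
    gene_b,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> GeneLinkage:
    """Association between the genotypic patterns of two genes.

    Computes bias-corrected Cramér's V on the pattern-code contingency table
    over subjects with valid vectors for both genes, with a label-shuffling
    permutation p-value (permuting gene_b's patterns across subjects). A
    duplicated gene yields V = 1; independent genes yield V near 0 with a
    uniform permutation p-value.
    """
    sub = vectors[[gene_a, gene_b]].dropna()
    if len(sub) < 2:
        raise ValueError("need >=2 subjects with valid vectors for both genes")
    a = pd.factorize(sub[gene_a])[0]
    b = pd.factorize(sub[gene_b])[0]
    ka, kb = a.max() + 1, b.max() + 1
    if ka < 2 or kb < 2:
        raise ValueError("each gene needs >=2 distinct patterns among shared subjects")

    def table_of(bb):
        t = np.zeros((ka, kb))
        np.add.at(t, (a, bb), 1.0)
        return t

    v, chi2, dof = _cramers_v_bias_corrected(table_of(b))
    rng = np.random.default_rng(rng)
    hits = 0
    for _ in range(n_permutations):
        vp, _, _ = _cramers_v_bias_corrected(table_of(rng.permutation(b)))
        if vp >= v - 1e-12:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return GeneLinkage(v=v, chi2=chi2, dof=dof, p_value=p, n=len(sub))
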