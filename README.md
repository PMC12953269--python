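# sidefx

Quantitative side-effect phenotyping and multilocus genotype-pattern
analysis for psychiatric inpatients under polypharmacy.

## The problem

Most inpatients treated for major depression (ICD-10 F3) or schizophrenia
(F2) receive several psychotropic and somatic drugs at once. Side effects
under such polypharmacy appear to split into two parts: an *unspecific
general component* whose severity tracks the overall medication load
(number of concurrent drugs), and *treatment-specific components* that
depend on the substance mix. Because patients on identical loads can show
very different side-effect patterns, a genetic disposition is plausible.
This package implements, as a tested pipeline, the quantitative side-effect
model and the molecular-genetic machinery needed to probe that hypothesis —
exercised end to end on a synthetic cohort generator that emulates the data
structure of such a study (no patient-level data are distributed).

## The model

**Phenotype side.** A 46-item side-effect inventory is grouped into 9
clusters: sleep (5 items), appetite (3), sexuality (3), gastro-intestinal
(7), cardiac-respiratory (4), autonomic (5), psychosomatic (6),
neurological (9), cardio-vascular (4). The global score S (sum over all
items, each rated 0–4) is stratified at S ≤ 10 (none), 10 < S ≤ 30 (mild),
30 < S ≤ 40 (moderate), 40 < S ≤ 50 (severe), S > 50 (very severe). The
general component **GSIDE** sums the 25 items of the sleep, appetite,
gastro-intestinal, cardiac-respiratory and psychosomatic clusters; the 21
remaining items form the specific components **SEX, AUTO, NEURO, CARDIO**.
Response is a sustained 50% (HAMD17) or 40% (PANSSP) baseline reduction,
onset of improvement a sustained 20% reduction; weight change at week 3
(LOCF from week 2 where needed) is classed at ±2 kg and binned [2,4],
(4,7.5], >7.5 kg.

**Genotype side.** Each gene is genotyped through m ordered SNPs
(4 ≤ m ≤ 8) coded s ∈ {0,1,2}, giving the base-3 *gene vector*

    v_i^(j) = Σ_{k=1..m(j)} s_ik^(j) · 3^(k−1)

with 3^m possible genotypic patterns per gene (81 for m = 4, 6561 for
m = 8). The number of distinct patterns observed in a sample — the
*diversity index* d — measures a gene's capacity to resolve
between-subject differences; its expectation follows a classical occupancy
formula implemented in closed form and by Monte Carlo. A two-stage
classifier then (1) screens genes for pattern sets covering a majority of
phenotype-positive subjects while each pattern stays rare (< 10%) among
phenotype-negative subjects, with permutation p-values and
Benjamini–Hochberg control, and (2) trains a sigmoid multilayer network by
the online backpropagation rules

    Δw_ij = α · ε_i · s_j · s_i(1−s_i),
    Δw_jk = α · Σ_i ε_i · s_k · s_i(1−s_i) · w_ij · s_j(1−s_j),

with gene-weighted inputs, random-walk restarts and stratified 10-fold
cross-validation.

## Worked example

The analysis is driven by the numbered scripts under `analysis/`:

```sh
python analysis/01_simulate_cohort.py --seed 1 --out results/cohort
python analysis/02_score_phenotypes.py --in results/cohort --out results
python analysis/03_gene_vectors.py    --in results/cohort --out results
python analysis/04_screen_patterns.py --in results --seed 1 --out results
python analysis/05_neural_net.py      --in results --cohort results/cohort --seed 1 --out results
python analysis/06_stats_report.py    --in results --cohort results/cohort --out results
```

With seed 1 this prints, step by step:

```
simulated 902 subjects (255 F2 / 647 F3), 559 SNPs in 100 genes
mean concurrent medications: 4.63 +/- 2.61 (F 4.88 / M 4.24)
...
responders: 33.8% of 902
weight gain >= 2 kg: 49.0% of 714 (mean 1.93 kg)
...
diversity index d: mean 221.1 (range 46-590)
...
no gene reached significance at the stated FDR (expected when genotypes
carry no phenotype signal)
...
with FN forced below 15% (fn=14.8%): FP rate 86.0% -> the null failure signature
...
corr(GSIDE, n_drugs): r = 0.22040; p = 2.193e-11
```

Read: the simulated cohort reproduces the intended clinical structure
(polypharmacy loads near 4.5 drugs, a third of subjects responding, half
gaining ≥ 2 kg), the general side-effect component correlates with the
medication load (r ≈ 0.22), and — because the default generator plants no
genotype effect — the screening stage flags nothing and the cross-validated
classifier shows the characteristic null signature: forcing the
false-negative rate below 15% drives the false-positive rate far above 50%.
Planted "side-effect genes" (see `sidefx.cohort.PlantedGene`) are recovered
by the same machinery with both error rates below 15%.

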