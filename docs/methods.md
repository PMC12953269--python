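# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data experiments do and do not
demonstrate.

## Side-effect phenotyping

Items are rated on a 5-point ordinal scale coded 0–4 (absent, mild,
moderate, severe, very severe); 0 is chosen for "absent" so that absence
contributes nothing to any sum score. Cluster scores are plain item sums;
the global score S is the sum over all 46 items, so S always equals the sum
of the 9 cluster scores and GSIDE (25 general items) plus the four specific
components (21 items) always equals S.

The severity cutpoints (10/30/40/50) are calibrated to the full 46-item
instrument. Cluster- or component-level stratification therefore rescales a
score by 46 / (items in the cluster) before applying the same cutpoints.
The case/control dichotomy used for screening is moderate-to-severe
(stratum ∈ {moderate, severe, very severe}) versus none/mild.

"Sustained" response is read strictly: the criterion (50% HAMD17 / 40%
PANSSP reduction from the first assessment; 20% for onset) must hold at
*every* available assessment from its first crossing through the last one.
This is deterministic and means a late relapse always cancels response. A
zero or negative baseline is an input error (relative reduction undefined).
LOCF (last observation carried forward) is applied per instrument
independently: item ratings for profile scoring, and week-2 weights where
the week-3 weight is missing. Subjects with no usable post-baseline weight
are excluded from weight analyses with a logged reason, not silently
dropped.

## Gene vectors and diversity

The base-3 encoding v = Σ s_k 3^(k−1) requires a fixed digit order; the
package uses the within-gene order k carried by the SNP map (file order
when no positions are known). Genotype code 0 is the major-allele
homozygote as realised by the simulator; any fixed orientation works, but
it must be deterministic because v depends on it. A missing constituent SNP
invalidates the whole vector for that subject and gene — imputation would
fabricate patterns, and diversity counts are highly sensitive to invented
values.

QC keeps subjects with sample call rate strictly above 80% and SNPs with
call rate strictly above 95%. Because each removal changes the other call
rates, the two filters are iterated to a fixed point, which makes QC
idempotent; after SNP removal the digit order is compacted so vectors stay
dense in [0, 3^m).

The expected fraction of the 3^m patterns observed in n subjects is the
occupancy expectation (1/3^m) Σ_p [1 − (1 − p_pattern)^n] under SNP
independence, with p_pattern the product of per-SNP genotype probabilities;
zero-probability patterns contribute nothing. The often-quoted rule of
thumb that n = 4·3^m reveals "about 95%" of patterns depends entirely on
the genotype distribution assumed: equiprobable genotypes give ≈ 98.2% at
m = 5, Hardy–Weinberg at allele frequency 0.5 gives ≈ 89.2%. The package
therefore exposes the distribution as a parameter instead of hard-coding a
number. Between-gene pattern linkage is scored with bias-corrected Cramér's
V on the pattern contingency table (the correlation measure for such tables
is not canonical; V is a documented stand-in) plus a seeded label-shuffling
permutation p-value.

## Pattern screening

For one gene and a binary phenotype, a pattern is *admissible* if its
frequency among the opposite class is strictly below the rarity threshold
(default 0.10 — the "< 10%" criterion) and it occurs at least
min_pattern_count = 5 times overall. The count guard matters: diversity
indices approach the sample size, so without it near-singleton patterns are
trivially "rare in controls" and the coverage statistic degenerates.
Admissible patterns are accumulated by ascending opposite-class frequency
(ties: descending target-class frequency, then ascending pattern code)
until the target-class coverage reaches the majority threshold. "Vast
majority" is not quantified anywhere authoritative, so the threshold is a
parameter (default 0.50) with sensitivity sweeps supported; the
strong-effect recovery experiment runs it at 0.9 so that the flagged set,
not just a bare majority, covers the carriers. Both directions
(case-enriched and control-enriched) are screened and reported separately.

Significance: the achieved statistic (coverage minus opposite-class
frequency of the selected set) is compared against label permutations
(default 999 — the smallest attainable p is 1/(B+1), and Benjamini–Hochberg
across ~100 genes × 2 directions needs p-values well below the FDR level).
Gene weights for the network stage are max(0, coverage − opposite
frequency) for significant genes and a 0.05 floor otherwise.

## Neural network

The classifier is a fully connected sigmoid network with one hidden layer,
trained by per-probe (online) gradient descent using exactly the stated
update rules; those rules are the gradients of the squared error
E = ½ Σ (y − s)² for logistic units, which fixes both the error function
and σ(z) = 1/(1 + e^(−z)) (the s(1−s) factor is the logistic derivative).
The decisive correctness oracle is a central finite-difference comparison,
asserted to 10⁻⁵ relative error in the test suite.

Bias terms are realised as a clamped constant unit (s = 1) appended to the
input and hidden layers, so the update rules apply to them unchanged.
Without biases the output at the origin is pinned to σ(Σa/2) and a 2-unit
hidden layer cannot represent XOR, which would make the standard
separability check unattainable; with biases XOR trains to error < 0.05
within the restart budget.

Weights initialise uniformly in [−0.5, 0.5] (seeded). Model selection uses
random restarts plus a random walk: each later restart perturbs the best
weights so far with Gaussian noise whose scale halves per restart,
distinguishing local from global minima without assuming anything about
the error surface. Divergent restarts (non-finite error) are abandoned and
logged. Default hidden size is ⌈√inputs⌉ (unreported in the source
setting; exposed in the config). Inputs are either gene vectors normalised
by 3^m − 1 and scaled by the gene weight (default; invalid vectors enter
as the uninformative midpoint 0.5) or 0/1 indicators of carrying a flagged
pattern per screened gene × direction. Classification uses the 0.5 output
threshold; multiple output units support simultaneous discrimination of
several clusters.

Cross-validation is stratified 10-fold (sizes differ by ≤ 1, every probe
tested exactly once), falling back to an unstratified partition when a
class is smaller than k (leave-one-out). False-negative rate is
FN/(FN+TP), false-positive rate FP/(FP+TN). The null-regime diagnostic
fixes the largest decision threshold keeping FN below 15% on the pooled
out-of-fold scores and reports the resulting FP rate: on uninformative
scores this necessarily lands near 1 − 0.15 = 85%, reproducing the
"FN < 15% forces FP > 50%" failure signature.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions, chosen once and not revisited.

Demographics and load: 902 subjects, F2 fraction 264/902, gender
frequencies per diagnosis (143/264 male in F2, 209/638 in F3); concurrent
medications from a truncated negative binomial matched to mean 4.50, SD
2.68 (overdispersed counts ≥ 1, capped at 15), with a gender gap of 0.82
drugs (females ≈ 4.9, males ≈ 4.0). The printed load decomposition
3.30 psychotropic + 0.79 adverse-effect-relief + 0.41 somatic = 4.50 is
kept as a module constant. Two synthetic drug classes stand in for the
266-drug reality: each subject's drugs split binomially into "AP-like"
(probability 0.6 for F2, 0.3 for F3) and "AD-like", mirroring
antipsychotic- versus antidepressant-oriented regimens.

Genotypes: ~100 genes with 4–8 SNPs drawn with probabilities
(0.30, 0.25, 0.20, 0.16, 0.09) (mean 5.49 SNPs/gene, ≈ 549 SNPs in total);
per SNP, Hardy–Weinberg genotypes at a uniform minor-allele frequency in
[0.10, 0.50], thresholded from an AR(1) Gaussian copula with adjacent-SNP
correlation ld_rho (default 0); designated gene pairs can share latents
with correlation gene_linkage_rho. Missingness is uniform (default 1%).

Liabilities: the general liability is load_effect·(n_drugs − 4.5) plus
planted-gene contributions plus N(0, 0.70) noise; AP-like and AD-like
liabilities are specific_effect·(class count − mean) + 0.12 + noise. The
AP-like liability drives the neurological and cardio-vascular clusters,
the AD-like one sexuality and autonomic. A 13% subpopulation receives a
shared −1.6 offset ("blunted disposition") — without it a Gaussian
liability cannot produce the observed ~15% zero-severity stratum. Item
ratings are ordinal thresholds (0.0, 0.83, 2.08, 2.85) on liability plus
unit item noise; thresholds and scales were calibrated once against the
cohort-level severity distribution (~13% none, ~50% mild–moderate, ~37%
severe or worse; general-component correlation with the load r ≈ 0.24) and
then frozen. load_effect defaults to 0.08; the load-calibrated scenario
used for the ~30% variance-share recovery sets 0.22. The severity profile
softens slightly (−0.15 latent) after day 10.

Trajectories: side-effect assessments at days 1–35 (8 visits; 30% of
subjects drop out at day ≥ 14), symptom scales at days 0–42 with
exponential improvement amplitudes drawn from three groups (non/partial/
full improvers at 33/34/33%), yielding ≈ 34% responders. Week-3 weight
change is 1.60 + 0.20·(n_drugs − 4.5) + 0.012·(baseline − 72) +
0.80·(mean early appetite rating) + planted weight effects + N(0, 1.8);
55% of subjects have a week-3 weight, half of the remainder a week-2
weight (the LOCF path).

Planted genes: carriers of a configurable pattern set receive an additive
liability effect; with patterns unspecified, the most frequent codes are
chosen until ≈ the requested carrier fraction, and the realised set is
recorded in the ground-truth record (kept separate from observables). The
liability_offset knob lowers the baseline severity so a strong planted
effect yields a clean case/control structure; the recovery experiments use
offset −1.5 and effect 3.0 on low-diversity genes (m = 4, ld_rho 0.5,
allele frequencies 0.25–0.5) so that pattern carriers are numerous enough
to clear the min-count guard.

What the generator does *not* emulate: real allele frequencies or LD
structure, pharmacokinetics, real drug identities, item-level response
styles, informative dropout, or the heavy right skew of clinical weight
gain. Passing tests therefore demonstrate the correctness and honesty of
the machinery (calibration under the null, recovery under planted signal),
not clinical validity on real data. In particular the diversity indices of
the default (LD-free) genotypes are higher than real genes would show;
nonzero ld_rho lowers them.

## Numerical conventions and problem sizes

All randomness flows from integer seeds through numpy SeedSequence spawns;
identical configs give byte-identical cohorts and results. Screening
p-values use the add-one permutation estimator (1 + hits)/(B + 1).
Tie-breaks in the greedy screen are fully specified (opposite-class
frequency, then target frequency, then pattern code) so results are
order-independent. The Monte-Carlo coverage comparison allows 3 standard
errors plus the estimator's resolution floor 1/(3^m · replicates). The
test suite and the acceptance script run the full-scale pipeline at 902
subjects × 100 genes with 499 screen permutations, 30 training epochs and
2 restarts per fold — sizes chosen to keep a complete run in the
single-digit minutes on one CPU; the null and recovery scenarios use 300
and 400 subjects with 25–30 genes, which is ample for their binomial
error bands.

## Known limitations

* The greedy screen is order-deterministic but not optimal; a pattern set
  with higher joint coverage can exist.
* Cramér's V between genes is attenuated for very high-diversity genes
  (many near-singleton categories) even with the bias correction.
* The network implements one hidden layer — the regime the update rules
  are stated for; deeper stacks are out of scope.
* GLM variance decomposition uses OLS on dummy-coded predictors;
  non-Gaussian outcome families are not implemented.
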