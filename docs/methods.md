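# Methods

This note documents the models behind `casdms`, the defaults of its
synthetic-data generator, the numerical choices, and what the verification
suite does and does not demonstrate about real data.

## 1. Survival-selection model for the bacterial screen

The screen couples nuclease activity to cell survival: an active variant
clears the toxin-encoding reporter plasmid, so its clones survive induction
and re-enter the next round. We model this with one survival weight `w >= 0`
per variant (`w = 1` is wild-type-equivalent). Each selection round applies
a deterministic expectation update

    f'(v) = f(v) * w(v) / sum_u f(u) * w(u)

so after `t` rounds a variant's odds have changed by `w^t` relative to a
neutral variant. Sequencing of a round is one multinomial draw of the
configured depth over that round's frequencies; replicates share the
deterministic trajectory and differ only in their sequencing draws. An
optional per-replicate bottleneck (multinomial resampling of the library to
a fixed number of cells between rounds, default off) adds
transformation-efficiency variance for robustness studies. We deliberately
do not model toxin kinetics, induction dynamics, plasmid copy number, or
PCR bias: the expectation-plus-sampling model is the simplest generative
process consistent with an iterative plating selection and is sufficient to
exercise every scoring code path.

Ground-truth weights are assigned **per amino-acid substitution**, not per
codon: every codon encoding the same missense change shares one `w`, so
amino-acid-level aggregation has a single well-defined truth. Synonymous
variants are forced to `w = 1` and nonsense variants to `w = 0` (a truncated
nuclease cannot clear the toxin plasmid). Default class composition among
missense substitutions: 10% beneficial (`w = 2`), 15% deleterious
(`w = 0.5`), 5% inactive (`w = 0`), remainder neutral; `effect_scale` sets
the beneficial weight and the reciprocal deleterious weight.

Default study scale: a 300-codon random reference (a desk-scale stand-in
for the 1228-residue nuclease), all ~9.4k NNK single-codon variants, four
selection rounds with rounds 3 and 4 sequenced at depth 1e6, three
replicates. A full simulate-and-score cycle takes about one second.

## 2. Enrichment (phenotype) scores

The phenotype score is the natural log of relative enrichment between the
two sequenced rounds (round 3 -> round 4 by default; the round pair is
configurable, including round 0 -> round 4):

    s_r(v) = ln[ ((c_post + a)/(N_post + aV)) / ((c_pre + a)/(N_pre + aV)) ]

with pseudocount `a = 0.5` over `V` library rows. Choices that matter:

- **Count filter.** A variant passes in a replicate iff its summed counts
  over that replicate's sequenced rounds are >= 50 (inclusive); it is
  scored globally only when it passes in every replicate. The filter is
  applied per replicate-sum because that is the only reading under which a
  single "minimum 50 counts" rule is well defined for multi-sample data.
- **Synonymous centering.** Each replicate's scores are centered on the
  median raw score of its passing synonymous variants. This *makes* the
  synonymous cluster sit at 0 by construction — it is a normalization
  choice, not an empirical finding — and removes library-composition drift
  (centering is invariant to adding any constant to a replicate's scores).
  With fewer than 10 passing synonymous anchors the replicate is left
  uncentered and flagged.
- **Positivity.** A variant is a positive hit iff it passes the filter and
  its centered score is strictly > 0 in *all* replicates. The mean centered
  score is reported regardless.
- **Resolution.** Scoring is at amino-acid level by default (missense and
  nonsense counts summed over synonymous codon encodings); codon-level
  scoring is available by flag. Synonymous rows always stay at codon
  resolution.

### What score recovery can and cannot show

On the default synthetic screen the mean centered score tracks `ln w`
almost perfectly in value (Pearson r ≈ 0.93 over active passing variants)
and the w=2 and w=1 classes separate by many standard errors. Two
structural effects dominate rank-based summaries, and both are properties
of the study design rather than of the estimator:

1. **Deleterious dropout.** With a uniform initial library over ~9.4k rows
   at depth 1e6, a `w = 0.5` variant has expected round-3 + round-4 counts
   of ~20–30, below the 50-count filter, so the deleterious class is
   largely absent from the passing set. This mirrors the real screen's data
   dropout at strongly deleterious positions.
2. **Rank ties.** With ground truth taking a handful of discrete values,
   the Spearman correlation between `ln w` and any score is bounded by
   sqrt(Var(E[rank | class]) / Var(rank)) — about 0.77 for class
   proportions 15/70/10 even with perfect class separation, and about 0.57
   once the deleterious class has dropped out. The measured Spearman
   (~0.55) sits essentially at this ceiling; the Pearson correlation, which
   ties do not bound, is the informative recovery summary for discrete
   truths.

The generator does not emulate epistasis, fitness-dependent growth-rate
differences within a round, PCR jackpots, or index hopping; passing tests
therefore validate the estimator's arithmetic, calibration and ranking
behaviour, not robustness to those artifacts.

## 3. Spec-seq / SEAM-seq specificity models

The target window is modelled as a position x base penalty matrix
`eps[i][b]` in kT units, zero at the target base, additive over mismatches:
`ddG(s) = sum_i eps[i][s_i]`. Positions are numbered 1-based from the
PAM-proximal end so statements about the seed-proximal ~18 bp are directly
addressable. The generator draws penalties uniformly from 0.25–3.0 kT over
positions 1–18 and 0.0–0.5 kT beyond, reflecting the empirical pattern that
the PAM-proximal core mediates most specificity.

- **Binding (Spec-seq).** Occupancy follows a logistic (Fermi) function
  `p_b = 1/(1 + exp(ddG - mu))` with chemical potential `mu` (default 0);
  bound/unbound fractions are multinomial over `f * p_b` and
  `f * (1 - p_b)`. The estimator
  `ddG_hat(s) = -ln[(b_s/u_s)/(b_ref/u_ref)]` inverts this link exactly
  (the bound:unbound odds are `exp(-(ddG - mu))`, and referencing to the
  perfect match cancels `mu`), so the noiseless round trip is exact by
  construction and the logistic saturation never biases the score.
- **Cleavage (SEAM-seq).** Survival of the digestion is
  `exp(-k * exp(-ddG))` with `k = cleavage_rate_scale`; the depletion score
  `d(s) = ln[(m_s/M)/(c_s/C)]` referenced to the perfect match equals
  `k_ref - k_s = k(1 - exp(-ddG))`, which is *not* additive in `eps`.
  Fitting the additive model to `d` is therefore a first-order
  approximation (exact in the `k -> 0` limit and for weak penalties); the
  binding assay carries the exact round-trip guarantee, and the cleavage
  model is interpreted as an effective mismatch-sensitivity profile.
- **Regression.** Weighted linear least squares on the mismatch indicator
  design (3L free parameters), observation weights the harmonic mean of the
  two fraction counts (an inverse-variance proxy for a log ratio, since
  Var(ln(a/b)) ~ 1/a + 1/b). Parameters never observed are reported as
  missing (NaN), not zero; a rank-deficient design raises an error naming
  the unidentifiable entries. With the exhaustive <=2-mismatch library over
  a 24-nt window (2,557 sequences) at depth 1e6 per fraction, the fit
  recovers the generating penalties with MAE ~0.01–0.03 kT.
- **Logos.** Per-position Boltzmann weights `p[i][b] ∝ exp(-eps[i][b])`
  give a PWM (rows sum to 1); letter heights in the rendered logo follow
  information content (2 - entropy, bits). Both the PWM (MEME minimal
  format) and the energy matrix are exported, since a logo can sensibly
  display either probabilities or transformed energies.

## 4. Plant genotype classification

A diploid T0 plant's allele-frequency spectrum is classified with explicit
thresholds (no community standard exists; all are config keys):
depth >= 100 to call at all; WT if the wild-type fraction w >= 0.95;
biallelic-homozygous if one mutant allele >= 0.90 and w < 0.05;
biallelic-heterozygous if two distinct mutant alleles >= 0.35 and w < 0.05;
monoallelic if 0.35 <= w <= 0.65 with exactly one major mutant allele;
chimeric otherwise (the residual class: >= 3 substantial alleles or an
intermediate WT fraction). Classification is total and deterministic above
the depth cutoff. Per-target summaries use plants-with-calls as the
denominator: 12 plants of which 6 homozygous gives a 50.0% homozygous rate,
10 of 12 gives 83.3%.

The generator draws clean diploid mixtures per class (deletion alleles of
3–14 bp, mild frequency jitter) plus an optional low-frequency mosaic
allele at rate `chimeric_noise`. It does not emulate amplification bias
between alleles of different lengths or sequencing error in the allele
descriptors, so recovery rates near 100% on clean fixtures bound the
classifier's arithmetic, not its behaviour on noisy amplicon data. The
bundled read-level allele caller (global alignment, match +1 / mismatch -1 /
gap open -4 / extend -1, indels keyed within ±20 bp of the cut site) is
intentionally minimal; production data should enter through the AlleleTable
TSV contract from a dedicated amplicon caller.

## 5. Reproducibility and numerics

One seed drives everything: it is split into independent per-stage streams
via `numpy.random.SeedSequence.spawn`, so stages are reproducible in
isolation and in the full pipeline. All writers are deterministic (stable
row order, 6-significant-digit floats, provenance header with version and
config digest); identical config + seed give byte-identical TSVs. Count
filters use inclusive boundaries; positivity is strict (> 0); medians of
even-sized anchor sets are exact to floating-point rounding (< 1e-12).
Pseudocounts are 0.5 everywhere by default and guard all log ratios;
setting `alpha = 0` restores scale-invariant pure ratios for analytic work.

## 6. Known limitations

- The additive (no pairwise interaction) energy model is the key modelling
  assumption of the specificity module; real mismatch interactions are not
  captured, and the fit's RMSE is the diagnostic to watch.
- Enrichment scores are moment estimates without variance shrinkage across
  replicates; hits are called by sign consistency, not significance.
- The deleterious-class dropout under the 50-count filter (Section 2) means
  sub-neutral effect sizes are systematically censored at default depth.
- Genotype thresholds are plausible defaults, validated only against the
  generator's own class definitions and hand-built arithmetic panels.
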