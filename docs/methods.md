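# Methods

This note documents the statistical procedures birkit implements, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Repair-outcome decomposition

Colonies from the disome BIR assay are scored by two markers. The mapping is
deterministic: Ade⁺Leu⁺ → gene conversion (GC); Ade⁻ʳᵉᵈLeu⁻ → chromosome
loss (CL); Ade⁻ʷʰⁱᵗᵉLeu⁻ → the visible half-crossover class (HC-I);
Ade⁺Leu⁻ → a mixed pool of completed BIR, gross chromosomal rearrangements
(GCR), and the invisible half-crossover class (HC-II); any Ade⁻/Leu⁺
combination is tallied as *other*.

The pool is split in two steps:

1. **GCR correction.** The GCR fraction *f* is estimated from CHEF
   karyotyping of a sample of Ade⁺Leu⁻ clones as *k/n* with an exact
   Clopper–Pearson 95% CI. The exact interval was chosen over a normal
   approximation because the karyotyped samples are small (tens of lanes)
   and can have zero numerators. The GCR count *f·N* is carried as a real
   number; rounding happens only at display (half away from zero, so 10/23
   prints as 43% and 1/30 as 3%).
2. **HC-II imputation.** The HC-II count is set equal to the observed HC-I
   count. The justification is the segregation model below. BIR is the
   remainder *N − f·N − H*; a negative remainder (possible when the
   karyotyped sample over-represents rearrangements) is floored at zero and
   the deficit recorded in a flag, so count conservation is always auditable.

Frequencies are reported over the total of all scored colonies, including
the *other* class; the denominator used is stored in the result.

Strain comparisons use the chi-square test of homogeneity without continuity
correction for multi-class tables and Fisher's exact test (two-sided) for
2×2 tables; the result records which method ran. Classes empty in both
conditions are dropped before testing.

## Half-crossover segregation model

A half-crossover fuses the broken recipient chromosome to part of the donor.
The model is phenotype-level: the four chromatids present at the next
mitosis are represented only through the two daughter configurations of the
fusion product — with an intact donor chromatid (scores Ade⁺Leu⁻, HC-II,
indistinguishable from BIR) or without one (scores Ade⁻ʷʰⁱᵗᵉLeu⁻, HC-I).
Under random segregation the two configurations are equiprobable, so the
HC-II fraction is exactly 1/2 — this is the entire content of the
HC-II = HC-I imputation, and `enumerate_hc_segregation` returns it together
with the scenario table. The weight is exposed as a parameter
(`hc_type_ii_weight`, default 0.5) so the sensitivity of downstream counts
to non-random segregation can be explored.

The colony simulator draws one repair mechanism per plated cell from a
categorical distribution, flips the segregation coin for HC cells, and
assumes every colony-forming event yields a colony (per-class plating
efficiency 1 — not quantified in the assay and therefore not modelled). Only
one broken chromatid is repaired per cell; multi-repair cells are out of
scope.

## Mutagenesis rates

The reversion frequency of one culture is
`(lys_colonies × dilution_selective) / (viable_colonies × dilution_permissive)`
— revertants per viable cell assayed, invariant to proportional rescaling of
both dilutions. The net BIR-associated rate is the induced (7-h) frequency
minus the pre-induction (0-h) background; negative nets are reported with a
flag, never clamped, so simulation studies see an unbiased estimator.

**Point estimate.** The default across replicate cultures is the pooled
ratio of totals (total revertant events over total cells assayed). The
per-culture median was considered and is available (`method="median"`), but
it is quantised: with ~10⁷ cells per culture, a strain at ~1.4×10⁻⁷ per cell
expects ~1.4 revertants per culture, and a median of integer counts can only
land on multiples of 10⁻⁷ — a ~30% discretisation error that makes fold
comparisons against low-rate strains (the 27-fold regime) unrecoverable. The
pooled estimator is the standard frequency estimator for rare events and has
no such floor; the cost is sensitivity to jackpot cultures, which is why the
median remains available for high-count data. The estimator is a frequency
over a fixed induction window, not a Luria–Delbrück fluctuation estimator:
the assay measures accumulation over 7 hours against a 0-h background
rather than growth-dependent mutant accumulation.

**Uncertainty.** Percentile bootstrap over replicate cultures (default 2000
resamples, seeded), resampling the induced and background platings
independently. Measured coverage at the simulated study conditions
(20 cultures × 10⁷ cells, rate 4×10⁻⁶) is ~92% at nominal 95% — the usual
mild undercoverage of the percentile method at n = 20 (see the calibration
test). Fold-changes are ratios of net rates with a bootstrap CI over the
joint resamples; resamples with a non-positive denominator are dropped and
the CI is flagged if more than 10% are.

Strain comparisons of per-replicate frequencies use the two-sided
Mann–Whitney U test, exact for small tie-free samples and normal with tie
correction otherwise.

A convenience function converts a fold-reduction into the implied fraction
of events reaching the 16-kb reporter (1/fold, e.g. 27-fold → ~4%), under
the assumption that per-event mutagenicity is unchanged and only tract
length differs.

## ddPCR (AMBER) quantification

Each droplet is an independent Poisson partition: with mean template copies
per droplet λ, a droplet is positive with probability 1 − e^(−λ), so
λ̂ = −ln(1 − p̂) from the positive fraction p̂. The CI on p̂ is exact
binomial and is pushed through the monotone inversion; a channel with every
droplet positive is a hard error (saturation), not a number. Droplet volume
is not modelled — only target/reference ratios are reported, so copies per
droplet is the natural unit.

The target/*ACT1* ratio CI divides opposite per-channel bounds
(lower = λ_t,low/λ_r,high; upper = λ_t,high/λ_r,low). This is conservative
by construction; a delta-method alternative on log λ (Fisher-information
variance p/((1−p)n)) is available via `method="delta"` and is the one used
for width-scaling checks. Copy numbers divide each locus' ratio by that
locus' 0-h ratio; the 0-h point estimate is treated as a scale constant
(its noise is shared by the whole series), and values are deliberately not
clamped to the physical [1, 2] range so that noise stays visible and fits
stay unbiased.

The synthesis call is `copy_number >= 1.1`, inclusive, on the point estimate;
a stricter mode additionally requires the CI lower bound to clear the
threshold. At the nominal 20,000 droplets and reference λ = 1 the point
estimate has ~2% relative error, so the false-positive rate of the 1.1×
call at a true ratio of 1 is far below 5% (measured in the calibration
test).

Time courses are summarised by the Boltzmann sigmoid
`y(t) = base + (top − base)/(1 + exp((t_half − t)/tau))`, fitted by bounded
least squares (trust-region reflective). Initialisation: base = min(y),
top = max(y), t_half = time of the mid-range crossing, tau = 1 h; tau is
bounded to (0.01, 20] h. A fit needs ≥5 points spanning ≥4 h. Flat series
are flagged degenerate; decreasing series are fitted with top < base and
flagged rather than rejected. The per-locus maximum copy number over the
course is reported separately because nascent DNA in helicase-defective
strains can degrade before the 10-h endpoint, making the maximum exceed the
final value.

## ChIP-qPCR enrichment

Per replicate, `percent_input = input_dilution × E^(cq_input − cq_ip)` for
the target and its control locus, and enrichment is their ratio.
Amplification efficiency E is fixed at 2.0 (no standard-curve calibration is
part of the assay) but exposed as a parameter. Percent-input ratioing was
chosen over ΔΔCq because both IP and input signals are normalised by
control-locus primers; under E = 2 the two conventions agree up to a
constant that cancels in any strain comparison. Both the per-locus
percent-input values and the normalised enrichment are reported per
replicate, since either may be the axis of interest. Fold-differences are
ratios of means with a Welch (unequal-variance) two-sided t-test, requiring
≥3 replicates per strain.

## Spore analysis

For a `DNA2/dna2::URA3 ; PIF1-variant/pif1::KANMX` cross, the suppression
fraction is the G418-sensitive share of viable Ura⁺ spores, with a
Clopper–Pearson 95% CI. Exact binomial tests (two-sided p = doubled smaller
tail, capped at 1) cover the 1:1 Mendelian control among Ura⁻ spores and
the suppression nulls: fraction 0 (no suppression — degenerate, refuted by
any sensitive survivor and flagged as such) and fraction 0.5 (parity with
the pif1-null class, i.e. full suppression). The doubled-tail convention
coincides with the minimum-likelihood convention at p₀ = 0.5, the only null
the scored crosses use, and is label-symmetric there.

The two markers are treated as unlinked (recombination fraction 0.5); no
linkage between the loci is part of the model, and the fraction is exposed
as a parameter.

## Synthetic-data generators

All generators take a single integer seed, use an isolated `numpy`
Generator (no global state), and are byte-deterministic per seed. Noise
families follow the physics of each assay: Poisson for colony and droplet
counting, Gaussian for Cq values, exact 2:2 segregation with Bernoulli
viability for spores.

- **Plating** (`generate_plating`): 20 cultures of 10⁷ cells by default,
  matching the fold-recovery simulations; culture size varies with 2%
  relative SD; revertant counts are Poisson with mean rate × cells
  (background only at 0 h, background + true rate at 7 h); the selective
  plating is undiluted (so a 3.9×10⁻⁶ rate yields ~39 colonies per
  culture) and the permissive count is a Poisson 10⁻⁵ aliquot recorded in
  the dilution column. The default background frequency is 10⁻⁷ per cell,
  an S-phase reversion background about 40-fold below the induced wild-type
  rate. Jackpot expansion of pre-induction mutants is not modelled beyond
  this constant background term.
- **Droplets** (`generate_droplet_counts`, `generate_droplet_timecourse`):
  each channel draws positives as Binomial(n, 1 − e^(−λ)) with 20,000
  droplets and reference λ = 1 by default, plus a matched 0-h pair at
  ratio 1.
- **Cq** (`generate_cq`): the noiseless configuration realises the target
  enrichment exactly (target IP Cq lowered by log₂(enrichment)); Gaussian
  noise of 0.2 cycles (a typical qPCR replicate SD) is added to all four Cq
  values independently.
- **Spores** (`generate_spores`): tetrad mode draws 4 spores per meiosis
  with exact 2:2 segregation per marker; the second marker's arrangement is
  drawn per spore (recombinant with probability r) and rejection-sampled to
  the 2:2 constraint — exact at the unlinked default (uniform over the six
  arrangements, PD:NPD:T = 1:1:4) and at r = 0 (parental ditypes only), an
  interpolation in between. RSA mode pools spores with independent fair-coin
  markers. Each spore then survives with its genotype's viability.

What the generators do **not** emulate: clonal jackpots, per-class colony
viability differences, droplet volume variation or rain (partial-positive
droplets), qPCR efficiency drift between loci, linkage maps beyond a single
recombination fraction, and any time-dependence within the 7-h induction.
Passing recovery tests therefore demonstrates estimator correctness under
the stated sampling models, not robustness to these real-data artefacts.

## Numerical conventions

- Exact binomial CI: beta-quantile Clopper–Pearson, collapsing to 0/1 at the
  boundaries.
- Two-sided exact binomial p: doubled smaller tail, capped at 1.
- Percent display: round half away from zero.
- Sequence coordinates: 1-based, inclusive, with an anchor mapping
  sub-sequences into full-protein numbering; the consensus spacer X accepts
  all 20 residues; ambiguity codes are rejected, lower case is upper-cased
  with a warning.
- Simulation sizes in the test suite (seed counts, culture counts, droplet
  counts) are the assay's own scales: 20 cultures × 10⁷ cells, 20,000
  droplets, 35-tetrad crosses; medians over ≥20 independent seeds summarise
  stochastic recoveries, with 201 seeds for the fold-recovery run where the
  per-seed ratio has ~30% spread.

## Known limitations

- The GCR correction assumes the karyotyped clones are a simple random
  sample of the Ade⁺Leu⁻ pool; exclusion of ambiguous lanes is not modelled.
- The HC-II imputation transfers HC-I's sampling noise to HC-II and to BIR;
  no variance is added for the imputation itself.
- The ratio-CI conservative bounds over-cover by construction; use the delta
  method when calibrated widths matter.
- The bootstrap rate CI mildly undercovers at 20 replicates (~92% at
  nominal 95%).
- The NLS scanner is a binary consensus matcher; it neither scores importin
  affinity nor detects bipartite signals.
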