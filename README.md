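# birkit

Analysis toolkit for the biostatistics of yeast **break-induced replication
(BIR)** assays, built for genome-stability labs that score double-strand-break
(DSB) repair in the chromosome-III disome system and its companion assays. It
implements, as tested reusable code:

- **Repair-outcome decomposition** — classify colony marker phenotypes
  (Ade⁺Leu⁻, Ade⁺Leu⁺, Ade⁻ʳᵉᵈLeu⁻, Ade⁻ʷʰⁱᵗᵉLeu⁻) into repair classes, apply
  the CHEF-measured GCR correction to the Ade⁺Leu⁻ pool, and impute the
  invisible half-crossover class (HC-II = HC-I), with contingency tests
  between strains.
- **Chromatid-segregation model** — the two-scenario enumeration showing that
  random mitotic segregation sends exactly half of half-crossover products
  into the Ade⁺Leu⁻ class, plus a seeded colony-level simulator.
- **Mutagenesis rates** — BIR-associated Lys⁺ reversion frequencies from
  plating counts, pre-induction background subtraction, bootstrap CIs,
  fold-changes, Mann–Whitney tests.
- **ddPCR (AMBER) quantification** — Poisson correction of droplet counts
  (λ = −ln(1 − p)), target/*ACT1* ratios with 95% CIs, 0-hr-normalized copy
  numbers, the ≥1.1× synthesis call, per-locus maxima, and Boltzmann
  sigmoidal kinetics fits.
- **ChIP-qPCR enrichment** — percent-of-input with control-locus
  normalization, strain fold-differences, Welch t-tests.
- **Tetrad / random-spore analysis** — dna2Δ-lethality suppression fractions
  with exact (Clopper–Pearson) CIs and exact binomial tests.
- **NLS motif scanning** — the classical monopartite nuclear localization
  signal consensus K-(K/R)-X-(K/R) over anchored protein sequences, plus
  construct edits (core deletion, SV40 NLS fusion).
- **Synthetic-data generators** — seeded, byte-deterministic generators for
  every stage (multinomial colonies, Poisson revertants and droplets,
  Gaussian Cq noise, 2:2 meiotic segregation with genotype-dependent spore
  viability), so the entire pipeline is testable offline.

## The core model

The Ade⁺Leu⁻ colony pool conflates three repair outcomes: completed BIR,
gross chromosomal rearrangements (GCR), and the HC-II half-crossover class.
With an observed Ade⁺Leu⁻ count *N*, a GCR fraction *f* estimated by CHEF
karyotyping of *k*/*n* sampled clones, and an observed HC-I count *H*:

```
GCR = f · N        HC-II = H        BIR = N − f·N − H
```

The HC-II = HC-I imputation rests on the segregation enumeration implemented
in `birkit.segregation`: an HC fusion product co-segregates with an intact
donor chromatid in exactly half of mitoses, and only then scores Ade⁺Leu⁻.
Droplet digital PCR concentrations use the Poisson inversion
λ = −ln(1 − p̂) with exact binomial CIs on p̂; reversion rates are
revertants per viable cell with 0-hr background subtracted.

## Worked example

```python
from birkit import fixtures, outcomes

k, n = fixtures.get("chef_counts")["pif1_null"]          # (10, 23)
gcr = outcomes.estimate_gcr_fraction(k, n)
print(f"GCR fraction: {gcr.fraction:.4f} ({gcr.percent}%), "
      f"95% CI [{gcr.ci_low:.3f}, {gcr.ci_high:.3f}]")

counts = outcomes.PhenotypeCounts(
    n_ade_plus_leu_minus=120, n_ade_plus_leu_plus=9,
    n_ade_red_leu_minus=41, n_ade_white_leu_minus=14, label="pif1-null")
dec = outcomes.decompose_outcomes(counts, gcr)
for cls in ("bir", "gcr", "hc_ii"):
    print(f"  {cls:6s} count {dec.counts[cls]:7.2f}  "
          f"frequency {dec.frequencies[cls]:.3f}")
```

prints

```
GCR fraction: 0.4348 (43%), 95% CI [0.232, 0.655]
  bir    count   53.83  frequency 0.293
  gcr    count   52.17  frequency 0.284
  hc_ii  count   14.00  frequency 0.076
```

Of 120 Ade⁺Leu⁻ colonies, 43% (52.2) are attributed to rearrangements, 14
are imputed as HC-II (equal to the observed HC-I count), and the remaining
53.8 are completed BIR — 29.3% of all 184 scored repair events.

The same analyses are scriptable from a shell via the `birkit` CLI
(`birkit nls scan`, `birkit bir decompose|compare|simulate`, `birkit mut
rate|compare`, `birkit amber quantify|fit|maxcn`, `birkit chip
enrich|compare`, `birkit spores analyze`, `birkit synth ...`); every
subcommand reads and writes validated TSV.

## Layout

- `src/birkit/` — the library (`sequences`, `outcomes`, `segregation`,
  `mutagenesis`, `amber`, `chip`, `spores`, `synth`, `tables`, `fixtures`,
  `cli`).
- `docs/methods.md` — the statistical methods, model assumptions, parameter
  defaults, and known limitations.
- `tests/` — unit, property (hypothesis), and end-to-end acceptance tests.
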