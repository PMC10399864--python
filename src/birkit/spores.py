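"""Tetrad and random-spore analysis of dna2-null lethality suppression.

The cross sporulates a ``DNA2/dna2::URA3 ; PIF1-variant/pif1::KANMX`` diploid.
Marker semantics: Ura+ spores are dna2-null; G418-resistant spores carry
``pif1::KANMX`` (pif1-null); G418-sensitive spores carry the PIF1 variant
allele. The informative quantity is the fraction of viable Ura+ spores that
are G418-sensitive — dna2-null cells surviving *with* the PIF1 variant — a
direct readout of how completely the variant suppresses the requirement for
Dna2. Full suppression predicts parity with the dna2-null pif1-null class
(fraction 1/2); no suppression predicts zero.

Ura- (DNA2 wild-type) spores are the internal control: both G418 classes are
fully viable, so their 1:1 segregation checks marker scoring and assortment.

All tests are exact binomial (the printed counts are tens of spores); the
two-sided p-value doubles the smaller tail, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._stats import binom_test_doubled, clopper_pearson
from .errors import InputError
from .outcomes import TestResult

#: Spore genotype classes: (DNA2 status, PIF1 status).
GENOTYPES = (
    "DNA2_PIF1var",  # Ura- G418s
    "DNA2_pif1null",  # Ura- G418r
    "dna2null_PIF1var",  # Ura+ G418s
    "dna2null_pif1null",  # Ura+ G418r
)


@dataclass(frozen=True)
class SporeTable:
    """Viable-colony counts per marker class from one cross."""

    source: str  # "tetrad" or "rsa"
    ura_plus_g418s: int
    ura_plus_g418r: int
    ura_minus_g418s: int = 0
    ura_minus_g418r: int = 0
    n_tetrads: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.source not in ("tetrad", "rsa"):
            raise InputError(f"source must be 'tetrad' or 'rsa', got {self.source!r}")
        for name in ("ura_plus_g418s", "ura_plus_g418r", "ura_minus_g418s", "ura_minus_g418r"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.source == "tetrad":
            if self.n_tetrads is None or self.n_tetrads < 1:
                raise InputError("tetrad tables need n_tetrads >= 1")
            if self.total_viable > 4 * self.n_tetrads:
                raise InputError(
                    f"{self.total_viable} viable spores exceed 4 x {self.n_tetrads} tetrads"
                )

    @property
    def total_viable(self) -> int:
        return (
            self.ura_plus_g418s + self.ura_plus_g418r
            + self.ura_minus_g418s + self.ura_minus_g418r
        )


@dataclass(frozen=True)
class SuppressionModel:
    """Genotype -> spore-survival probability (the generator's ground truth)."""

    viability: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in GENOTYPES}
    )

    def __post_init__(self) -> None:
        unknown = set(self.viability) - set(GENOTYPES)
        if unknown:
            raise InputError(f"unknown genotypes: {sorted(unknown)}")
        for g in GENOTYPES:
            v = self.viability.get(g, 1.0)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"viability[{g}] must be in [0, 1], got {v}")

    def prob(self, genotype: str) -> float:
        return self.viability.get(genotype, 1.0)


@dataclass(frozen=True)
class FractionEstimate:
    fraction: float
    ci_low: float
    ci_high: float
    k: int
    n: int


def suppression_fraction(table: SporeTable) -> FractionEstimate:
    """G418-sensitive fraction among viable Ura+ (dna2-null) spores, with exact CI.

    E.g. the random-spore counts 8 sensitive / 34 resistant give 8/42 = 0.190.
    """
    n = table.ura_plus_g418s + table.ura_plus_g418r
    if n < 1:
        raise InputError("no viable Ura+ spores: suppression fraction undefined")
    k = table.ura_plus_g418s
    lo, hi = clopper_pearson(k, n)
    return FractionEstimate(fraction=k / n, ci_low=lo, ci_high=hi, k=k, n=n)


def mendelian_control_test(table: SporeTable) -> TestResult:
    """Exact binomial test of 1:1 G418 segregation among Ura- (DNA2) spores.

    Both Ura- classes are fully viable, so deviation from 1:1 indicates a
    scoring or assortment problem. Symmetric in the two marker labels.
    """
    n = table.ura_minus_g418s + table.ura_minus_g418r
    if n < 1:
        raise InputError("no Ura- spores scored")
    p = binom_test_doubled(table.ura_minus_g418s, n, 0.5)
    return TestResult(
        statistic=table.ura_minus_g418s / n, pvalue=p, method="exact_binomial_vs_0.5"
    )


def suppression_test(table: SporeTable, null_fraction: float = 0.0) -> TestResult:
    """Exact binomial test of the Ura+ G418-sensitive count against a null fraction.

    ``null_fraction=0`` is the no-suppression null (the variant-bearing
    dna2-null class is dead): any sensitive survivor refutes it outright and
    the result is flagged ``null_degenerate`` with p = 0.
    ``null_fraction=0.5`` is the full-suppression null (parity with the
    pif1-null class); the p-value is the doubled smaller binomial tail.
    """
    if not 0.0 <= null_fraction < 1.0:
        raise InputError("null_fraction must be in [0, 1)")
    n = table.ura_plus_g418s + table.ura_plus_g418r
    if n < 1:
        raise InputError("no viable Ura+ spores")
    k = table.ura_plus_g418s
    if null_fraction == 0.0:
        # Degenerate null: P(X >= k | p=0) is 1 for k=0, else exactly 0.
        p = 1.0 if k == 0 else 0.0
        flags = {"flags": ("null_degenerate",)} if k > 0 else {}
        return TestResult(
            statistic=k / n, pvalue=p, method="exact_binomial_vs_0", extra=flags
        )
    p = binom_test_doubled(k, n, null_fraction)
    return TestResult(
        statistic=k / n, pvalue=p, method=f"exact_binomial_vs_{null_fraction:g}"
    )
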