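"""Chromatid-segregation model for half-crossover products, and the colony simulator.

A half-crossover (HC) fuses the broken recipient chromosome to part of the
donor. At the next mitosis the cell carries three relevant chromatids — the
HC fusion product and the two sister chromatids of the intact donor — and the
fusion product co-segregates with an intact donor copy in half of all
divisions. The two equiprobable daughter configurations score differently:

* fusion product *without* an intact donor: Ade-white Leu- (HC-I, visible);
* fusion product *with* an intact donor: Ade+ Leu- (HC-II), genetically
  indistinguishable from completed BIR.

:func:`enumerate_hc_segregation` makes that argument executable (and yields
exactly 1/2 under the default equiprobable model), which is the premise of
the HC-II = HC-I imputation in :func:`birkit.outcomes.decompose_outcomes`.

:func:`simulate_colonies` is the colony-level synthetic-data generator: each
plated cell commits to one repair mechanism, HC cells flip the segregation
coin, and the resulting phenotype counts follow the marker logic above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .outcomes import PhenotypeCounts

#: Mechanism labels in simulation draw order. HC is split into HC_I / HC_II
#: in the per-colony truth record after the segregation coin flip.
MECHANISMS = ("bir", "gc", "hc", "cl", "gcr", "other")


@dataclass(frozen=True)
class SegregationParams:
    """Per-cell repair-mechanism probabilities plus the HC segregation weight.

    ``hc_type_ii_weight`` is the probability that an HC product segregates
    with an intact donor chromosome (default 0.5: random segregation of the
    two equiprobable daughter configurations).
    """

    p_bir: float
    p_gc: float
    p_hc: float
    p_cl: float
    p_gcr: float = 0.0
    p_other: float = 0.0
    hc_type_ii_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        probs = self.mechanism_probs()
        for name, p in zip(MECHANISMS, probs):
            if not 0.0 <= p <= 1.0:
                raise InputError(f"p_{name} must be in [0, 1], got {p}")
        if not math.isclose(sum(probs), 1.0, abs_tol=1e-12):
            raise InputError(f"mechanism probabilities sum to {sum(probs)!r}, not 1")
        if not 0.0 <= self.hc_type_ii_weight <= 1.0:
            raise InputError("hc_type_ii_weight must be in [0, 1]")

    def mechanism_probs(self) -> tuple[float, ...]:
        return (self.p_bir, self.p_gc, self.p_hc, self.p_cl, self.p_gcr, self.p_other)


@dataclass(frozen=True)
class SegregationScenario:
    """One daughter-cell configuration of the HC product at mitosis."""

    description: str
    has_intact_donor: bool
    probability: float
    phenotype: str  # colony phenotype of the daughter that kept the HC product
    scored_class: str  # "hc_ii" (pooled with BIR) or "hc_i" (visible)


def enumerate_hc_segregation(
    hc_type_ii_weight: float = 0.5,
) -> tuple[float, list[SegregationScenario]]:
    """Enumerate the two HC segregation scenarios and the HC-II fraction.

    Returns ``(fraction_hc_ii, scenarios)`` where ``fraction_hc_ii`` is the
    probability that an HC product is scored Ade+ Leu- (HC-II). With the
    default weight the enumeration gives exactly 1/2 — the analytic basis for
    imputing the invisible HC-II count as equal to the observed HC-I count.
    """
    w = float(hc_type_ii_weight)
    if not 0.0 <= w <= 1.0:
        raise InputError("hc_type_ii_weight must be in [0, 1]")
    scenarios = [
        SegregationScenario(
            description="HC fusion product co-segregates with an intact donor chromatid",
            has_intact_donor=True,
            probability=w,
            phenotype="Ade+ Leu-",
            scored_class="hc_ii",
        ),
        SegregationScenario(
            description="HC fusion product segregates away from both intact donor chromatids",
            has_intact_donor=False,
            probability=1.0 - w,
            phenotype="Ade-white Leu-",
            scored_class="hc_i",
        ),
    ]
    fraction_hc_ii = sum(s.probability for s in scenarios if s.scored_class == "hc_ii")
    return fraction_hc_ii, scenarios


def expected_phenotype_probs(params: SegregationParams) -> dict[str, float]:
    """Analytic phenotype-class probabilities implied by the mechanism mix."""
    w = params.hc_type_ii_weight
    return {
        "ade_plus_leu_minus": params.p_bir + params.p_gcr + params.p_hc * w,
        "gc": params.p_gc,
        "cl": params.p_cl,
        "hc_i": params.p_hc * (1.0 - w),
        "other": params.p_other,
    }


def simulate_colonies(
    params: SegregationParams, n: int, seed: int | None = None
) -> tuple[PhenotypeCounts, np.ndarray]:
    """Draw ``n`` colonies and score them by the marker logic.

    Each colony commits to one mechanism from the categorical distribution in
    ``params``; HC colonies then segregate as HC-II with probability
    ``hc_type_ii_weight``. Returns the phenotype counts plus the hidden truth
    record: an array of per-colony mechanism labels (``bir``, ``gc``,
    ``hc_i``, ``hc_ii``, ``cl``, ``gcr``, ``other``) that the phenotype
    counts deliberately confound.

    Identical ``(params, n, seed)`` give bitwise-identical output; ``seed``
    defaults to ``params.seed``.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    mech_idx = rng.choice(len(MECHANISMS), size=n, p=params.mechanism_probs())
    labels = np.array(MECHANISMS, dtype=object)[mech_idx]

    is_hc = labels == "hc"
    n_hc = int(is_hc.sum())
    if n_hc:
        flips = rng.random(n_hc) < params.hc_type_ii_weight
        labels[is_hc] = np.where(flips, "hc_ii", "hc_i")

    counts = {lab: int((labels == lab).sum()) for lab in
              ("bir", "gc", "hc_i", "hc_ii", "cl", "gcr", "other")}
    phen = PhenotypeCounts(
        n_ade_plus_leu_minus=counts["bir"] + counts["gcr"] + counts["hc_ii"],
        n_ade_plus_leu_plus=counts["gc"],
        n_ade_red_leu_minus=counts["cl"],
        n_ade_white_leu_minus=counts["hc_i"],
        n_other=counts["other"],
        label="simulated",
    )
    return phen, labels
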