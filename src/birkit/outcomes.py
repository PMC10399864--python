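"""Classification and decomposition of DSB-repair outcomes from colony markers.

The disome assay distinguishes repair pathways by two colony markers:

* ``Ade+ Leu-`` — completed break-induced replication (BIR), but also gross
  chromosomal rearrangements (GCR) and one half-crossover class (HC-II);
* ``Ade+ Leu+`` — gene conversion (GC);
* ``Ade-red Leu-`` — chromosome loss (CL);
* ``Ade-white Leu-`` — the visible half-crossover class (HC-I).

Because the ``Ade+ Leu-`` pool is heterogeneous, the BIR count is obtained by
two corrections: (i) the GCR fraction, measured by CHEF karyotyping of a
sample of ``Ade+ Leu-`` clones, is applied to the whole pool; (ii) the
invisible HC-II class is imputed as equal in number to the observed HC-I
class, because random mitotic segregation sends half of all half-crossover
products to a daughter that also carries an intact donor chromosome (see
:mod:`birkit.segregation` for the enumeration that justifies this).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import clopper_pearson
from .errors import InputError


class RepairClass(str, enum.Enum):
    """Phenotype-level repair classes (ADE_PLUS_LEU_MINUS is a mixed pool)."""

    ADE_PLUS_LEU_MINUS = "ade_plus_leu_minus"  # BIR + GCR + HC-II, indistinguishable
    GC = "gc"
    CL = "cl"
    HC_I = "hc_i"
    OTHER = "other"


_ADE_TOKENS = ("plus", "minus_red", "minus_white")
_LEU_TOKENS = ("plus", "minus")


def classify_colony(ade: str, leu: str) -> RepairClass:
    """Map an (Ade, Leu) phenotype pair to its repair class.

    ``ade`` is one of ``plus``, ``minus_red``, ``minus_white``; ``leu`` is
    ``plus`` or ``minus``. Any Ade- / Leu+ combination is OTHER.
    """
    if ade not in _ADE_TOKENS:
        raise InputError(f"unknown ade phenotype {ade!r}; expected one of {_ADE_TOKENS}")
    if leu not in _LEU_TOKENS:
        raise InputError(f"unknown leu phenotype {leu!r}; expected one of {_LEU_TOKENS}")
    if ade == "plus":
        return RepairClass.GC if leu == "plus" else RepairClass.ADE_PLUS_LEU_MINUS
    if leu == "plus":
        return RepairClass.OTHER
    return RepairClass.CL if ade == "minus_red" else RepairClass.HC_I


@dataclass(frozen=True)
class PhenotypeCounts:
    """Colony counts per marker class for one strain/condition."""

    n_ade_plus_leu_minus: int
    n_ade_plus_leu_plus: int
    n_ade_red_leu_minus: int
    n_ade_white_leu_minus: int
    n_other: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        for name in (
            "n_ade_plus_leu_minus",
            "n_ade_plus_leu_plus",
            "n_ade_red_leu_minus",
            "n_ade_white_leu_minus",
            "n_other",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return (
            self.n_ade_plus_leu_minus
            + self.n_ade_plus_leu_plus
            + self.n_ade_red_leu_minus
            + self.n_ade_white_leu_minus
            + self.n_other
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "ade_plus_leu_minus": self.n_ade_plus_leu_minus,
            "gc": self.n_ade_plus_leu_plus,
            "cl": self.n_ade_red_leu_minus,
            "hc_i": self.n_ade_white_leu_minus,
            "other": self.n_other,
        }

    @classmethod
    def from_table(cls, df: pd.DataFrame, label: str = "") -> "PhenotypeCounts":
        """Aggregate a colony table (columns ade_phenotype, leu_phenotype, count)."""
        tallies = dict.fromkeys(RepairClass, 0)
        for ade, leu, n in zip(df["ade_phenotype"], df["leu_phenotype"], df["count"]):
            tallies[classify_colony(str(ade), str(leu))] += int(n)
        return cls(
            n_ade_plus_leu_minus=tallies[RepairClass.ADE_PLUS_LEU_MINUS],
            n_ade_plus_leu_plus=tallies[RepairClass.GC],
            n_ade_red_leu_minus=tallies[RepairClass.CL],
            n_ade_white_leu_minus=tallies[RepairClass.HC_I],
            n_other=tallies[RepairClass.OTHER],
            label=label,
        )


@dataclass(frozen=True)
class GcrEstimate:
    """Fraction of CHEF-karyotyped Ade+ Leu- clones showing a rearrangement."""

    n_rearranged: int
    n_tested: int
    fraction: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> int:
        """Fraction as a whole percent, rounding half away from zero."""
        return int(math.floor(self.fraction * 100 + 0.5))


def estimate_gcr_fraction(n_rearranged: int, n_tested: int) -> GcrEstimate:
    """GCR fraction among tested Ade+ Leu- clones with exact 95% CI.

    Uses the Clopper-Pearson interval, which keeps nominal coverage at the
    small sample sizes typical of CHEF karyotyping (tens of lanes).
    """
    if n_tested < 1:
        raise InputError("n_tested must be >= 1")
    if not 0 <= n_rearranged <= n_tested:
        raise InputError("need 0 <= n_rearranged <= n_tested")
    lo, hi = clopper_pearson(n_rearranged, n_tested)
    return GcrEstimate(
        n_rearranged=n_rearranged,
        n_tested=n_tested,
        fraction=n_rearranged / n_tested,
        ci_low=lo,
        ci_high=hi,
    )


#: Order of classes in a decomposition report.
DECOMPOSED_CLASSES = ("gc", "cl", "hc_i", "hc_ii", "gcr", "bir", "other")


@dataclass(frozen=True)
class OutcomeDecomposition:
    """Per-class counts and frequencies after GCR correction and HC-II imputation.

    ``counts['gcr']`` and ``counts['bir']`` are real-valued: the GCR fraction
    is applied to the Ade+ Leu- count without rounding, and the BIR count is
    what remains. ``denominator`` is the total number of scored colonies
    (all five marker classes, including ``other``).
    """

    counts: dict[str, float]
    frequencies: dict[str, float]
    denominator: int
    flags: tuple[str, ...] = ()
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(DECOMPOSED_CLASSES),
                "count": [self.counts[c] for c in DECOMPOSED_CLASSES],
                "frequency": [self.frequencies[c] for c in DECOMPOSED_CLASSES],
            }
        )


def decompose_outcomes(
    counts: PhenotypeCounts, gcr: GcrEstimate | float
) -> OutcomeDecomposition:
    """Split the Ade+ Leu- pool into BIR, GCR, and HC-II components.

    The GCR count is ``gcr_fraction x n_ade_plus_leu_minus`` (kept as a real
    number); HC-II is imputed equal to the observed HC-I count; BIR is the
    remainder. A remainder below zero is floored at 0 and flagged
    ``bir_floored`` — the exact deficit is recorded in the flag so that
    count conservation can always be audited.
    """
    frac = gcr.fraction if isinstance(gcr, GcrEstimate) else float(gcr)
    if not 0.0 <= frac <= 1.0:
        raise InputError(f"GCR fraction must be in [0, 1], got {frac}")

    pool = counts.n_ade_plus_leu_minus
    gcr_count = frac * pool
    hc_ii = counts.n_ade_white_leu_minus  # imputed: HC-II = HC-I
    bir = pool - gcr_count - hc_ii
    flags: list[str] = []
    if bir < 0:
        flags.append(f"bir_floored:deficit={-bir:.6g}")
        bir = 0.0

    out_counts = {
        "gc": float(counts.n_ade_plus_leu_plus),
        "cl": float(counts.n_ade_red_leu_minus),
        "hc_i": float(counts.n_ade_white_leu_minus),
        "hc_ii": float(hc_ii),
        "gcr": float(gcr_count),
        "bir": float(bir),
        "other": float(counts.n_other),
    }
    denom = counts.total
    if denom == 0:
        raise InputError("cannot decompose an all-zero phenotype table")
    freqs = {k: v / denom for k, v in out_counts.items()}
    return OutcomeDecomposition(
        counts=out_counts,
        frequencies=freqs,
        denominator=denom,
        flags=tuple(flags),
        label=counts.label,
    )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str
    extra: dict = field(default_factory=dict)


def _to_class_vector(x) -> np.ndarray:
    if isinstance(x, PhenotypeCounts):
        return np.array(
            [
                x.n_ade_plus_leu_minus,
                x.n_ade_plus_leu_plus,
                x.n_ade_red_leu_minus,
                x.n_ade_white_leu_minus,
                x.n_other,
            ]
        )
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError("expected a 1-D vector of class counts per condition")
    return arr


def compare_distributions(a, b) -> TestResult:
    """Contingency test between two outcome distributions.

    Two conditions with k > 2 classes are compared by the chi-square test of
    homogeneity (no continuity correction); 2-class tables use Fisher's exact
    test (two-sided). Classes with zero counts in both conditions are dropped
    before testing.
    """
    va, vb = _to_class_vector(a), _to_class_vector(b)
    if va.shape != vb.shape:
        raise InputError("the two conditions must share the same class set")
    keep = (va + vb) > 0
    va, vb = va[keep], vb[keep]
    if va.sum() < 1 or vb.sum() < 1:
        raise InputError("each condition needs at least one observed colony")
    if len(va) < 2:
        raise InputError("need at least two non-empty classes to compare")
    table = np.vstack([va, vb])
    if len(va) == 2:
        res = stats.fisher_exact(table, alternative="two-sided")
        return TestResult(
            statistic=float(res[0]), pvalue=float(res[1]), method="fisher_exact"
        )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(
        statistic=float(chi2),
        pvalue=float(p),
        method="chi_square_homogeneity",
        extra={"dof": int(dof)},
    )
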