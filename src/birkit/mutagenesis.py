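"""BIR-associated mutagenesis: reversion frequencies, net rates, fold-changes.

The assay scores Lys- to Lys+ reversion of a frameshift reporter placed 16 kb
downstream of the break on the donor chromosome: only repair tracts that copy
at least 16 kb can revert it, so the reversion frequency reads out both the
mutagenicity and the reach of break-induced replication. Cells are plated on
selective (Sc-Ade,Lys) and permissive (Sc-Ade) media before galactose
addition (0 h, background S-phase mutagenesis) and 7 h after the
galactose-induced break; the BIR-associated rate is the 7-h frequency minus
the 0-h background.

Estimator
---------
Per replicate culture, the frequency is::

    f = (lys_colonies x dilution_selective) / (viable_colonies x dilution_permissive)

i.e. revertants per viable cell assayed. Across replicates the default point
estimate is the pooled ratio of totals (total revertant events over total
cells assayed), the standard frequency estimator for rare events: at low
rates the expected revertant count per culture is of order one, and any
per-culture statistic is quantised to multiples of 1/(cells per culture),
which a ratio of totals avoids. ``method="median"`` (the per-culture median,
more resistant to jackpot cultures) is available where counts are large.
Confidence intervals come from a seeded percentile bootstrap over replicate
cultures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError
from .outcomes import TestResult


@dataclass(frozen=True)
class Replicate:
    """One culture's plating counts and dilution factors."""

    lys_colonies: int
    viable_colonies: int
    dilution_selective: float = 1.0
    dilution_permissive: float = 1.0

    def __post_init__(self) -> None:
        if self.lys_colonies < 0 or self.viable_colonies < 0:
            raise InputError("colony counts must be >= 0")
        if self.dilution_selective < 1 or self.dilution_permissive < 1:
            raise InputError("dilution factors must be >= 1")


@dataclass(frozen=True)
class PlatingExperiment:
    strain: str
    timepoint_hr: float
    replicates: tuple[Replicate, ...]

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise InputError("need at least one replicate culture")
        object.__setattr__(self, "replicates", tuple(self.replicates))

    def frequencies(self) -> np.ndarray:
        return np.array([reversion_frequency(r) for r in self.replicates])


def reversion_frequency(rep: Replicate) -> float:
    """Per-cell Lys+ reversion frequency of a single culture.

    Scale-invariant under proportional rescaling of both dilution factors.
    """
    cells = rep.viable_colonies * rep.dilution_permissive
    if cells <= 0:
        raise InputError("scaled viable-cell count is zero; frequency undefined")
    return (rep.lys_colonies * rep.dilution_selective) / cells


def _point_estimate(reps: tuple[Replicate, ...], method: str) -> float:
    if method == "pooled":
        events = sum(r.lys_colonies * r.dilution_selective for r in reps)
        cells = sum(r.viable_colonies * r.dilution_permissive for r in reps)
        if cells <= 0:
            raise InputError("total scaled viable-cell count is zero")
        return events / cells
    if method == "median":
        return float(np.median([reversion_frequency(r) for r in reps]))
    raise InputError(f"unknown estimator method {method!r}")


@dataclass(frozen=True)
class RateEstimate:
    """Net BIR-associated reversion rate for one strain."""

    strain: str
    frequency_per_cell: float  # induced (7 h) frequency
    background_frequency: float  # pre-induction (0 h) frequency
    net_rate: float  # frequency - background; may be negative (flagged)
    ci_low: float
    ci_high: float
    n_replicates: int
    method: str = "pooled"
    flags: tuple[str, ...] = ()
    # raw per-replicate data retained so fold_change can bootstrap the ratio
    replicates_induced: tuple[Replicate, ...] = field(default=(), repr=False)
    replicates_background: tuple[Replicate, ...] = field(default=(), repr=False)


def _bootstrap_nets(
    induced: tuple[Replicate, ...],
    background: tuple[Replicate, ...],
    method: str,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resample cultures (independently per timepoint) and recompute net rates."""
    idx7 = rng.integers(0, len(induced), size=(n_boot, len(induced)))
    idx0 = rng.integers(0, len(background), size=(n_boot, len(background)))
    nets = np.empty(n_boot)
    for b in range(n_boot):
        f7 = _point_estimate(tuple(induced[i] for i in idx7[b]), method)
        f0 = _point_estimate(tuple(background[i] for i in idx0[b]), method)
        nets[b] = f7 - f0
    return nets


def estimate_rate(
    exp_induced: PlatingExperiment,
    exp_background: PlatingExperiment,
    method: str = "pooled",
    n_boot: int = 2000,
    seed: int = 0,
) -> RateEstimate:
    """Background-corrected reversion rate with a percentile-bootstrap 95% CI.

    ``exp_induced`` and ``exp_background`` are the 7-h and 0-h platings of
    the same strain. A negative net rate is reported as-is and flagged
    ``negative_net`` rather than clamped, so that the estimator stays
    unbiased in simulation studies.
    """
    if exp_induced.strain != exp_background.strain:
        raise InputError(
            f"strain mismatch: {exp_induced.strain!r} vs {exp_background.strain!r}"
        )
    f7 = _point_estimate(exp_induced.replicates, method)
    f0 = _point_estimate(exp_background.replicates, method)
    net = f7 - f0
    rng = np.random.default_rng(seed)
    nets = _bootstrap_nets(
        exp_induced.replicates, exp_background.replicates, method, n_boot, rng
    )
    lo, hi = np.percentile(nets, [2.5, 97.5])
    flags = ("negative_net",) if net < 0 else ()
    return RateEstimate(
        strain=exp_induced.strain,
        frequency_per_cell=f7,
        background_frequency=f0,
        net_rate=net,
        ci_low=float(lo),
        ci_high=float(hi),
        n_replicates=len(exp_induced.replicates),
        method=method,
        flags=flags,
        replicates_induced=exp_induced.replicates,
        replicates_background=exp_background.replicates,
    )


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    ci_low: float
    ci_high: float
    flags: tuple[str, ...] = ()


def fold_change(
    a: RateEstimate, b: RateEstimate, n_boot: int = 2000, seed: int = 0
) -> FoldChange:
    """Ratio of net rates ``a / b`` with a bootstrap 95% CI.

    Both strains' cultures are resampled within the same bootstrap pass and
    the ratio of net rates recomputed per resample. Resamples in which the
    denominator's net rate is not positive are dropped from the percentile
    CI; if more than 10% are dropped the CI is flagged unstable.
    """
    if b.net_rate <= 0:
        raise InputError("denominator net rate must be > 0 for a fold-change")
    ratio = a.net_rate / b.net_rate
    if not (a.replicates_induced and b.replicates_induced):
        return FoldChange(ratio=ratio, ci_low=np.nan, ci_high=np.nan,
                          flags=("no_replicate_data",))
    rng = np.random.default_rng(seed)
    nets_a = _bootstrap_nets(
        a.replicates_induced, a.replicates_background, a.method, n_boot, rng
    )
    nets_b = _bootstrap_nets(
        b.replicates_induced, b.replicates_background, b.method, n_boot, rng
    )
    ok = nets_b > 0
    flags: tuple[str, ...] = ()
    if ok.mean() < 0.9:
        flags = ("unstable_ci",)
    if not ok.any():
        return FoldChange(ratio=ratio, ci_low=np.nan, ci_high=np.nan, flags=flags)
    lo, hi = np.percentile(nets_a[ok] / nets_b[ok], [2.5, 97.5])
    return FoldChange(ratio=ratio, ci_low=float(lo), ci_high=float(hi), flags=flags)


def reporter_reach_fraction(fold_reduction: float) -> float:
    """Fraction of events reaching the 16-kb reporter implied by a fold-reduction.

    If a mutant's net reversion rate is ``fold_reduction`` times lower than
    wild type's and per-event mutagenicity is unchanged, the mutant completes
    the 16-kb tract in ``1/fold_reduction`` of events relative to wild type
    (e.g. a 27-fold reduction implies ~4% of events reach the reporter).
    """
    if fold_reduction <= 0:
        raise InputError("fold_reduction must be > 0")
    return 1.0 / fold_reduction


def compare_rates(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test between two sets of replicate frequencies.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise (scipy's ``method="auto"`` policy). Each
    group needs at least 3 replicates.
    """
    fa = np.asarray(a, dtype=float)
    fb = np.asarray(b, dtype=float)
    if fa.size < 3 or fb.size < 3:
        raise InputError("need at least 3 replicate frequencies per group")
    res = stats.mannwhitneyu(fa, fb, alternative="two-sided", method="auto")
    return TestResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), method="mann_whitney_u"
    )
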