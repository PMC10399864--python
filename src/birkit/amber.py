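"""AMBER ddPCR quantification of BIR-associated DNA synthesis.

Droplet digital PCR partitions a genomic DNA sample into ~20,000 droplets and
scores each droplet positive or negative for a primer set. Under Poisson
partitioning the mean template copies per droplet is recovered from the
positive fraction p as ``lambda = -ln(1 - p)``. Donor-locus concentrations at
positions downstream of the DSB (P2 at 1.9 kb, P3 at 22.4 kb, P4 at 61.4 kb)
are normalized to a reference locus (*ACT1*) and then to the pre-induction
(0 h) target/reference ratio, giving a copy number that starts at 1x and can
rise to at most 2x as BIR duplicates the donor. An increase of at least 1.1x
is called evidence of synthesis.

Confidence intervals: the positive fraction gets an exact binomial
(Clopper-Pearson) 95% CI, transformed through the monotone Poisson map to a
CI on lambda. The target/reference ratio CI divides opposite bounds
(conservative; guaranteed to contain the per-channel-CI-consistent ratios); a
delta-method alternative on log lambda is available via ``method="delta"``.

Copy-number time courses are summarized by a Boltzmann sigmoid
``y(t) = base + (top - base) / (1 + exp((t_half - t) / tau))`` and by the
maximum copy number reached over the time course — the latter matters for
helicase-defective strains in which nascent DNA turns over before 10 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._stats import clopper_pearson
from .errors import InputError, SaturatedChannelError

#: Copy-number increase called as evidence of DNA synthesis ("at least 1.1x").
SYNTHESIS_THRESHOLD = 1.1

#: Nominal droplet count per ddPCR reaction.
NOMINAL_DROPLETS = 20_000


@dataclass(frozen=True)
class DropletChannel:
    """One locus' droplet counts with its Poisson concentration estimate."""

    locus: str
    n_total: int
    n_positive: int
    lam: float
    ci_low: float
    ci_high: float


def lambda_from_droplets(
    n_positive: int, n_total: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Poisson-corrected copies-per-droplet with exact 95% CI.

    Returns ``(lambda, ci_low, ci_high)``. Raises
    :class:`~birkit.errors.SaturatedChannelError` when every droplet is
    positive, since the Poisson inversion diverges there.
    """
    if n_total < 1:
        raise InputError("n_total must be >= 1")
    if not 0 <= n_positive <= n_total:
        raise InputError("need 0 <= n_positive <= n_total")
    if n_positive == n_total:
        raise SaturatedChannelError(
            f"all {n_total} droplets positive: concentration unquantifiable"
        )
    p_hat = n_positive / n_total
    p_lo, p_hi = clopper_pearson(n_positive, n_total, alpha)
    lam = -math.log1p(-p_hat)
    lo = -math.log1p(-p_lo)
    hi = -math.log1p(-p_hi) if p_hi < 1.0 else math.inf
    return lam, lo, hi


def channel_from_counts(locus: str, n_positive: int, n_total: int) -> DropletChannel:
    lam, lo, hi = lambda_from_droplets(n_positive, n_total)
    return DropletChannel(
        locus=locus, n_total=n_total, n_positive=n_positive,
        lam=lam, ci_low=lo, ci_high=hi,
    )


@dataclass(frozen=True)
class RatioEstimate:
    """Target/reference concentration ratio with 95% CI."""

    ratio: float
    ci_low: float
    ci_high: float
    method: str = "conservative"


def ratio_with_ci(
    target: DropletChannel, reference: DropletChannel, method: str = "conservative"
) -> RatioEstimate:
    """Target lambda over reference lambda with a 95% CI.

    ``method="conservative"`` divides opposite per-channel CI bounds
    (lower = target_low / reference_high, upper = target_high / reference_low).
    ``method="delta"`` propagates the Fisher-information variance of lambda,
    ``var(lambda) = p / ((1 - p) n)``, on the log scale.
    """
    if reference.lam <= 0:
        raise InputError(f"reference channel {reference.locus!r} has lambda = 0")
    ratio = target.lam / reference.lam
    if method == "conservative":
        lo = target.ci_low / reference.ci_high
        hi = target.ci_high / reference.ci_low if reference.ci_low > 0 else math.inf
        return RatioEstimate(ratio=ratio, ci_low=lo, ci_high=hi, method=method)
    if method == "delta":
        if target.lam <= 0:
            return RatioEstimate(ratio=0.0, ci_low=0.0,
                                 ci_high=target.ci_high / reference.lam, method=method)
        var_log = 0.0
        for ch in (target, reference):
            p = ch.n_positive / ch.n_total
            var_log += p / ((1.0 - p) * ch.n_total) / ch.lam**2
        half = 1.959963984540054 * math.sqrt(var_log)
        return RatioEstimate(
            ratio=ratio,
            ci_low=ratio * math.exp(-half),
            ci_high=ratio * math.exp(half),
            method=method,
        )
    raise InputError(f"unknown CI method {method!r}")


@dataclass(frozen=True)
class DdpcrTimepoint:
    """One locus/time sample: ratio plus 0-h-normalized copy number."""

    time_hr: float
    locus: str
    target: DropletChannel
    reference: DropletChannel
    ratio: float
    ratio_ci_low: float
    ratio_ci_high: float
    copy_number: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan


def quantify_timepoint(
    time_hr: float,
    target: DropletChannel,
    reference: DropletChannel,
    method: str = "conservative",
) -> DdpcrTimepoint:
    r = ratio_with_ci(target, reference, method)
    return DdpcrTimepoint(
        time_hr=time_hr, locus=target.locus, target=target, reference=reference,
        ratio=r.ratio, ratio_ci_low=r.ci_low, ratio_ci_high=r.ci_high,
    )


def copy_number_series(timepoints: list[DdpcrTimepoint]) -> list[DdpcrTimepoint]:
    """Normalize each locus' ratios to that locus' 0-h ratio.

    ``copy_number(t) = ratio(t) / ratio(0 h)``; the 0-h point is 1 by
    construction. CI bounds are divided by the 0-h point estimate (the 0-h
    sampling noise is a common scale factor within a locus and is not
    re-propagated). Values are not clamped to [1, 2]: sampling noise can
    carry estimates outside the physical bounds, and clamping would bias
    time-course fits.
    """
    out: list[DdpcrTimepoint] = []
    for locus in sorted({tp.locus for tp in timepoints}):
        series = sorted(
            (tp for tp in timepoints if tp.locus == locus), key=lambda tp: tp.time_hr
        )
        baselines = [tp for tp in series if tp.time_hr == 0]
        if not baselines:
            raise InputError(f"locus {locus!r} has no 0-hr sample to normalize to")
        r0 = baselines[0].ratio
        if r0 <= 0:
            raise InputError(f"locus {locus!r} has non-positive 0-hr ratio")
        for tp in series:
            out.append(
                replace(
                    tp,
                    copy_number=tp.ratio / r0,
                    ci_low=tp.ratio_ci_low / r0,
                    ci_high=tp.ratio_ci_high / r0,
                )
            )
    return out


def series_frame(timepoints: list[DdpcrTimepoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_hr": [tp.time_hr for tp in timepoints],
            "locus": [tp.locus for tp in timepoints],
            "ratio": [tp.ratio for tp in timepoints],
            "copy_number": [tp.copy_number for tp in timepoints],
            "ci_low": [tp.ci_low for tp in timepoints],
            "ci_high": [tp.ci_high for tp in timepoints],
        }
    )


def call_synthesis(
    copy_number: float,
    threshold: float = SYNTHESIS_THRESHOLD,
    ci_low: float | None = None,
    require_ci: bool = False,
) -> bool:
    """True iff the copy number shows evidence of DNA synthesis (>= 1.1x).

    The default call uses the point estimate with an inclusive threshold
    ("at least 1.1x"). With ``require_ci=True`` the call additionally
    requires the CI lower bound to clear the threshold.
    """
    if copy_number < 0:
        raise InputError("copy_number must be >= 0")
    called = copy_number >= threshold
    if require_ci:
        if ci_low is None:
            raise InputError("require_ci=True needs ci_low")
        called = called and ci_low >= threshold
    return called


@dataclass(frozen=True)
class KineticsFit:
    """Boltzmann sigmoid parameters for one locus' copy-number time course."""

    base: float
    top: float
    t_half: float
    tau: float
    rss: float
    converged: bool
    flags: tuple[str, ...] = ()

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.base + (self.top - self.base) / (
            1.0 + np.exp((self.t_half - t) / self.tau)
        )


def fit_boltzmann(times, values) -> KineticsFit:
    """Least-squares Boltzmann sigmoid fit of a copy-number time course.

    Model: ``y(t) = base + (top - base) / (1 + exp((t_half - t) / tau))``
    with ``tau`` bounded to (0.01, 20] hours. Initialization: base = min(y),
    top = max(y), t_half = time nearest the mid-range crossing, tau = 1 h.
    Decreasing series (top < base at the optimum) are fitted but flagged.
    Needs at least 5 points spanning at least 4 hours.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise InputError("times and values must have equal length")
    if t.size < 5:
        raise InputError("Boltzmann fit needs at least 5 timepoints")
    if t.max() - t.min() < 4.0:
        raise InputError("Boltzmann fit needs a time span of at least 4 hours")

    y_lo, y_hi = float(y.min()), float(y.max())
    mid = 0.5 * (y_lo + y_hi)
    t_half0 = float(t[np.argmin(np.abs(y - mid))])
    x0 = np.array([y_lo, y_hi, t_half0, 1.0])

    def resid(theta):
        base, top, t_half, tau = theta
        return base + (top - base) / (1.0 + np.exp((t_half - t) / tau)) - y

    lb = [-np.inf, -np.inf, -np.inf, 0.01]
    ub = [np.inf, np.inf, np.inf, 20.0]
    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
    base, top, t_half, tau = (float(v) for v in sol.x)
    rss = float(np.sum(sol.fun**2))
    flags: list[str] = []
    if abs(top - base) < 1e-6:
        flags.append("degenerate_flat")
    if top < base:
        flags.append("decreasing_fit")
    converged = bool(sol.success) and "degenerate_flat" not in flags
    return KineticsFit(
        base=base, top=top, t_half=t_half, tau=tau, rss=rss,
        converged=converged, flags=tuple(flags),
    )


def max_copy_number(timepoints: list[DdpcrTimepoint]) -> dict[str, tuple[float, float]]:
    """Per-locus maximum observed copy number and the time it occurred.

    Returns ``{locus: (max_copy_number, time_hr)}``. Because incomplete BIR
    products can degrade late in the time course, the maximum can exceed the
    final (10 h) value.
    """
    if not timepoints:
        raise InputError("empty series")
    out: dict[str, tuple[float, float]] = {}
    for tp in timepoints:
        if math.isnan(tp.copy_number):
            raise InputError("series must be copy-number normalized first")
        best = out.get(tp.locus)
        if best is None or tp.copy_number > best[0]:
            out[tp.locus] = (tp.copy_number, tp.time_hr)
    return out


def quantify_table(
    droplets: pd.DataFrame, reference: str = "ACT1", method: str = "conservative"
) -> list[DdpcrTimepoint]:
    """Quantify a droplet-count table (columns time_hr, locus, n_total, n_positive).

    Rows whose ``locus`` equals ``reference`` are the reference channel for
    their timepoint; every other locus at the same time is normalized to it.
    """
    required = {"time_hr", "locus", "n_total", "n_positive"}
    missing = required - set(droplets.columns)
    if missing:
        raise InputError(f"droplet table missing columns: {sorted(missing)}")
    out: list[DdpcrTimepoint] = []
    for time_hr, group in droplets.groupby("time_hr"):
        refs = group[group["locus"] == reference]
        if refs.empty:
            raise InputError(f"no reference ({reference!r}) channel at t={time_hr}")
        ref_row = refs.iloc[0]
        ref = channel_from_counts(reference, int(ref_row.n_positive), int(ref_row.n_total))
        for row in group[group["locus"] != reference].itertuples(index=False):
            tgt = channel_from_counts(str(row.locus), int(row.n_positive), int(row.n_total))
            out.append(quantify_timepoint(float(time_hr), tgt, ref, method))
    return copy_number_series(out)
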