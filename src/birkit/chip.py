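"""ChIP-qPCR enrichment: percent-of-input with control-locus normalization.

Each replicate contributes four quantification cycles: IP and input reactions
for the target locus (*MAT*, *CEN13*, or mtDNA) and for its control locus
(*ACT1* for *MAT*; *YBL028C* for *CEN13* and mtDNA). With amplification
efficiency E (default 2.0, i.e. perfect doubling per cycle) and the input
diluted ``input_dilution``-fold before qPCR::

    percent_input(locus) = input_dilution x E**(cq_input - cq_ip)
    enrichment           = percent_input(target) / percent_input(control)

The dilution factor and any global Cq offset cancel in the ratio, so the
enrichment is robust to pipetting scale; both the per-locus percent-input
values and the normalized enrichment are reported per replicate. Strain
comparisons use the ratio of mean enrichments with a Welch (unequal-variance)
two-sided t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError


@dataclass(frozen=True)
class ChipReplicate:
    cq_ip_target: float
    cq_input_target: float
    cq_ip_control: float
    cq_input_control: float

    def __post_init__(self) -> None:
        for name in ("cq_ip_target", "cq_input_target", "cq_ip_control", "cq_input_control"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0:
                raise InputError(f"{name} must be a finite positive Cq, got {v!r}")


@dataclass(frozen=True)
class ChipSample:
    strain: str
    locus: str
    control_locus: str
    replicates: tuple[ChipReplicate, ...]
    input_dilution: float = 10.0

    def __post_init__(self) -> None:
        if not self.replicates:
            raise InputError("need at least one replicate")
        if self.input_dilution < 1:
            raise InputError("input_dilution must be >= 1")
        object.__setattr__(self, "replicates", tuple(self.replicates))


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-replicate enrichments for one strain x locus."""

    strain: str
    locus: str
    enrichments: tuple[float, ...]
    percent_input_target: tuple[float, ...]
    percent_input_control: tuple[float, ...]
    mean: float
    sd: float
    n: int


def percent_input(cq_input: float, cq_ip: float, dilution: float, efficiency: float = 2.0) -> float:
    """IP signal as a fraction of the (dilution-corrected) input signal."""
    return dilution * efficiency ** (cq_input - cq_ip)


def enrichment(sample: ChipSample, efficiency: float = 2.0) -> EnrichmentResult:
    """Control-locus-normalized percent-input enrichment, per replicate.

    The per-replicate enrichment is invariant both to a constant added to all
    four Cq values and to the input dilution factor.
    """
    if efficiency <= 1.0:
        raise InputError("amplification efficiency must be > 1")
    pit, pic, enr = [], [], []
    for rep in sample.replicates:
        t = percent_input(rep.cq_input_target, rep.cq_ip_target, sample.input_dilution, efficiency)
        c = percent_input(rep.cq_input_control, rep.cq_ip_control, sample.input_dilution, efficiency)
        pit.append(t)
        pic.append(c)
        enr.append(t / c)
    arr = np.array(enr)
    return EnrichmentResult(
        strain=sample.strain,
        locus=sample.locus,
        enrichments=tuple(enr),
        percent_input_target=tuple(pit),
        percent_input_control=tuple(pic),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n=arr.size,
    )


@dataclass(frozen=True)
class FoldComparison:
    ratio: float  # mean(wt) / mean(mut): how many fold lower the mutant binds
    t_statistic: float
    pvalue: float
    method: str = "welch_t"


def fold_reduction(wt: EnrichmentResult, mut: EnrichmentResult) -> FoldComparison:
    """Fold-difference in mean enrichment with a Welch two-sided t-test.

    Requires at least 3 replicates per strain. A ratio of 4.6 means the
    mutant's binding at the locus is 4.6-fold lower than wild type's.
    """
    if wt.n < 3 or mut.n < 3:
        raise InputError("need at least 3 replicates per strain")
    if mut.mean <= 0:
        raise InputError("mutant mean enrichment must be > 0")
    res = stats.ttest_ind(wt.enrichments, mut.enrichments, equal_var=False)
    return FoldComparison(
        ratio=wt.mean / mut.mean,
        t_statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )
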