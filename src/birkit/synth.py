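"""Seeded synthetic-data generators for every assay stage.

Each generator emulates the physical sampling process of its assay — Poisson
counting noise for colonies and droplets, Gaussian noise for qPCR
quantification cycles, 2:2 meiotic segregation with genotype-dependent spore
viability — so that every estimator in the package can be exercised, and its
calibration checked, without any external data. All generators take a single
integer seed and are byte-deterministic: the same seed and parameters always
produce the identical table. (Colony-level phenotype generation lives in
:func:`birkit.segregation.simulate_colonies`.)

Default parameter choices (documented per generator) reflect the study
conditions of the assays they emulate: 20 replicate cultures of ~1e7 cells
with a 1e-7 per-cell background reversion frequency for the mutagenesis
stage; 20,000 droplets with a reference concentration of 1 copy per droplet
for ddPCR; 0.2-cycle Cq noise for qPCR; 2% relative spread in viable culture
size.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .chip import ChipReplicate, ChipSample
from .errors import InputError
from .mutagenesis import PlatingExperiment, Replicate
from .spores import GENOTYPES, SporeTable, SuppressionModel


def generate_plating(
    true_rate: float,
    background_rate: float = 1e-7,
    n_cultures: int = 20,
    cells_per_culture: float = 1e7,
    seed: int = 0,
    strain: str = "synthetic",
    dilution_permissive: float = 1e5,
    viable_cv: float = 0.02,
) -> tuple[PlatingExperiment, PlatingExperiment]:
    """Synthetic 0-h and 7-h platings for one strain.

    Per culture, the viable-cell number is ``cells_per_culture`` with a
    ``viable_cv`` relative Gaussian spread. Lys+ revertants are Poisson with
    mean ``rate x cells`` — ``background_rate`` alone at 0 h, plus
    ``true_rate`` at 7 h — and the whole culture is plated selectively
    (dilution 1). Permissive plates count a ``1/dilution_permissive`` aliquot
    (Poisson), recorded in the dilution column so the frequency arithmetic
    reconstructs per-cell rates. Returns ``(experiment_0h, experiment_7h)``.
    """
    if not 0.0 <= true_rate <= 1e-2 or not 0.0 <= background_rate <= 1e-2:
        raise InputError("rates must be in [0, 1e-2] per cell")
    if n_cultures < 1:
        raise InputError("n_cultures must be >= 1")
    rng = np.random.default_rng(seed)

    def one_timepoint(rate: float, timepoint: float) -> PlatingExperiment:
        reps = []
        for _ in range(n_cultures):
            cells = max(1.0, cells_per_culture * (1.0 + viable_cv * rng.standard_normal()))
            lys = int(rng.poisson(rate * cells))
            viable = int(rng.poisson(cells / dilution_permissive))
            viable = max(viable, 1)  # a permissive plate with zero colonies is re-streaked
            reps.append(
                Replicate(
                    lys_colonies=lys,
                    viable_colonies=viable,
                    dilution_selective=1.0,
                    dilution_permissive=dilution_permissive,
                )
            )
        return PlatingExperiment(strain=strain, timepoint_hr=timepoint, replicates=tuple(reps))

    exp_0h = one_timepoint(background_rate, 0.0)
    exp_7h = one_timepoint(background_rate + true_rate, 7.0)
    return exp_0h, exp_7h


def plating_frame(experiments: list[PlatingExperiment]) -> pd.DataFrame:
    rows = []
    for exp in experiments:
        for i, r in enumerate(exp.replicates, start=1):
            rows.append(
                {
                    "strain": exp.strain,
                    "timepoint_hr": exp.timepoint_hr,
                    "replicate": i,
                    "lys_colonies": r.lys_colonies,
                    "viable_colonies": r.viable_colonies,
                    "dilution_selective": r.dilution_selective,
                    "dilution_permissive": r.dilution_permissive,
                }
            )
    return pd.DataFrame(rows)


def generate_droplet_counts(
    true_ratio: float,
    ref_lambda: float = 1.0,
    n_droplets: int = 20_000,
    seed: int = 0,
    time_hr: float = 10.0,
    locus: str = "P2",
    reference: str = "ACT1",
    strain: str = "synthetic",
) -> pd.DataFrame:
    """Synthetic droplet table: a 0-h baseline pair plus one induced timepoint.

    Each droplet is positive with probability ``1 - exp(-lambda)``. At 0 h
    both channels sit at ``ref_lambda`` (copy number 1); at ``time_hr`` the
    target concentration is ``true_ratio x ref_lambda``. Columns follow the
    droplet TSV schema (strain, time_hr, locus, n_total, n_positive).
    """
    if not 0.0 < ref_lambda <= 5.0:
        raise InputError("ref_lambda must be in (0, 5]")
    if true_ratio < 0 or true_ratio * ref_lambda <= 0:
        raise InputError("target lambda must be > 0")
    if n_droplets < 100:
        raise InputError("n_droplets must be >= 100")
    rng = np.random.default_rng(seed)

    def draw(lam: float) -> int:
        return int(rng.binomial(n_droplets, 1.0 - math.exp(-lam)))

    rows = [
        {"strain": strain, "time_hr": 0.0, "locus": locus, "n_total": n_droplets,
         "n_positive": draw(ref_lambda)},
        {"strain": strain, "time_hr": 0.0, "locus": reference, "n_total": n_droplets,
         "n_positive": draw(ref_lambda)},
        {"strain": strain, "time_hr": time_hr, "locus": locus, "n_total": n_droplets,
         "n_positive": draw(true_ratio * ref_lambda)},
        {"strain": strain, "time_hr": time_hr, "locus": reference, "n_total": n_droplets,
         "n_positive": draw(ref_lambda)},
    ]
    return pd.DataFrame(rows)


def generate_droplet_timecourse(
    copy_numbers: dict[float, float],
    ref_lambda: float = 1.0,
    n_droplets: int = 20_000,
    seed: int = 0,
    locus: str = "P2",
    reference: str = "ACT1",
    strain: str = "synthetic",
) -> pd.DataFrame:
    """Droplet table across a full {time_hr: copy_number} course (0 h must be 1)."""
    if 0.0 not in copy_numbers:
        raise InputError("time course must include a 0-hr sample")
    rng = np.random.default_rng(seed)
    rows = []
    for time_hr in sorted(copy_numbers):
        cn = copy_numbers[time_hr]
        if cn * ref_lambda <= 0:
            raise InputError("target lambda must be > 0 at every timepoint")
        for loc, lam in ((locus, cn * ref_lambda), (reference, ref_lambda)):
            rows.append(
                {"strain": strain, "time_hr": time_hr, "locus": loc,
                 "n_total": n_droplets,
                 "n_positive": int(rng.binomial(n_droplets, 1.0 - math.exp(-lam)))}
            )
    return pd.DataFrame(rows)


def generate_cq(
    true_enrichment: float,
    base_cq: float = 20.0,
    noise_sd: float = 0.2,
    n_replicates: int = 6,
    input_dilution: float = 10.0,
    seed: int = 0,
    strain: str = "synthetic",
    locus: str = "MAT",
    control_locus: str = "ACT1",
) -> ChipSample:
    """Synthetic ChIP-qPCR replicates with a known true enrichment.

    In the noiseless configuration all four Cq values equal ``base_cq``
    (enrichment 1); the target IP Cq is lowered by ``log2(true_enrichment)``
    so that the percent-input ratio equals ``true_enrichment`` exactly, then
    independent Gaussian noise of ``noise_sd`` cycles is added to every Cq.
    """
    if true_enrichment <= 0:
        raise InputError("true_enrichment must be > 0")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    shift = math.log2(true_enrichment)
    reps = []
    for _ in range(n_replicates):
        noise = noise_sd * rng.standard_normal(4)
        reps.append(
            ChipReplicate(
                cq_ip_target=base_cq - shift + noise[0],
                cq_input_target=base_cq + noise[1],
                cq_ip_control=base_cq + noise[2],
                cq_input_control=base_cq + noise[3],
            )
        )
    return ChipSample(
        strain=strain, locus=locus, control_locus=control_locus,
        replicates=tuple(reps), input_dilution=input_dilution,
    )


def _tetrad_patterns(rng: np.random.Generator, r: float) -> np.ndarray:
    """Marker-2 allele pattern (booleans) for the 4 spores of one tetrad.

    Marker 1 is fixed as [1, 1, 0, 0]. Each spore's marker-2 allele is
    parental-phase with probability 1 - r, then the draw is rejection-sampled
    to the 2:2 meiotic constraint. At r = 0.5 this is uniform over the six
    arrangements (PD:NPD:T = 1:1:4, the unlinked expectation); at r = 0 only
    the parental ditype survives.
    """
    while True:
        recomb = rng.random(4) < r
        m2 = np.array([True, True, False, False]) ^ recomb
        if m2.sum() == 2:
            return m2


def generate_spores(
    model: SuppressionModel,
    n_tetrads: int | None = None,
    n_spores: int | None = None,
    source: str = "tetrad",
    recombination_fraction: float = 0.5,
    seed: int = 0,
    label: str = "synthetic",
) -> SporeTable:
    """Synthetic viable-spore table from a heterozygous-double cross.

    Tetrad mode (``n_tetrads``): each meiosis yields 4 spores with exact 2:2
    segregation per marker; the two markers assort with the given
    recombination fraction (0.5 = unlinked, the default). RSA mode
    (``n_spores``): spores are pooled, each marker an independent fair coin.
    Each spore then survives with its genotype's viability probability, and
    only survivors are tallied (marker phase: marker 1 true = dna2-null/Ura+,
    marker 2 true = pif1-null/G418-resistant).
    """
    if source not in ("tetrad", "rsa"):
        raise InputError("source must be 'tetrad' or 'rsa'")
    if not 0.0 <= recombination_fraction <= 0.5:
        raise InputError("recombination_fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)

    if source == "tetrad":
        if n_tetrads is None or n_tetrads < 1:
            raise InputError("tetrad mode needs n_tetrads >= 1")
        dna2_null = []
        pif1_null = []
        for _ in range(n_tetrads):
            order = rng.permutation(4)
            m1 = np.array([True, True, False, False])[order]
            m2 = _tetrad_patterns(rng, recombination_fraction)[order]
            dna2_null.append(m1)
            pif1_null.append(m2)
        dna2_null = np.concatenate(dna2_null)
        pif1_null = np.concatenate(pif1_null)
    else:
        if n_spores is None or n_spores < 1:
            raise InputError("rsa mode needs n_spores >= 1")
        dna2_null = rng.random(n_spores) < 0.5
        pif1_null = rng.random(n_spores) < 0.5

    genotype = np.where(
        dna2_null,
        np.where(pif1_null, "dna2null_pif1null", "dna2null_PIF1var"),
        np.where(pif1_null, "DNA2_pif1null", "DNA2_PIF1var"),
    )
    survives = rng.random(genotype.size) < np.array([model.prob(g) for g in genotype])
    tally = {g: int(((genotype == g) & survives).sum()) for g in GENOTYPES}
    return SporeTable(
        source=source,
        ura_plus_g418s=tally["dna2null_PIF1var"],
        ura_plus_g418r=tally["dna2null_pif1null"],
        ura_minus_g418s=tally["DNA2_PIF1var"],
        ura_minus_g418r=tally["DNA2_pif1null"],
        n_tetrads=n_tetrads if source == "tetrad" else None,
        label=label,
    )


def spore_frame(table: SporeTable) -> pd.DataFrame:
    rows = [
        ("plus", "sensitive", table.ura_plus_g418s),
        ("plus", "resistant", table.ura_plus_g418r),
        ("minus", "sensitive", table.ura_minus_g418s),
        ("minus", "resistant", table.ura_minus_g418r),
    ]
    return pd.DataFrame(
        {
            "source": table.source,
            "n_tetrads": table.n_tetrads if table.n_tetrads is not None else 0,
            "ura_phenotype": [r[0] for r in rows],
            "g418_phenotype": [r[1] for r in rows],
            "count": [r[2] for r in rows],
        }
    )
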