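"""Named read-only fixtures: the published counts, sequences, and constants.

Every quantity the package treats as an input — CHEF karyotyping counts,
spore tallies, the candidate NLS sequences with their residue anchors, and
the assay constants — lives here with its source attached, so analyses can
cite exactly what they consumed. The cNLS Mapper prediction scores are
external program outputs recorded as fixtures; this package never computes
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Any

from .sequences import ProteinSequence
from .spores import SporeTable


@dataclass(frozen=True)
class Fixture:
    name: str
    value: Any
    source: str  # where the value was reported


_FIXTURES: dict[str, Fixture] = {}


def _register(name: str, value: Any, source: str) -> None:
    _FIXTURES[name] = Fixture(name=name, value=value, source=source)


def get(name: str) -> Any:
    """Return a fixture's value by name."""
    return _FIXTURES[name].value


def describe(name: str) -> Fixture:
    return _FIXTURES[name]


def names() -> list[str]:
    return sorted(_FIXTURES)


registry = MappingProxyType(_FIXTURES)


# --- candidate NLS sequences (superscript residue numbering, 1-based) -------
_register(
    "nls_monopartite_candidate",
    ProteinSequence(id="monopartite_candidate", residues="DEQVKKRKLDY", anchor=777),
    "candidate monopartite NLS 777-787 in the 859-aa nuclear Pif1 isoform",
)
_register(
    "nls_bipartite_candidate",
    ProteinSequence(
        id="bipartite_candidate",
        residues="RQRGDVKFIDMLNRMRLGNIDDETEREFKKLSRP",
        anchor=417,
    ),
    "candidate bipartite NLS 417-450, overlapping helicase motif IV",
)
_register(
    "sv40_nls",
    ProteinSequence(id="SV40_T_antigen_NLS", residues="PKKKRKV", anchor=126),
    "SV40 large T antigen NLS, residues 126-132",
)
_register("pif1_length_aa", 859, "length of the nuclear Pif1 isoform")
_register(
    "cnls_mapper_scores",
    {"monopartite_candidate": 8, "bipartite_candidate": 5},
    "cNLS Mapper prediction scores (external program output, not computed here)",
)

# --- CHEF karyotyping counts among Ade+ Leu- repair outcomes ----------------
_register(
    "chef_counts",
    {"pif1_null": (10, 23), "wild_type": (1, 30)},
    "rearranged/tested Ade+ Leu- clones by CHEF electrophoresis: 10/23 (43%) "
    "in pif1-null, 1/30 (3%) in wild type",
)

# --- mutagenesis assay ------------------------------------------------------
_register(
    "wt_lys_rate", 3.9e-6,
    "wild-type BIR-associated Lys+ reversion rate, 7 h after DSB induction",
)
_register(
    "pif1_null_fold_reduction", 27.0,
    "pif1-null cells show 27-fold lower BIR-associated Lys+ mutagenesis than WT",
)
_register("reporter_offset_kb", 16.0, "lys2 frameshift reporter 16 kb from the DSB")

# --- AMBER ddPCR ------------------------------------------------------------
_register("nominal_droplets", 20_000, "droplets per ddPCR reaction")
_register(
    "synthesis_call_threshold", 1.1,
    "copy-number increase of at least 1.1x called as evidence of DNA synthesis",
)
_register(
    "locus_offsets_kb", {"P2": 1.9, "P3": 22.4, "P4": 61.4},
    "donor-locus primer positions centromere-distal to the DSB",
)
_register(
    "wt_copy_number_10h", {"P2": 1.7, "P3": 1.7, "P4": 1.6},
    "wild-type donor copy numbers 10 h after DSB induction",
)

# --- ChIP-qPCR --------------------------------------------------------------
_register(
    "chip_mat_fold_reduction", 4.6,
    "NLS-deleted mutant binds MAT ~4.6-fold lower than wild type",
)
_register(
    "chip_control_loci", {"MAT": "ACT1", "CEN13": "YBL028C", "mtDNA": "YBL028C"},
    "control locus used to normalize each ChIP target",
)

# --- dna2-null suppression crosses ------------------------------------------
_register(
    "tetrad_nls_deletion_cross",
    SporeTable(source="tetrad", ura_plus_g418s=3, ura_plus_g418r=24,
               n_tetrads=35, label="NLS-deleted variant cross"),
    "35 dissected tetrads: 3 viable Ura+ G418-sensitive vs 24 Ura+ G418-resistant",
)
_register(
    "tetrad_wt_cross",
    SporeTable(source="tetrad", ura_plus_g418s=0, ura_plus_g418r=24,
               n_tetrads=36, label="wild-type cross"),
    "36 dissected tetrads of the WT cross: no viable Ura+ G418-sensitive spores "
    "(Ura+ G418-resistant total not itemized; 24 assumed comparable to the "
    "variant cross for CI illustration only)",
)
_register(
    "rsa_nls_deletion_cross",
    SporeTable(source="rsa", ura_plus_g418s=8, ura_plus_g418r=34,
               label="NLS-deleted variant cross"),
    "random spore analysis: among 42 Ura+ clones, 8 G418-sensitive, 34 resistant",
)
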