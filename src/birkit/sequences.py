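"""Protein sequences, the monopartite NLS consensus scanner, and construct edits.

Coordinates throughout are 1-based and inclusive on both ends, following the
superscript residue-numbering convention used for motifs such as
:sup:`781`\\ KKRK\\ :sup:`784`. A :class:`ProteinSequence` carries an ``anchor``:
the full-protein coordinate of its first residue, so that sub-sequences (e.g.
an 11-residue candidate NLS excised from an 859-residue helicase) report motif
positions in full-protein coordinates.

The scanner is a binary matcher for the classical monopartite nuclear
localization signal consensus K-(K/R)-X-(K/R); it does not score candidate
NLSs by importin affinity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, RangeError

#: The 20 standard amino acids. Ambiguity codes (B, Z, X) and stops (*) are
#: rejected because the consensus spacer "X" would be ill-defined for them.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Classical monopartite NLS consensus: K, then K/R, any residue, then K/R.
MONOPARTITE_PATTERN_ID = "K(K/R)X(K/R)"
_MONOPARTITE_RE = re.compile(r"(?=(K[KR].[KR]))")


def _validate_residues(residues: str, what: str = "residues") -> str:
    if residues != residues.upper():
        warnings.warn(f"lower-case {what} upper-cased on input", stacklevel=3)
        residues = residues.upper()
    for i, aa in enumerate(residues):
        if aa not in AMINO_ACIDS:
            raise InputError(
                f"invalid character {aa!r} at position {i + 1} of {what}: "
                "not one of the 20 standard amino acids"
            )
    return residues


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid string anchored in full-protein coordinates.

    Parameters
    ----------
    id : str
        Label for the sequence (strain, allele, or accession-style name).
    residues : str
        Upper-case amino-acid string; may be empty only when a construct edit
        deliberately removes everything.
    anchor : int
        1-based full-protein coordinate of ``residues[0]``. Residue ``i`` of
        the string (1-based) sits at full-protein coordinate ``anchor + i - 1``.
    """

    id: str
    residues: str
    anchor: int = 1

    def __post_init__(self) -> None:
        if self.anchor < 1:
            raise InputError(f"anchor must be >= 1, got {self.anchor}")
        object.__setattr__(self, "residues", _validate_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        """Full-protein coordinate of the first residue."""
        return self.anchor

    @property
    def end(self) -> int:
        """Full-protein coordinate of the last residue (anchor-based, inclusive)."""
        return self.anchor + len(self.residues) - 1

    def slice(self, start: int, end: int) -> str:
        """Residues spanning full-protein coordinates [start, end], inclusive."""
        self._check_range(start, end)
        return self.residues[start - self.anchor : end - self.anchor + 1]

    def _check_range(self, start: int, end: int) -> None:
        if not (self.anchor <= start <= end <= self.end):
            raise RangeError(
                f"coordinates [{start}, {end}] outside sequence "
                f"[{self.anchor}, {self.end}] of {self.id!r}"
            )


@dataclass(frozen=True)
class MotifMatch:
    """One 4-residue consensus hit, in full-protein coordinates (inclusive)."""

    start: int
    end: int
    matched: str
    pattern_id: str = MONOPARTITE_PATTERN_ID

    def __post_init__(self) -> None:
        if self.end != self.start + 3 or len(self.matched) != 4:
            raise InputError("monopartite consensus matches are exactly 4 residues")


def scan_monopartite_consensus(seq: ProteinSequence) -> list[MotifMatch]:
    """Find every window matching the monopartite NLS consensus K-(K/R)-X-(K/R).

    Overlapping matches are all reported, in ascending coordinate order.
    The spacer position accepts any of the 20 residues, including K and R.

    Examples
    --------
    Scanning the 11-residue candidate ``DEQVKKRKLDY`` anchored at 777 returns
    a single match, ``KKRK`` at 781-784.
    """
    out = []
    for m in _MONOPARTITE_RE.finditer(seq.residues):
        start = seq.anchor + m.start()
        out.append(MotifMatch(start=start, end=start + 3, matched=m.group(1)))
    return out


def delete_segment(seq: ProteinSequence, start: int, end: int) -> ProteinSequence:
    """Excise residues [start, end] (full-protein coordinates, inclusive).

    The anchor is unchanged; downstream residues shift left. Deleting the
    781-784 core from a candidate NLS yields the NLS-deleted allele.
    """
    seq._check_range(start, end)
    i, j = start - seq.anchor, end - seq.anchor + 1
    return replace(seq, residues=seq.residues[:i] + seq.residues[j:])


def insert_segment(seq: ProteinSequence, at: int, segment: str) -> ProteinSequence:
    """Insert ``segment`` so that its first residue lands at coordinate ``at``.

    ``at`` may range from ``anchor`` to ``end + 1`` (append position). This is
    the exact inverse of :func:`delete_segment`: deleting [s, e] and
    re-inserting the excised residues at ``s`` reconstructs the original.
    """
    segment = _validate_residues(segment, "segment")
    if not seq.anchor <= at <= seq.end + 1:
        raise RangeError(
            f"insertion point {at} outside [{seq.anchor}, {seq.end + 1}] of {seq.id!r}"
        )
    i = at - seq.anchor
    return replace(seq, residues=seq.residues[:i] + segment + seq.residues[i:])


def append_segment(seq: ProteinSequence, tail: str) -> ProteinSequence:
    """Fuse ``tail`` to the carboxyl terminus (e.g. the SV40 NLS ``PKKKRKV``)."""
    tail = _validate_residues(tail, "tail")
    return replace(seq, residues=seq.residues + tail)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

_ANCHOR_RE = re.compile(r"\banchor=(\d+)\b")


def read_fasta(path, default_anchor: int = 1) -> list[ProteinSequence]:
    """Read protein FASTA records.

    An ``anchor=<int>`` key in the record description sets the full-protein
    coordinate of the first residue; otherwise ``default_anchor`` is used.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _ANCHOR_RE.search(rec.description)
        anchor = int(m.group(1)) if m else default_anchor
        out.append(ProteinSequence(id=rec.id, residues=str(rec.seq), anchor=anchor))
    if not out:
        raise InputError(f"no FASTA records found in {path}")
    return out


def write_fasta(seqs: list[ProteinSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=f"anchor={s.anchor}")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")
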