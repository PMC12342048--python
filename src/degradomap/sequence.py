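"""Protein sequence handling, peptide localization and in-silico tryptic digestion.

All residue numbering is 1-based on the precursor sequence (signal peptide
included), with inclusive spans, so that printed cleavage-site labels such as
S77-V78 on an NCBI precursor entry can be used directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

__all__ = [
    "CANONICAL_RESIDUES",
    "TERMINUS",
    "ProteinRecord",
    "PeptideSpan",
    "TerminusClass",
    "read_fasta",
    "locate_peptide",
    "classify_termini",
    "classify_termini_from_context",
    "peptide_status",
    "cleavage_positions",
    "tryptic_digest",
    "protparam_properties",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Marker used for the preceding/following context at a protein terminus.
TERMINUS = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """A substrate protein with 1-based precursor numbering.

    Residue ``i`` of ``sequence`` is residue ``i`` of the precursor; no offset
    is ever applied, so a site label like Q76-S77 refers to ``sequence[75]``
    and ``sequence[76]`` in Python indexing.
    """

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("protein sequence must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = [
            (i + 1, aa)
            for i, aa in enumerate(self.sequence)
            if aa not in CANONICAL_RESIDUES
        ]
        if bad:
            pos, aa = bad[0]
            raise ValueError(
                f"non-canonical residue {aa!r} at position {pos} in {self.accession}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position, or the terminus marker."""
        if position < 1 or position > len(self.sequence):
            return TERMINUS
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Subsequence for an inclusive 1-based span."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"span {start}-{end} outside 1-{len(self.sequence)}")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class PeptideSpan:
    """Inclusive 1-based location of a peptide on a protein, with context."""

    protein: ProteinRecord = field(compare=False)
    start: int
    end: int
    preceding: str = TERMINUS
    following: str = TERMINUS

    def __post_init__(self) -> None:
        n = len(self.protein)
        if not (1 <= self.start <= self.end <= n):
            raise ValueError(f"invalid span {self.start}-{self.end} on length {n}")
        if self.preceding != self.protein.residue(self.start - 1):
            raise ValueError(
                f"preceding residue {self.preceding!r} disagrees with sequence "
                f"at {self.start - 1}"
            )
        if self.following != self.protein.residue(self.end + 1):
            raise ValueError(
                f"following residue {self.following!r} disagrees with sequence "
                f"at {self.end + 1}"
            )

    @property
    def peptide(self) -> str:
        return self.protein.slice(self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TerminusClass:
    side: Literal["N", "C"]
    status: Literal["tryptic", "nontryptic", "protein_terminus"]


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file into :class:`ProteinRecord` objects.

    The accession is the first whitespace-delimited token of the header. In
    strict mode any non-canonical residue letter raises; in lenient mode the
    record is kept and a warning names the residue and position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {entry.id}")
        if strict:
            records.append(
                ProteinRecord(entry.id, seq, description=entry.description)
            )
        else:
            bad = [(i + 1, aa) for i, aa in enumerate(seq) if aa not in CANONICAL_RESIDUES]
            if bad:
                warnings.warn(
                    f"{entry.id}: non-canonical residue(s) "
                    + ", ".join(f"{aa}@{pos}" for pos, aa in bad[:5])
                )
                seq = "".join(aa if aa in CANONICAL_RESIDUES else "G" for aa in seq)
            records.append(ProteinRecord(entry.id, seq, description=entry.description))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def locate_peptide(protein: ProteinRecord, peptide: str) -> list[PeptideSpan]:
    """All exact-match spans of ``peptide`` on ``protein``, ascending by start."""
    if not peptide:
        raise ValueError("peptide must be non-empty")
    peptide = peptide.upper()
    spans: list[PeptideSpan] = []
    pos = protein.sequence.find(peptide)
    while pos != -1:
        start = pos + 1
        end = pos + len(peptide)
        spans.append(
            PeptideSpan(
                protein,
                start,
                end,
                preceding=protein.residue(start - 1),
                following=protein.residue(end + 1),
            )
        )
        pos = protein.sequence.find(peptide, pos + 1)
    return spans


def classify_termini_from_context(
    peptide: str,
    preceding: str,
    following: str,
    proline_rule: bool = True,
) -> tuple[TerminusClass, TerminusClass]:
    """Classify both termini from the peptide string and its flanking residues.

    A terminus is tryptic when the residue N-terminal to the (putative)
    cleavage is K or R — the preceding residue for the N side, the peptide's
    last residue for the C side — optionally requiring the next residue not to
    be proline. Flanks equal to :data:`TERMINUS` mark a protein terminus,
    which is classified separately because a peptide ending at the mature
    protein terminus is not evidence of proteolysis.
    """
    peptide = peptide.upper()

    if preceding == TERMINUS:
        n_status = "protein_terminus"
    elif preceding in "KR" and not (proline_rule and peptide[0] == "P"):
        n_status = "tryptic"
    else:
        n_status = "nontryptic"

    if following == TERMINUS:
        c_status = "protein_terminus"
    elif peptide[-1] in "KR" and not (proline_rule and following == "P"):
        c_status = "tryptic"
    else:
        c_status = "nontryptic"

    return TerminusClass("N", n_status), TerminusClass("C", c_status)


def classify_termini(
    span: PeptideSpan, proline_rule: bool = True
) -> tuple[TerminusClass, TerminusClass]:
    """Classify the termini of a localized peptide span."""
    return classify_termini_from_context(
        span.peptide, span.preceding, span.following, proline_rule=proline_rule
    )


def peptide_status(
    n_term: TerminusClass, c_term: TerminusClass
) -> Literal["fully", "semi", "non"]:
    """Collapse two terminus classes into fully/semi/non-tryptic status."""
    nontryptic = sum(t.status == "nontryptic" for t in (n_term, c_term))
    return ("fully", "semi", "non")[nontryptic]


def cleavage_positions(sequence: str, proline_rule: bool = True) -> list[int]:
    """1-based positions i such that trypsin cleaves between i and i+1.

    Cleavage occurs C-terminal to K/R; with the proline rule enabled no
    cleavage occurs when the next residue is proline. The protein C-terminus
    is not included.
    """
    sequence = sequence.upper()
    positions = []
    for i, aa in enumerate(sequence[:-1], start=1):
        if aa in "KR" and not (proline_rule and sequence[i] == "P"):
            positions.append(i)
    return positions


def tryptic_digest(
    protein: ProteinRecord, max_missed: int = 3, proline_rule: bool = True
) -> list[PeptideSpan]:
    """All fully tryptic peptides with 0..max_missed internal missed cleavages.

    Peptides are returned sorted by (start, end). The zero-missed peptides
    tile the protein exactly.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cuts = cleavage_positions(protein.sequence, proline_rule=proline_rule)
    bounds = [0] + cuts + [len(protein)]  # fragment i spans bounds[i]+1..bounds[i+1]
    n_frag = len(bounds) - 1
    spans: list[PeptideSpan] = []
    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            start, end = bounds[i] + 1, bounds[j + 1]
            spans.append(
                PeptideSpan(
                    protein,
                    start,
                    end,
                    preceding=protein.residue(start - 1),
                    following=protein.residue(end + 1),
                )
            )
    spans.sort(key=lambda s: (s.start, s.end))
    return spans


# Trp, Tyr and cystine molar extinction coefficients at 280 nm (M^-1 cm^-1).
_EXT_TRP, _EXT_TYR, _EXT_CYSTINE = 5500, 1490, 125


def protparam_properties(sequence: str, reduced: bool = False) -> tuple[float, float]:
    """Average mass (Da) and molar extinction coefficient at 280 nm.

    The extinction coefficient follows the standard ProtParam formula:
    5500*nTrp + 1490*nTyr + 125*nCystine, where cystines are counted as
    paired cysteines and omitted when ``reduced`` is set. The mass is the
    average (isotope-weighted) mass of the free peptide including water.
    """
    sequence = sequence.upper()
    bad = set(sequence) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(f"non-canonical residue(s): {sorted(bad)}")
    ext = _EXT_TRP * sequence.count("W") + _EXT_TYR * sequence.count("Y")
    if not reduced:
        ext += _EXT_CYSTINE * (sequence.count("C") // 2)
    mass = molecular_weight(sequence, seq_type="protein", monoisotopic=False)
    return float(mass), float(ext)
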