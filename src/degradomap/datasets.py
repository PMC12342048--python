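"""Bundled desk-scale evidence tables and a synthetic scaffold substrate.

Two peptide-evidence tables are shipped, one per protease arm of a COMP
digestion experiment (ADAMTS4 and ADAMTS1, each paired with its inactive EQ
control). Each table holds the published semi-tryptic peptides with their
flanking residues and cleavage-site positions, the corresponding spanning
tryptic peptides, and a synthetic both-group background of fully tryptic
peptides whose log2 ratios are constructed so that the both-group population
reproduces the z-score scale of the original experiment.

The full COMP precursor sequence is not bundled. Instead,
:func:`scaffold_substrate` reconstructs a SYNTHETIC scaffold at run time by
placing every evidence peptide at its known precursor position and filling
unconstrained residues with glycine. Within the evidence regions the scaffold
is identical to the real precursor, so site positions and flanking windows are
faithful; outside them it is synthetic filler.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache

import pandas as pd

from .calling import CleavageSiteCaller, PeptideObservation
from .sequence import TERMINUS, ProteinRecord, classify_termini_from_context

__all__ = [
    "load_evidence_table",
    "evidence_observations",
    "scaffold_substrate",
    "call_evidence_sites",
    "SCAFFOLD_ACCESSION",
]

SCAFFOLD_ACCESSION = "COMP-scaffold-synthetic"

_TABLES = {"adamts4": "adamts4_comp_evidence.tsv", "adamts1": "adamts1_comp_evidence.tsv"}


@lru_cache(maxsize=None)
def load_evidence_table(protease: str) -> pd.DataFrame:
    """Load the bundled evidence table for 'adamts4' or 'adamts1'."""
    try:
        name = _TABLES[protease.lower()]
    except KeyError:
        raise ValueError(f"unknown protease {protease!r}; expected one of {sorted(_TABLES)}")
    ref = importlib.resources.files("degradomap").joinpath("data", name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"peptide": str}, keep_default_na=False)


def evidence_observations(df: pd.DataFrame) -> list[PeptideObservation]:
    """Convert an evidence table into quantification observations."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PeptideObservation(
                peptide=row.peptide,
                preceding=row.preceding or TERMINUS,
                following=row.following or TERMINUS,
                abundance_active=float(row.abundance_active) if row.abundance_active != "" else None,
                abundance_control=float(row.abundance_control) if row.abundance_control != "" else None,
            )
        )
    return out


def _row_span(row) -> tuple[int, int]:
    """Inclusive 1-based span of an evidence peptide on the precursor."""
    peptide = row.peptide
    if row.role == "spanning":
        start = int(row.span_start)
        return start, start + len(peptide) - 1
    if row.role == "semi":
        p1 = int(row.site_p1)
        n_term, c_term = classify_termini_from_context(
            peptide, row.preceding or TERMINUS, row.following or TERMINUS
        )
        if n_term.status == "nontryptic":
            start = p1 + 1
        elif c_term.status == "nontryptic":
            start = p1 - len(peptide) + 1
        else:  # pragma: no cover - malformed table
            raise ValueError(f"evidence row {peptide} is not semi-tryptic")
        return start, start + len(peptide) - 1
    raise ValueError(f"role {row.role!r} has no intrinsic span")


@lru_cache(maxsize=None)
def scaffold_substrate() -> ProteinRecord:
    """Synthetic scaffold substrate hosting all bundled evidence peptides.

    Every published peptide (and its flanking residues) is placed at its
    precursor position; the placements are cross-checked for consistency and
    any residue conflict raises. Synthetic background peptides are appended
    downstream of the evidence region, each preceded by an arginine so they
    digest out as fully tryptic peptides. All remaining positions are glycine
    (never K/R, so the filler creates no spurious tryptic context).
    """
    constraints: dict[int, str] = {}

    def place(position: int, residue: str, what: str) -> None:
        if residue == TERMINUS or residue == "":
            return
        old = constraints.get(position)
        if old is not None and old != residue:
            raise ValueError(
                f"scaffold conflict at {position}: {old} vs {residue} ({what})"
            )
        constraints[position] = residue

    background: list[str] = []
    seen_bg: set[str] = set()
    for protease in ("adamts4", "adamts1"):
        df = load_evidence_table(protease)
        for row in df.itertuples(index=False):
            if row.role == "background":
                if row.peptide not in seen_bg:
                    seen_bg.add(row.peptide)
                    background.append(row.peptide)
                continue
            start, end = _row_span(row)
            for offset, residue in enumerate(row.peptide):
                place(start + offset, residue, row.peptide)
            place(start - 1, row.preceding, f"preceding of {row.peptide}")
            place(end + 1, row.following, f"following of {row.peptide}")

    # Append the synthetic background block after the evidence region.
    position = max(constraints) + 15
    for peptide in background:
        place(position, "R", f"anchor of background {peptide}")
        for offset, residue in enumerate(peptide):
            place(position + 1 + offset, residue, f"background {peptide}")
        position += len(peptide) + 2  # one glycine gap between entries

    length = max(constraints) + 1
    sequence = ["G"] * length
    sequence[0] = "M"
    for pos, residue in constraints.items():
        sequence[pos - 1] = residue
    return ProteinRecord(
        SCAFFOLD_ACCESSION,
        "".join(sequence),
        description="synthetic scaffold reconstructed from published peptide evidence",
    )


def call_evidence_sites(protease: str, **caller_params) -> CleavageSiteCaller:
    """Run the cleavage-site caller on a bundled evidence table."""
    observations = evidence_observations(load_evidence_table(protease))
    return CleavageSiteCaller(**caller_params).fit(observations, scaffold_substrate())
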