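"""Positional cleavage-specificity profiling (P4-P4' windows vs a background).

For a collection of cleavage sites, the residues flanking each scissile bond
are aligned on the P1-P1' boundary (Schechter-Berger nomenclature: P4..P1 on
the N-terminal side, P1'..P4' on the C-terminal side). Per position, the
observed residue frequency (%) is compared with a reference amino-acid
composition; the difference is scored for significance with a two-sided
normal approximation to the binomial, mirroring percentage-scoring sequence
logos. No multiple-testing correction is applied, matching that convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .calling import SiteCall
from .sequence import ProteinRecord

__all__ = [
    "HUMAN_SWISSPROT_COMPOSITION",
    "SiteWindow",
    "SpecificityMatrix",
    "extract_windows",
    "windows_from_positions",
    "positional_enrichment",
    "consensus_report",
    "SpecificityProfiler",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

#: Average amino-acid composition (%) of human UniProtKB/Swiss-Prot entries.
#: Embedded as a fixed, documented default because the online reference set is
#: a moving resource; user-overridable in every profiling entry point.
HUMAN_SWISSPROT_COMPOSITION: dict[str, float] = {
    "A": 7.01, "R": 5.64, "N": 3.59, "D": 4.74, "C": 2.30,
    "Q": 4.77, "E": 7.10, "G": 6.58, "H": 2.63, "I": 4.34,
    "L": 9.97, "K": 5.72, "M": 2.13, "F": 3.65, "P": 6.31,
    "S": 8.33, "T": 5.36, "W": 1.22, "Y": 2.66, "V": 5.96,
}


def position_labels(n_flank: int) -> list[str]:
    """['P4', ..., 'P1', "P1'", ..., "P4'"] for the given flank width."""
    return [f"P{i}" for i in range(n_flank, 0, -1)] + [
        f"P{i}'" for i in range(1, n_flank + 1)
    ]


@dataclass(frozen=True)
class SiteWindow:
    """Residues around one scissile bond, P-n..P1 | P1'..Pn', gap-padded."""

    residues: tuple[str, ...]
    n_flank: int = 4

    def __post_init__(self) -> None:
        if len(self.residues) != 2 * self.n_flank:
            raise ValueError("window length must be 2 * n_flank")
        if GAP in (self.residues[self.n_flank - 1], self.residues[self.n_flank]):
            raise ValueError("P1 and P1' must always be present")

    @property
    def p1(self) -> str:
        return self.residues[self.n_flank - 1]

    @property
    def p1prime(self) -> str:
        return self.residues[self.n_flank]


@dataclass
class SpecificityMatrix:
    """Observed/background/difference frequency tables (positions x residues, %)."""

    observed: pd.DataFrame
    background: pd.DataFrame
    difference: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame
    n_windows: pd.Series  # non-gap count per position
    alpha: float


def extract_windows(
    sites: Iterable[SiteCall],
    proteins: dict[str, ProteinRecord] | ProteinRecord,
    n_flank: int = 4,
) -> list[SiteWindow]:
    """Read P-n..Pn' windows off the substrate sequence around each site."""
    if isinstance(proteins, ProteinRecord):
        proteins = {proteins.accession: proteins}
    windows = []
    for site in sites:
        try:
            protein = proteins[site.accession]
        except KeyError:
            raise KeyError(f"no substrate sequence for accession {site.accession!r}")
        windows.extend(
            windows_from_positions(protein, [site.p1_position], n_flank=n_flank)
        )
    return windows


def windows_from_positions(
    protein: ProteinRecord, p1_positions: Sequence[int], n_flank: int = 4
) -> list[SiteWindow]:
    """Windows for explicit P1 positions (e.g. an external site-list table)."""
    windows = []
    for p1 in p1_positions:
        if not (1 <= p1 < len(protein)):
            raise ValueError(
                f"P1 position {p1} outside 1..{len(protein) - 1} of {protein.accession}"
            )
        residues = []
        for pos in range(p1 - n_flank + 1, p1 + n_flank + 1):
            aa = protein.residue(pos)
            residues.append(aa if aa != "-" else GAP)
        windows.append(SiteWindow(tuple(residues), n_flank=n_flank))
    return windows


def _validate_background(background: dict[str, float] | None) -> pd.Series:
    comp = pd.Series(background or HUMAN_SWISSPROT_COMPOSITION, dtype=float)
    missing = set(AMINO_ACIDS) - set(comp.index)
    if missing or (comp < 0).any():
        raise ValueError(f"malformed background composition (missing {sorted(missing)})")
    comp = comp.reindex(list(AMINO_ACIDS))
    total = comp.sum()
    if not np.isclose(total, 100.0, atol=1.0):
        raise ValueError(f"background must sum to ~100%, got {total:.2f}")
    return comp / total * 100.0


def positional_enrichment(
    windows: Sequence[SiteWindow],
    background: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> SpecificityMatrix:
    """Observed %, difference vs background and binomial significance per position.

    Significance uses the two-sided normal approximation to the binomial with
    p0 = background/100 and n = number of non-gap residues at the position,
    evaluated independently per residue/position pair at level ``alpha``.
    """
    if not windows:
        raise ValueError("need at least one window")
    n_flank = windows[0].n_flank
    if any(w.n_flank != n_flank for w in windows):
        raise ValueError("windows have mixed flank widths")
    comp = _validate_background(background)
    labels = position_labels(n_flank)

    counts = pd.DataFrame(0, index=labels, columns=list(AMINO_ACIDS), dtype=float)
    n_pos = pd.Series(0, index=labels, dtype=int)
    for w in windows:
        for label, aa in zip(labels, w.residues):
            if aa == GAP:
                continue
            counts.loc[label, aa] += 1
            n_pos[label] += 1

    observed = counts.div(n_pos, axis=0) * 100.0
    bg = pd.DataFrame(
        np.tile(comp.to_numpy(), (len(labels), 1)), index=labels, columns=list(AMINO_ACIDS)
    )
    difference = observed - bg

    p0 = bg / 100.0
    phat = observed / 100.0
    n = n_pos.to_numpy()[:, None].astype(float)
    se = np.sqrt(p0 * (1.0 - p0) / n)
    zstat = (phat - p0) / se
    pvalues = pd.DataFrame(
        2.0 * norm.sf(np.abs(zstat.to_numpy())), index=labels, columns=list(AMINO_ACIDS)
    )
    significant = pvalues < alpha
    return SpecificityMatrix(
        observed=observed,
        background=bg,
        difference=difference,
        pvalues=pvalues,
        significant=significant,
        n_windows=n_pos,
        alpha=alpha,
    )


def consensus_report(matrix: SpecificityMatrix, top_k: int = 3) -> pd.DataFrame:
    """Significant residues per position, ranked by enrichment difference.

    Returns a tidy frame (position, rank, residue, observed %, difference %,
    p-value) restricted to significantly enriched residues (difference > 0),
    at most ``top_k`` per position.
    """
    rows = []
    for label in matrix.observed.index:
        enriched = [
            (aa, matrix.difference.loc[label, aa], matrix.observed.loc[label, aa],
             matrix.pvalues.loc[label, aa])
            for aa in matrix.observed.columns
            if matrix.significant.loc[label, aa] and matrix.difference.loc[label, aa] > 0
        ]
        enriched.sort(key=lambda item: (-item[1], item[0]))
        for rank, (aa, diff, obs, p) in enumerate(enriched[:top_k], start=1):
            rows.append((label, rank, aa, obs, diff, p))
    return pd.DataFrame(
        rows, columns=["position", "rank", "residue", "observed_pct", "difference_pct", "pvalue"]
    )


def render_text_logo(matrix: SpecificityMatrix, top_k: int = 3) -> str:
    """Plain-text logo-like summary: one line per position."""
    report = consensus_report(matrix, top_k=top_k)
    lines = []
    for label in matrix.observed.index:
        hits = report[report.position == label]
        cells = " ".join(
            f"{r.residue}(+{r.difference_pct:.1f}%)" for r in hits.itertuples()
        )
        lines.append(f"{label:>4}: {cells or '.'}")
    return "\n".join(lines)


class SpecificityProfiler(BaseEstimator):
    """Positional specificity profiler over a cleavage-site collection.

    Parameters: ``n_flank`` (window half-width, default 4 for P4-P4'),
    ``alpha`` (per-cell significance level), ``background`` (composition in %,
    default embedded human Swiss-Prot table). After :meth:`fit`: ``matrix_``
    (:class:`SpecificityMatrix`) and ``windows_``.
    """

    def __init__(
        self,
        n_flank: int = 4,
        alpha: float = 0.05,
        background: dict[str, float] | None = None,
    ):
        self.n_flank = n_flank
        self.alpha = alpha
        self.background = background

    def fit(
        self,
        sites: Iterable[SiteCall] | Sequence[SiteWindow],
        proteins: dict[str, ProteinRecord] | ProteinRecord | None = None,
    ) -> "SpecificityProfiler":
        sites = list(sites)
        if sites and isinstance(sites[0], SiteWindow):
            windows = list(sites)
        else:
            if proteins is None:
                raise ValueError("proteins required when fitting from SiteCall objects")
            windows = extract_windows(sites, proteins, n_flank=self.n_flank)
        self.windows_ = windows
        self.matrix_ = positional_enrichment(
            windows, background=self.background, alpha=self.alpha
        )
        return self

    def consensus(self, top_k: int = 3) -> pd.DataFrame:
        return consensus_report(self.matrix_, top_k=top_k)
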