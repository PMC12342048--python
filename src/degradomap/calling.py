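"""Cleavage-site calling from paired active/inactive-enzyme peptide quantification.

The procedure mirrors the degradomics design in which a substrate is digested
with an active protease and, in parallel, with a catalytically inactive (EQ)
control, trypsinized, and quantified by label-free LC-MS/MS:

1. abundance ratios active/control are computed per unique peptide, with
   peptides detected in only one arm ("singletons") given an arbitrary ratio
   of 100 (log2 100 = 6.64);
2. z-scores are the number of standard deviations of a peptide's log2 ratio
   from the mean log2 ratio of peptides found in both arms;
3. semi-tryptic peptides that are active-arm singletons or have z above a
   threshold are candidate proteolytic products; the non-tryptic terminus of
   each candidate defines a P1-P1' cleavage site;
4. fully tryptic peptides spanning a called boundary whose abundance moves the
   converse way (control-arm singleton or high converse z) corroborate it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .sequence import (
    TERMINUS,
    PeptideSpan,
    ProteinRecord,
    classify_termini_from_context,
    locate_peptide,
    peptide_status,
)

__all__ = [
    "PeptideObservation",
    "RatioRecord",
    "SiteCall",
    "aggregate_observations",
    "compute_ratios",
    "compute_zscores",
    "annotate_tryptic_status",
    "localize_records",
    "select_candidates",
    "call_cleavage_sites",
    "find_spanning_evidence",
    "compare_site_sets",
    "CleavageSiteCaller",
]

SINGLETON_RATIO = 100.0


@dataclass(frozen=True)
class PeptideObservation:
    """One quantified peptide row: sequence, termini context, two abundances."""

    peptide: str
    preceding: str = TERMINUS
    following: str = TERMINUS
    abundance_active: float | None = None
    abundance_control: float | None = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("peptide must be non-empty")
        for name in ("abundance_active", "abundance_control"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if self.abundance_active is None and self.abundance_control is None:
            raise ValueError("at least one abundance must be present")


@dataclass
class RatioRecord:
    """A unique peptide with its ratio, z-scores and tryptic annotation.

    Ratios are kept on both directed scales: ``ratio`` is active/control
    (semi-tryptic discovery scale) and ``ratio_converse`` is control/active
    (tryptic corroboration scale). Singletons carry the arbitrary ratio 100 on
    the scale of the arm in which they were detected and are undefined (None)
    on the other scale.
    """

    peptide: str
    preceding: str
    following: str
    detection_class: Literal["both", "active_only", "control_only"]
    abundance_active: float | None
    abundance_control: float | None
    ratio: float | None = None
    log2_ratio: float | None = None
    ratio_converse: float | None = None
    log2_ratio_converse: float | None = None
    z: float | None = None
    z_converse: float | None = None
    tryptic_status: Literal["fully", "semi", "non"] | None = None
    nontryptic_side: Literal["N", "C"] | None = None
    spans: list[PeptideSpan] = field(default_factory=list)

    @property
    def span(self) -> PeptideSpan | None:
        """Primary (first) localization, or None when the peptide is unplaced."""
        return self.spans[0] if self.spans else None


@dataclass
class SiteCall:
    """A called P1-P1' cleavage site with its peptide evidence."""

    accession: str
    p1_position: int
    p1_residue: str
    p1prime_residue: str
    region_label: str = ""
    supporting_semitryptic: list[RatioRecord] = field(default_factory=list)
    spanning_tryptic: list[tuple[RatioRecord, bool]] = field(default_factory=list)

    @property
    def p1prime_position(self) -> int:
        return self.p1_position + 1

    @property
    def label(self) -> str:
        return f"{self.p1_residue}{self.p1_position}-{self.p1prime_residue}{self.p1prime_position}"

    @property
    def max_z(self) -> float | None:
        zs = [r.z for r in self.supporting_semitryptic if r.z is not None]
        return max(zs) if zs else None

    @property
    def n_corroborating(self) -> int:
        return sum(flag for _, flag in self.spanning_tryptic)


def aggregate_observations(
    rows: Iterable[PeptideObservation], abundance_floor: float = 0.0
) -> list[PeptideObservation]:
    """Collapse duplicate rows (e.g. charge states) of the same unique peptide.

    Rows sharing (peptide, preceding, following) are merged by summing the
    per-condition abundances. Abundances at or below ``abundance_floor``
    (default 0) count as not detected.
    """
    sums: dict[tuple[str, str, str], list[float]] = {}
    order: list[tuple[str, str, str]] = []
    for row in rows:
        key = (row.peptide.upper(), row.preceding.upper(), row.following.upper())
        if key not in sums:
            sums[key] = [0.0, 0.0]
            order.append(key)
        if row.abundance_active is not None:
            sums[key][0] += row.abundance_active
        if row.abundance_control is not None:
            sums[key][1] += row.abundance_control
    out = []
    for key in order:
        active, control = sums[key]
        out.append(
            PeptideObservation(
                *key,
                abundance_active=active if active > abundance_floor else None,
                abundance_control=control if control > abundance_floor else None,
            )
        )
    return out


def compute_ratios(
    quants: Iterable[PeptideObservation], singleton_ratio: float = SINGLETON_RATIO
) -> list[RatioRecord]:
    """Per-peptide abundance ratios with the singleton convention.

    Peptides found in both arms get ratio = active/control (and its converse);
    active-only peptides get exactly ``singleton_ratio`` (default 100, log2 =
    6.64) on the active/control scale, control-only peptides the same on the
    converse scale. Rows with no usable abundance are rejected with a warning.
    """
    records: list[RatioRecord] = []
    for q in quants:
        a, c = q.abundance_active, q.abundance_control
        if (a is None or a <= 0) and (c is None or c <= 0):
            warnings.warn(f"peptide {q.peptide}: no abundance in either arm; dropped")
            continue
        rec = RatioRecord(
            peptide=q.peptide.upper(),
            preceding=q.preceding.upper(),
            following=q.following.upper(),
            detection_class="both",
            abundance_active=a,
            abundance_control=c,
        )
        if a is not None and a > 0 and c is not None and c > 0:
            rec.ratio = a / c
            rec.ratio_converse = c / a
        elif a is not None and a > 0:
            rec.detection_class = "active_only"
            rec.ratio = singleton_ratio
        else:
            rec.detection_class = "control_only"
            rec.ratio_converse = singleton_ratio
        if rec.ratio is not None:
            rec.log2_ratio = math.log2(rec.ratio)
        if rec.ratio_converse is not None:
            rec.log2_ratio_converse = math.log2(rec.ratio_converse)
        records.append(rec)
    return records


def _both_group_stats(
    records: Sequence[RatioRecord], scope: str, ddof: int
) -> tuple[float, float]:
    attr = "log2_ratio" if scope == "active" else "log2_ratio_converse"
    values = np.array(
        [getattr(r, attr) for r in records if r.detection_class == "both"]
    )
    if values.size < 2:
        raise ValueError(
            f"need >= 2 both-group peptides on the {scope} scale, got {values.size}"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=ddof))
    if sd == 0:
        raise ValueError("degenerate ratio distribution: both-group sd is zero")
    return mean, sd


def compute_zscores(
    records: Sequence[RatioRecord],
    scope: Literal["active", "control", "both_scales"] = "both_scales",
    ddof: int = 1,
) -> dict[str, tuple[float, float]]:
    """Fill z-scores in place; returns {scale: (mean, sd)} of the both-group log2 ratios.

    The mean and standard deviation are estimated from peptides found in both
    arms only; every record with a defined log2 ratio on the scale — including
    singletons at log2(100) — is then assigned z = (log2_ratio - mean) / sd.
    ``ddof=1`` uses the sample standard deviation.
    """
    scopes = ("active", "control") if scope == "both_scales" else (scope,)
    stats: dict[str, tuple[float, float]] = {}
    for sc in scopes:
        mean, sd = _both_group_stats(records, sc, ddof)
        stats[sc] = (mean, sd)
        for rec in records:
            value = rec.log2_ratio if sc == "active" else rec.log2_ratio_converse
            if value is None:
                continue
            z = (value - mean) / sd
            if sc == "active":
                rec.z = z
            else:
                rec.z_converse = z
    return stats


def annotate_tryptic_status(
    records: Iterable[RatioRecord], proline_rule: bool = True
) -> None:
    """Classify each record as fully/semi/non-tryptic from its termini context."""
    for rec in records:
        n_term, c_term = classify_termini_from_context(
            rec.peptide, rec.preceding, rec.following, proline_rule=proline_rule
        )
        rec.tryptic_status = peptide_status(n_term, c_term)
        if rec.tryptic_status == "semi":
            rec.nontryptic_side = "N" if n_term.status == "nontryptic" else "C"


def localize_records(
    records: Iterable[RatioRecord], protein: ProteinRecord, warn_ambiguous: bool = True
) -> None:
    """Attach exact-match spans on the substrate to each record.

    When a peptide occurs more than once (internal repeats), all spans are
    kept, downstream calling uses the first, and a warning lists the
    alternatives. A peptide whose recorded flanking residues disagree with the
    sequence at a span is not matched to that span.
    """
    for rec in records:
        spans = locate_peptide(protein, rec.peptide)
        # Prefer spans whose flanking residues agree with the recorded context.
        strict = [
            s
            for s in spans
            if s.preceding == rec.preceding and s.following == rec.following
        ]
        rec.spans = strict or spans
        if warn_ambiguous and len(rec.spans) > 1:
            alternatives = ", ".join(f"{s.start}-{s.end}" for s in rec.spans[1:])
            warnings.warn(
                f"peptide {rec.peptide} occurs at multiple spans; using "
                f"{rec.spans[0].start}-{rec.spans[0].end}, alternatives: {alternatives}"
            )


def select_candidates(
    records: Iterable[RatioRecord], z_threshold: float = 2.0
) -> tuple[list[RatioRecord], list[RatioRecord]]:
    """Semi-tryptic site candidates and separately flagged non-tryptic records.

    Candidates are semi-tryptic peptides that are active-arm singletons
    (selected regardless of z) or both-group with z strictly above the
    threshold. Records with both termini non-tryptic are returned separately:
    they are not used for site calling but never silently dropped.
    """
    candidates, nontryptic = [], []
    for rec in records:
        if rec.tryptic_status is None:
            raise ValueError("records must be annotated with tryptic status first")
        if rec.tryptic_status == "non":
            nontryptic.append(rec)
            continue
        if rec.tryptic_status != "semi":
            continue
        if rec.detection_class == "active_only" or (
            rec.detection_class == "both" and rec.z is not None and rec.z > z_threshold
        ):
            candidates.append(rec)
    return candidates, nontryptic


def _record_sort_key(rec: RatioRecord) -> tuple[float, str]:
    ratio = rec.ratio if rec.ratio is not None else rec.ratio_converse or 0.0
    return (-ratio, rec.peptide)


def call_cleavage_sites(
    candidates: Iterable[RatioRecord], protein: ProteinRecord
) -> list[SiteCall]:
    """Derive deduplicated P1-P1' sites from candidate semi-tryptic peptides.

    The non-tryptic terminus of each localized candidate defines the boundary:
    a non-tryptic N-terminus at start s gives site (s-1, s); a non-tryptic
    C-terminus at end e gives site (e, e+1). Boundaries falling on a protein
    terminus are rejected (not proteolytic evidence), duplicate boundaries are
    merged, and output is sorted by P1 position.
    """
    sites: dict[int, SiteCall] = {}
    for rec in candidates:
        if rec.tryptic_status != "semi" or rec.nontryptic_side is None:
            warnings.warn(f"peptide {rec.peptide}: not semi-tryptic; skipped")
            continue
        span = rec.span
        if span is None:
            warnings.warn(f"peptide {rec.peptide}: not localized on {protein.accession}")
            continue
        p1 = span.start - 1 if rec.nontryptic_side == "N" else span.end
        if p1 < 1 or p1 >= len(protein):
            warnings.warn(
                f"peptide {rec.peptide}: boundary at protein terminus; rejected"
            )
            continue
        site = sites.get(p1)
        if site is None:
            site = SiteCall(
                accession=protein.accession,
                p1_position=p1,
                p1_residue=protein.residue(p1),
                p1prime_residue=protein.residue(p1 + 1),
            )
            sites[p1] = site
        site.supporting_semitryptic.append(rec)
        # invariant: the candidate's non-tryptic terminus coincides with the boundary
        boundary_residue = span.start if rec.nontryptic_side == "N" else span.end
        assert boundary_residue in (p1, p1 + 1)
    out = sorted(sites.values(), key=lambda s: s.p1_position)
    for site in out:
        site.supporting_semitryptic.sort(key=_record_sort_key)
    return out


def find_spanning_evidence(
    site: SiteCall,
    records: Iterable[RatioRecord],
    protein: ProteinRecord,
    z_threshold: float = 2.0,
) -> SiteCall:
    """Attach fully tryptic peptides strictly containing the site boundary.

    A spanning peptide must start at or before P1 and end at or after P1'
    (a peptide ending exactly at P1, or starting at P1', does not span the
    scissile bond). It is marked corroborating when it is a control-arm
    singleton or its converse (control/active) z exceeds the threshold.
    """
    site.spanning_tryptic = []
    p1 = site.p1_position
    for rec in records:
        if rec.tryptic_status != "fully":
            continue
        span = rec.span
        if span is None or span.protein.accession != protein.accession:
            continue
        if not (span.start <= p1 and span.end >= p1 + 1):
            continue
        corroborating = rec.detection_class == "control_only" or (
            rec.z_converse is not None and rec.z_converse > z_threshold
        )
        site.spanning_tryptic.append((rec, corroborating))
    site.spanning_tryptic.sort(key=lambda pair: _record_sort_key(pair[0]))
    return site


def compare_site_sets(
    a: Sequence[SiteCall], b: Sequence[SiteCall]
) -> tuple[list[SiteCall], list[SiteCall], list[SiteCall]]:
    """(shared, only_a, only_b) by (accession, P1 position), position-sorted.

    Shared sites are reported with the evidence of set ``a``. Raises when the
    two sets are on different substrates.
    """
    accs = {s.accession for s in a} | {s.accession for s in b}
    if len(accs) > 1:
        raise ValueError(f"site sets span different substrates: {sorted(accs)}")
    keys_a = {(s.accession, s.p1_position) for s in a}
    keys_b = {(s.accession, s.p1_position) for s in b}
    by_pos = lambda s: s.p1_position
    shared = sorted((s for s in a if (s.accession, s.p1_position) in keys_b), key=by_pos)
    only_a = sorted((s for s in a if (s.accession, s.p1_position) not in keys_b), key=by_pos)
    only_b = sorted((s for s in b if (s.accession, s.p1_position) not in keys_a), key=by_pos)
    return shared, only_a, only_b


class CleavageSiteCaller(BaseEstimator):
    """End-to-end cleavage-site caller over a paired quantification table.

    Parameters
    ----------
    z_threshold : float, default 2.0
        Strict z cutoff for both-group significance, on either directed scale.
    proline_rule : bool, default True
        Whether trypsin is assumed not to cleave before proline.
    singleton_ratio : float, default 100.0
        Arbitrary ratio assigned to peptides detected in a single arm.
    ddof : int, default 1
        Degrees-of-freedom correction for the both-group standard deviation
        (1 = sample sd).
    abundance_floor : float, default 0.0
        Abundances at or below this value count as not detected.

    Attributes (after :meth:`fit`)
    ------------------------------
    records_ : list of RatioRecord — all unique peptides, annotated.
    sites_ : list of SiteCall — called sites with spanning evidence, sorted.
    candidates_ : list of RatioRecord — selected semi-tryptic candidates.
    nontryptic_ : list of RatioRecord — both-termini-non-tryptic records.
    control_enriched_ : list of RatioRecord — semi-tryptic peptides significant
        on the converse scale (control-arm singletons or converse z above the
        threshold); reported, never suppressed.
    scale_stats_ : dict — both-group log2 mean/sd per directed scale.
    """

    def __init__(
        self,
        z_threshold: float = 2.0,
        proline_rule: bool = True,
        singleton_ratio: float = SINGLETON_RATIO,
        ddof: int = 1,
        abundance_floor: float = 0.0,
    ):
        self.z_threshold = z_threshold
        self.proline_rule = proline_rule
        self.singleton_ratio = singleton_ratio
        self.ddof = ddof
        self.abundance_floor = abundance_floor

    def fit(
        self, observations: Iterable[PeptideObservation], protein: ProteinRecord
    ) -> "CleavageSiteCaller":
        quants = aggregate_observations(observations, self.abundance_floor)
        records = compute_ratios(quants, singleton_ratio=self.singleton_ratio)
        annotate_tryptic_status(records, proline_rule=self.proline_rule)
        self.scale_stats_ = compute_zscores(records, "both_scales", ddof=self.ddof)
        localize_records(records, protein)
        candidates, nontryptic = select_candidates(records, self.z_threshold)
        sites = call_cleavage_sites(candidates, protein)
        for site in sites:
            find_spanning_evidence(site, records, protein, self.z_threshold)
        self.protein_ = protein
        self.records_ = records
        self.candidates_ = candidates
        self.nontryptic_ = nontryptic
        self.control_enriched_ = [
            r
            for r in records
            if r.tryptic_status == "semi"
            and (
                r.detection_class == "control_only"
                or (r.z_converse is not None and r.z_converse > self.z_threshold)
            )
        ]
        self.sites_ = sites
        return self

    def site_positions(self) -> list[int]:
        return [s.p1_position for s in self.sites_]
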