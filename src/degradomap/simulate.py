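"""Seeded generators emulating a paired-protease degradomics study and its kinetics.

The degradome generator emulates the data-generating process of a substrate
digested by an active protease and by its inactive control, then trypsinized
and quantified: fully tryptic peptides detected in both arms with log2
abundance ratios centred near zero; semi-tryptic peptides arising from
injected cleavage events, mostly as active-arm singletons; and fully tryptic
peptides spanning an injected site depleted from (or absent in) the active
arm. A machine-readable truth record accompanies every table so callers can
be scored mechanically.

Kinetic generators sample the progress-curve and Morrison models with
Gaussian noise. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calling import PeptideObservation
from .kinetics import InhibitionSeries, ProgressCurve, morrison_velocity, progress_fraction
from .sequence import ProteinRecord, cleavage_positions, tryptic_digest

__all__ = [
    "DegradomeSimConfig",
    "ProgressSimConfig",
    "InhibitionSimConfig",
    "make_substrate",
    "simulate_degradome",
    "simulate_progress_curves",
    "simulate_inhibition_series",
]

TRUTH_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class DegradomeSimConfig:
    """Conditions for one simulated paired digest.

    The both-group log2 ratio noise has mean 0 and sd 2 by default — the
    spread of a real paired digest's both-group population (the empirical
    z-score scale implies a log2 sd close to 2). Injected protease products
    are active-arm singletons with probability ``singleton_fraction`` (the
    dominant mode in practice), otherwise both-group with a large positive
    log2 shift. Tryptic peptides spanning an injected site drop out of the
    active arm with probability ``control_spanning_dropout``, else are
    depleted by the converse shift.
    """

    substrate: ProteinRecord | None = None
    length: int = 400
    n_sites: int = 5
    injected_sites: tuple[int, ...] | None = None
    site_efficiency: float = 0.9
    max_missed: int = 3
    proline_rule: bool = True
    both_group_log2_mean: float = 0.0
    both_group_log2_sd: float = 2.0
    singleton_fraction: float = 0.95
    enriched_log2_shift: float = 6.64
    control_spanning_dropout: float = 0.8
    semi_background_rate: float = 0.05
    tryptic_detection_rate: float = 0.6
    min_peptide_length: int = 6
    base_intensity: float = 1.0e6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "site_efficiency",
            "singleton_fraction",
            "control_spanning_dropout",
            "semi_background_rate",
            "tryptic_detection_rate",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.both_group_log2_sd <= 0:
            raise ValueError("both_group_log2_sd must be > 0")
        if self.substrate is not None and self.injected_sites is not None:
            n = len(self.substrate)
            if any(not 1 < p < n - 1 for p in self.injected_sites):
                raise ValueError("injected sites must lie strictly inside the substrate")


@dataclass(frozen=True)
class ProgressSimConfig:
    """Progress-curve assay design: enzyme at ``enzyme_conc`` (M), sampled on
    ``times`` (s), noise sd on the cleaved fraction, replicates."""

    kcat_km: float = 2.4e5  # M^-1 s^-1
    enzyme_conc: float = 5.5e-9  # M
    times: tuple[float, ...] = (0.0, 200.0, 400.0, 600.0, 800.0, 1000.0, 1200.0)
    noise_sd: float = 0.02
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.times:
            raise ValueError("time grid must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class InhibitionSimConfig:
    """Tight-binding titration design: enzyme ``Et`` (M), inhibitor grid (M),
    Gaussian noise on vi/v0.

    The default grid spans 0-8 nM with points concentrated around ``Et``,
    where a tight-binding titration is informative about Ki, and each reported
    point is the mean of ``technical_replicates`` noisy measurements (the
    usual duplicate-well plate layout)."""

    ki: float = 45.0e-12  # M
    Et: float = 0.2e-9  # M
    inhibitor_concs: tuple[float, ...] = (
        0.0, 0.025e-9, 0.05e-9, 0.1e-9, 0.15e-9, 0.2e-9, 0.25e-9,
        0.3e-9, 0.4e-9, 0.6e-9, 1.0e-9, 2.0e-9, 4.0e-9, 8.0e-9,
    )
    noise_sd: float = 0.03
    technical_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inhibitor_concs:
            raise ValueError("inhibitor grid must be non-empty")
        if 0.0 not in self.inhibitor_concs:
            raise ValueError("inhibitor grid must include 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


_COMPOSITION_DEFAULT = {
    # loosely globular-protein-like; K+R ~11% so tryptic fragments average ~9 aa
    "A": 8, "C": 2, "D": 5, "E": 6, "F": 4, "G": 7, "H": 2, "I": 5, "K": 6,
    "L": 9, "M": 2, "N": 4, "P": 5, "Q": 4, "R": 5, "S": 7, "T": 5, "V": 7,
    "W": 1, "Y": 3,
}


def make_substrate(
    length: int = 400,
    seed: int = 0,
    composition: dict[str, float] | None = None,
    accession: str = "SYN-SUBSTRATE",
) -> ProteinRecord:
    """Random substrate with at least one K/R per 30 residues.

    Reproducible for a given seed. A composition with zero K and R weight is
    rejected because the tryptic digest would be degenerate.
    """
    if length < 20:
        raise ValueError("substrate length must be >= 20")
    comp = composition or _COMPOSITION_DEFAULT
    letters = sorted(comp)
    weights = np.array([comp[aa] for aa in letters], dtype=float)
    if weights.sum() <= 0 or comp.get("K", 0) + comp.get("R", 0) <= 0:
        raise ValueError("composition must give non-zero K/R probability")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(letters, size=length, p=weights / weights.sum()))
    # guarantee digestibility: inject a K into any 30-residue window without K/R
    for win_start in range(0, length, 30):
        window = seq[win_start : win_start + 30]
        if not any(aa in "KR" for aa in window):
            seq[win_start + int(rng.integers(0, len(window)))] = "K"
    return ProteinRecord(accession, "".join(seq), description="synthetic substrate")


def _pick_sites(protein: ProteinRecord, n_sites: int, rng: np.random.Generator) -> list[int]:
    """P1 positions strictly inside the substrate whose P1 residue is not K/R."""
    n = len(protein)
    valid = [
        p
        for p in range(10, n - 10)
        if protein.residue(p) not in "KR" and protein.residue(p + 1) not in "KR"
    ]
    if len(valid) < n_sites:
        raise ValueError("substrate too short for requested number of sites")
    chosen = rng.choice(len(valid), size=n_sites, replace=False)
    return sorted(valid[i] for i in chosen)


def simulate_degradome(
    config: DegradomeSimConfig, seed: int | None = None
) -> tuple[list[PeptideObservation], dict]:
    """Simulate one paired quant table plus its truth record.

    Returns (observations, truth) where truth is a versioned JSON-ready dict
    listing the injected sites and every piece of generated evidence.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    protein = config.substrate or make_substrate(config.length, seed=seed + 1)
    if config.injected_sites is not None:
        sites = sorted(config.injected_sites)
        bad = [p for p in sites if protein.residue(p) in "KR"]
        if bad:
            raise ValueError(f"injected P1 positions on K/R (would look tryptic): {bad}")
    else:
        sites = _pick_sites(protein, config.n_sites, rng)

    cuts = [0] + cleavage_positions(protein.sequence, config.proline_rule) + [len(protein)]

    def draw_control() -> float:
        return float(np.exp(rng.normal(math.log(config.base_intensity), 0.7)))

    def noise() -> float:
        return float(rng.normal(config.both_group_log2_mean, config.both_group_log2_sd))

    observations: list[PeptideObservation] = []
    spanning_overrides: dict[tuple[int, int], str] = {}
    truth_sites = []

    # --- injected cleavage events ---
    for p1 in sites:
        detected = bool(rng.random() < config.site_efficiency)
        products = []
        if detected:
            upstream = [c for c in cuts if c < p1]
            downstream = [c for c in cuts if c >= p1 + 1]
            m_left = int(rng.integers(0, config.max_missed + 1))
            m_right = int(rng.integers(0, config.max_missed + 1))
            left = (upstream[max(0, len(upstream) - 1 - m_left)] + 1, p1)
            right = (p1 + 1, downstream[min(len(downstream) - 1, m_right)])
            for start, end in (left, right):
                if end - start + 1 < config.min_peptide_length:
                    continue
                peptide = protein.slice(start, end)
                prec, foll = protein.residue(start - 1), protein.residue(end + 1)
                if rng.random() < config.singleton_fraction:
                    cls = "active_only"
                    obs = PeptideObservation(
                        peptide, prec, foll,
                        abundance_active=draw_control(), abundance_control=None,
                    )
                else:
                    cls = "both"
                    ctrl = draw_control()
                    obs = PeptideObservation(
                        peptide, prec, foll,
                        abundance_active=ctrl * 2.0 ** (config.enriched_log2_shift + noise()),
                        abundance_control=ctrl,
                    )
                observations.append(obs)
                products.append(
                    {"peptide": peptide, "span": [start, end], "detection_class": cls}
                )
        truth_sites.append(
            {
                "p1": p1,
                "p1_residue": protein.residue(p1),
                "p1prime_residue": protein.residue(p1 + 1),
                "detected": detected,
                "semi_peptides": products,
                "spanning": [],
            }
        )

    # --- both-group tryptic background (with spanning-peptide perturbation) ---
    digest = tryptic_digest(protein, config.max_missed, config.proline_rule)
    for span in digest:
        if len(span) < config.min_peptide_length:
            continue
        if rng.random() >= config.tryptic_detection_rate:
            continue
        spanned = [t for t in truth_sites if span.start <= t["p1"] < span.end]
        ctrl = draw_control()
        if spanned and rng.random() < config.control_spanning_dropout:
            cls = "control_only"
            obs = PeptideObservation(
                span.peptide, span.preceding, span.following,
                abundance_active=None, abundance_control=ctrl,
            )
        elif spanned:
            cls = "both_depleted"
            obs = PeptideObservation(
                span.peptide, span.preceding, span.following,
                abundance_active=ctrl * 2.0 ** (-config.enriched_log2_shift + noise()),
                abundance_control=ctrl,
            )
        else:
            cls = "both"
            obs = PeptideObservation(
                span.peptide, span.preceding, span.following,
                abundance_active=ctrl * 2.0 ** noise(), abundance_control=ctrl,
            )
        observations.append(obs)
        for t in spanned:
            t["spanning"].append(
                {"peptide": span.peptide, "span": [span.start, span.end], "detection_class": cls}
            )
        # occasional spurious semi-tryptic peptide with null ratio
        if rng.random() < config.semi_background_rate:
            semi = _truncate_semi(protein, span, config.min_peptide_length, rng)
            if semi is not None:
                start, end = semi
                ctrl2 = draw_control()
                observations.append(
                    PeptideObservation(
                        protein.slice(start, end),
                        protein.residue(start - 1),
                        protein.residue(end + 1),
                        abundance_active=ctrl2 * 2.0 ** noise(),
                        abundance_control=ctrl2,
                    )
                )

    truth = {
        "version": TRUTH_SCHEMA_VERSION,
        "seed": seed,
        "substrate": {"accession": protein.accession, "length": len(protein)},
        "sites": truth_sites,
    }
    return observations, truth


def _truncate_semi(
    protein: ProteinRecord,
    span,
    min_len: int,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Random one-sided truncation of a tryptic span into a semi-tryptic span."""
    candidates: list[tuple[int, int]] = []
    for start in range(span.start + 1, span.end - min_len + 2):
        if protein.residue(start - 1) not in "KR":  # ragged N-terminus
            candidates.append((start, span.end))
    for end in range(span.start + min_len - 1, span.end):
        if protein.residue(end) not in "KR":  # ragged C-terminus
            candidates.append((span.start, end))
    if not candidates:
        return None
    return candidates[int(rng.integers(0, len(candidates)))]


def simulate_progress_curves(
    config: ProgressSimConfig, seed: int | None = None
) -> list[ProgressCurve]:
    """Noisy progress curves from the single-exponential depletion model."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    times = np.asarray(config.times, dtype=float)
    curves = []
    for rep in range(config.replicates):
        P = progress_fraction(config.enzyme_conc, times, config.kcat_km)
        if config.noise_sd > 0:
            P = P + rng.normal(0.0, config.noise_sd, size=times.size)
        curves.append(
            ProgressCurve(
                enzyme_conc=config.enzyme_conc,
                times=times,
                fraction_cleaved=np.clip(P, 0.0, 1.05),
                replicate=rep,
            )
        )
    return curves


def simulate_inhibition_series(
    config: InhibitionSimConfig, seed: int | None = None
) -> InhibitionSeries:
    """Noisy tight-binding inhibition series from the Morrison model."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    I = np.asarray(config.inhibitor_concs, dtype=float)
    v = morrison_velocity(config.Et, I, config.ki)
    if config.noise_sd > 0:
        n_rep = max(1, config.technical_replicates)
        measured = v[None, :] + rng.normal(0.0, config.noise_sd, size=(n_rep, I.size))
        v = np.clip(measured, 0.0, 1.05).mean(axis=0)
    return InhibitionSeries(
        Et=config.Et, inhibitor_concs=I, vi_over_v0=np.clip(v, 0.0, 1.05)
    )
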