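# Methods

## The problem and the approach

A protease digest of a purified substrate, run in parallel with a digest by a
catalytically inactive (E→Q) variant of the same protease, then trypsinized
and quantified by label-free LC-MS/MS, yields a peptide table in which
protease-generated cleavage events leave two complementary signatures:

* **semi-tryptic peptides** — peptides with exactly one terminus conforming to
  trypsin specificity — that are strongly enriched in (or exclusive to) the
  active-enzyme arm; their non-tryptic terminus marks the scissile bond; and
* **fully tryptic peptides spanning the bond** that are depleted from the
  active arm (the converse ratio), corroborating the site.

`degradomap` implements this caller, plus the positional specificity profile
of a site collection and the two kinetic models used to characterize the
protease (single-exponential progress curves for k<sub>cat</sub>/K<sub>m</sub>
and the Morrison equation for tight-binding K<sub>i</sub>), with seeded
generators standing in for raw mass-spectrometry and plate-reader data.

## Ratio, z-score and selection conventions

For each unique peptide (identified by sequence plus preceding/following
residues; duplicate rows such as charge states are summed per condition), the
abundance ratio active/control is computed. Peptides detected in only one arm
("singletons") receive the arbitrary ratio 100 (log₂ 100 = 6.64) on the scale
of their arm. Both directed scales — active/control for discovery,
control/active for corroboration — are maintained in one pass.

z-scores are computed on **log₂ ratios**: the mean and standard deviation are
estimated from the peptides found in **both** arms only (sample sd, n−1;
configurable), and every record with a defined ratio on the scale — including
singletons — gets z = (log₂r − mean)/sd. The log₂ scale is forced by internal
consistency: a published table in which ratio 100 maps to z 3.37 and ratio
142.61 to z 3.63 is affine-consistent only on a log scale with both-group
mean ≈ 0 (sd ≈ 1.97); solving the same pair of equations on the raw-ratio
scale gives an impossible negative mean ratio.

Candidates for site calling are semi-tryptic peptides that are active-arm
singletons (selected regardless of z) or both-group with z strictly above the
threshold (default 2). Non-tryptic peptides (both termini non-tryptic) and
control-enriched semi-tryptic peptides are reported in separate outputs,
never silently dropped.

## Site calling

Peptides are localized on the substrate by exact match, with 1-based
precursor numbering (signal peptide included) so published site labels such
as S77-V78 can be compared directly. A non-tryptic N-terminus at start *s*
calls site (*s*−1, *s*); a non-tryptic C-terminus at end *e* calls (*e*,
*e*+1). Boundaries at the protein termini are rejected: a peptide ending at
the mature terminus is not proteolytic evidence (such termini are classified
`protein_terminus`, distinct from both tryptic and non-tryptic). Duplicate
boundaries merge into one site accumulating all supporting peptides; sites
are sorted by P1 position and peptides within a site by descending ratio then
lexicographically, so reports are deterministic. For repeated peptides
(substrates with internal repeats) all spans are kept, the first is used for
calling, and a warning lists the alternatives; spans whose flanking residues
match the recorded context are preferred.

Spanning evidence: a fully tryptic peptide corroborates a site when its span
strictly contains the P1–P1′ bond (ending exactly at P1 or starting at P1′
does not count) and it is a control-arm singleton or has converse z above the
threshold.

Trypsin specificity is cleavage C-terminal to K/R; "no cleavage before
proline" is ON by default but exposed as a flag, because search engines
differ and the published tables do not pin the setting down.

## Specificity profiling

Sites are expanded into P4–P4′ windows (configurable width; gap-padded at
substrate termini; P1/P1′ always present). Per position, observed residue
frequencies (%) are compared against a background composition — an embedded
human Swiss-Prot average table by default, user-overridable, because the
online reference set is a moving resource. Significance per residue/position
uses the two-sided normal approximation to the binomial (p₀ = background/100,
n = non-gap count) at α = 0.05 with no multiple-testing correction, mirroring
percentage-scoring logo tools. The consensus report lists significantly
enriched residues per position ranked by frequency difference.

## Kinetics

* **Progress model**: P = 1 − exp(−[E]·t·k<sub>cat</sub>/K<sub>m</sub>),
  valid for substrate far below K<sub>m</sub>. One-parameter ordinary least
  squares over pooled replicates; SE from the fit covariance. Initialized
  from the median per-point estimate −ln(1−P)/([E]·t).
* **Morrison model**: vi/v0 = 1 − (E<sub>t</sub>+I+K<sub>i</sub> −
  √((E<sub>t</sub>+I+K<sub>i</sub>)² − 4E<sub>t</sub>I))/(2E<sub>t</sub>),
  fitted in K<sub>i</sub> with E<sub>t</sub> known and fixed; the discriminant
  is clamped at zero against floating-point negatives; optionally a v0 scale
  is floated as a nuisance parameter for raw-velocity inputs (the fit uses an
  explicit parameter scale since K<sub>i</sub> and v0 differ by ~11 orders of
  magnitude). As E<sub>t</sub>→0 the model reduces to the classical
  1/(1+I/K<sub>i</sub>); E<sub>t</sub>=0 is rejected with a pointer to that
  limit.
* All concentrations are molar internally; the CLI accepts explicit unit
  suffixes (pM/nM/uM/mM/M). ELISA readouts are converted to amounts by linear
  interpolation on a strictly monotone standard curve; out-of-range signals
  are flagged, never extrapolated (a 4PL calibration model is deliberately
  out of scope).

## Synthetic data generators

All generators are pure functions of (config, seed).

* `make_substrate`: random canonical sequence with ≥1 K/R per 30 residues so
  digestion is nondegenerate (length 400 by default).
* `simulate_degradome` emits (i) fully tryptic background peptides (0–3
  missed cleavages, detection rate 0.6, minimum length 6) with both-group
  log₂ ratios ~ N(0, 2) — sd 2 chosen to mimic the ≈1.97 implied by the
  empirical z-scale; (ii) per injected site (5 by default, detected with
  probability 0.9, P1 never on K/R), semi-tryptic products on both sides of
  the bond, active-arm singletons with probability 0.95, else both-group with
  a +6.64 log₂ shift; (iii) spanning tryptic peptides made control-only with
  probability 0.8, else depleted by the converse shift; and (iv) occasional
  spurious semi-tryptic truncations with null ratios (rate 0.05 per detected
  tryptic peptide). A versioned JSON truth record lists injected sites and
  all generated evidence. Abundances are drawn log-normally around a base
  intensity; only the ratio structure matters to the caller, so the base is
  cosmetic.
* Kinetic generators sample the two models with Gaussian noise clipped to
  [0, 1.05]. Defaults follow the characterized assay designs: progress curves
  at 5.5 nM enzyme, 7 time points over 0–20 min, 3 replicates, noise sd 0.02
  on P; Morrison titrations at E<sub>t</sub> = 0.2 nM over a 0–8 nM grid with
  points concentrated around E<sub>t</sub> (where a tight-binding titration
  is informative), each reported point the mean of two technical replicates
  with noise sd 0.03.

What the generators do **not** emulate: spectrum-level effects (m/z,
retention time, missed identifications correlated with peptide chemistry),
between-run normalization, PTMs, or the protease kinetics of the digestion
itself. Passing recovery tests therefore demonstrate correctness of the
calling logic under the stated noise model, not robustness to every artifact
of real LC-MS/MS data.

## Bundled evidence tables and the scaffold substrate

Two desk-scale evidence tables (one per protease arm of a COMP digestion
study) are bundled for end-to-end reproduction of the published site counts
(32 and 17 unique sites, 3 shared). Each contains the published semi-tryptic
and spanning tryptic peptides with flanking residues and positions, plus 60
synthetic fully tryptic background peptides whose log₂ ratios are solved in
closed form so that the both-group population reproduces the experiment's
implied z-scale exactly (ratio 100 → z 3.37 for the first arm, 3.33 for the
second). Because the full substrate sequence is not bundled, a synthetic
scaffold is reconstructed at run time by placing every evidence peptide at
its known precursor position (all placements are cross-checked; conflicts
raise) and filling unconstrained residues with glycine — faithful within the
evidence regions, synthetic filler outside them. Published converse-scale
z-scores are not reproduced: the printed values are mutually inconsistent
with any single affine log₂→z map, so spanning corroboration is checked
qualitatively (converse z > 2 or control-only).

## Numerical and degenerate-input choices

* z-computation requires ≥2 both-group peptides and errors on zero sd
  ("degenerate ratio distribution").
* Abundances ≤ a configurable floor (default 0) count as not detected.
* Fits error on non-identifiable data (all-zero conversion; no inhibition).
* Significance thresholds are strict inequalities (z > 2).
* Window extraction requires P1 strictly inside the sequence.

## Known limitations

* Exact-match localization only: I/L ambiguity and PTM-shifted peptides are
  out of scope.
* Single-pair design: no cross-run normalization beyond the per-peptide
  ratio.
* The binomial normal approximation is anticonservative for rare residues in
  small site sets (n·p₀ < 5); the calibration test bounds the aggregate
  false-call rate, not each cell's.
* The progress model ignores enzyme inactivation and product inhibition over
  the time course.
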