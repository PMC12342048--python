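# degradomap

Mapping protease cleavage sites on a purified substrate from paired
quantitative degradomics — plus the specificity and kinetics analyses that
accompany such studies.

## Who this is for

A common design for locating where a protease cuts a substrate (e.g. an
extracellular-matrix protein such as COMP attacked by ADAMTS proteases) is to
digest the substrate with the active enzyme and, in parallel, with a
catalytically inactive E→Q control, trypsinize both reactions and quantify
peptides by label-free LC-MS/MS. `degradomap` takes the exported peptide
quantification table from there:

* **Site calling.** For each unique peptide the abundance ratio
  active/control is computed; peptides found in only one arm (*singletons*)
  get the arbitrary ratio 100 (log₂ 100 = 6.64). z-scores are the number of
  standard deviations of a peptide's log₂ ratio from the mean over peptides
  found in both arms. Semi-tryptic peptides that are active-arm singletons or
  have z > 2 are candidate proteolytic products; the non-tryptic terminus of
  each candidate defines a P1–P1′ cleavage site, and fully tryptic peptides
  spanning the bond with the converse ratio corroborate it.
* **Specificity.** Called (or externally supplied) sites are expanded into
  P4–P4′ windows and scored per position against a proteome background
  composition with a two-sided binomial test (percentage-scoring logos).
* **Kinetics.** k<sub>cat</sub>/K<sub>m</sub> from single-exponential
  substrate-depletion progress curves, P = 1 − exp(−[E]·t·k<sub>cat</sub>/K<sub>m</sub>),
  and apparent K<sub>i</sub> from the Morrison tight-binding equation,
  vi/v0 = 1 − (E<sub>t</sub>+I+K<sub>i</sub> − √((E<sub>t</sub>+I+K<sub>i</sub>)² − 4E<sub>t</sub>I))/(2E<sub>t</sub>).
* **Synthetic data.** Seeded generators emulating the whole design (injected
  cleavage events, both-group ratio noise, control-only spanning peptides,
  noisy kinetic assays), each with a machine-readable truth record, so every
  stage is testable without raw data.

The analysis classes follow scikit-learn conventions (`fit`, fitted
attributes with trailing underscores, `get_params`/`set_params`); thin
module-level functions expose each step individually, and a `degradomap` CLI
wraps the common workflows.

## Worked example

```python
import degradomap as dm
from degradomap.simulate import DegradomeSimConfig, simulate_degradome, make_substrate
from degradomap.io import site_report_frame

cfg = DegradomeSimConfig(both_group_log2_sd=1.0, seed=7)
observations, truth = simulate_degradome(cfg)
protein = make_substrate(cfg.length, seed=8)          # same substrate the simulator used

caller = dm.CleavageSiteCaller(z_threshold=2.0).fit(observations, protein)
print("injected:", [t["p1"] for t in truth["sites"]])
print(site_report_frame(caller.sites_).to_string(index=False))
```

prints

```
injected: [228, 244, 266, 345, 359]
     site  n_semitryptic  n_spanning  n_corroborating    max_z detection_classes
V228-T229              1           5                5 4.340883       active_only
V244-L245              1           7                7 4.340883       active_only
L266-Y267              2           2                2 4.340883       active_only
I359-D360              2           7                7 4.340883       active_only
```

Four of the five injected sites were detected by the simulator (site 345 fell
to the 0.9 per-site detection efficiency) and all four are recovered, each
supported by semi-tryptic singletons (max_z 4.34 is the singleton log₂ ratio
6.64 measured on this run's both-group scale) and corroborated by spanning
tryptic peptides; no spurious site is called. The kinetics fitters recover
their generating constants the same way:

```python
from degradomap.simulate import (ProgressSimConfig, InhibitionSimConfig,
                                 simulate_progress_curves, simulate_inhibition_series)
k, se = dm.fit_progress_kcat_km(simulate_progress_curves(ProgressSimConfig(seed=7)))
ki, kse = dm.fit_morrison_ki(simulate_inhibition_series(InhibitionSimConfig(seed=7)))
print(f"kcat/Km = {k:.3e} +/- {se:.1e} M-1 s-1")
print(f"Ki = {ki/1e-12:.1f} +/- {kse/1e-12:.1f} pM")
```

```
kcat/Km = 2.318e+05 +/- 2.5e+03 M-1 s-1
Ki = 38.8 +/- 94.0 pM
```

(true values 2.4×10⁵ M⁻¹s⁻¹ and 45 pM; the large K<sub>i</sub> standard error
is the expected behaviour of a tight-binding titration when K<sub>i</sub> ≪
E<sub>t</sub>).

From the shell, the same pipeline is:

```sh
degradomap simulate degradome --seed 7 --out sim/
degradomap call-sites --fasta sim/substrate.fasta --quant sim/quant.tsv --z 2 --out called/
degradomap specificity --sites called/sites.json --fasta sim/substrate.fasta --out spec/
```

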