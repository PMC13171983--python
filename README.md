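# ccmscan

Semi-targeted HILIC–HRMS data processing for central carbon metabolism
(CCM).

Full-scan high-resolution LC-MS lets a lab acquire everything once and
interrogate the data afterwards with a targeted list of expected ions —
"semi-targeted" analysis. `ccmscan` implements the data side of such a
workflow for the CCM of mammalian cells: glycolysis, pentose phosphate
pathway, TCA cycle, nucleotides, redox cofactors and amino acids. It is a
Python library first (with an `examples/` directory of narrative
scripts), plus a thin `ccmscan` command-line wrapper.

## What it does

* **Exact-mass engine** — parses chemical formulas, including uniformly
  ¹³C-labelled internal standards (`13C6H13O9P`), sums monoisotopic
  isotope masses, and derives the singly charged adduct m/z:
  `m/z = M ± m_p` with the proton mass `m_p = 1.007276466` Da. Matching
  uses the relative error `ppm = (m_obs − m_theo)/m_theo × 10⁶` with a
  ±5 ppm gate.
* **Compound panel** — a packaged, validated table of 81 CCM metabolites
  and 10 U-¹³C internal standards: formula, HILIC retention time,
  theoretical [M+H]⁺/[M−H]⁻, internal-standard assignment, per-mode
  limits of detection. Every stored m/z is reproduced from its formula
  to ≤ 5×10⁻⁵ Da at load time.
* **Targeted extraction** — extracted-ion chromatograms per compound
  (±5 ppm, ±0.5 min), trapezoid peak integration between flanking local
  minima, robust noise (1.4826 × MAD) for S/N, and retention-time
  disambiguation of isobars (G6P/F6P resolve; Leu/Ile collide and are
  flagged ambiguous).
* **Calibration** — nine-level 1:2 dilution ladder (20 → 0.08 µM),
  linear-range selection as the longest contiguous run of ≥ 5 levels
  with OLS r² > 0.95, LOD as the lowest continuously detected level, and
  back-calculation through the curve.
* **Isotope-dilution normalization** — analyte/IS area ratios per sample
  and polarity, which cancel per-sample preparation factors exactly; an
  IS stability screen (CV < 22%) and pooled-QC precision/drift metrics.
* **Statistics** — min–max scaling, prcomp-style PCA (center, no
  scaling), Welch two-sample t-tests with Benjamini–Hochberg FDR,
  top-10 reporting, and a retention-time-vs-logD regression helper.
* **Simulator** — a seeded synthetic LC-MS run generator (Gaussian
  peaks at panel RTs, ppm-level m/z jitter, baseline noise, prep-factor
  scatter, QC interleaving, inhibitor fold-change scenarios) that gives
  every stage a ground truth.

## Worked example

```bash
python examples/inhibitor_study.py
```

simulates a six-condition study (control + five metabolic inhibitors,
N = 4, pooled QCs every six injections, 20% per-sample preparation
scatter) and processes it end to end:

```
injections: 29 (24 study, 5 pooled QC)
IS stability screen: 6/6 below the 22% CV gate (CVs track the injected 20% prep scatter)
pooled-QC precision after normalization: median CV 0.04%
PCA explained variance: PC1 13%, PC2 11%

top differential metabolites per condition (adjusted p < 0.05):
  2DG         7 hits; strongest: Glucose; Fumarate; Uridine diphosphate N-acetylglucosamine (UDP-GlcNAc)
  etomoxir    4 hits; strongest: Fumarate; Malate; Creatine
  rotenone    5 hits; strongest: Fumarate; Uridine diphosphate-glucose (UDP-Glc); Uridine diphosphate N-acetylglucosamine (UDP-GlcNAc)
  UK-5099     5 hits; strongest: Pyruvate; Malate; Nicotinamide adenine dinucleotide oxidized (NAD+)
  3-NPA       5 hits; strongest: Glutathione (GSH); Succinate; Fumarate
```

Each inhibitor surfaces the metabolites its mechanism perturbs: the
glycolysis block (2DG) accumulates glucose and depletes TCA and
hexosamine intermediates; the succinate-dehydrogenase block (3-NPA)
accumulates succinate while fumarate and glutathione fall. The other
example scripts demonstrate exact-mass arithmetic
(`exact_mass.py`), EIC extraction (`targeted_extraction.py`),
calibration and LOD calling (`calibration_lod.py`), and the
retention–lipophilicity trend (`rt_logd.py`).

The same pipeline is available from the shell:

```bash
ccmscan demo --seed 1 -o demo_out/          # end-to-end synthetic study
ccmscan mass 13C6H13O9P                     # labeled-formula m/z
ccmscan simulate ladder --seed 1 -o runs/   # 9-level standards run
ccmscan extract --features runs/ladder_neg.csv --polarity - -o peaks.tsv
```

## Layout

```
src/ccmscan/        library (chem, panel, ms_io, extract, quantify,
                    normalize, stats, simulate, pipeline, cli)
src/ccmscan/data/   packaged compound-panel TSV
examples/           one narrative script per capability
docs/methods.md     models, conventions, defaults, limitations
tests/              pytest suite (unit, property, end-to-end)
```
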