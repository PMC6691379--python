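# hifwnt

Glioblastoma (GBM) stem-like cells can be pushed toward a neuronal phenotype
when Wnt signalling is activated under hypoxia: HIF-1α is recruited by the
β-catenin/TCF1 complex onto promoter-proximal sites of differentiation
genes, while at higher oxygen TCF4 occupies the same regions and represses
them. `hifwnt` implements the computational chain that links this
transcription-factor co-binding to a differentiation gene signature and to
patient stratification:

1. **Peak → gene annotation.** ChIP-seq peak summits (BED6/narrowPeak) are
   assigned to genes whose strand-oriented TSS window `[-2 kb, +6 kb]`
   contains them.
2. **Co-binding architecture.** For genes bound by both factors, composite
   (cumulative) summit profiles are built around shared anchor points and
   partitioned into a *shared-occupancy window* plus *factor-specific
   flanks* — the 40 bp + 2×20 bp composite element geometry.
3. **Differential expression (SAM).** A moderated statistic
   `d_i = (x̄₂ − x̄₁) / (sᵢ + s₀)` with a permutation-estimated false
   discovery rate over symmetric cutoffs (exhaustive label splits for
   small designs such as 4 vs 4 arrays), plus set-algebra signature
   derivation, median log2 fold-change summaries and Ward.D2 clustering.
4. **Wnt-burden survival.** Per patient, the number of a 44-gene Wnt panel
   with cohort z-score ≥ 1.5; patients with burden ≥ 7 versus 0–6 are
   compared by Kaplan–Meier curves, log-rank, and a single-covariate Cox
   model whose Wald statistic is scanned over all candidate cutoffs.
5. **Limiting dilution.** Sphere-forming cell frequency `f` under the
   single-hit Poisson model `P(well negative | dose n) = exp(−f·n)`,
   fitted by weighted regression of `ln(fraction negative)` on dose
   through the origin, with a two-slope contrast between conditions.

Because the raw patient data behind the original study are not bundled, a
first-class synthetic-data module generates every input with planted
ground truth (binding geometry, silenced signatures, burden-dependent
hazards, dilution counts), so each stage is verified by parameter recovery
and brute-force oracles.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a simulated
study (raw inputs land in `scratch/study_data/`, summary tables in
`results/`):

```sh
python analysis/01_simulate_study.py
python analysis/02_cobinding_architecture.py
python analysis/03_signature_diffexp.py
python analysis/04_burden_survival.py
python analysis/05_limiting_dilution.py
```

Script 02 recovers the planted binding geometry from the peak files alone:

```
TCF1/HIF1A co-bound genes: 1426
shared window: (-40.0, 0.0) (width 40 bp)
TCF1-specific: [(0.0, 20.0)] (mean offset -10.5 bp)
HIF1A-specific: [(20.0, 40.0)] (mean offset -3.8 bp)
genes carrying the composite window: 1214 of 1426 co-bound
```

i.e. a 40 bp window upstream of the anchor where both factors sit,
flanked by two consecutive 20 bp windows occupied by TCF1 and HIF-1α
alone. Script 03 finds the silenced signature and its grade-wise shutdown:

```
SAM core vs periphery: 50 significant genes at FDR<=0.05 (s0=0.743, 70 label splits)
  planted silenced genes recovered: 49/60; false calls: 1
median log2 fold change of the top-20 down-regulated genes:
  normal=+0.00  gradeII=-0.58  gradeIII=-1.10  GBM=-2.22
```

Script 04 stratifies the simulated cohort by Wnt burden (planted hazard
ratio 3 at burden ≥ 7):

```
197/400 patients with >= 7 of 44 Wnt genes at z >= 1.5
log-rank chi2=70.8, p=3.93e-17
Cox at cutoff 7: HR=2.77 (95% CI 2.17-3.54), Wald p=4.95e-16
cutoff scan over 14 candidates: minimal Wald p at burden >= 7
```

and script 05 estimates sphere-forming frequencies (planted 0.004 and
0.012 per cell):

```
hypoxia_wnt3a: frequency 0.00404 per cell (95% CI 0.00341-0.00467) = 1 sphere-forming cell in 248
normoxia:      frequency 0.01320 per cell (95% CI 0.01114-0.01527) = 1 sphere-forming cell in 76
slope contrast hypoxia_wnt3a vs normoxia: z=8.32, p=8.54e-17
```

The same stages are exposed as a CLI (`hifwnt simulate | annotate |
cobind | architecture | signature | diffexp | cluster | burden-survival |
limdil`) with a flat `--config` file, `--seed` and `--out-dir`.

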