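#!/usr/bin/env python
"""Generate the synthetic study all downstream analyses run on.

Writes, under scratch/study_data/ (raw inputs are regenerated on demand;
only summary tables ship under results/): a TSS annotation, narrowPeak
files for TCF1
and HIF-1a (hypoxia) and TCF4 (normoxia) with the planted shared-window /
flank binding geometry, a core-vs-periphery expression matrix with a
planted silenced signature, a graded-cohort matrix (normal -> grade II ->
grade III -> GBM) with progressive signature shutdown, a TCGA-like cohort
matrix with a planted 44-gene Wnt burden plus matched survival times, and
limiting-dilution well tables for two culture conditions.  Every file has
a #truth record alongside.
"""

import pathlib

from hifwnt import io
from hifwnt.simulate import (BindingSpec, DilutionSpec, ExpressionSpec,
                             SurvivalSpec, simulate_annotation,
                             simulate_cohort_expression, simulate_dilution,
                             simulate_expression, simulate_peaks,
                             simulate_survival)

SEED = 20190709
OUT = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "study_data"
OUT.mkdir(parents=True, exist_ok=True)

N_GENES = 1500
CHROM_SIZES = {"chr1": 4_000_000, "chr2": 3_000_000}

ann = simulate_annotation(N_GENES, CHROM_SIZES, 2000, SEED)
io.write_tss(ann, OUT / "annotation.tsv")
genes = frozenset(ann["gene_id"])

# TCF1 occupies the 40 bp shared window plus the first 20 bp downstream
# flank; HIF-1a the shared window plus the second flank; TCF4 (normoxia)
# spreads over the whole 80 bp region.
specs = {
    "TCF1": BindingSpec("TCF1", "hypoxia", genes, [(-40, 20, 1.0)],
                        per_gene_binding_probability=0.9),
    "HIF1A": BindingSpec("HIF1A", "hypoxia", genes,
                         [(-40, 0, 2 / 3), (20, 40, 1 / 3)],
                         per_gene_binding_probability=0.9),
    "TCF4": BindingSpec("TCF4", "normoxia", genes, [(-40, 40, 1.0)],
                        per_gene_binding_probability=0.6),
}
for i, (factor, spec) in enumerate(specs.items()):
    peaks, truth = simulate_peaks(ann, spec, CHROM_SIZES, SEED + 10 + i)
    io.write_peaks(peaks, OUT / f"peaks_{factor}.narrowPeak")
    io.write_truth(truth, OUT / f"truth_peaks_{factor}.tsv")
    print(f"{factor}: {len(peaks)} peaks "
          f"({int(truth['bound'].sum())} bound genes)")

# core vs periphery arrays (4 vs 4), signature silenced in the core
expr_genes = sorted(genes)[:1000]
signature = frozenset(expr_genes[:60])
core_spec = ExpressionSpec(groups=[("periphery", 4), ("core", 4)],
                           genes=expr_genes, signature_genes=signature,
                           log2_effect_per_group={"core": -1.5})
matrix, labels, truth = simulate_expression(core_spec, SEED + 20)
io.write_expression(matrix, OUT / "expression_core_periphery.tsv")
io.write_labels(labels, OUT / "labels_core_periphery.tsv")
io.write_truth(truth, OUT / "truth_core_periphery.tsv")
io.write_gene_list(sorted(signature), OUT / "planted_signature.txt")
print(f"core/periphery matrix: {matrix.shape[0]} genes x "
      f"{matrix.shape[1]} samples, {len(signature)} silenced")

# graded cohort: progressive shutdown of the same signature with grade
grade_spec = ExpressionSpec(
    groups=[("normal", 6), ("gradeII", 6), ("gradeIII", 6), ("GBM", 6)],
    genes=expr_genes, signature_genes=signature,
    log2_effect_per_group={"gradeII": -0.5, "gradeIII": -1.0, "GBM": -2.0})
gm, gl, gt = simulate_expression(grade_spec, SEED + 30)
io.write_expression(gm, OUT / "expression_grades.tsv")
io.write_labels(gl, OUT / "labels_grades.tsv")
io.write_truth(gt, OUT / "truth_grades.tsv")

# TCGA-like cohort with a planted 44-gene Wnt burden and survival
panel = [f"WNT{i:02d}" for i in range(1, 45)]
cohort, ctruth = simulate_cohort_expression(panel, 400, SEED + 40)
surv, struth = simulate_survival(cohort, SurvivalSpec(panel_genes=panel),
                                 SEED + 41)
io.write_expression(cohort, OUT / "expression_cohort.tsv")
io.write_gene_list(panel, OUT / "wnt_panel.txt")
io.write_survival(surv, OUT / "survival_cohort.tsv")
io.write_truth(ctruth.merge(struth, on="patient"),
               OUT / "truth_cohort.tsv")
print(f"cohort: {len(surv)} patients, "
      f"{int((surv['event'] == 0).sum())} censored")

# limiting dilution: hypoxia+Wnt3a lowers sphere-forming frequency
for cond, f in (("hypoxia_wnt3a", 0.004), ("normoxia", 0.012)):
    table = simulate_dilution(DilutionSpec(f), SEED + 50)
    io.write_well_table(table, OUT / f"wells_{cond}.tsv")
    print(f"wells {cond}: true frequency {f}")
print(f"study written to {OUT}")
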