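"""Score feature reproducibility between the two kernel renderings with
Lin's concordance correlation coefficient."""

from kernelharm import PhantomSpec, generate_cohort
from kernelharm.radfeat import extract_table, feature_groups
from kernelharm.reproducibility import ccc_table, grouped_ccc

cohort = generate_cohort(20, 0.5, PhantomSpec(), seed=8)
masks = {r.id: r.mask.values for r in cohort.records}
t_smo = extract_table({r.id: r.smooth_image for r in cohort.records}, masks,
                      setting="ori_smo")
t_shp = extract_table({r.id: r.sharp_image for r in cohort.records}, masks,
                      setting="ori_shp")

report = ccc_table(t_smo, t_shp)
print(f"{report.comparison}: {report.n_defined} features with a defined CCC")
print(f"mean +/- sd CCC = {report.mean:.3f} +/- {report.sd:.3f}, "
      f"median = {report.median:.3f}")
print(f"fraction of features with CCC > 0.85: {report.fraction_high:.2f}")
# low agreement is expected here: these are *unharmonized* kernels, the
# situation the converter is meant to repair

groups = grouped_ccc(report, feature_groups())
worst = groups.sort_values("mean_ccc").head(3)
best = groups.sort_values("mean_ccc").tail(3)
print("\nleast reproducible groups:\n", worst.to_string())
print("\nmost reproducible groups (shape: mask shared across kernels):\n",
      best.to_string())
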