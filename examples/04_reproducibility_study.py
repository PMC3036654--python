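"""Run a miniature repeated-superimposition study and build the stats tables.

Each synthetic case is superimposed twice on the anterior cranial base and
twice on the left zygomatic arch, each time from an independently perturbed
rough alignment (the repeat-to-repeat variability of redoing the manual
steps).  Regional mean distances per repeat feed paired t-tests with 95%
CIs and Pearson correlations across repeats — the reproducibility analysis.
"""

from voxelreg import PhantomSpec, StudyConfig, build_study_table, run_study

config = StudyConfig(
    n_cases=4,             # the full design uses 16 cases
    cb_repeats=2, zl_repeats=2,
    phantom=PhantomSpec.coarse(),
    noise_sd=30.0,
    master_seed=11,
)
distances, records = run_study(config)
ok = distances[distances.region.notna()]
table = build_study_table(ok[["case", "repeat", "region", "mean"]])

print("Regional mean distances (mm) per repeat (Table-1 analogue):")
print(table.table1.round(3).to_string(index=False))
print("\nPaired differences, cranial-base repeat 1 vs 2 (Table-2 analogue):")
print(table.comparisons["table2_cb_repeat"].round(3).to_string(index=False))
print("\nPearson r across repeats per region:")
print(table.correlations.round(3).to_string(index=False))
# Mean differences near zero with CIs covering zero indicate the repeated
# semi-automated superimpositions are reproducible at this noise level.
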