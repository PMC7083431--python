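"""The whole indirect-RI workflow on a synthetic raw extract.

Clean -> sex partition -> age trend -> female age partition -> per-group
transformation, outlier deletion and both RI routes; the run report is the
JSON-ready analogue of a results section.
"""

from refint import RunConfig, SyntheticConfig, generate_cohort, run_pipeline

frame, truth = generate_cohort(SyntheticConfig(n_per_group=5000, seed=0))
report = run_pipeline(RunConfig(), raw=frame)

c = report["cleaning"]
print(f"cleaning: {c['n_raw']} raw -> {c['n_retained']} retained "
      f"({c['percent_excluded']}% excluded: {c['n_out_of_limits']} outside "
      f"limits, {c['n_missing_demographics']} incomplete, "
      f"{c['n_duplicates_removed']} repeat visits)")
for name, d in report["partitions"].items():
    print(f"partition {name}: Z={d['z']:.2f} vs Z*={d['z_star']:.2f} "
          f"-> separate={d['separate']}")
for name, d in report["correlations"].items():
    print(f"age correlation ({name}): rho={d['rho']:.3f}")
print(f"{'group':>14} {'n':>5} {'iters':>5} {'out':>4} "
      f"{'parametric RI':>17} {'non-parametric RI':>18}")
for g in report["groups"]:
    o = g["outliers"]
    print(f"{g['name']:>14} {g['n']:>5} {o['n_iterations']:>5} "
          f"{o['total_removed']:>4} {g['parametric']['display']['ri']:>17} "
          f"{g['nonparametric']['display']['ri']:>18}")
print("truth (healthy 2.5th-97.5th, ug/L):",
      {k: (round(v[0], 2), round(v[1], 2))
       for k, v in truth.true_percentiles.items()})
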