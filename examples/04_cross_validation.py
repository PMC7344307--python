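"""Repeated CV comparison of the selection pipelines vs fixed-window CSP.

On data whose ERD is confined to the early imagery period, the classic
single fixed window dilutes the signal, while the temporal-combination
selectors find it; the paired t-test quantifies the difference on the
shared fold partition.
"""

import tempocsp as tc

ts = tc.generate_mi_trialset(tc.early_erd_config(seed=0, n_trials_per_class=50))
reports = {}
for selector in ("muin", "lasso", "pca", "swlda", "none"):
    cfg = tc.PipelineConfig(selector=selector, n_repeats=3, seed=0)
    reports[selector] = tc.cross_validate(ts, cfg)
    print(f"{selector:6s}: {100 * reports[selector].mean_accuracy:5.1f}% "
          f"+- {100 * reports[selector].sd_accuracy:.1f}%")

print()
for name, cmp in tc.compare_methods(reports, "none").items():
    print(f"{name} vs fixed-window CSP: +{100 * cmp['mean_diff']:.1f} points, "
          f"p = {cmp['p']:.2g}")

counts, ratio = tc.segment_usage([reports[s] for s in ("muin", "lasso", "pca", "swlda")])
print("\nselected-column counts per window:", counts)
print(f"fraction of folds combining >= 2 windows: {ratio:.2f}")
print("windows 1-3 dominate because the simulated ERD stops at 1.5 s.")
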