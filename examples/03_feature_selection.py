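"""The four selectors over one feature table.

MUIN ranks by mutual information, LASSO by |beta| of an l1-penalized
regression, PCA projects onto principal axes, SWLDA runs stepwise
partial-F regression.  The column selectors always return pair-closed
sets: a CSP filter and its eigenvalue partner travel together.
"""

import tempocsp as tc

ts = tc.generate_mi_trialset(tc.early_erd_config(seed=0, n_trials_per_class=50))
segments = tc.decompose_trialset(ts)
models = [tc.fit_csp(s.signals[s.labels == 1], s.signals[s.labels == 2]) for s in segments]
table = tc.build_feature_table(models, segments)
names = table.column_names()

for fn in (tc.select_muin, tc.lasso_select, tc.pca_transform, tc.swlda_select):
    res = fn(table, 4)
    if res.method == "pca":
        print(f"pca   : {res.meta['captured_variance'] / res.meta['total_variance']:.0%} "
              "of table variance in 4 components")
    else:
        cols = [names[c] for c in res.selected_columns]
        print(f"{res.method:6s}: {cols}")

print("sN_fM = window N (1..5 after cue), CSP filter M (1,4 and 2,3 are pairs).")
print("ERD here lives in 0-1.5 s, so selections cluster in windows 1-3.")
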