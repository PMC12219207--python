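"""Refit the seven published structure-property regressions.

Each physicochemical property is regressed on the index set of its published
model (enter method: all regressors kept).  n is 22 minus the drugs missing
that property; RMSE = sqrt(SSE/n) measures fit on the original scale, and
polarizability (model 3) is the best-predicted property.
"""
from tiqspr import fixtures, qspr

pt, it = fixtures.load_property_table(), fixtures.load_index_table()
results, report = qspr.reproduce_models(pt, it, fixtures.load_model_specs())
for mid, (fit, stats) in results.items():
    print(f"model {mid} ({fit.spec.response:>2}): n={stats.n}  r={stats.r:.3f} "
          f"R2={stats.r_squared:.3f}  RMSE={stats.rmse:.3f}")
fit3 = results[3][0]
preds = qspr.predict(fit3, it)
print("\npredicted polarizability (model 3):")
for drug in ["Diclofenac", "Tacrolimus", "Pranoprofen"]:
    obs = pt.loc[drug, "P"]
    print(f"  {drug}: predicted {preds[drug]:.3f}  observed {obs}")
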