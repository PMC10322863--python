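"""Detect a drought legacy effect with spline regression model comparison.

Two restricted-cubic-spline models of daily growing-season GPP are fitted:
one on concurrent drivers only (PPFD, SWC), one adding drought history
(SPEI at 90 and 365 days). A year whose productivity the concurrent-driver
model systematically overestimates - while the SPEI model does not - carries
a legacy effect.
"""

from fluxlegacy import feature_importance
from fluxlegacy.pipeline import legacy_experiment

ex = legacy_experiment(seed=1, legacy_gain=0.7)
c = ex.comparison

print(f"AIC: simple {ex.simple.aic:.0f} vs SPEI model {ex.full.aic:.0f} "
      f"(delta {c.delta_aic:+.0f}; negative favours drought history)")
print(f"adjusted R2: {ex.simple.adj_r2:.2f} -> {ex.full.adj_r2:.2f}\n")

print("mean percentage error of daily GPP per year (negative = overestimation):")
print(c.per_year.round(1).to_string(index=False))
red = c.legacy_mpe_reduction[ex.legacy_year]
print(f"\nlegacy year {ex.legacy_year}: |MPE| reduced by {100 * red:.0f}% "
      f"when SPEI is included -> legacy effect detected: {ex.detected}")

print("\nfeature importance (chi2 - df):")
for pred in ex.full.predictors:
    imp = feature_importance(ex.full, pred)
    print(f"  {pred:>9}: {imp.importance:8.1f}  (nonlinear share {imp.nonlinearity:.2f})")
print("-> SPEI_365 carries most of the added information, as expected when")
print("   the suppression is driven by the lagged annual water deficit")
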