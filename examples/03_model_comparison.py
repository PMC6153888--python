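"""Fit the five (an)isotropy error models and rank them by AICc.

The cohort is generated with a horizontal-vertical anisotropy (w_h = 0.36 m,
w_v = 0.40 m): absolute error is lowest for forward/backward translations and
highest for up/down. The model comparison should therefore prefer the
horizontal-vertical variant, with the richer variants penalised for their
extra parameters.
"""

import distaniso as da

config = da.CohortConfig(seed=2)
table = da.simulate_cohort(config)
kept, _ = da.screen_participants(table)
upright = kept[kept["orientation"] == "upright"]

fits = [da.fit_mixed_model(upright, variant, seed=2) for variant in da.VARIANTS]
comparison = da.compare_models(fits)
print(comparison[["variant", "k", "loglik", "aicc", "daicc", "best"]].to_string(index=False))

best = next(f for f in fits if f.variant == comparison.loc[comparison["best"], "variant"].iloc[0])
print(f"\nbest model: {best.variant}, estimates {best.fixed_estimates.to_dict()}")
print(
    "dAICc < 4 marks models statistically indistinguishable from the best; "
    "the fitted weights are the expected absolute error (m) on each axis."
)
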