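"""Summed probability distribution and logistic null-model test.

Generates a synthetic boom-bust study (population rises logistically,
plateaus ~4,500 cal BP, then declines from 4,200 cal BP), builds the
binned unnormalized SPD and tests it against a 95% envelope of SPDs
simulated under the best-fitting logistic curve.
"""

import numpy as np

from paleodem import (
    AnalysisConfig,
    DemographyScenario,
    generate_dates,
    make_spd,
    model_test,
    synthetic_calibration_curve,
)

config = AnalysisConfig()
curve = synthetic_calibration_curve()
scenario = DemographyScenario(kind="boom_bust", n_dates=500, n_sites=60, seed=42)
dates = generate_dates(scenario, curve)

spd = make_spd(dates, curve, config)
print(f"{spd.meta['n_dates']} dates -> {spd.meta['n_bins']} site-level 50-yr bins")

result = model_test(spd, curve, dates["error"], config, np.random.default_rng(42), nsim=499)
fit = result.fit
print(f"logistic fit: K={fit.K:.3f}, r={fit.r:.2e}/yr, inflection {fit.t_mid:.0f} cal BP")
print(f"global p = {result.global_p:.3g} ({result.nsim} simulations)")
for a, b in result.positive_regions:
    print(f"  growth beyond the model: {a:.0f}-{b:.0f} cal BP")
for a, b in result.negative_regions:
    print(f"  decline beyond the model: {a:.0f}-{b:.0f} cal BP")
print()
print("A small global p says the observed SPD deviates from logistic growth")
print("more than chance allows; the listed intervals are where it escapes the")
print("pointwise 95% envelope (above = boom, below = bust).")
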