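"""Cross-proxy Pearson correlation matrices.

Puts the SPD and the settlement proxies of one synthetic study on the
shared 100-year slice grid, min-max scales them for display, and computes
the pairwise correlation matrix over the full window (6,000-3,000 cal BP)
and over the truncated window (6,000-4,000 cal BP).
"""

import numpy as np

from paleodem import (
    AnalysisConfig,
    DemographyScenario,
    aoristic_series,
    correlation_matrix,
    generate_study,
    make_spd,
    randomized_start,
    raw_counts,
    spd_to_slices,
    summed_area,
    synthetic_calibration_curve,
)

config = AnalysisConfig()
curve = synthetic_calibration_curve()
study = generate_study(
    DemographyScenario(n_dates=400, n_sites=50, n_survey_sites=300, n_survey_phases=700, seed=13),
    curve,
)
edges = config.slice_edges

series = {
    "spd": spd_to_slices(make_spd(study.dates, curve, config), edges),
    "count": raw_counts(study.survey_phases, edges),
    "aoristic": aoristic_series(study.survey_phases, edges),
    "random_start": randomized_start(
        study.survey_phases, edges, nsim=200, rng=np.random.default_rng(13)
    ),
    "urban_area": summed_area(study.urban_phases, edges, weighting="aoristic"),
}

for window in (None, (6000, 4000)):
    m = correlation_matrix(series, window=window)
    label = "full 6,000-3,000" if window is None else "truncated 6,000-4,000"
    print(f"\nPearson r, {label} cal BP ({m.n} slices):")
    print(m.r.round(2).to_string())
    sig = m.significant()
    pairs = [
        f"{a}~{b}" for i, a in enumerate(m.labels) for b in m.labels[i + 1 :] if sig.loc[a, b]
    ]
    print("significant at p<0.05:", ", ".join(pairs) if pairs else "none")
print()
print("All proxies derive from one demographic truth, so they correlate; the")
print("raw count is dragged down by coarse chronological periods, which is")
print("why the aoristic series is preferred for the poorly resolved spans.")
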