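"""Settlement proxies on the 100-year slice grid.

Survey phases of mixed chronological resolution (one synthetic 'period'
spans 2,400 years) are converted to raw counts, aoristic weights and
randomized-start occupancy, showing how the three proxies treat the same
underlying occupations differently.
"""

import numpy as np

from paleodem import (
    AnalysisConfig,
    DemographyScenario,
    aoristic_series,
    generate_phases,
    randomized_start,
    raw_counts,
    summed_area,
)

config = AnalysisConfig()
scenario = DemographyScenario(n_survey_sites=300, n_survey_phases=700, seed=11)
survey_phases, urban_phases, surveys = generate_phases(scenario)
edges = config.slice_edges

count = raw_counts(survey_phases, edges)
aorist = aoristic_series(survey_phases, edges)
random_start = randomized_start(survey_phases, edges, nsim=500, rng=np.random.default_rng(11))
area = summed_area(urban_phases, edges, weighting="aoristic")

print(f"{len(survey_phases)} survey phases, {len(urban_phases)} urban phases")
print(f"{'slice':>12} {'count':>7} {'aoristic':>9} {'rand.start':>10} {'area_ha':>9}")
for i in range(0, 30, 5):
    older, younger = edges[i], edges[i + 1]
    print(
        f"{older:5.0f}-{younger:4.0f} {count.values[i]:7.0f} {aorist.values[i]:9.2f} "
        f"{random_start.values[i]:10.2f} {area.values[i]:9.1f}"
    )
print()
print("Raw counts treat a 2,400-yr phase as present in all 24 slices; the")
print("aoristic series spreads its unit probability (1/24 per slice); the")
print("randomized-start series asks how many 100-yr occupations would")
print("actually overlap each slice. Counts overestimate where phases are long.")
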