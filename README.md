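# paleodem

Archaeo-demographic inference for the radiocarbon-and-settlement era:
summed probability distributions (SPDs) of calibrated ¹⁴C dates with
Monte-Carlo null-model and mark-permutation testing, aoristic and
randomized-start settlement proxies, size-weighted spatial density
surfaces, and cross-proxy correlation — plus a synthetic-data generator so
the entire pipeline can be validated against a known demographic truth.

It is written for archaeologists and quantitative paleodemographers who
infer relative population trajectories from (a) radiocarbon-date
inventories, (b) regional survey site-phase tables of mixed chronological
resolution, and (c) registers of urban sites (≥ 10 ha). The reference
application is a Northern Fertile Crescent study window of 6,000–3,000
cal BP around the 4.2 kya rapid climate-change event, but every window,
grid and threshold is configurable.

## The model in brief

**Calibration.** A date *cra ± σ_lab* is mapped to a calendar density on a
1-year grid through a calibration curve (m(θ), s(θ)):

    f(θ) ∝ N(cra; m(θ), √(σ_lab² + s(θ)²))

used either raw ("unnormalized", which avoids artificial peaks at steep
curve segments) or rescaled to unit mass.

**SPD.** Dates are filtered (σ_lab ≤ 300 yr, anthropogenic, non-marine,
inside the 6,500–2,500 uncal BP collection window), clustered within sites
into 50-¹⁴C-year bins (complete linkage), and the bin-mean densities are
summed per calendar year. Each bin contributes mean, not sum, so
oversampled contexts don't dominate.

**Null model.** A logistic curve K/(1+e^(−r(τ−τ_mid))) is least-squares
fitted to the SPD; 1,000 simulated SPDs drawn under it (calendar years ∝ f,
back-sampled through the curve with resampled lab errors) give a pointwise
95% envelope. Years where the observed SPD escapes the envelope mark
growth/decline beyond logistic expectation, with a global p-value
(1+#{S_sim ≥ S_obs})/(n_sim+1) on the total out-of-envelope deviation.

**Permutation test.** Bins carry marks (e.g. above/below the 300 mm
rainfall isohyet); shuffling marks across bins yields per-zone envelopes
and global p-values for trajectory divergence.

**Settlement proxies.** Site phases on a 100-year slice grid as raw
counts, aoristic weights (overlap/length, unit mass per phase) and
randomized-start occupancy (uniform 100-yr occupations, Monte-Carlo mean);
urban area summed per slice; 200-year snapshot maps via Gaussian KDE
(bandwidth 50 km, weighted by site size) and survey site densities
(sites/km²). Proxies are min-max scaled and compared with Pearson's r.

## Worked example

```sh
python examples/spd_nullmodel.py
```

generates a boom-bust synthetic study (logistic rise, plateau from ~4,500
cal BP, decline from 4,200 cal BP), builds the SPD and tests it against
the logistic null:

```
474 dates -> 353 site-level 50-yr bins
logistic fit: K=0.134, r=1.02e-02/yr, inflection 5536 cal BP
global p = 0.002 (499 simulations)
  growth beyond the model: 4481-4260 cal BP
  decline beyond the model: 3313-3147 cal BP
```

The global p ≤ 0.01 correctly rejects pure logistic growth, the positive
region overlaps the injected boom/plateau and the negative region falls in
the post-decline tail — the full structure of the envelope-test figure,
recovered from data with a known truth. The other scripts in `examples/`
each exercise one capability (calibration, zone permutation, settlement
proxies, KDE snapshots, correlation matrices, and reproduction of the real
published dataset when its supplementary tables and an IntCal20 file are
placed under `data/external/`).

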