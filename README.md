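# sporesense

Quantitative toolkit for enantiomer-ratio sensing by *Bacillus subtilis*
spores.

Dormant spores germinate in response to L-alanine, while its mirror-image
enantiomer D-alanine — secreted almost exclusively by bacteria —
competitively inhibits germination at the same germinant receptor.  The
consequence is that spores respond to the *ratio* of the two enantiomers
rather than their absolute levels, which lets them detect (and avoid waking
up among) other bacterial species.  This package implements the
quantitative machinery for studying that behaviour:

- the **competitive-binding germination model** and its least-squares fit
  to dose-response rate maps,
- a **1D finite-difference diffusion simulator** for opposing L-/D-alanine
  gradients on an agarose pad,
- **single-spore germination quantification** from phase-contrast
  intensity traces (germination-time calling, CDF, maximum-rate estimator),
- **strip-image quantification** (segmentation, state classification,
  color-coded maps, germinated fraction vs distance),
- the **co-culture yield-ratio statistic** N_nat/N_germ from CFU dilution
  counts, and
- seeded **synthetic-data generators** for every one of these inputs.

## The model

L- and D-alanine compete for a shared germinant receptor G:

    L + G ⇌ [LG]   (dissociation constant k_l)
    D + G ⇌ [DG]   (dissociation constant k_d)

With binding fast compared to downstream signalling and total receptor
normalised to 1, the active fraction at equilibrium is

    [LG]/G_T = (L/k_l) / (1 + L/k_l + D/k_d)

and the germination rate is proportional to it:

    rate(L, D) = α · L / (k_l + L + g·D),     g = k_l / k_d .

Whenever D-alanine is appreciable (g·D ≫ k_l + L), the rate collapses to a
function of L/D alone — ratiometric sensing.  Fitting this surface to a
measured rate map yields k_l = 0.026 mM and k_d = 0.0052 mM (g = 5): the
receptor binds the inhibitor five-fold more tightly than the germinant.

## Worked example

Generate a noisy synthetic rate map at the fitted constants, refit it, and
map the germination region:

```python
import sporesense as ss

truth = ss.BindingParams(alpha=1.0, k_l=0.026, k_d=0.0052)
rate_map = ss.gen_rate_map(truth, noise_cv=0.05, seed=1)

model = ss.CompetitiveBindingModel(rate_map)
print(model.fit().summary())
```

```
Competitive binding germination model
==============================================
n grid cells                                81
loss                                    linear
converged                                 True
restarts                                    27
residual SS                           0.048687
----------------------------------------------
alpha (h^-1)                          0.994591
k_l (mM)                              0.025125
k_d (mM)                            0.00500262
g = k_l/k_d                            5.02238
==============================================
```

The fit recovers the generating constants to within a few percent at 5%
multiplicative measurement noise (exactly, at zero noise).  `alpha` is the
maximal germination rate in events per hour — the largest slope the
germination-time CDF can attain; `k_l`/`k_d` are in mM.

Downstream, `ss.germination_region(...)` thresholds the fitted surface into
the germinate/dormant phase diagram, `ss.simulate_profile(
ss.opposing_sources_config())` diffuses a 0.1 mM L source (left) against a
0.2 mM D source (right) across a 2 cm pad, and
`ss.predict_spatial_germination(...)` converts the simulated gradients into
a germination-probability-vs-position curve.

The same operations are scriptable through the `sporesense` CLI
(`map`, `fit`, `recover`, `diffuse`, `traces`, `segment`, `stripmap`,
`compete`, `generate`).

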