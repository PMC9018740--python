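# c14turnover

Retrospective ¹⁴C bomb-pulse birth dating of cell populations.

Above-ground nuclear testing nearly doubled atmospheric ¹⁴C before the
1963 test-ban treaty, and the subsequent decline of the "bomb pulse"
time-stamps DNA synthesis: genomic ¹⁴C of a post-mitotic cell matches
the atmospheric Δ¹⁴C of the year its DNA was made (shifted by about one
year through the food chain).  Comparing the genomic Δ¹⁴C of a sorted
cell population with the atmospheric level in the subject's birth year
therefore reveals whether cells were added after birth, and modelling
the mismatch quantifies the turnover rate.  The approach is the
standard tool for asking whether adult neurogenesis exists in a human
brain region — here motivated by post-mortem measurements of amygdala
neurons — and is complemented by lipofuscin "age-pigment" counts:
neurons devoid of lipofuscin are substantially younger than the
individual.

## Model

For subject *i* born at calendar year *b*ᵢ, the mean genomic Δ¹⁴C
c̄ᵢ(t) at age *t* of a homeostatic population renewing at rate β(t)
follows

    dc̄ᵢ/dt = β(t) · ( c_a(t + bᵢ) − c̄ᵢ(t) ),    c̄ᵢ(0) = c_a(bᵢ),

where c_a is the (lagged) atmospheric curve.  Three renewal scenarios
are fitted:

* **A** — constant rate β;
* **LIN** — rate linear in age, β(t) = β₀ + (β₁₀ − β₀)·t/10, clamped
  to [0, 0.5] /year;
* **2POP** — a fraction *f* of cells renews at rate β, the rest is
  quiescent; the whole-population turnover is the product f·β.

Measured values cᵢ deviate from the model prediction at collection by
Gaussian noise of common SD σ.  Priors are log-uniform on rates over
[10⁻⁶, 0.5] /year, uniform on [0, 1] for *f* and uniform on [0, 100] ‰
for σ.  Posteriors are sampled with the affine-invariant ensemble
sampler (50 walkers per parameter, 1000 burn-in steps, 2000 retained);
point estimates are posterior medians with 16th/84th-percentile
("1 σ") intervals.  Scenarios are compared by PSIS-LOO cross-validation
with stacking weights, and per-neuron lipofuscin granule counts are
trichotomised ({0}, {1–3}, {>3} granules) and tested with the
tie-corrected Kruskal–Wallis rank test plus a Nemenyi post hoc.

## Worked example

```python
import c14turnover as ct

record = ct.make_bomb_curve()                     # stylised bomb pulse
spec = ct.default_sim_spec(seed=11)               # 2POP truth: f=0.29, β=0.1, σ=10‰
samples, truth = ct.simulate_measurements(spec, record)

model = ct.TurnoverModel(samples, record, scenario="2POP")
res = model.fit(seed=2)
print(res.summary())
```

Output (12 subjects + one bilateral duplicate, full protocol):

```
          median  lower_1sig  upper_1sig
beta   0.0900436   0.0775181     0.10824
f       0.294141    0.281984     0.30646
sigma    10.7306     8.60839     14.1014
f_beta 0.0265166   0.0231849    0.031312
```

The renewal rate `beta` (truth 0.1 /year), renewing fraction `f`
(truth 0.29) and noise SD `sigma` (truth 10 ‰) are all recovered;
`f_beta` is the posterior of the whole-population turnover f·β, here
≈ 2.7 %/year with a 1 σ interval [2.3; 3.1] %/year.
The same measurements can be fitted under `scenario="A"` or `"LIN"`
and compared:

```python
loos = []
for scen in ("A", "LIN", "2POP"):
    fit = ct.TurnoverModel(samples, record, scenario=scen).fit(seed=2)
    loos.append(ct.elpd_loo(fit.pointwise_loglik(thin=20)))
print(ct.compare(loos))
```

which prints each scenario's LOO expected log predictive density and
its stacking weight (the probability of being the best-predicting
scenario).  A command-line interface mirrors the library:
`c14turnover simulate | fit | compare | lipofuscin | cellage | run-all`.

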