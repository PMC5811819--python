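# sitar-trends

Shape-invariant (SITAR) growth-curve analysis of secular trends in child
height and weight, built for *survey means*: national anthropometric
surveys tabulated as mean height (cm) or weight (kg) in 1-year age groups
by sex, country and year of measurement — the kind of series collected for
decades in Japan (annual, 1949-2011) and South Korea (1965-2005).

Over such a period the whole growth curve drifts: children end up taller
and heavier (**size**), puberty comes earlier (**timing**), and the growth
period itself shrinks (**intensity**).  Treating each survey's mean curve
as one "individual", the shape-invariant model expresses survey *i* at
transformed age *t* as

    y_it = a0 + alpha_i + h( e^(c0 + gamma_i) (t - b0 - beta_i) ) + e_it

with a shared natural cubic B-spline `h` (knots at age quantiles, dimension
chosen by BIC) and zero-mean random effects `(alpha_i, beta_i, gamma_i)` =
(size in cm/kg, timing in years, log-intensity; reported as 100 gamma %).
Fitting is by Laplace-approximate maximum likelihood.  Around the core fit
the package provides:

* data preparation — mid-year age assignment, 3-year merging of annual
  series, period and cohort curve construction (`growth_tables`);
* axis-transformation search over {identity, sqrt, log}^2 with
  Jacobian-corrected BIC, and back-transformation of curves and effects to
  natural units (`scale_selection`);
* velocity curves (analytic derivative), age-specific secular increments
  and effect-trend summaries, and the period-vs-cohort sensitivity
  comparison (`trend_analysis`);
* a synthetic survey-mean generator with known ground truth, so the whole
  pipeline is testable end-to-end without any data download
  (`synthetic_data`);
* a CLI (`sitar fit / scan / simulate / recover / increments /
  compare-cohort`).

See `docs/methods.md` for the model, estimation details and the
assumptions behind the synthetic study conditions.

## Worked example

Simulate a canonical 12-survey height series (seven decennial Japan-style
surveys 1950-2010, five Korea-style 1965-2005; noise SD 0.3 cm), fit, and
read off the secular-trend decomposition:

```python
import sitar

spec = sitar.default_spec("height", "male", seed=1)   # truth is known
table = sitar.simulate_surveys(spec)
fit = sitar.fit_sitar(table, df=6)

print(round(sitar.variance_explained(fit, table), 1))
effects = sitar.effects_table(fit)
print(effects.round(2).to_string(index=False))
```

```
99.6
         survey  size  timing  intensity_pct
Japan-like 1950 -5.56    0.73          -7.54
Japan-like 1960 -2.77    0.26          -4.25
Japan-like 1970 -0.17   -0.16          -1.78
Japan-like 1980  1.35   -0.20           0.09
Japan-like 1990  2.16   -0.23           2.10
Japan-like 2000  2.37   -0.26           3.99
Japan-like 2010  2.21   -0.33           5.15
Korea-like 1965 -2.38    0.81          -6.58
Korea-like 1975 -1.33    0.45          -3.01
Korea-like 1984 -0.35    0.07           0.20
Korea-like 1997  1.72   -0.31           4.42
Korea-like 2005  2.74   -0.84           7.22
```

The random effects explain 99.6% of the between-survey variance; the
Japan-style size series rises by about 7.8 cm (truth: 8), the Korea-style
one by 5.1 cm (truth: 5), and the intensity range spans about 14.8
percentage points (truth: 15) — the generator's injected secular trend,
recovered from the noisy tables.  The same decomposition applied to real
survey CSVs (`sitar fit tables.csv --sex male --measurement height`)
yields the corresponding country estimates.

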