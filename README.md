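# dioica

Sex-specific dendroecology for dioecious trees: ring-width processing into
standardized basal-area-increment (BAI) chronologies, wood carbon-isotope
discrimination, multi-scale SPEI drought indexing, climate–growth
correlation analysis, and AICc / stepwise model selection — with a
synthetic study generator so the whole pipeline is testable end to end.

## Who this is for

Dendroecologists comparing male and female trees of a dioecious species
(growth rates, water-use efficiency, climate sensitivity) from increment
cores, pentad wood-isotope measurements and gridded monthly climate.  The
package is used from Python (see `examples/`), with a thin `dioica`
command-line wrapper for the simulate → analyze → report pipeline.

## The quantities it computes

- **BAI**: annual basal area added by a stem, BAI_t = π(r_t² − r_{t−1}²)
  (cm² yr⁻¹), from Tucson/RWL ring-width files; per-tree series are
  divided by a fitted straight line (ratio indices) and averaged into
  per-sex chronologies.
- **Δ¹³C**: discrimination against ¹³C relative to air,
  Δ¹³C = (δ¹³C_air − δ¹³C_wood)/(1 + δ¹³C_wood/1000) (‰), inversely
  related to intrinsic water-use efficiency, on 5-year blocks (pentads).
- **SPEI**: the water balance P − PET accumulated over k = 1…36 months,
  fitted per calendar month with a log-logistic distribution via unbiased
  probability-weighted moments and mapped to standard-normal deviates.
- **Climate–growth analysis**: Pearson correlation functions over 20
  month slots (Apr of the previous year … Nov of the growth year), and the
  16 × 36 month-by-lag SPEI correlation surface whose peak locates each
  sex's drought legacy.
- **Models**: pentad-level linear models (pentad, sex, ecological memory,
  historical diameter, pentad×sex) selected by exhaustive AICc with a
  tree-random-intercept screen and a residual-normality log gate, and
  chronology-level stepwise climate regressions with a
  variance-inflation-factor bar.

See `docs/methods.md` for the full model description and the numerical
choices.

## Worked example

```bash
python examples/01_simulate_study.py
python examples/02_chronologies.py
python examples/05_climate_sensitivity.py
```

prints (seed 1):

```
trees: 30 (16 male, 14 female)
climate: 1900-2001, mean annual precipitation 952 mm, mean temperature 9.4 degC

male:   mean BAI 1942-2001 = 3.36 cm2/yr over 16 trees
female: mean BAI 1942-2001 = 2.71 cm2/yr over 14 trees

male drought legacy:   r = 0.62 for SPEI accumulated over 13 months ending Jan
female drought legacy: r = 0.75 for SPEI accumulated over 31 months ending Nov
```

Males out-grow females (the implanted sex difference in growth rate), and
the drought-legacy peaks land at or near the implanted sensitivities — a
short (~10-month) water-availability memory ending in January for males
and a long (~30-month) one for females.  At 30-month accumulation
neighbouring surface cells are correlated ≈ 0.98, so single-sample peak
locations at long scales scatter by a few months around the true cell
(quantified in `docs/methods.md`).

The same pipeline runs from a shell:

```bash
dioica simulate --seed 1 --outdir fixtures/
dioica analyze fixtures/ --outdir results/
dioica report results/
```

`results/` then holds the chronologies, pentad table with Δ¹³C, the SPEI
cube, correlation functions, lag surfaces, model-selection and stepwise
summaries, and a markdown report; a fixed seed gives byte-identical reruns.

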