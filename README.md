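# wavemorph

Wave-climate trends and their coupling to the morphometry and market
quality of the stalked barnacle *Pollicipes pollicipes* ("percebe"), a
high-value intertidal fishery resource of the NE Atlantic rocky shore.

Harvesters price barnacles by shape: stubby, wide animals are valuable,
elongated ones are not. Shape tracks wave exposure — breaking-wave orbital
currents select for low aspect ratios — so a changing wave climate can
silently move the quality of whole extraction sites. `wavemorph`
implements the full analysis chain that quantifies this link:

1. **Wave mechanics** — hourly offshore sea states (significant height
   `H_o`, peak period `T_p`) are shoaled to the 1 m intertidal fringe with
   the linear-theory energy-flux coefficient

   `H_i = H_o * { [sinh(2k_i d_i)(2k_o d_o + sinh 2k_o d_o)] /
   [sinh(2k_o d_o)(2k_i d_i + sinh 2k_i d_i)] * tanh(k_o d_o)/tanh(k_i d_i) }^{1/2}`

   with wavelengths from the Eckart closed form
   `l_w = (gT²/2π)·tanh^{1/2}(4π²d/T²g)`; the daily-max inshore height
   gives the orbital current `u = sqrt(g·H_i)`, the mechanical stressor.
2. **Trend decomposition** — daily `u` is split into a cyclic seasonal
   component and a long-term smooth (penalized B-splines, 15/12 basis
   functions, GCV), from which a linear rate of change (m s⁻¹ yr⁻¹) and
   Jan–Mar / Jun–Aug subset trends are extracted.
3. **Morphometry and quality** — per individual, the index `S = TL/DBC`
   (total length over capitulum base diameter) and the sigmoidal quality
   limit `TL(DBC) = 67.8055 + (10.9002 − 67.8055)/(1 + (DBC/12.216)^2.8008)`
   classify animals as good (on/below the curve) or bad; the high quality
   fraction (HQF) aggregates a sample.
4. **Topography** — per site: shore-normal bearing from the chord of a
   500 m-radius circle intersected with the coastline, relative wave
   incidence angle α (circular-mean wave direction vs normal), and the
   nearshore slope along a 1000 m seaward bathymetry transect.
5. **Coupling and model selection** — per-site regressions of pooled mean
   S and HQF on the preceding-winter mean `u` (R²_S, R²_HQF); Gamma GLMs
   (log link) for skewed responses; exhaustive AICc ranking with Akaike
   weights over admissible term subsets; McFadden pseudo-R².
6. **Quality geometry** — the descending Gompertz law
   `HQF(S) = A/(1+exp((S−x0)/b))` linking population mean shape to
   quality, and intersections of constant-S rays `TL = S·DBC` with the
   quality limit, which bound the sizes at which an average animal is
   still marketable.

Because the source hindcast (SIMAR) and harvester datasets are not
public, the package ships a first-class synthetic generator
(`wavemorph.simulate`) that reproduces the statistical structure of all
inputs — seasonal storm-driven wave climate, 30–50 individuals per
site × intertidal level × year with wave-sensitive shape, idealized
coasts with known exposure — so every stage is testable end to end with
ground truth in hand.

## Worked example

Where does an average-shaped population stop being marketable?

```bash
$ wavemorph geometry --out quality_domain.csv
S=2.37: good up to DBC 26.0 mm
S=1.51: good up to DBC 43.9 mm
S=3.27: good up to DBC 4.1 mm
```

A population at the long-term mean shape (S = 2.37) stays good quality up
to a capitulum diameter of 26 mm (2.6 cm) — comfortably above the 15 mm
legal minimum and the 18 mm optimum capture size. At the recorded maximum
elongation (S = 3.27) the crossing drops to 4.1 mm: essentially no legal
animal is good quality. At the minimum (S = 1.51) every size up to
~44 mm is good.

Simulating a 15-year wave record and decomposing it:

```python
from wavemorph.simulate import WaveGenConfig, gen_wave_series
from wavemorph.waves import daily_max_inshore, PhysicalConstants
from wavemorph.trends import decompose

df, point, _ = gen_wave_series(WaveGenConfig(seed=1))
days = daily_max_inshore(df, point, PhysicalConstants())
fit = decompose(days)
print(f"slope={fit.linear_slope:.4f} m/s/yr, seasonal peak doy={fit.seasonal_peak_doy:.0f}")
# slope=0.0848 m/s/yr, seasonal peak doy=31
```

The recovered long-term increase in winter-peaking orbital currents
(~0.08 m s⁻¹ yr⁻¹, seasonal maximum in late January) matches the trend
injected by the generator.

The full pipeline — simulate, shoal, decompose, classify, measure
exposure, rank models, fit the quality law — runs with:

```bash
wavemorph run --seed 1 --outdir out/
```

## Layout

- `src/wavemorph/waves.py` — shoaling, wavelengths, orbital currents
- `src/wavemorph/trends.py` — penalized-spline decomposition, subset trends
- `src/wavemorph/morphometry.py` — S, quality limit, HQF, study filters
- `src/wavemorph/topography.py` — circle–coast geometry, α, nearshore slope
- `src/wavemorph/coupling.py` — site couplings, Gamma GLM, AICc dredge
- `src/wavemorph/quality.py` — Gompertz law, ray–limit quality domain
- `src/wavemorph/simulate.py` — seeded synthetic generators + ground truth
- `src/wavemorph/io.py`, `config.py`, `pipeline.py`, `cli.py` — formats,
  configuration, driver, CLI

See `docs/methods.md` for the modelling choices and their rationale.
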