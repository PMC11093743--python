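# Methods

This note records the models implemented in `wavemorph`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Wave transformation

Offshore hourly sea states are transformed to the intertidal with linear
wave theory. The wavelength uses the Eckart explicit approximation to the
dispersion relation, `l_w = (gT²/2π)·tanh^{1/2}(4π²d/(T²g))`. This closed
form is exact in the deep- and shallow-water limits and is accurate to
about 5% at worst at intermediate relative depths (the classical accuracy
figure for this approximation; our tests measure a 5.2% worst case against
an iterative exact-dispersion solver over 1–1000 m depth and 4–20 s
period). The shoaling coefficient is the standard energy-flux form in
sinh/tanh of `k·d` at the two depths; we implement the symmetric
`2·k_i·d_i` inshore term, which is required for the equal-depth identity
`H_i(d, d) = H_o` to hold, and expose a `literal_printed_form` flag that
reproduces a published variant with `2·k_i·d_o` in that position for
comparison. Because the two depths enter as a ratio of group-velocity-like
factors, the shoaling coefficient agrees with the exact-dispersion oracle
to better than 1% even where the wavelength itself is several percent off.

Hourly heights are transformed **before** taking the daily maximum, since
shoaling depends on that hour's period; days are UTC calendar days.
Defaults: inshore depth `d_i = 1 m` (shallowest zone the barnacles
occupy), `g = 9.81 m s⁻²`. The orbital current scale is `u = sqrt(g·H)`;
no breaking criteria, refraction or spectral effects are modelled.

## Trend decomposition

The daily maximum orbital current is modelled additively:
`u(t) = f_trend(t) + f_season(doy) + ε`, with a clamped cubic B-spline
basis (15 functions) for the slow trend and a periodic cubic B-spline
basis (12 functions, period 365.25 d, Feb 29 folded onto Feb 28) for the
annual cycle. Both components carry second-difference (P-spline)
penalties; the two smoothing parameters are selected by generalized
cross-validation over a 10-point log grid (1e-4…1e4) per component, ties
broken toward the smoother fit. The seasonal design is column-centred to
decouple it from the trend intercept, and the fitted seasonal component is
re-centred to integrate to zero over one year. The long-term rate of
change is the OLS slope of the fitted trend values against time in years;
its standard error and p-value come from that OLS t-test without any
autocorrelation correction — a known limitation for persistent sea-state
series, which inflates apparent significance but leaves the slope estimate
unbiased. Seasonal-subset trends (Jan–Mar, Jun–Aug) are OLS fits to yearly
subset means, requiring at least three represented years. This is a
deterministic fixed-effects stand-in for mixed-model additive smoothers:
no random effects and no explicit error correlation structure.

## Morphometry and quality

`S = TL/DBC` is the aspect ratio of an individual (total length over
capitulum base diameter, both mm): higher S means a more elongated,
breakage-prone, lower-value animal. The market quality boundary is a
four-parameter sigmoid in the TL–DBC plane rising from 10.9 mm to a
67.8 mm plateau with half-saturation at 12.216 mm and Hill exponent
2.8008. An individual exactly on the curve counts as **good**: the
inclusive convention keeps HQF upper-semicontinuous in TL and is asserted
in tests. HQF is the fraction of good individuals in a sample.

Study filters: individuals with DBC ≤ 2 mm are excluded (strict
inequality), and sites with fewer than 6 distinct sampling years are
dropped. Field series contain gap years, so "distinct years" is the
default criterion, with a strict-consecutive-run option. Site-level
summaries are offered both per intertidal level and with the three levels
pooled (individual-weighted), since either aggregation is defensible.

## Topographic exposure

All metric geometry runs in a local tangent-plane projection about each
site (x east, y north, metres); at the 0.5–1 km scales involved the
projection error is far below the bathymetry-grid resolution. The
coastline orientation proxy is the chord between the two crossings of a
500 m-radius circle with the coastline polyline; with more than two
crossings, the pair bracketing the along-coast point nearest the site is
kept. The shore normal is the chord perpendicular oriented toward deeper
water (depth probes 250 m along each candidate). Wave directions use the
nautical "coming-from" convention; their circular mean (atan2 of mean
sin/cos, undefined below resultant length 1e-9) gives the incidence, and
α is the minimal angular difference to the shore normal, folded to
[0, 180]° — values above 90° mean the shore faces away from the swell.
The nearshore slope is the OLS slope of (−depth) against distance at 50 m
steps along a 1000 m seaward transect, sampled from the depth grid by
bilinear interpolation; seaward deepening is negative. Transects that
partially leave the grid are fitted on the available samples (≥ 5) with a
warning.

## Coupling and model ranking

Per site, pooled yearly mean S and HQF are regressed (OLS) on the mean
Jan–Mar daily-max orbital current preceding each sampling; the R² values
(R²_S, R²_HQF) measure how tightly that site's shape tracks wave forcing.
Across sites these R² values are modelled on α, nearshore slope and
site-mean ū with Gaussian linear models including all interactions.

Skewed positive responses (individual S; HQF compressed away from {0,1}
by `(p(n−1)+0.5)/n`) use Gamma GLMs with a log link. Coefficients come
from IRLS (statsmodels); for the Gamma family the coefficient ML does not
depend on the shape, which is then profiled out by maximum likelihood
(solving `log a − ψ(a) = −c` by bracketing) and the exact log-likelihood
evaluated there, so each model's parameter count includes the shape.
Candidate models are every subset of the supplied terms respecting
marginality (an interaction requires all its lower-order relatives that
are themselves candidates), ranked by small-sample
`AICc = −2logLik + 2p + 2p(p+1)/(n−p−1)` with Akaike weights
`exp(−Δ/2)/Σ`; ties break toward fewer parameters, and models whose fit
fails (e.g. rank-deficient designs) are flagged and excluded from the
weights. Random effects are deliberately not implemented: site and
intertidal level enter as fixed factors, and AICc is the small-sample
correction, not the conditional mixed-model criterion. McFadden
pseudo-R² is `1 − logLik/logLik₀`; with continuous densities it is only
interpretable when both log-likelihoods are negative, so exact fits get a
1e-12 ML-variance floor which also makes degenerate constant-response
comparisons resolve to the null model by parameter count.

## Quality–morphometry geometry

The population-level quality law is the descending sigmoid
`HQF(S) = A/(1+exp((S−x0)/b))` with `b > 0` (algebraically identical to
the double-negative exponent sometimes printed). Fitting is nonlinear
least squares with multi-start (x0 over the S quartiles, b over
{0.1, 0.3, 1.0}, A started at max HQF), best SSE kept; a flat response
leaves the midpoint unidentifiable and raises an explicit failure.

Constant-S rays `TL = S·DBC` are intersected with the quality limit by
sign-change bracketing on a 2001-point grid over DBC ∈ [2, 50] mm
followed by Brent root-finding to 1e-8 mm; an empty root set is a valid
outcome (the whole size range is good quality). Because the limit is
convex then concave, rays with S near the inflection slope (S ≈ 2.9–3.1)
cross it three times; the field-relevant S values (1.51, 2.37, 3.27) each
have at most one crossing, and the domain report uses the smallest
crossing as the largest good-quality size. The default domain's lower
bound is the 2 mm measurement filter and its upper bound sits above any
plausible capitulum diameter.

## Synthetic generators

The generators define the study conditions and emit ground-truth sidecars
for recovery tests.

*Waves*: 15 years of hourly heights built from a mean of 1.4 m, a 0.9 m
cosine seasonal cycle peaking in late January, a +0.055 m yr⁻¹ linear
height trend (≈ +0.07 m s⁻¹ yr⁻¹ in u after shoaling), AR(1) hourly noise
(φ = 0.9, marginal sd 0.45 m) for sea-state persistence, and
Poisson-count winter storms (10 per Nov–Mar season, exponential height
surcharges of mean 1.2 m decaying over 12 h). Periods increase with
sqrt(height); directions are von Mises about a prevailing 280° bearing.
These values were chosen once so that winter daily-max orbital currents
fall in the 5–8 m s⁻¹ envelope and summer in 4–5 m s⁻¹, the ranges
characteristic of the NW Iberian shelf. Not emulated: spectral structure,
directionally dependent shoaling, tides.

*Barnacles*: S — not TL — is the generative variable, which makes HQF
directly controllable; TL = S·DBC is derived. Per site × level × year,
30–50 individuals draw S lognormally around a site mean (grand mean 2.37,
between-site sd 0.25, within-group sigma 0.22, small intertidal-level
shifts with stubbier animals higher on the shore) shifted by
`coupling_beta·(ū − ū̄)` at "coupled" sites and not at "decoupled" ones;
DBC is lognormal (median 10 mm) clipped to the measurable range. Not
emulated: growth, recruitment, density dependence, measurement error
correlated within clumps — so passing recovery tests demonstrate the
statistical machinery, not ecological realism.

*Coasts*: straight (optionally gently curved) coastline through the site
at a prescribed bearing, with a planar depth field growing linearly
seaward; land carries the negative continuation of the plane so bilinear
sampling is exact and the ground-truth slope and shore normal are known
analytically.

*World*: one offshore point drives all sites; per-site winter u gets a
fixed fetch/sheltering multiplier (0.85–1.15), orientations vary to
spread α, and coupled sites pair with gentle slopes (0.02) versus
decoupled/steep (0.09), the contrast the coupling analysis is meant to
resolve.

## Numerical choices and problem sizes

Penalized-spline systems are ~27 parameters and solved by dense normal
equations with a 1e-8 ridge pinning the seasonal sum-to-zero direction.
Gamma shape solving brackets log-shape in [−30, 30]; near-perfect fits
return a capped large shape. The test suite runs the statistical recovery
properties at deliberately modest sizes — 20 seeds for trend-slope and
dredge recovery, 10 synthetic worlds of 8 sites × 8 years for the
end-to-end coupling contrast — chosen to make sampling statements (≥ 75%,
≥ 90% of seeds) meaningful while keeping the whole suite fast and fully
deterministic.

## Known limitations

- OLS p-values on serially correlated daily series overstate
  significance; treat slopes, not p-values, as the primary output.
- Fixed-effects GLMs in place of mixed models understate uncertainty when
  sites are viewed as a random sample of the coastline.
- The Eckart wavelength is a few percent off at intermediate depths
  (worst ~5%); the shoaling ratio largely cancels this but single-depth
  wavelengths should not be quoted to better than that.
- The incidence angle α folds to [0, 180]°; comparisons with conventions
  folding to [0, 90]° must halve the range first.
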