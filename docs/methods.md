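# Methods

## Scope and model structure

`runoffmit` evaluates plot-scale mitigation trials (micro-dams,
conservation tillage) with the two empirical relations regulatory
field-scale pesticide models use: the USDA-SCS curve-number (CN)
rainfall–runoff relation and the MUSS event soil-loss equation. It does
not re-implement a full root-zone model: there is no soil profile, no
evapotranspiration, no pesticide transport, and no soil-moisture
adjustment of the CN. The season simulator is the deliberately minimal
loop — one fixed CN applied to every day of a daily rainfall series —
that makes the two inverse problems (CN from a seasonal runoff total, C
from a seasonal eroded mass) well-posed and fast. That simplification is
intended: regulatory practice itself applies one CN for essentially the
whole cropping period, and the calibration targets are seasonal totals,
not individual events. Event counts and per-event magnitudes from the
simulator should not be compared against observations.

## Runoff

Retention S = 25400/CN − 254 (mm), initial abstraction Ia = `ia_ratio`·S,
Q = (P − Ia)²/(P − Ia + S) for P > Ia. `ia_ratio` defaults to the
standard 0.2 and is exposed as a parameter; the inversion solves the
general quadratic in S (which reduces to the familiar
S = 5(P + 2Q − √(4Q² + 5PQ)) at 0.2), so forward/inverse round-trips are
exact to ~1e−12 for any abstraction ratio. Events with Q = 0 are not
invertible (every sufficiently low CN explains them) and are excluded
from the precipitation-weighted mean, as are QC-flagged events (e.g. an
overflown collection reservoir); exclusions are logged, never inferred.
CNs are kept continuous internally and rounded to integers only in
report views, which is how trial tables print them.

## Erosion

MUSS: Xe = 0.79 (Vr·qp)^0.65 · A^0.009 · K·LS·C·P, in tonnes per event.
The peak runoff rate qp is not observable from daily data; the package
uses the uniform-rate surrogate qp = Vr/n over the n = min(24, ⌈P/2⌉)
hourly 2-mm rain segments of the day. This is the only rate consistent
with the 2-mm segmentation the dilution equation also uses, but it is a
surrogate for (not a reproduction of) a sub-daily hydrograph peak —
absolute C-factor fits inherit that convention, which is why only
*relative* C-factors between treatments are interpreted. C is not
clamped to the handbook range [0, 1]: on small bare-ridged plots the
calibrated value absorbs everything the event model leaves out and can
exceed 16. Unit conventions are explicit: Xe in t/event, per-area views
in kg/ha (measured-event tables) and t/ha (seasonal summaries).

## Calibration

Sequential, mirroring the regulatory workflow: CN first, then C at that
CN. The seasonal runoff total is continuous and nondecreasing in CN, so
the fitted CN is found by scanning the integer grid 30…100 and taking
the smallest value whose total reaches at least the measured one (the
"at least" convention keeps the fit conservative for exposure). A
relative slack of 1e−9 absorbs float summation-order noise so that a
target equal to a simulated total always selects that CN. A continuous
CN root (Brent's method between the bracketing integers) is returned for
diagnostics. The C-factor is closed-form by exact linearity:
C = measured / simulated-at-C=1; re-simulation reproduces the measured
mass to machine precision. Degenerate cases: a zero runoff target
returns the lower grid bound with a warning; a target above the CN=100
total (total rainfall) raises; a season with no simulated erosive events
at the fitted CN leaves C unidentifiable and raises.

## Treatment comparison

Reductions are computed from unrounded values and rounded only in report
views (integers for mm, kg/ha, CN and percent; two decimals for relative
C-factors). Summary blocks use the population standard deviation
(divisor n): back-calculating the printed "(±…)" figures from the
packaged fit table is only consistent with the population form (e.g. the
six micro-dam CN point deltas [5, 7, 1, 5, 3, 5] give 1.89 → "±1.9";
the sample form would give 2.07). The micro-dam comparison set pools the
disc- and drum-plow setups of the two-device trial with the single-device
trials (n = 6); conservation tillage versus conventional tillage has
n = 4. For blocks whose control is not conventional tillage the package
always uses the pairwise definition 1 − C_treated/C_control; a published
table that instead differences ratios-to-a-third-arm will disagree
slightly on those (and only those) blocks.

## Stream PEC correction

Encoding mitigation as a lower CN/C mitigates the entire simulated
upstream catchment, but the stream scenario defines only fa = 0.208 of
it as treated. The correction therefore works day-wise on paired
unmitigated/mitigated daily outputs: fractional reductions fr (pesticide
mass flux) and fv (runoff volume), the dilution equation

PEC_nomiti = (RFLX/n · fa) / (BASF/24 + raindr·INFLMON/24 + RUNF/n),

and PEC_miti = PEC_nomiti·(1 − fr)/(1 − fa·fv). Defaults fa = 0.208,
BASF = 0.2 L/m²/day (median of the stream scenarios), raindr = 0.1.
RFLX is consumed in mg/m²/day — the unit of the worked example — with an
explicit ×1e7 option for raw model output in g/cm²/day. n is taken from
the same 2-mm segmentation rule as the erosion peak rate; the worked
example (19.9 mm → n = 10) fixes that reading over the alternative
"hours with simulated runoff" gloss. PECs are computed in mg/L and
reported in µg/L. Only days with unmitigated runoff carry a PEC from
this pathway; the endpoint is the maximum of the mitigated daily series,
whose date may differ from the unmitigated maximum (mitigation reshapes
the time series, not just its amplitude). Useful identities, asserted as
properties: fr = fv with fa = 1 leaves the concentration unchanged, and
PEC_miti ≤ PEC_nomiti whenever fr ≥ fa·fv.

## Synthetic trials

The generator emulates the *structure* of the trials: one shared daily
rainfall series per trial; treatment arms that differ only through their
true (CN, C); event tables listing the runoff days. Rainfall is wet-day
Bernoulli (p = 0.15) with gamma(shape 0.8, scale 12 mm) depths over a
180-day season — episodic 5–20+ mm storms at a realistic temperate
wet-day frequency, totalling ≈ 260 mm in expectation, comparable to the
190–340 mm seasons such trials see. It does not emulate real rainfall
autocorrelation, intra-day intensity, seasonal degradation of micro-dams,
or any soil-moisture feedback — so passing recovery tests demonstrate
that the inverse machinery is correct, not that the fixed-CN model
captures real-event physics. Measurement noise, when enabled, is
multiplicative log-normal on the measured runoff/erosion (volumetric
sampling error), capped so measured runoff never exceeds the collected
rain; it is off by default so recovery is exact (CN at integer
granularity, C to machine precision). All randomness flows through one
integer seed; weather and noise use separate streams so enabling noise
never changes the weather.

## Numerical choices and problem sizes

- Integer CN grid scan (71 season simulations) for calibration; each
  simulation is vectorised over days, so a full calibrate-and-fit runs in
  milliseconds on a 180-day season.
- The noisy-recovery property uses 50 replicate seeds; the distributional
  weather check uses 200 replicates. The whole suite runs in a few
  seconds.
- Report rounding uses Python's banker's rounding; every printed figure
  asserted in tests is insensitive to the half-even/half-up choice.
- Ties in the mitigated-PEC argmax resolve to the earliest day.

## Known limitations

Absolute fitted CN/C values depend on the fixed-CN, uniform-qp
simplifications and should be read comparatively (treated vs control);
no antecedent-moisture CN classes; no sediment routing, deposition or
enrichment; no uncertainty quantification on the point fits; the PEC
correction covers the stream dilution pathway only (pond and sediment
concentrations are outside its scope).
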