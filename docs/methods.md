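# Methods

## Scope and model assumptions

The package treats a shallow (≲1 m), well-mixed aqueous reservoir in
contact with an anoxic, CO₂–N₂ early-Earth atmosphere. The reservoir is
assumed saturated in the dissolving gas at the Henry's-law value — valid
when atmospheric exchange is the only significant source and sink, i.e.
for shallow, well-mixed, not strongly acidic or hot waters; otherwise
the equilibrium numbers are upper bounds. Gases are treated as ideal
(fugacity = partial pressure). All equilibrium constants are fixed at
their 25 °C dilute-water values; temperature and salinity corrections to
the Henry constants and pKa values are deliberately out of the core path
(cooler water holds roughly an order of magnitude more S(IV) per 25 K,
so the defaults are conservative for cool climates). Callers who need
T-corrected constants can override the registry values.

## Speciation

Mass action is evaluated in activities, a = γc, with Extended
Debye-Hückel coefficients (A = 0.5085 M^-1/2, B = 0.3281 M^-1/2 Å^-1,
25 °C water). The ion-size parameters α ship as an explicit, overridable
table taken from the standard Kielland compilation (H⁺ 9, OH⁻ 3.5,
HS⁻ 3.5, S²⁻ 5, HSO₃⁻ 4, SO₃²⁻ 4.5, Ca²⁺ 6, CO₃²⁻ 4.5, HCO₃⁻ 4 Å);
the disulfite adduct HS₂O₅⁻ has no tabulated α and its γ is pinned to 1.
Beyond I = 0.1 M the form is still evaluated but a warning is emitted:
the 0.1 M focus is motivated by lipid-vesicle formation constraints on
prebiotic chemistry, not by a mathematical breakdown.

The unbuffered solve reduces the whole system to one unknown, the proton
activity: every species is an explicit function of a_H⁺ through the
cascade, and the charge-balance residual Σz[C] is monotone in a_H⁺, so
bracketed Brent root finding on log₁₀ a_H⁺ over [−14, 0] converges
unconditionally (solutions outside pH 0–14 raise rather than clip). The
background electrolyte is modelled as inert and charge-symmetric: it
contributes to I but not to the charge balance. Whether the solved ions
also feed back into I is genuinely underdetermined in this model class;
both behaviours are implemented — the default iterates γ(I_total) to a
fixed point (relative change < 1e-10), and `freeze_ionic_strength=True`
keeps I at the background value.

The ionic-strength insensitivity property ("the I = 0 and I = 0.1 M
curves overplot") is stated and tested on the **activity** map of the
solution state. In activity space every species moves by < 15 % between
I = 0 and 0.1 M because the γ factors largely cancel through the charge
balance; in concentration space divalent ions (SO₃²⁻, S²⁻) shift by
factors of ~2.5 through 1/γ alone, which no overplotting curve could
show. The state object carries both maps, so either view is available.

Threshold pressures invert the buffered cascade by Brent root finding in
log-pressure space. Reported "order of magnitude" values use decade
rounding 10^round(log₁₀ p) with exact half-decades rounded down.
Unreachable targets (e.g. millimolar S²⁻ anywhere near neutral pH, a
consequence of pK₂ = 19) raise a dedicated error rather than returning a
huge pressure.

## Atmosphere anchors

Only the published anchor points of the literature photochemistry models
are packaged (the high-CO₂ set: Φ_S = 3×10⁹ → r_H₂S 4×10⁻¹⁰ / r_SO₂
3×10⁻¹⁰; 1×10¹⁰ → 1×10⁻⁹ / 9×10⁻¹⁰; 10^11.5 → r_SO₂ 1×10⁻⁸, plus the
alternate model rows for comparison). Interpolation is log-log linear —
abundances and fluxes span decades and the underlying photochemistry is
closer to power-law than linear — and is exact at the anchors. H₂S has
no anchor above 10¹⁰ cm⁻² s⁻¹, so requests there fail loudly unless
extrapolation is explicitly enabled; dynamic-lake sweeps therefore run
on the two joint anchors, and equilibrium sweeps emit NaN H₂S columns at
the top flux. Column-integrated vs surface mixing-ratio provenance is
carried as metadata (surface values are modestly larger; no correction
is applied).

## Dynamic lake

The steady state balances per-volume deposition F = r·n_atm·v_dep·
(A_catch/A_lake)/d_lake (converted to M/s) against the two redox sinks.
Defaults: d_lake = 100 cm, v_dep(H₂S) = 0.015 cm/s, v_dep(SO₂) = 1 cm/s,
A_catch/A_lake = 1, pH 7, T = 288 K, n_atm = 2.4×10¹⁹ cm⁻³ (the adopted
literature value for a 1 bar column; kept as printed rather than
recomputed from kT). k₁₈ = 4×10³ M⁻² s⁻¹ (measured at pH 9, I = 0.2 M,
applied unchanged to the pH-7 lake — a logged caveat); k₁₇ =
exp(−Ea/RT) with Ea bracketed by 40 and 50 kJ/mol.

The solve is algebraic: the H₂S balance fixes the comproportionation
rate k₁₈[HS⁻][HSO₃⁻]² = (3/2)F_H₂S outright; substituting into the SO₂
balance gives [S(IV)] = (F_SO₂ − 2F_H₂S)/k₁₇ in closed form, and [HS⁻]
follows. The S(IV) split uses the pKa cascade at the lake pH with γ = 1
(the deposition balance is an activity-free treatment), dropping the
negligible HS₂O₅⁻ term. With k₁₈ = 0 the H₂S side has no sink and no
steady state; the solver then returns the SO₂-only closed form with
[HS⁻] = NaN. An explicit ODE relaxation of the two balance equations is
kept in the test suite as the independent oracle.

Solubility cap: when the solved [HS⁻] implies [H₂S(aq)] above the Henry
value the lake would degas, so [HS⁻] is capped at the Henry-equilibrium
value, [S(IV)] re-solved as a quadratic with [HS⁻] fixed, and the H₂S
balance closed by an explicit degassing flux (both capped and uncapped
values are reported, since the published treatment of the cap is
ambiguous). The analogous check on SO₂ shows its steady state can sit
*slightly above* (≈7 %) the Henry value in the slow-k₁₇ regime, so the
package records a warning flag rather than asserting the contrary; the
reported S(IV) is then a mild upper bound.

## Precipitation screen

Strictly first-order, γ = 1 throughout: CO₂(aq) = H·pCO₂ at saturation
(deposition of CO₂ exceeds the weathering calcium flux by ~5 orders of
magnitude, so saturation is safe), carbonate through the two-pKa
cascade, [Ca²⁺] = Ksp(CaCO₃)/[CO₃²⁻] (calcite, two orders of magnitude
less soluble than CaSO₃, controls calcium), and the sulfite saturation
threshold Ksp(CaSO₃)/[Ca²⁺]. Two precision modes: `full` carries all
digits; `paper` rounds every chained intermediate to one significant
figure, matching the back-of-envelope convention in which such screens
are usually quoted (0.03 → 6×10⁻⁵ → 6×10⁻⁵ → 5×10⁻³ M at 0.9 bar;
threshold 1×10⁻³ M at 0.2 bar). Below pH 6.35 the calcite control breaks
down and sulfite salts may precipitate instead; no closed form exists at
this order, so the regime is only flagged.

## Scenario generation

The packaged scenario set covers the study conditions: buffered
reservoirs at pH 8.2 (modern-ocean carbonate buffer), 7 (near-neutral
phosphate-buffer lab conditions), and 4.25 (raindrops under ~0.1 bar
CO₂); unbuffered reservoirs at background I = 0 and 0.1 M; pressure
grids spanning 10⁻¹² to 10⁻⁴ bar (33 points, quarter-decade spacing),
which bracket every plotted regime with margin; and the flux anchors.
Random scenarios (seeded, deterministic) draw pressures log-uniform over
the same decades, pH uniform on [2, 10], background I uniform on
[0, 0.1] M, and k₁₇ log-uniform between the Arrhenius bounds at the lake
temperature. The generator samples parameter space only — the underlying
model is deterministic, so no noise model is added. What these synthetic
sweeps do not emulate: real waters are partially buffered (between the
two bracketing regimes), have additional cation chemistry, and see
transient volcanic forcing; passing tests show internal consistency of
the equilibrium/steady-state model, not field realism.

## Numerical choices

* Root finding: Brent with xtol 1e-15 on log₁₀ a_H⁺; charge-balance
  residuals land below 1e-12 of the gross ionic charge.
* Ionic-strength fixed point: successive substitution, relative change
  < 1e-10, 200-iteration cap with a residual-bearing error.
* Test oracles: dense pH-grid scan at step 1e-4 (agreement required
  within 2e-4 pH) run in frozen-I mode where the scan is well-defined;
  ODE relaxation via BDF with an integration horizon set from the
  closed-form no-comproportionation timescale estimates (agreement
  within 1e-4 relative).
* Problem sizes: sweeps use 33-point pressure grids; oracle comparisons
  use 100–110 random scenarios; the ODE oracle uses 10 draws. These
  sizes make the full suite run in a few seconds while exercising every
  regime boundary (water-dominated, acid-dominated, capped/uncapped).

## Known limitations

No temperature or salinity dependence of constants; no Davies/Pitzer
extension beyond I ≈ 0.1 M; no UV radiative transfer (out of scope);
no kinetic treatment of dissolution (equilibrium assumed); precipitation
of FeS/CuS treated only qualitatively (not computable at first order);
the flux-to-abundance map is only as good as its three published
anchors, so off-anchor fluxes are interpolations, not model output.
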