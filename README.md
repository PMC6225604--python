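# sulfanion

Models of sulfidic-anion concentrations (HS⁻, HSO₃⁻, SO₃²⁻) in shallow
surface waters on the early Earth, fed by volcanogenic atmospheric H₂S
and SO₂. The package is aimed at origins-of-life researchers who need to
know whether a proposed surficial prebiotic chemistry — e.g. cyanosulfidic
networks that consume sulfidic anions as feedstocks and photoreductants —
could have been supplied by nothing more exotic than a lake open to the
atmosphere.

## What it computes

**Henry dissolution + speciation.** A gas Z at partial pressure p_Z
dissolves to [Z] = H_Z·p_Z (H_H₂S = 0.101, H_SO₂ = 1.34 M/bar at 25 °C),
then dissociates:

    H₂S  ⇌ HS⁻  + H⁺   pK₁ = 7.05      SO₂·H₂O ⇌ HSO₃⁻ + H⁺   pK₁ = 1.86
    HS⁻  ⇌ S²⁻  + H⁺   pK₂ = 19        HSO₃⁻   ⇌ SO₃²⁻ + H⁺   pK₂ = 7.2
                                       HSO₃⁻ + SO₂ ⇌ HS₂O₅⁻   pK = 1.5

Mass action is written in activities a = γ·c with Extended Debye-Hückel
coefficients log₁₀γ = −A z²√I/(1 + B α√I). For a *buffered* reservoir the
pH is imposed and the cascade is closed-form; for an *unbuffered* one the
proton activity is solved from charge conservation by bracketed root
finding on log₁₀ a_H⁺ ∈ [−14, 0], with γ iterated to self-consistency
with the total ionic strength.

**Flux → abundance.** Literature photochemistry anchor points map a total
sulfur outgassing flux Φ_S (molecules cm⁻² s⁻¹) to H₂S/SO₂ mixing ratios
(log-log interpolation, loud failure outside the anchor range), and
mixing ratio × bulk pressure gives the partial pressure.

**Redox-limited lake.** A dynamic steady state balances dry deposition
(r·n_atm·v_dep·A_catch/A_lake) against sulfite disproportionation
(first-order k₁₇, Arrhenius-bounded) and hydrosulfide–bisulfite
comproportionation (k₁₈[HS⁻][HSO₃⁻]²), with a Henry solubility cap on
HS⁻ (excess H₂S degasses).

**Precipitation screen.** First-order CaSO₃ saturation check: carbonate
from pCO₂ and pH, calcium from calcite equilibrium, threshold sulfite
from Ksp(CaSO₃)/[Ca²⁺].

## Worked example

```python
from sulfanion import speciation as sp
from sulfanion import lake as lk, atmosphere as atm

# millimolar bisulfite in a pH-7 lake under 1e-8 bar SO2
st = sp.speciate_buffered(sp.so2_system(), {"SO2": 1e-8}, pH=7.0)
print(f"[HSO3-] = {st.concentrations['HSO3-']:.3e} M")

# the same lake left unbuffered acidifies
u = sp.speciate_unbuffered(sp.so2_system(), {"SO2": 1e-8})
print(f"unbuffered pH = {u.pH:.2f}")

# redox-limited steady state at modern-level outgassing, fast k17
ss = lk.steady_state(lk.LakeConfig(), lk.RateModel.fast(293.0),
                     atm.default_model(), 3e9)
print(f"[HSO3-]+[SO3--] = {ss.so2_anion_sum_molar:.2e} M")
```

prints

```
[HSO3-] = 1.850e-03 M
unbuffered pH = 4.86
[HSO3-]+[SO3--] = 1.62e-06 M
```

i.e. a pH-7 reservoir under 10⁻⁸ bar of SO₂ holds ~1.9 mM bisulfite; if
nothing buffers it, dissolved SO₂ (a strong acid once hydrated) drives
the pH down to ~4.9; and even with the fastest plausible sulfite
disproportionation sink, deposition at modern outgassing rates sustains
a micromolar SO₂-derived anion pool — the level usually quoted as
prebiotically relevant.

The same machinery is scriptable from the shell:

```sh
sulfanion speciate --name buffered_so2_ph7 --out sweep.csv
sulfanion flux-sweep --mode dynamic --out lake.csv
sulfanion precip --pco2 0.9 --ph 7 --mode paper
```

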