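# clperox

Kinetic analysis of **cardiolipin (CL) liposome peroxidation** and of the
antioxidants that inhibit it.  The package is aimed at membrane/lipid
biochemists running azo-initiator peroxidation assays monitored by UV
spectrophotometry: it turns raw absorbance time series into
conjugated-diene kinetics, derives the classical inhibited-autoxidation
summary statistics, and ships a mass-action simulator of the underlying
radical chain reaction that doubles as a synthetic-data generator.

## The model in brief

A thermally decomposing azo initiator emits peroxyl radicals at a constant
rate *R*ᵢ.  They abstract bis-allylic hydrogens from polyunsaturated tails
(LH), launching the chain

&nbsp;&nbsp;LOO· + LH → L· + LOOH, L· + O₂ → LOO·  (*k*ₚ = 60 M⁻¹s⁻¹)

terminated by 2 LOO· → products (*k*ₜ) and broken by chain-breaking
antioxidants, QH₂ + LOO· → QH· + LOOH (*k*ᵢₙₕ ≈ 3×10⁵ M⁻¹s⁻¹).  Each
abstraction rearranges a tail into a conjugated diene (ε₂₃₄ =
27 400 M⁻¹cm⁻¹), so the diene record at 234 nm *is* the reaction
coordinate.  From it the package computes:

- *R*ₒₓ — oxidation rate (OLS slope; Beer–Lambert inversion A/ε·l);
- *R*ᵢ = *n*·[AH]/τ — radical flux calibrated from a reference
  antioxidant (α-tocopherol traps *n* = 2 radicals);
- ν = *R*ₒₓ/*R*ᵢ — chain propagation length (tails oxidized per radical);
- inhibition efficiency *R*ₒₓ(uninhibited)/*R*ₒₓ(inhibited);
- inhibition duration τ — intersection of the plateau and post-lag lines;
- stoichiometric factor *n* = *R*ᵢ·τ/[AH].

The simulator integrates the full quinol scheme (semiquinone quenching,
disproportionation, autooxidation by clamped O₂) and reproduces the class
behaviour: chromanols *n* = 2, ubiquinols *n* ≈ 1.8, plastoquinols
*n* ≈ 1.  See `docs/methods.md` for assumptions, calibrations and
limitations.

## Worked example

Desk arithmetic with the library:

```python
from clperox import radical_flux, chain_propagation_length, absorbance_to_concentration

flux = radical_flux(1e-6, 170.0, 2.0)       # 1 uM reference, 170 min lag, n=2
print(f"Ri  = {flux.Ri*1e9:.3g} nM/min")
print(f"nu  = {chain_propagation_length(330e-9, flux):.1f} tails per radical")
print(f"A234=0.04 -> {absorbance_to_concentration(0.04, 27400)*1e6:.2f} uM dienes")
```

prints

```
Ri  = 11.8 nM/min
nu  = 28.1 tails per radical
A234=0.04 -> 1.46 uM dienes
```

i.e. the initiator feeds ~11.8 nM of radicals per minute into the
liposomes, each radical oxidizes ~28 tails before termination, and an
absorbance of 0.04 corresponds to ~1.5 µM of peroxidized tails.

A full closed loop — generate a synthetic panel, then analyze it blind:

```python
from clperox import generate_fixture_panel, GroupConfig, StudyConfig, run_full_pipeline

generate_fixture_panel(seed=7, outdir="panel")          # 14 spectral CSVs + manifest
groups = [
    GroupConfig("pure CL", [f"panel/pureCL_{i}.csv" for i in range(1, 6)], uninhibited=True),
    GroupConfig("alpha-tocopherol", ["panel/alpha-tocopherol_1.csv", "panel/alpha-tocopherol_2.csv"],
                antioxidant="alpha-tocopherol", concentration=1e-6, reference=True),
    GroupConfig("Q10H2", ["panel/Q10H2_1.csv", "panel/Q10H2_2.csv"],
                antioxidant="Q10H2", concentration=1e-6),
    GroupConfig("SkQ1H2", ["panel/SkQ1H2_1.csv", "panel/SkQ1H2_2.csv"],
                antioxidant="SkQ1H2", concentration=1e-6),
]
res = run_full_pipeline(StudyConfig(groups, make_plots=False))
print(f"calibrated Ri = {res.flux.Ri*1e9:.3g} nM/min")
print(res.to_frame().to_string(index=False))
```

```
calibrated Ri = 12.1 nM/min
     antioxidant  rate_nM_min  rate_sd_nM_min  chain_length  inhibition_efficiency  inhibition_duration_min  inhibition_duration_sd  stoichiometric_factor  n_replicates
         pure CL       327.00           3.130         27.00                    NaN                      NaN                     NaN                    NaN             5
alpha-tocopherol         6.93           0.201          0.57                   47.0                    165.0                   0.040                    2.0             2
           Q10H2         2.46           0.142          0.20                  133.0                    150.0                   0.080                    1.8             2
          SkQ1H2         2.46           1.090          0.20                  133.0                     83.9                   0.096                    1.0             2
```

The analyzer recovers the generator's ground truth: a 327 nM/min
uninhibited rate (configured 330), a radical flux of 12.1 nM/min
(configured 11.8), lags of 165/150/84 min against the stoichiometric
predictions 169.5/152.5/84.7, and trapping stoichiometries 2.0/1.8/1.0.
The quinols (Q₁₀H₂, SkQ1H₂) hold the oxidation rate ~3× lower than the
chromanol — the relative-protection ordering the assay is designed to
resolve — while ubiquinol protects almost twice as long as plastoquinol
because its semiquinone resists autooxidation.

A command-line interface mirrors the library: `clperox analyze`,
`clperox simulate` and `clperox reproduce` (the latter recomputes every
derivable cell of the published summary table and flags agreement).

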