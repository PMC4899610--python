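# Methods

## The assay being modelled

Liposomes of bovine-heart cardiolipin (CL, ~100 µM; four linoleoyl tails
per molecule, so ~400 µM oxidizable tails) are oxidized by a thermally
decomposing azo initiator that emits peroxyl radicals at a constant rate
Ri.  Peroxidation rearranges the tail's double bonds into a conjugated
diene absorbing at 234 nm (ε = 27 400 M⁻¹ cm⁻¹), so the diene
concentration is read off a double-beam UV record sampled every 5 min with
~0.002 AU instrument noise.  Chain-breaking antioxidants (quinols,
chromanols) suppress diene accumulation until they are exhausted; their
own expenditure is visible as an oxidized-minus-reduced difference band
near 281 nm.

The analysis layer reduces such records to the classical
inhibited-autoxidation summary statistics:

- **uninhibited oxidation rate** R_ox: OLS slope of the diene trace over
  the first 25 min after initiation (configurable window); on two points
  this reduces exactly to the difference quotient;
- **radical flux** Ri = n·[AH]/τ, calibrated from a reference antioxidant
  of known stoichiometry (chromanols: n = 2, since neither the chromanol
  nor its radical reacts appreciably with O₂);
- **chain propagation length** ν = R_ox / Ri (tails oxidized per radical);
- **inhibition efficiency** R_uninhibited / R_inhibited;
- **inhibition duration** τ: intersection of the plateau line with the
  post-lag line (below);
- **stoichiometric factor** n = Ri·τ/[AH].

Replicates are combined as mean ± sample (n−1) standard deviation; groups
with fewer than three runs are flagged.  Reported tables round rates to 3
significant figures, chain length and stoichiometry to 2, efficiency to
the nearest integer.

## Reaction scheme and simulator

The generator integrates the mass-action scheme (O₂-rich medium; carbon
radicals become peroxyls instantaneously, and the initiator-derived
peroxyl is lumped into the LOO· pool):

    source      → LOO·                Ri (zero order)
    LOO· + LH   → LOO· + diene        k_p = 60 M⁻¹s⁻¹
    2 LOO·      → products            k_t (calibrated, see below)
    QH₂ + LOO·  → QH· + LOOH          k_inh = 3×10⁵ M⁻¹s⁻¹ (quinols)
    QH· + LOO·  → Q + LOOH            k_q = k_inh
    2 QH·       → Q + QH₂             k_disp = 10⁸ M⁻¹s⁻¹
    QH· + O₂    → Q + O₂·⁻            k_auto (class-specific; O₂ clamped at 200 µM)

A diene is counted at H-abstraction (the k_p step), which is where the
conjugated system forms; the LOOH produced later by quenching belongs to
the same molecule, so peroxides and dienes stay stoichiometrically equal
and the lipid pool obeys [LH] + [diene] = const.  The quinone ring is
conserved: [QH₂] + [QH·] + [Q] = const (jumping by the dose at a delayed
addition).  A cumulative counter of the two LOO·-consuming antioxidant
channels is integrated alongside the species; divided by the initial
quinol concentration at exhaustion it gives the **effective
stoichiometry**.  Disproportionation regenerates QH₂ and therefore does
not count as a quench directly, but it restores material to the pool —
with no autooxidation the count converges to 2 whichever of the k_q or
k_disp channels dominates.

### Calibrations (all overridable)

- **Ri** defaults to 11.8 nM/min, the flux implied by a 1 µM chromanol
  reference lasting 170 min with n = 2.
- **k_t** is not independently known for this system; it is calibrated
  once from the quasi-steady closed form R_ox = k_p[LH]·√(Ri/2k_t) so the
  uninhibited rate is 330 nM/min at default composition, giving
  k_t ≈ 1.87×10³ M⁻¹s⁻¹.  The calibrated value is recorded on the
  constants object and logged.
- **k_auto** per class is chosen from the closed-form branching
  n = 2/(1+p), p = k_auto[O₂]/(k_auto[O₂] + 2k_disp[QH·]_ss), so the
  effective stoichiometry tracks the class values: chromanol 0 (n = 2),
  ubiquinol 125 M⁻¹s⁻¹ (n ≈ 1.8), plastoquinol 5×10⁴ M⁻¹s⁻¹ (n ≈ 1).
  Methoxy-substituted ubisemiquinones are oxidized by O₂ far more slowly
  than plastosemiquinones, which is exactly this knob.
- **k_inh** for the chromanol class defaults to 1×10⁵ M⁻¹s⁻¹, three-fold
  below the quinol value, reflecting the consistently higher inhibited
  rates (chain length ~0.9 vs ~0.3–0.4) of chromanols in this membrane;
  the generic default keeps k_inh/k_p = 5000.

### Radical-pool treatment

With k_p = 60 M⁻¹s⁻¹, [LH] = 400 µM and the calibrated k_t, the peroxyl
pool relaxes with τ = ν/(k_p[LH]) ≈ 19 min.  A literal integration of the
scheme therefore shows ~19-min transients at initiation and after
antioxidant exhaustion that the measured records do not show (diene growth
is linear from the first 5-min sample).  The generator's default
(`radical_model="qssa"`) therefore treats [LOO·] quasi-stationarily — the
positive root of 2k_t x² + (k_inh[QH₂] + k_q[QH·])x = Ri — which is the
same algebra under which R_ox = k_p[LH]√(Ri/2k_t) and τ = n[AH]/Ri are
exact.  The full stiff integration (`radical_model="full"`, BDF,
rtol 1e-8, atol 1e-13 M, optionally seeded at the quasi-steady value) is
retained for mechanistic work and is cross-checked in the test suite
against an exact (Gillespie) stochastic simulation of a reduced system at
~100-molecule occupancy.  Internally time is in seconds and constants in
M⁻¹s⁻¹; the API reports minutes and M/min.

### Lag estimation

The inhibition duration is the intersection of two lines fitted to the
diene trace after the addition time.  The plateau line is fitted to the
longest contiguous run of points whose local slope stays below 25% of the
uninhibited rate.  The terminal line is fitted to the first ⌈0.2·N⌉
points immediately after that plateau: this window is used rather than
the trailing points because substrate depletion (LH falls ~10% per
100 min of uninhibited oxidation) bends the late curve downward and would
systematically pull the intersection several minutes early — a bias that
is irrelevant for a 170-min lag but reaches ~15% for a 40-min lag.  When
the plateau extends to the end of the record the trailing 20% is fitted
instead, and a terminal slope below 25% of the uninhibited rate yields the
"inhibition ongoing" sentinel (∞).  On noiseless generator output this
construction recovers n[AH]/Ri within 5% for n ∈ {1, 2} and
[AH] ∈ {0.5, 1, 5} µM.

Note that the plateau slope is *not* the initial inhibited rate: because
the momentary rate scales as Ri·k_p[LH]/(k_inh[QH₂]) and [QH₂] falls
roughly linearly, the plateau steepens toward exhaustion and its fitted
slope is several-fold above the initial closed form.  The fixture-panel
manifest therefore records both (`rate_initial_nM_min` and the
noiseless-analysis `rate_nM_min`); recovery is judged against the latter.

### What the synthetic data does and does not emulate

`synthesize_absorbance` forward-transforms trajectories into spectra on a
210–300 nm grid: a Gaussian diene band centred at 234 nm peaking at
27 400 M⁻¹cm⁻¹, the antioxidant's difference band at its monitor
wavelength, and additive Gaussian noise (default 0.002 AU), sampled every
5 min.  The 6-nm band widths keep the two bands spectrally separated,
mirroring the isosbestic-clean monitoring the assay relies on.  Real
spectra have asymmetric bands, baseline drift, finite isosbestic leakage
and turbidity changes, none of which are modelled — so passing tests
demonstrate correctness of the kinetic analysis under the stated noise
model, not robustness to instrumental artefacts.  The two-liposome
(carrier-vesicle) delivery geometry is reduced to the aqueous-competition
closed form `competition_slowdown`; with interception probability
f = k_inh[AH]/(k_inh[AH] + k_p[tails]) the naive slowdown 1/(1−f) is
~13.5 at 1 µM vs 400 µM tails, while the chain-amplified variant
(propagation denominator scaled by ν = 28) gives ~1.4.  The observed
slowdown in such experiments lies between the two; both variants are
exposed and neither is asserted quantitatively.

### Measurement-noise floor

With 0.002 AU noise, 5-min sampling and three replicates, the propagated
1σ of a plateau-slope estimate over a 50–170 min window is
~0.15–0.5 nM/min.  Inhibited-phase rates of ~1–7 nM/min therefore cannot
be recovered to 5% from noisy data — no estimator can beat the Fisher
bound — so closure tests hold inhibited rates to max(5%, 3σ propagated),
while every rate well above the floor (uninhibited ~330 nM/min) is held
to 5%.  Estimator unbiasedness itself is asserted on noiseless runs.

## Default panel (study conditions)

`generate_fixture_panel` emits five uninhibited runs (120 min) and three
runs per antioxidant class (representatives: α-tocopherol, Q₁₀H₂,
SkQ1H₂; 1 µM; two incorporated at t = 0 and one added at 30 min;
duration = lag + 120 min rounded up), all at 100 µM CL, 0.002 AU noise,
5-min sampling.  Seeds for the per-run noise are spawned deterministically
from the panel seed, so the same seed reproduces the files byte for byte.
The manifest stores the generator's closed-form truths (330 nM/min
uninhibited rate, n[AH]/Ri lags with nominal class stoichiometries, the
noiseless-analysis plateau rates).

## Degenerate inputs and sentinels

Empty or malformed spectral files raise format errors; non-monotone times
report the offending index.  Wavelength lookup is nearest-column within
1 nm.  The default baseline is the first-sample absorbance (the reference
cuvette removes static absorbers but not the t = 0 offset); negative
concentrations from noise are retained unclipped so rate fits stay
unbiased, with a warning below −3σ.  An inhibited rate ≤ 0 reports the
"complete inhibition" sentinel rather than an infinite efficiency; an
antioxidant that never exhausts within the run reports NaN effective
stoichiometry; a summary row without measurable durations (e.g. a
compound lost variably during liposome preparation) carries "N.A."
rather than an imputed number.

## Reproduction of the published summary table

`reproduce_published_table` recomputes every derivable cell (chain
lengths, efficiencies) from the transcribed mean rates and the published
calibration inputs (1 µM reference, 170 min, n = 2 → Ri = 11.76 nM/min,
printed as 11.8).  The 170-min figure is used here because the published
derived columns were computed with it; pipeline runs on actual spectra
instead calibrate Ri from the replicate-mean reference lag measured in
the data.

## Known limitations

- No spectral unmixing: overlapping absorbers beyond the modelled bands
  will bias the Beer–Lambert inversion.
- The clamped-O₂, constant-Ri idealization ignores initiator depletion
  (~few % over 5 h) and any O₂ gradient.
- Antioxidant exchange between vesicles is not modelled (it is
  hours-slow for hydrophobic compounds).
- The chromanol k_inh default encodes a membrane-specific empirical
  ratio, not a first-principles constant.
- Quantitation coefficients for chromanols and all 281-nm difference
  coefficients are provisional literature/stand-in values and should be
  overridden with measured ones where available.
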