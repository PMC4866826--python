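# girkgate

Quantitative analysis of how the neuronal GIRK2 (Kir3.2) potassium channel
is opened by membrane-anchored G-protein βγ subunits (Gβγ) and amplified by
intracellular Na⁺.

GIRK2 is the channel that silences neurons when inhibitory G-protein-coupled
receptors (e.g. GABA_B receptors) release Gβγ onto the inner membrane
leaflet. The channel is a homotetramer with four Gβγ sites and four Na⁺
sites. This package implements, as tested reusable code:

- a **25-state equilibrium gating model** over the occupancy pairs
  (i Na⁺, j Gβγ), 0 ≤ i, j ≤ 4, built from a binding polynomial with
  pairwise cooperativity factors;
- the **calibration fits** (Hill, rectangular hyperbola, shared-coefficient
  Hill family, Kd-vs-Na⁺ hyperbola) and the **activity-matching procedure**
  that converts solution concentrations of His-tagged soluble Gβγ into
  membrane Ni-NTA-lipid mole fractions, including the His10 vs His4
  anchoring-stoichiometry estimate;
- the **global fit** of the model to two-dimensional titration surfaces
  (normalized current vs mole fraction × Na⁺) and the cooperative vs
  non-cooperative (b = 1) model comparison;
- the **limiting-slope stoichiometry analysis** of log activity vs log Gβγ;
- the **Na⁺-amplification inversion** that estimates the membrane Gβγ
  concentration in neurons from paired current recordings at two internal
  Na⁺ levels, with unit conversions to areal density and slab molarity;
- **synthetic-data generators** that emulate every measurement type, so the
  whole pipeline runs and is tested without any external data.

## The model

The statistical weight of state (i, j) relative to the empty channel is

    w(i,j) = C(4,i) C(4,j) (Na⁺/K_dn)^i (m/K_db)^j · n^{-i(i-1)/2} · b^{-j(j-1)/2} · η^{-ij}

with `m` the membrane Gβγ level in Ni-NTA-lipid mole-fraction units, `K_dn`
and `K_db` the first-ligand dissociation constants, `b` the Gβγ–Gβγ
cooperativity factor per occupied-site pair, `n` the Na⁺–Na⁺ factor (fixed
at 1), and `η` the Na⁺/Gβγ cross-cooperativity factor. Populations are
`c(i,j) = w(i,j)/Z` with `Z = Σ w`, and predicted normalized current is
`A = Σ c(i,j) θ(i,j)` where `θ(i,j) = 0` unless j = 4 and
`θ(i,4) = θ₀₄ + i(θ₄₄−θ₀₄)/4`.

The reference parameter set (the global-fit constants used throughout) is
`K_dn = 60 mM, K_db = 0.019, b = 0.30, η = 0.63, θ₀₄ = 0.49, θ₄₄ = 1.19`.
Since `b < 1`, the fourth Gβγ binds with `b⁻³ ≈ 37`-fold higher affinity
than the first; full Na⁺ occupancy raises Gβγ affinity `η⁻⁴ ≈ 6`-fold.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic
data; each prints what it found and writes a report under `results/`.

```
python analysis/01_simulate_datasets.py
python analysis/02_calibrate_anchoring.py
python analysis/03_fit_titration_surface.py
python analysis/04_na_dependence_of_gbg_affinity.py
python analysis/05_infer_neuronal_gbg.py
```

The final stage prints (from one run of the pipeline above):

```
neuron currents: 10 cells at 0 mM, 11 cells at 32 mM internal Na+
  group means: 20.0 +/- 1.5 pA vs 154.2 +/- 5.2 pA
Na+ amplification = 7.71-fold [6.69, 9.08] (bootstrap 95% CI)
inverted membrane Gbg level = 0.002833 mole fraction [0.0026, 0.00306]
  = 1138 Gbg per um^2 (single leaflet, 0.83 nm^2 per lipid, 3 NTA lipids per Gbg)
  = 270 uM in a 70 A membrane-adjacent slab
fourth-subunit Kd = 0.000513 mole fraction = 51 uM
  at kon = 1e7 /M/s: single-complex lifetime 1.9 ms; fully liganded channel 0.49 ms
```

Reading: the ~8-fold Na⁺ amplification of the simulated neuronal currents
inverts to a membrane Gβγ level of ≈ 0.003 mole fraction (the simulation's
true value was 0.00278), i.e. on the order of 1200 Gβγ per μm² or ≈ 280 μM
in the 70 Å solution layer adjacent to the membrane — squarely on the steep
limb of the activation curve, where small Na⁺ changes produce large changes
in inhibitory current. The weak fourth-subunit affinity (≈ 50 μM) implies
millisecond-scale Gβγ–channel complexes, so receptor-controlled Gα kinetics,
not Gβγ unbinding, set the duration of GIRK responses.

There is also a command-line interface exposing each stage
(`girkgate --help`): `simulate-surface`, `fit-surface`,
`compare-cooperativity`, `fit-hill`, `calibrate`, `fit-kd-vs-na`,
`amplify`, `estimate-gbg`, `units`, `limiting-slope`.

## Layout

```
src/girkgate/      model, calibration, surface, amplification, synth, io, cli
analysis/          numbered narrative drivers (simulate → calibrate → fit → infer)
tests/             pytest suite incl. property tests and recovery studies
scripts/           acceptance.py
docs/methods.md    model, assumptions, numerical choices, limitations
```
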