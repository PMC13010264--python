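# cellodyn

Quantitative analysis of enzymatic cellulose degradation at the nanoscale,
for researchers studying why cellulose hydrolysis slows down and how the
answer differs between dispersed **cellulases** (free enzymes, e.g. from
*Trichoderma reesei*) and the **cellulosome** (the multi-enzyme complex of
*Clostridium thermocellum*). Two toolboxes, plus synthetic ground-truth
generators that make every stage verifiable without instrument data:

1. **Isotope-competition adsorption kinetics** (`cellodyn.kinetics`).
   Enzyme pre-adsorbed on unlabeled cellulose redistributes to added
   ¹³C-labeled cellulose; the isotope composition of released glucose is
   fitted with a three-pool model (irreversible *I*, reversible *R₁₂*,
   *R₁₃*, free *F*):

   ```
   dR_j/dt = k_on·S_j·F − k_off·R_j,   F = E_T − I − R12 − R13
   I = E_i·E_T  (fixed on the ¹²C substrate, catalytically active)
   ```

   yielding the desorption rate constant *k*_off and the irreversibly
   adsorbed fraction *E*_i. At equal substrate loads the long-time
   ¹²C/¹³C release ratio is `(1 + E_i)/(1 − E_i)` — unity iff adsorption
   is fully reversible. Bulk descriptors (initial rate, conversion,
   rate-vs-conversion stall extrapolation, specific adsorbed-enzyme
   activity R_ads) are included.

2. **Time-lapse force-volume AFM nanomechanics** (`cellodyn.afm`,
   `cellodyn.degradation`). Stacks of paired height/modulus maps of single
   fibrils on HOPG are leveled, drift-registered, and segmented; moduli
   are normalized per frame to the HOPG background (**E\***, cancelling
   tip/laser drift), averaged over nanodomains (**E\*_av**, minimum
   ≈ 10,000 nm²), and paired with fiber volume and **relative activity**
   (% of initial material lost per minute). The E\*_av-vs-loss trajectory
   is classified as *continuous* (layer-by-layer ablation, the cellulase
   signature) or *biphasic* (lag then sharp rise — cavity/fragmentation,
   the cellulosome signature) by AICc comparison of a line against a
   lag-constrained two-segment fit.

`cellodyn.synthetic` generates competition series, core–shell fibril
phantoms, degradation stacks in both modes (with tilt, drift, noise, and
gain jitter applied on top of a recorded ground truth), and DMT-model
force curves.

## Worked example

```python
import dataclasses
from cellodyn import kinetics as K, synthetic, afm, degradation

# --- competition kinetics: simulate at the cellulosome operating point and refit
truth = K.AdsorptionParams(k_off=0.005, E_i=0.54)
design = dataclasses.replace(K.CompetitionDesign(), noise_sd=0.03)
series, _ = synthetic.gen_competition_data(truth, design, seed=1)
fit = K.fit_competition(series, design)
print(f"k_off = {fit.k_off:.4f} 1/min, E_i = {fit.E_i:.3f}")
# k_off = 0.0050 1/min, E_i = 0.563

# --- AFM: fragmentation-mode degradation end to end
phantom = synthetic.FibrilPhantom()
scenario = synthetic.DegradationScenario(mode="fragmentation", seed=7)
stack, gt = synthetic.gen_fragmentation_stack(phantom, scenario)
records, qc = afm.process_stack(stack)
traj = degradation.build_trajectory(records)
pattern = degradation.classify_pattern(traj)
corr = degradation.correlate_rate_stiffness(traj)
print(pattern.label, f"breakpoint at {pattern.breakpoint_loss_pct:.1f}% loss,",
      f"truth {gt.breakpoint_loss_pct:.1f}%, rate-stiffness rho = {corr.spearman_rho:.2f}")
# biphasic breakpoint at 20.3% loss, truth 18.3%, rate-stiffness rho = -0.04
```

The fitted irreversible fraction lands near the 54% truth despite 3%
fraction noise; the fragmentation stack is recognized as biphasic with the
breakpoint close to the ground-truth knee, and the degradation rate is
uncorrelated with stiffness — the cellulosome signature. An ablation-mode
stack instead yields a `continuous` label with a strongly negative
rate–stiffness correlation (activity drops as the surface stiffens).

A CLI mirrors the library:

```bash
cellodyn simulate-competition --k-off 0.01 --e-i 0.19 --noise-sd 0.03 --seed 1 --out series.csv
cellodyn fit-competition --data series.csv --out fit.json
cellodyn simulate-afm --mode ablation --seed 2 --out-prefix sim
cellodyn process-afm --height sim_height.tif --modulus sim_modulus.tif \
                     --config sim_config.yaml --out traj.csv
cellodyn analyze-degradation --traj traj.csv --out result.json
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates, from scratch, synthetic ¹³C-competition data at the
cellulosome and cellulase operating points (equal 1.0 mg/mL substrates,
E/S 0.83 mg/g, 3% fraction noise, 20 replicates each), refits the kinetic
model to every replicate, and writes the mean recovered
irreversibly-adsorbed-enzyme percentage for each system to the JSON file.

See `docs/methods.md` for the models, numerical choices, defaults, and
limitations.
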