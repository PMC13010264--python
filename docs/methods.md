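# Methods

`cellodyn` couples two quantitative procedures used to study how
cellulolytic enzyme systems — dispersed fungal cellulases and the
bacterial multi-enzyme cellulosome — degrade bacterial cellulose fibrils,
and why the reaction slows down: an isotope-competition model of enzyme
adsorption dynamics, and a time-lapse force-volume AFM pipeline that
relates the evolving surface stiffness of single fibrils to their material
loss. Because no raw data accompany the study design, every input can be
generated synthetically with known ground truth; this note records the
models, the defaults, and what a passing test does and does not establish.

## 1. Isotope-competition adsorption model

**Setup.** Enzyme is pre-adsorbed on unlabeled (¹²C) cellulose; an equal
concentration (1.0 mg/mL) of uniformly ¹³C-labeled cellulose is added at
t = 0. At the low enzyme load used (E/S ≈ 0.83 mg/g) the free-enzyme
concentration is effectively zero. The isotope composition of released
glucose, measured per sampling interval, reports how the adsorbed enzyme
redistributes between the two substrates.

**Model.** Three enzyme pools:

- irreversible `I = E_i · E_T`, fixed on the ¹²C substrate and
  catalytically active;
- reversible pools `R12`, `R13` with
  `dR_j/dt = k_on · S_j · F − k_off · R_j`;
- free `F = E_T − I − R12 − R13` (conservation).

Glucose release from substrate *j* is proportional to the enzyme bound to
it (`kcat_app`), which cancels from the observed fractions. At equal
substrate concentrations the long-time ¹²C/¹³C release-rate ratio is
`(1 + E_i)/(1 − E_i)` — unity iff adsorption is fully reversible. Treating
the irreversible pool as catalytically active is required for that ratio
to exceed one at steady state, which is the experimental observation the
model exists to explain; an inactive irreversible pool would relax to
unity regardless of `E_i`.

**Numerics.** With substrate depletion neglected (the default, matching a
fit restricted to the early reaction interval) the state
`(R12, R13, G12, G13)` obeys a constant-coefficient affine ODE, which is
propagated *exactly* between sample times with a matrix exponential — this
sidesteps the stiffness introduced by the large `k_on`. A `solve_ivp`
(LSODA) path with explicit substrate consumption (0.162 mg anhydroglucose
per µmol glucose) is available for forward simulation only.

**Identifiability and fitting.** Because `F ≈ 0`, `k_on` is not
identifiable and is fixed at 10⁴ mL·mg⁻¹·min⁻¹ (adsorption-limited
regime); the free parameters are `(k_off, E_i)`, fitted to the
per-interval ¹²C fraction by bounded trust-region least squares, with 95%
confidence intervals from the Gauss–Newton covariance. A series with no
resolvable transient (data span below three residual standard deviations)
fixes only the steady-state level, i.e. `E_i`; the result is then flagged
`k_off_identifiable = False` rather than reported at a bound.

**Defaults.** Sampling at 15–600 min (12 samples) with the full range as
fit window. The window spans ≥ 3 desorption time constants at the slowest
default `k_off`, which is what keeps the `(k_off, E_i)` estimates
decorrelated; with sampling truncated at ~1.8 τ the Monte-Carlo spread of
the recovered `E_i` roughly doubles. The operating points used throughout
(cellulosome `E_i = 0.54`, cellulase `E_i = 0.19`) are the study's fitted
values; the paired desorption constants (0.005 and 0.010 min⁻¹) are
package defaults chosen in the reported "very slow dissociation" regime,
not published numbers. Fraction noise is truncated-Gaussian (σ = 0.03)
with renormalization to `f12 + f13 = 1`.

## 2. Force-volume AFM pipeline

Inputs are paired height (nm) and elastic-modulus (MPa) maps per frame,
recorded on fibrils deposited on HOPG at ~5 min intervals over ≤ 2 h,
default 2 nm/px (the 10,000 nm² ↔ 2500-point minimum-area rule implies
4 nm²/point).

Processing order and the reasoning behind it:

1. **Two-pass plane leveling.** A least-squares plane fitted on background
   pixels is subtracted and the background median zeroed. The first pass
   uses a provisional (robust-threshold) background; after segmentation the
   plane is refit on the proper background *excluding a 4-px guard band
   around any material*. The guard band matters quantitatively: fiber-edge
   pixels that fall below the segmentation threshold (tip convolution,
   interpolation tails) otherwise bias the plane intercept by ~0.01–0.03 nm
   in a way that varies frame to frame, which is the dominant noise term in
   the pixel-sum–based activity measure.
2. **Drift registration.** Phase cross-correlation with 10× upsampled peak
   refinement, *sequential* (each frame against its temporal neighbour,
   offsets accumulated): a late, heavily degraded frame shares too little
   structure with the first frame for a direct correlation to lock on.
   Offsets are reported at sub-pixel precision but applied rounded to whole
   pixels — integer translation is exact (no resampling), so region sums
   acquire no interpolation noise, and the ≤ 0.5 px residual is harmless to
   region statistics. Registration of a flat frame is flagged, not guessed.
3. **Segmentation.** Threshold = background median + 5 robust σ (MAD);
   connected components ≥ 100 px with elongation ≥ `min_aspect` form the
   fiber class. Single-frame use defaults to aspect ≥ 3 (excluding compact
   residues such as enzymes or detached debris); the time-lapse pipeline
   relaxes this to 2 because isolated crystalline cores at late degradation
   stages are legitimate — indeed central — analysis targets. Volumetrics
   additionally use a broader *material* mask (any above-threshold
   component ≥ 25 px), since attached fragments too compact for the fiber
   class still hold real volume.
4. **HOPG normalization (E\*).** Each frame's modulus map is scaled so its
   background mean equals the nominal HOPG value (default 1000 MPa; only
   the per-frame ratio matters). Any uniform per-frame gain — tip wear,
   laser drift — cancels exactly, and MPa units are preserved so the
   reported E\* peak remains in the 10–20 MPa range.
5. **Nanodomain statistics.** `E*_av` is the arithmetic mean over fiber
   pixels in the ROI, computed on a mask eroded by 2 px and stripped of
   pixels above half the HOPG reference (both remove fiber/support mixture
   pixels, which are up to ~25× stiffer than the fiber and would otherwise
   dominate the mean). Minimum analysis area ≈ 10,000 nm² (2500 points) is
   applied as an *admission* rule on the first frame; an admitted unit is
   followed to near-complete degradation with a 100-px per-frame floor —
   material loss is the signal under study, so a per-frame 2500-point gate
   would censor exactly the late phase the analysis exists to see.
   Distribution summaries report the KDE mode (Silverman bandwidth),
   adjusted Fisher–Pearson skewness, and a peak-count unimodality flag;
   multimodal ROIs are excluded.
6. **Volumetrics and activity.** Volume = Σ height · px² over the material
   mask. Relative activity (% of initial material per minute) is the
   backward difference of the height pixel sum over one *fixed* region (the
   union of material masks, dilated 3 px to catch interpolation tails),
   normalized by the initial sum — a fixed region makes the temporal
   difference immune to segmentation flicker.

The contact model for single force–distance curves is sphere-on-flat DMT,
`F = (4/3)·E·√R·δ^{3/2} − F_adh` inside contact, fitted on the retract
segment in log-modulus parameterization (Hertz variant available). Round
trips recover 5 MPa–2 GPa within 1% at 1% force noise.

## 3. Degradation analysis

Trajectories pair relative volume, raw and 0–100% scaled `E*_av`, and
activity per frame, dropping excluded frames. Rate–stiffness coupling is a
least-squares slope plus Spearman rank correlation (invariant under any
monotone rescaling of E\*). Pattern classification compares a single line
against the best *lag-compatible* continuous two-segment fit (breakpoint on
a 50-point interior grid; first-segment |slope| < 20% of the single-line
slope) using AICc with two extra parameters; "biphasic" requires that such
a fit exist and beat the line. Restricting the two-segment hypothesis to
lag-shaped fits is deliberate: measured curves can rise in more than one
step, and an unconstrained breakpoint locks onto the largest curvature —
possibly a late secondary rise — misplacing the knee and failing the
flatness test even when an initial lag phase is plainly present. The
false-positive rate on constant-plus-noise data (n = 10) is ≤ 10%.

## 4. Synthetic world

**Fibril phantom.** Half-elliptical ridge (default 1000 × 24 × 20 nm;
closed-form volume π/4·L·W·H, rasterized with 4× supersampling to < 2%
discretization error), with a stiff crystalline core (40 MPa) under a
softer shell (15 MPa, 6 nm thick; logistic depth transition pinned to the
endpoint values) and periodic soft segments (spacing 250 nm) emulating
twists and fiber ends. Soft-segment width (24 nm) and modulus factor (0.7)
are set so that even complete removal of all soft segments changes the
surface mean by < 5% — the fragmentation mode's early lag phase must not
be spoofed by preferential soft-site attack alone.

**Ablation (cellulase-like).** Uniform layer-by-layer erosion; the exposed
surface follows the core–shell depth profile, so the surface mean modulus
rises monotonically with loss. The per-frame erosion rate decays as
`rate₀·(1 − s)` with `s` the 0–1 scaled depth modulus — the degradation
rate is programmed to fall as the surface stiffens, which is the cellulase
phenotype; with full slowdown the depth asymptotically approaches the
shell thickness and both series stay strictly monotone over the run.

**Fragmentation (cellulosome-like).** Full-depth cavities nucleate as a
Poisson process (75% at soft sites; intensity ramping linearly in time,
mean 0.6/frame — fragmentation intensifies late) and expand; fiber ends
also recede. Fragments shorter than 150 nm undergo near-complete
degradation: their surface modulus ramps toward the core value and they
erode away. The total loss per frame is rate-controlled at 2.2% of the
initial volume (±5% jitter), with a carry of the column-quantization
remainder between frames, partitioned between cavity expansion and
fragment consumption — the cellulosome phenotype is that its degradation
rate is unaffected by substrate stiffening, and the jitter/carry prevent
spurious rank correlations from exact ties. The ground-truth breakpoint is
the knee of the noise-free (loss, surface-modulus) curve.

**Corruptions** (applied after degradation, truth recorded before): static
tilt (0.004/0.006 nm/px), cumulative drift (1.2/−0.8 nm per frame),
additive height noise (0.3 nm), multiplicative modulus noise (5%), and
per-frame gain jitter (±20%) emulating tip and laser drift. All generators
are deterministic under a fixed seed.

**What a green test establishes — and what it does not.** The synthetic
world exercises the full measurement chain (tilt, drift, gain, noise,
segmentation, normalization) with known truth, so passing tests establish
that the pipeline recovers volumes within ~1–3%, keeps E\*_av invariant
under per-frame gain, and separates the two degradation signatures at the
stated noise. It does not emulate tip-shape convolution, raster-scan line
noise, piezo creep, rotation, or real cellulose heterogeneity beyond the
core–shell/soft-segment idealization; agreement here does not validate
the contact mechanics of real measurements.

## Known limitations

- The kinetic fit assumes equal, constant substrate concentrations inside
  the fit window; strong conversion during sampling biases `E_i` upward.
- Breakpoint uncertainty is reported only through the model-comparison
  score, not a confidence interval.
- Registration is translation-only; rotational drift would alias into
  apparent volume change.
- `E*_av` of strongly bimodal late-stage fiber populations (shell remnants
  plus exposed cores) is a mixture mean; the unimodality flag marks, but
  does not resolve, such frames.
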