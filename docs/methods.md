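# Methods

This note documents the models implemented in `cytodiff`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## 1. FRAP forward model and fitting

**Model.** The observable is a line profile *I(x, t)* along the long axis
of a rod-shaped cell, recorded after bleaching one pole. The profile
obeys the 1D diffusion equation ∂u/∂t = D ∂²u/∂x² with no-flux
(reflecting) boundaries at both ends — the cell is closed, so no
fluorophore crosses the poles.

**Discretisation.** Crank–Nicolson on the uniform pixel grid, with
ghost-node Neumann boundaries. Internal sub-steps are exact divisors of
each frame interval, chosen so the diffusion number r = D·Δt/dx² ≤ 1 per
sub-step. Consequences, both tested: the column sums of the discrete
Laplacian vanish, so total intensity is conserved to solver precision
(≤ 1e−10 relative); with r ≤ 1 the update matrix is a convex
combination, so the discrete maximum principle holds. Against the
closed-form spreading Gaussian (variance σ₀² + 2Dt) on a domain large
enough that the walls are irrelevant, the solver is accurate to relative
L2 < 1e−3 at the default grid.

**Fitting.** The first post-bleach frame is taken verbatim as the
initial condition — no parametric bleach shape is assumed. A single
multiplicative scale and additive offset, absorbing acquisition
photobleaching and background, are solved in closed form inside a
bounded scalar search over log₁₀(D) (tolerance 1e−4, default bounds
1e−3 to 50 µm²/s, spanning all cytoplasmic values of interest).
Residuals are summed over all frames after the first.

**Normalisation.** When a mean pre-bleach profile is available the stack
is divided by a *first-order (linear) fit* to it rather than by the raw
profile. The pre-bleach reference is typically an average of only ~3
frames; dividing by it verbatim imprints its pixel noise on every frame
as fixed-pattern noise, which empirically doubles the median error of
the recovered D in the synthetic sweep. Illumination varies smoothly
over the few micrometres of a cell, so a linear reference captures the
gradient (verified on a synthetically tilted stack) while rejecting the
pixel noise. Pass `normalize=False` to fit raw intensities.

**Identifiability.** A stack whose bleach contrast (peak-to-peak of the
lightly smoothed first frame) is below three times the noise estimate
(from the difference of the last two frames, where the profile is nearly
stationary) is flagged non-identifiable and no D is reported. This is
the pipeline's analogue of discarding cells that were too noisy or
showed no bleach; excluded counts are reported.

**Expected accuracy.** With 2% Gaussian read noise, 8–16 pixels and
50–150 frames, single-stack recovery has a median relative error of
2–4% across D ∈ [0.05, 15] µm²/s when the acquisition is scaled to the
expected speed (`acquisition_for`: 4 ms intervals for fast probes, up to
100 ms × 150 frames for slow ones — mirroring experimental practice).
Individual stacks can err by 10–20% in unlucky noise realisations; the
per-probe statistic of record is therefore the population median.

## 2. Two-state effective diffusion and the site census

At exchange much faster than the measurement time the displacement
kernel over a window Δt is the convolution of a free-state Gaussian
(variance 2·D_free·f_free·Δt) and a bound-state Gaussian
(variance 2·D_bound·(1−f_free)·Δt), i.e. a single Gaussian with
variance 2·D_eff·Δt and

    D_eff = f_free·D_free + (1 − f_free)·D_bound.

The inversion for f_free clamps measurement noise that pushes D_eff
outside [D_bound, D_free] into [0, 1] and sets a flag, so population
histograms remain processable. With binding sites in large excess over
the probe, f_bound = [site]/(K_d + [site]).

The site pool is geometric: sphere area π·d² of a 20 nm ribosome
(1260 nm², 3 significant figures), half of it RNA (630 nm²), divided by
the π·(d_probe/2)² = 9.6 nm² (2 s.f.) footprint of a 3.5 nm probe →
66 sites per ribosome; at 10 µM ribosomes, a 660 µM site pool.
Intermediate areas are deliberately rounded to these conventional
reporting precisions *before* the division, so the printed census is
reproduced exactly; the full-precision inputs are retained on the result
object. Concentrations are µM throughout this module; conversion to M
happens only at the electrostatics boundary.

## 3. Screened electrostatic binding model

The binding free energy at ionic strength I is

    ΔG_b(I) = ΔG_nio + ΔG_io0 · exp(−C1·√I) / (1 + C1·√I),

the modified Debye–Hückel form used for partly electrostatic
protein–protein interactions, with K_d = exp(ΔG_b/RT) at a 1 M standard
state (default T = 293 K, R = 8.314 J K⁻¹ mol⁻¹). The √I placement of
the radical is validated numerically: only this form reproduces the
parameter set (−20 400, −28 900, 1.53) from the measured K_d triple
(6.7, 65, 155 µM at 0.2, 0.8, 2.1 M).

**Ionic fit.** Residuals are minimised in free-energy (log K_d) space,
which equalises the >20× dynamic range of the K_d values. At fixed C1
the problem is linear in (ΔG_nio, ΔG_io0), so the fit reduces to a
deterministic multi-start (C1 ∈ {0.5, 1, 1.5, 2, 3}) 1D search with
bounded refinement (tolerance 1e−9 in C1). With three distinct points
the fit interpolates; exact synthetic triples are recovered to 1e−6
relative.

**Charge model.** Assuming ΔG_io0 = ΔG_pc·charge, the composition of
the four relations above gives D_eff as a function of net charge with
three parameters (ΔG_nio, ΔG_pc, C1) and fixed constants
(D_free = 10, D_bound = 0.04 µm²/s, [site] = 660 µM, I, T). Fitting is
least squares on log₁₀(D_eff) over a deterministic multi-start grid with
a trust-region refinement. **Identifiability caveat:** at a single
ionic strength ΔG_pc and C1 enter only through the product
ΔG_pc·e^(−C1·√I)/(1+C1·√I); the pair is structurally degenerate and
only ΔG_nio, this *charge slope* (exposed as
`ChargeModelFit.charge_slope`) and the curve itself are determined.
Fits driven entirely to the free-diffusion plateau are flagged as
boundary solutions. An all-flat dataset leaves the binding parameters
unidentifiable by construction.

## 4. Protein net charge and isoelectric point

Net charge is the Henderson–Hasselbalch sum over titratable groups
(basic: N-terminus, His, Lys, Arg; acidic: C-terminus, Asp, Glu, Cys,
Tyr). Two modes: `ipc` titrates all groups with the protein-optimised
IPC_protein pKa table; `counting` titrates only Asp/Glu/Lys/Arg plus the
termini with a classic textbook table — the "count the charged
residues" estimate. Both tables ship as versioned JSON data files; no
pKa value is hard-coded in logic. The termini are included in counting
mode so it remains a strict group-subset of ipc mode; an
`include_termini=False` switch exists for additivity checks. Ambiguity
codes (B/Z/X/U/O) and unknown characters are non-titratable and warn
once per call.

Z(pH) is strictly decreasing, so the isoelectric point is the unique
zero on (0, 14), found by bisection to |Z| < 1e−4 (equivalent to a
dense-grid scan within 0.002 pH, tested against that oracle). If Z has
no sign change in (0, 14) — impossible with standard tables because the
termini always titrate, but possible with user-supplied ones — the
nearer boundary is returned with a warning.

Proteome distributions bin net charge in unit-charge bins centred on
integers and pI in 0.25-pH bins over (0, 14); copy-number weighting
multiplies each protein by its count. The default pH is 7.5, the
physiological internal pH of the organisms studied. Cytoplasmic
filtering keeps records annotated GO:0005737 (cytoplasm) or GO:0005829
(cytosol).

## 5. Synthetic-data generators

All generators are pure functions of (config, seed).

**FRAP stacks** emulate a pole-bleached line profile: flat pre-bleach
intensity 1.0, a Gaussian bleach dip (default depth 0.6, width one
pixel — chosen to match typical post-bleach contrast), forward
evolution with the same solver the fit uses, and homoscedastic Gaussian
read noise (default 2% of the pre-bleach level; Poisson shot noise is a
non-default option). The defaults mirror a confocal recording on a
~3 µm bacterium: 50 frames of 8 pixels at 4 ms. The pre-bleach profile
is the average of 3 noisy flat frames. Not emulated: confocal PSF,
photophysics (blinking, reversible bleaching), 3D geometry, nucleoid
exclusion, cell-to-cell variability of D. Passing recovery tests
therefore shows the estimator is correct and precise under the stated
noise model, not that real-cell systematics are absent.

**Switching walks** realise the two-state model literally: per step a
particle displaces by N(0, 2·D_state·dt) and switches state with
probability rate·dt (valid for dt·rate ≤ 0.1, enforced). Particles
start in the stationary state distribution
f_free = k_release/(k_bind + k_release). D_eff is estimated per
particle as x²/(2T) and averaged; the standard error is over particles.
Fast exchange (rates ≫ 1/T) reproduces the mixing rule within ~3 SE;
slow exchange (rates ≪ 1/T) produces a two-Gaussian scale mixture with
excess kurtosis ≈ 3·E[σ⁴]/E[σ²]² − 3 ≈ 2.9 at the default parameters.

**Synthetic proteomes** draw residues i.i.d. from frequencies calibrated
analytically so the expected net charge at pH 7.5 equals the target
bias: probability mass δ is moved onto Lys/Arg and off Asp/Glu, with δ
solved from the linear relation between the shift and the expected
Henderson–Hasselbalch charge (including termini) at the mean length.
Exactly round(fraction·n) records carry the cytosol GO label; copy
numbers are log-normal (µ = 3, σ = 1.5 on the log scale, i.e. a median
of ~20 copies with a heavy tail, loosely following measured abundance
distributions). Real proteomes have length-dependent composition,
domain structure and correlated charge patches; none of that is
emulated, so the generator supports calibration and plumbing tests, not
biological conclusions.

## 6. Pipeline

One YAML block per organism (ionic strength, D_free, D_bound, site
pool, probes). Probes carry exactly one data source: stack CSV paths,
synthesis settings, or a directly injected D_eff; organisms may instead
inject a K_d directly. Per-probe populations are summarised by median,
interquartile range (linear interpolation), mean and n; a config switch
(`center`) selects whether the mean or the median feeds the two-state
inversion (default mean, matching how the bound-fraction analysis is
usually quoted; the planted-loop analyses use the median for
robustness). The ionic fit runs when ≥ 3 organisms provide a K_d, the
charge fit when an organism has ≥ 4 probes with distinct charges.
Failures are isolated per stage and logged; excluded stacks are
counted. Reports carry a config digest, the seed and the package
version, and contain no timestamps, so reruns are byte-identical.

**Error propagation in the full loop.** With 12 cells per probe at 2%
read noise the per-probe median D is recovered to ~1–2%. The chain
K_d = [site]·f_free/f_bound amplifies a relative D_eff error by roughly
D_eff/(D_eff − D_bound), and the linear solve for (ΔG_nio, ΔG_io0) at
fixed C1 amplifies the resulting ΔG errors about five-fold. Planted
screened-electrostatics parameters therefore come back at the several-
percent level; the planted-truth test asserts 10%. The deterministic
2% check on the parameter set lives with the exact measured triple.

## 7. Problem sizes

Defaults are chosen so the full test suite runs in well under a minute
on one CPU: 20-stack recovery sweeps, 2000–3000 walk particles × 1000–
10 000 steps, 300–1000-protein proteomes, and a 3-organism × 2-probe ×
12-replicate planted loop. All sizes scale up linearly through the
configs if tighter statistics are wanted.

## 8. Known limitations

- 1D analysis only: no 2D/3D cell geometry, membrane or nucleoid
  compartments, PSF modelling, segmentation or drift correction.
- Fast-exchange assumption: slow-exchange (two-population) FRAP is
  detected qualitatively by the walk kurtosis, but no two-component
  recovery fitting is provided.
- The charge model's (ΔG_pc, C1) degeneracy at fixed I means its
  per-organism parameters should be compared only through the charge
  slope or the predicted curve.
- Net-charge calculations ignore specific ion binding and
  context-dependent pKa shifts; measured protein charges can differ
  from the calculated ones by several units.
- The ribosome concentration entering the site pool is taken as the
  conventional 10 µM; a number-density-based value would be ~3× higher,
  and K_d scales linearly with this choice.
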