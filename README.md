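# cytodiff

Why do some proteins crawl through the bacterial cytoplasm while others of
the same size race? For surface-engineered GFP variants spanning net
charges from −30 to +25, the translational diffusion coefficient in vivo
drops up to ~100-fold with increasing positive charge, because positive
proteins stick electrostatically to the RNA-rich ribosome surface. The
effect weakens at higher cytoplasmic ionic strength, where small ions
screen the attraction. `cytodiff` implements the full quantitative chain
of this analysis for biophysicists studying intracellular mobility:

1. **FRAP fitting** (`cytodiff.frap`) — a pole of a rod-shaped cell is
   bleached and the intensity profile *I(x, t)* along the long axis is
   recorded; the profile obeys the 1D diffusion equation with no-flux
   boundaries at the poles, and *D* is fitted by forward simulation
   (Crank–Nicolson) of the first post-bleach frame.
2. **Two-state effective diffusion** (`cytodiff.binding`) — at exchange
   much faster than the measurement,
   `D_eff = f_free·D_free + (1 − f_free)·D_bound`. Inverting this for
   the measured `D_eff` gives the bound fraction; with binding sites in
   excess, `f_bound = [site]/(K_d + [site])` yields the dissociation
   constant. The site pool comes from a geometric census: a 20 nm
   ribosome sphere, half RNA, divided into 3.5 nm probe footprints.
3. **Screened electrostatics** (`cytodiff.electrostatics`) — the binding
   free energy follows a modified Debye–Hückel form,
   `ΔG_b(I) = ΔG_nio + ΔG_io0 · e^(−C1·√I)/(1 + C1·√I)`, with
   `K_d = exp(ΔG_b/RT)`; with `ΔG_io0 = ΔG_pc · charge` the composition
   predicts `D_eff` directly as a function of the probe's net charge.
4. **Proteome charge statistics** (`cytodiff.charge`) — Henderson–
   Hasselbalch net charge and isoelectric points from FASTA sequences,
   with GO-based cytoplasmic filtering and copy-number weighting,
   explaining why cytoplasmic proteomes avoid net-positive proteins.
5. **Synthetic data** (`cytodiff.synth`) — seeded generators for noisy
   FRAP stacks, two-state switching random walks and synthetic proteomes,
   so the whole chain is testable with planted ground truth.
6. **Pipeline** (`cytodiff.pipeline`, `cytodiff` CLI) — end-to-end
   orchestration from stacks or configs to a serialized report.

## Worked example

The measured effective diffusion coefficient of the +25 variant in the
low-ionic-strength organism (I = 0.2 M) is 0.14 µm²/s, with
D_free = 10 µm²/s and the ribosome at D_bound = 0.04 µm²/s:

```sh
$ cytodiff binding --deff 0.14 --dfree 10 --dbound 0.04 --site-conc 660
{
  "clamped": false,
  "f_bound": 0.9899598393574297,
  "f_free": 0.010040160642570281,
  "kd_uM": 6.6937119675456485
}
```

The probe spends 99% of its time ribosome-bound; against the 660 µM site
pool that corresponds to K_d ≈ 6.7 µM. Running the analysis drivers:

```sh
$ python analysis/02_bound_fractions.py
ribosome surface 1260 nm^2, RNA fraction 0.5 -> 66 sites/ribosome, site pool 660 uM
low_salt_0.2M: D_eff 0.14 -> bound fraction 0.99, Kd 6.7 uM
mid_salt_0.8M: D_eff 0.61 -> bound fraction 0.91, Kd 67.3 uM
high_salt_2.1M: D_eff 1.9 -> bound fraction 0.81, Kd 151.6 uM

$ python analysis/03_ionic_strength_fit.py
dG_nio  =   -20398 J/mol   (non-ionic part)
dG_io0  =   -28855 J/mol   (electrostatic, I=0)
C1      =    1.533 M^-1/2  (screening parameter)
```

K_d rises ~20-fold from 0.2 M to 2.1 M ionic strength, but even at 2.1 M
the probe stays 81% bound: screening removes most of the electrostatic
attraction (−28.9 kJ/mol at zero ionic strength) yet a non-ionic
component of −20.4 kJ/mol remains. The numbered scripts under
`analysis/` walk through the whole chain (FRAP recovery sweep, binding
chain, ionic and charge-model fits, switching-walk validation, proteome
survey, planted full-loop pipeline) and write their tables under
`results/`.

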