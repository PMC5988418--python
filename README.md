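# tfdimer

Quantitative analysis of a monomer–dimer chaperone system, built around the
bacterial chaperone Trigger Factor (TF). TF exchanges between a 48 kDa
monomer and a 96 kDa dimer with a dissociation constant of ~2 µM, and the
two forms differ in everything that matters for chaperone function: the
dimer binds unfolded substrates faster but holds them more loosely, and the
dimer cannot bind the ribosome. The package provides, as a library plus a
small CLI, the complete analysis chain used to characterize such a system:

* **Equilibria** — closed-form monomer–dimer speciation, the
  weight-average molar mass isotherm measured by SEC-MALS,

  $$M_w(C_T) = M_m\,\frac{8C_T + K_d - \sqrt{K_d^2 + 8C_T K_d}}{4C_T},$$

  the signal-weighted sedimentation-coefficient isotherm $s_w(C_T)$
  measured by sedimentation-velocity AUC, and the coupled competition
  between dimerization ($2M \rightleftharpoons D$, $K_d = [M]^2/[D]$) and
  ribosome binding ($M + R \rightleftharpoons MR$).
* **Isotherm fitting** — nonlinear least squares for $K_d$ (and optionally
  $M_m$, $s_M$, $s_D$) from either isotherm, with log-space positivity,
  bound-hit diagnostics and Jacobian-based standard errors.
* **Stopped-flow kinetics** — simulation and analysis of rapid-mixing
  traces: dimer dissociation after dilution
  ($\dot d = k_{ass} m^2 - k_{diss} d$), substrate association with
  coexisting monomer and dimer, single/double-exponential fitting with
  photobleach-baseline correction, AICc phase counting, attribution of the
  fast phase to the dimer, and extraction of $k_{on}$/$k_{off}$ per species
  from the pseudo-first-order law $k_{obs} = k_{on} C + k_{off}$.
* **Kinetic partitioning** — a holdase/anti-aggregation model in which an
  unfolded substrate partitions among folding ($k_f$), second-order
  aggregation ($k_{agg}$) and reversible chaperone capture
  ($k_{on,c}, k_{off,c}$), yielding soluble/aggregated fractions and
  half-folding delay factors.
* **Synthetic data** — seeded, bit-reproducible generators for all of the
  above, with ground-truth sidecars, so every stage is testable without
  instrument files.

Intended users are protein biophysicists analyzing self-associating
systems by MALS/AUC/stopped-flow, and method developers who need an
executable, fully tested reference for this analysis chain.

## Worked example

```python
import numpy as np
from tfdimer import (SelfAssociationModel, solve_speciation, DimerKinetics,
                     BindingModel, simulate_association, fit_exponentials,
                     attribute_phases, regress_kobs)

model = SelfAssociationModel(Mm=48.0, Kd_dim=2.0)
spec = solve_speciation(40.0, model)
print(f"m = {spec.m:.3f} µM, d = {spec.d:.3f} µM, "
      f"dimer mass fraction = {spec.dimer_mass_fraction:.3f}")

kin = DimerKinetics(kdiss=10.0, model=model)
t = np.linspace(2e-3, 2.0, 1000)
fast, slow = [], []
for chap in (5, 10, 20, 30, 40):
    trace = simulate_association(2.0, chap, BindingModel(), kin, t)
    fit = fit_exponentials(trace, n_phases=2)
    s = solve_speciation(chap, model)
    fast.append((s.d, fit.rates[0])); slow.append((s.m, fit.rates[1]))
rd, rm = regress_kobs(fast, "dimer"), regress_kobs(slow, "monomer")
print(f"dimer:   kon = {rd.kon:.3g} M⁻¹s⁻¹, koff = {rd.koff:.3g} s⁻¹")
print(f"monomer: kon = {rm.kon:.3g} M⁻¹s⁻¹, koff = {rm.koff:.3g} s⁻¹")
```

prints

```
m = 5.844 µM, d = 17.078 µM, dimer mass fraction = 0.854
dimer:   kon = 1.1e+06 M⁻¹s⁻¹, koff = 30 s⁻¹
monomer: kon = 5e+05 M⁻¹s⁻¹, koff = 6 s⁻¹
```

At 40 µM total chaperone, 85% of the protein mass is dimeric; the
bi-exponential association traces separate into a fast dimer phase and a
slow monomer phase, and the concentration dependence of the two observed
rates returns the per-species association and dissociation constants —
the dimer associating ~2-fold faster and releasing ~5-fold faster than the
monomer.

The same pipeline is available from the shell:

```bash
tfdimer speciate --ct 40 --kd 2
tfdimer make-synthetic --what mals --noise 0.01 --seed 1 --out mals.csv
tfdimer fit-mals mals.csv --out fit.json
```

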