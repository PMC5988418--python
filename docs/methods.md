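# Methods

## The thermodynamic core

All stages share one self-association model: $2M \rightleftharpoons D$
with dissociation constant $K_d = [M]^2/[D]$, free monomer $m$ in
monomer-molar units and dimer particles $d$ in dimer-molar units. With
total protein $C_T = m + 2d$ (monomer units) the mass balance
$2m^2/K_d + m - C_T = 0$ has a single non-negative root, evaluated in the
rationalized form $m = 2C_T/(1 + \sqrt{1 + 8C_T/K_d})$ to avoid
cancellation at low saturation; $d = m^2/K_d$ then satisfies the
equilibrium condition to machine precision. With this convention a sample
at $C_T = K_d$ is exactly half monomer, half dimer by mass.

Two instrument observables follow directly. The SEC-MALS observable is
the weight-average molar mass
$M_w = M_m (2C_T - m)/C_T$, algebraically identical to the closed
expression $M_m\,(8C_T + K_d - \sqrt{K_d^2 + 8C_T K_d})/(4C_T)$ (also
evaluated in rationalized form); it runs from $M_m$ at infinite dilution
to $2M_m$ at saturation and is 0/0 at $C_T = 0$, so zero concentration is
rejected and the limit documented instead. The AUC observable is the
signal-weighted sedimentation coefficient
$s_w = (s_M m + s_D (C_T - m))/C_T$, which assumes equal mass-specific
signal for both species — the experiment records absorbance at two
wavelengths but reports a single weighted average, and nothing indicates a
per-species extinction difference, so equal weighting is the default.

Coupled dimerization/ribosome-binding speciation adds
$M + R \rightleftharpoons MR$ (the dimer's ribosome-binding loops are
buried, so only the monomer binds). Free ribosome is eliminated
analytically and the TF mass balance is solved by bracketed Brent
iteration on $m \in [0, C_{T}]$; the balance is strictly increasing in
$m$, so convergence is unconditional.

Internal units are fixed — µM, s, kDa, Svedberg — with conversion to
M⁻¹s⁻¹ (×10⁶) only at the reported bimolecular rate constants. Defaults
(monomer 48 kDa, dimerization $K_d$ 2 µM, ribosome $K_d$ 0.5 µM,
$k_{diss}$ 10 s⁻¹, binding constants 0.5 µM⁻¹s⁻¹/6 s⁻¹ monomer and
1.1 µM⁻¹s⁻¹/30 s⁻¹ dimer) are collected in `tfdimer.DEFAULTS`. The
monomer mass is set to 48 kDa from the 96 kDa dimer plateau; the
sequence-exact value is not fixed by that observable, so the parameter is
configurable everywhere it appears.

## Isotherm fitting

Both isotherm fits minimize weighted squared residuals with
$1/\sigma^2$ weights when observation errors are supplied and uniform
weights otherwise (no weighting scheme is implied by the source analyses).
$K_d$ is parameterized as $\log_{10} K_d$ bounded in $[-4, 4]$ (µM), which
enforces positivity and makes "the data carry no association signal"
detectable as a bound hit rather than a wild excursion. The sw fit
enforces $s_M < s_D$ by fitting $s_D = s_M + \Delta s$ with
$\Delta s > 0$, and multistarts over three decades of $K_d$ because the
three-parameter, four-point problem has genuine local minima. Standard
errors come from the Jacobian-based covariance at the optimum; with four
points they are advisory, which is why the Monte-Carlo recovery tests
quote medians across seeds rather than per-fit intervals. Floating the
monomer mass in the Mw fit is supported but off by default: the monomer
mass is normally known from sequence, and four points constrain two shape
parameters poorly.

## Stopped-flow kinetics

**Dilution relaxation.** The dimer pool obeys
$\dot d = k_{ass} m^2 - k_{diss} d$ with $m = C_T - 2d$ and
$k_{ass} = k_{diss}/K_d$ fixed by detailed balance. Simulation starts
from the pre-dilution equilibrium scaled by the dilution factor,
integrates through the instrument dead time (default 2 ms, configurable;
the observable window simply starts there), and reports a fluorescence
signal $\alpha_M m + \alpha_D\,2d$. The species coefficients are unknown
for any real instrument; the generator defaults to (1.0, 0.7), and the
fitting route profiles both out linearly, so their values never influence
recovered rates. Parameter recovery fits the full ODE with variable
projection: for each trial $k_{diss}$ the two linear signal coefficients
are solved by least squares, and the single nonlinear parameter is
minimized by bounded scalar search on $\log_{10} k_{diss}$. Near
equilibrium the relaxation is single-exponential with eigenvalue
$k_{diss} + 4k_{ass}m_{eq}$ (11.8 s⁻¹ for the 10-fold dilution of 1 µM at
the defaults), so a plain single-exponential fit overestimates
$k_{diss}$ by ~17%; the ODE fit is the accurate route and the
single-exponential rate is reported as the standard quick approximation.

**Association with coexisting species.** Dimer exchange
($k_{diss} \approx 10$ s⁻¹) is slow relative to the observed binding
rates, and the experimental traces behave as two independent exponentials
whose amplitude fractions track the species mass fractions. The default
"decoupled" mode makes that phenomenology exact: the chaperone is
speciated once at $t=0$ and frozen, and the substrate is partitioned
between a monomer pool and a dimer pool in proportion to species mass
fraction, each pool relaxing as reversible pseudo-first-order binding
with rate $k_{on} C + k_{off}$ ($C$ = free monomer $m$ or dimer particles
$d$). A "coupled" mode integrates the full five-state network
(M, D, S, MS, DS) including dimer exchange, for assessing how much the
frozen-speciation idealization matters — a real caveat, since
$k_{diss}$ is comparable to the $k_{off}$ values. The dimer is modeled
as binding one substrate molecule; dimer avidity appears only through its
larger $k_{on}$, not as explicit two-site binding. The $k_{obs}$
regression for the dimer phase uses dimer-particle concentration by
default (monomer-equivalent is a caller-side doubling), and slopes are
converted to M⁻¹s⁻¹ at reporting time.

**Exponential fitting.** Traces are fit as
$y(t) = c + \sum_i A_i e^{-\lambda_i t'}$ by variable projection:
amplitudes and offset are solved linearly for each trial rate vector, and
only the log-rates are iterated (Levenberg–Marquardt), multistarted from
log-spaced initial guesses spanning the resolvable rate window
(0.5/span to the Nyquist-like 1/(2Δt)). Rates are reported sorted
descending (phase 1 = fast; rate ties broken by amplitude), and
amplitudes are extrapolated to the mixing time $t = 0$ — the standard
dead-time correction, and what makes amplitude fractions comparable to
equilibrium species fractions. Photobleach correction fits
$c + a e^{-rt}$ to the segment after 1 s (configurable), where binding
chemistry at these rates has fully equilibrated, subtracts the decaying
component from the whole trace, and restricts the kinetic fit to the
pre-cut window; subtraction rather than division is used because the
simulated bleach enters additively. Model order (1 vs 2 phases) is chosen
by AICc with a conservative threshold of 10, tie-breaking to the simpler
model; on strictly noiseless synthetic data AICc comparisons are
degenerate (any extra phase "improves" a zero-residual fit), so the
selection tests operate at realistic noise.

## Kinetic partitioning (holdase / anti-aggregation)

Unfolded substrate $U$ partitions irreversibly into folded $F$
(first order, $k_f$) and aggregated $A$ (second order,
$\dot A = 2k_{agg}U^2$, monomer-equivalents), while a chaperone binds it
reversibly ($B$, with free chaperone $= chap - B$). Aggregation is an
irreversible sink without nucleation structure, matching a
light-scattering readout that is not mass-calibrated — only relative
aggregate amounts are meaningful. With no chaperone the folded yield has
the closed form $(k_f/2k_{agg}U_0)\ln(1+2k_{agg}U_0/k_f)$, used as an
independent check on the integrator. The holdase observable is the ratio
of times to 50% folded with and without chaperone (∞ when folding never
reaches half within the horizon); the anti-aggregation observable is the
final aggregated fraction, flagged if the trajectory has not committed
99% of the substrate by the horizon (default 30 over the slowest
relevant rate).

One modeling consequence worth stating: when capture/release is fast
relative to folding (rapid-exchange regime), the delay factor approaches
$1/(1-\theta)$ with $\theta$ the bound fraction, nearly independent of
$k_f$ — slow and fast folders are delayed by similar factors, and the
ordering between them comes only from the finite equilibration transient.
The strong folding-rate selectivity (a chaperone that delays a slow folder
but not a fast one) emerges when $k_f$ approaches the capture flux
$k_{on,c}\cdot chap$ itself, and the tests probe exactly that regime.

## Synthetic data and what passing tests show

Generators mirror the experimental protocols: the four-concentration
isotherm ladder (40.18, 12.13, 3.83, 0.596 µM), 10-fold dilution of 1 µM
protein for dissociation kinetics, 2 µM substrate against a 5–40 µM
chaperone titration for association, 2 s traces so the >1 s
photobleach-baseline window exists. Noise is additive or multiplicative
Gaussian with an explicit seed (bit-reproducible); the working convention
for "x% noise" is x% of the observable's dynamic range unless
multiplicative noise is requested explicitly. Every generator returns a
ground-truth sidecar, so recovery tests compare against what was actually
synthesized. The generators do not emulate chromatograms, radial
absorbance scans, mixing artifacts beyond a dead-time cut, or correlated
instrument drift — so passing recovery tests demonstrates correctness of
the analysis chain under the stated noise model, not robustness to every
pathology of real instrument data.

## Numerical choices

ODEs are integrated with LSODA at rtol 1e-8 (1e-10 for the partitioning
network) and tight atol; final simulated states are verified against
closed-form equilibria at 1e-6. Root-finding uses bracketed Brent
(speciation coupling) and plain bisection only as an independent test
oracle. Degenerate inputs are contracts, not surprises: zero total
concentration returns the empty speciation state, $C_T \le 0$ is rejected
where the observable is undefined, infeasible fixed parameters
($s_M \ge s_D$) and too-few-points conditions raise input errors, and
non-convergence of a fit flags the result rather than raising.

## Limitations

No higher-order oligomers or cooperative association; no global
multi-trace fitting; no temperature correction between datasets; dimer
avidity and the monomerization pathway of substrate-bound dimers are not
explicitly parameterized; the coupled association mode exists to bound
the decoupled idealization, not to model the binding mechanism in full.
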