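# Methods

This note documents the models, numerical choices, and limitations behind
`kowtherm`. Units throughout: energies in kJ/mol, temperatures in K
internally (°C at the I/O boundary), denaturant concentrations in M,
chemical shifts in ppm, rates in s⁻¹. R = 8.314×10⁻³ kJ/(mol·K); the
reference temperature for chemical denaturation and exchange energetics is
298.15 K (25 °C), overridable everywhere it appears.

## Two-state thermodynamic core

Everything reduces to a two-state equilibrium N ⇌ U with
K_u = exp(−ΔG_u/RT) and folded fraction f_N = 1/(1+K_u). Two
parameterizations of ΔG_u are used:

- **Thermal (spectroscopic melts):** ΔG_u(T) = ΔH_u(T_m)·(1 − T/T_m).
  This deliberately omits a heat-capacity term: optical melts of small
  domains rarely constrain ΔC_p, and fitting it destabilizes T_m.
  Only the DSC model carries ΔC_p.
- **Chemical (LEM):** ΔG_u = ΔG_u(H₂O) − m·[denat]. The midpoint
  [denat]₁/₂ = ΔG_u(H₂O)/m is always derived from the fitted pair, never
  fitted independently, so the identity between the three printed
  quantities is exact by construction.

The exchange free energy from populations, ΔG = −RT·ln(p_B/p_A), is the
closed form. Note that recomputing ΔG from populations rounded to two
decimals does not exactly reproduce values derived from unrounded fit
output (e.g. 7.04 vs 7.18 kJ/mol at p_B ≈ 5.5%); the package computes the
closed form of whatever populations it is given and makes no attempt to
force agreement with previously published roundings.

## Spectroscopic unfolding fits

Both fitters are unweighted trust-region nonlinear least squares
(`scipy.optimize.least_squares`, TRF) over six parameters: the two
thermodynamic parameters plus linear native/unfolded baselines. Thermal
baselines are anchored at T_m (slopes multiply T − T_m); chemical baselines
are anchored at zero denaturant. The anchoring affects parameter values,
not the fitted curve.

When no initial guess is supplied, three multi-starts are tried: the
midpoint is seeded from the maximum of a lightly smoothed |dS/dx|,
baselines from straight-line fits to the end tertiles, and the energy
scale from three values spanning the plausible range for small β-barrel
domains (ΔH 80/150/250 kJ/mol thermal; m 2/5/9 kJ/(mol·M) chemical). The
lowest-cost converged start wins. Standard errors are asymptotic, from the
covariance (JᵀJ)⁻¹·s² with s² the residual variance — the same convention
used for all fitters in the package.

Diagnostics rather than exceptions flag scientifically suspect fits:

- *Baseline coverage*: if the fitted f_N never exceeds 0.95 or never falls
  below 0.05 inside the data range, the transition is not bracketed and
  parameters are marked unreliable (the case of a stable domain that never
  denatures, or a melt lacking the unfolded baseline).
- *No resolvable transition*: if a straight line explains the data nearly
  as well as the two-state model (dof-adjusted residual variance ratio
  > 0.5), there is no transition to fit.
- *Multi-state suspicion*: a Wald–Wolfowitz runs test on residual signs at
  p < 0.01 flags systematic structure, the signature of an intermediate
  plateau. The package deliberately does not fit three-state chemical
  unfolding; domains with an observable equilibrium intermediate get a
  diagnostic, not a forced two-state number.

## DSC model

The molar heat capacity is C_p = C_p,0 + δC_p^int + δC_p^exc with
C_p,0 = a₀ + b₀T (a₀ absorbs the instrument offset),
ΔC_p,u(T) = a + bT + cT²,

- ΔH_u(T) = ΔH_u(T_m) + a(T−T_m) + b/2(T²−T_m²) + c/3(T³−T_m³)
- ΔS_u(T) = ΔH_u(T_m)/T_m + a·ln(T/T_m) + b(T−T_m) + c/2(T²−T_m²)
- δC_p^int = ΔC_p,u·K_u/(1+K_u), δC_p^exc = ΔH_u²/(RT²)·K_u/(1+K_u)².

Both occupancy factors are evaluated through the logistic function of
−ΔG/(RT) (`scipy.special.expit`), so K_u never overflows. δC_p^exc equals
ΔH_u·df_U/dT identically (the van't Hoff relation), which the tests verify
by quadrature; the excess peak therefore integrates to the calorimetric
enthalpy. The apparent peak sits below the thermodynamic T_m by the small
intrinsic skew ≈ 4R²T_m³/ΔH² (0.1–0.4 K for realistic parameters) coming
from the 1/T² prefactor — a property of the model, not a numerical error.

Fitting floats a₀, b₀, a, b, T_m, ΔH_u(T_m) with c fixed, per the usual
practice of constraining the quadratic curvature from the theoretical
unfolded-state heat capacity of the sequence: per-residue contributions at
5/25/50/75/100/125 °C are summed and an OLS parabola gives c. The packaged
contribution table is a **synthetic stand-in** (and says so in its header
and filename): it reproduces the rise-then-flatten temperature dependence
characteristic of unfolded polypeptides, which is all the c-extraction
path needs structurally, but its values are not transcribed from a
published compilation. For real analyses supply your own table or pass c
directly (`fit_dsc(..., c_fixed=...)`, CLI `--c-coeff`). Buffer
subtraction and scan-rate normalization are assumed done upstream.

## CEST

The two-state Bloch–McConnell generator is the 6×6 real matrix over
(I_x, I_y, I_z) of states A and B: offset precession at
2π(δ − offset)·f_larmor, B1 nutation at ω₁ = 2πν₁ (B1 along x), R₂ decay
of transverse and R₁ decay of longitudinal components (relaxation toward
zero — the return-to-equilibrium term is neglected, the standard
approximation for heteronuclear CEST where the irradiated nucleus's
equilibrium polarization is small relative to the prepared state), and
first-order exchange k_AB = p_B·k_ex, k_BA = p_A·k_ex. Detailed balance
k_AB·p_A = k_BA·p_B holds exactly by construction. The initial condition
is equilibrium longitudinal magnetization (p_A, p_B); the observable is
I_zA(T_ex)/p_A.

Propagation is by eigendecomposition of the generator stack (one 6×6 per
offset, diagonalized in a single batched `numpy.linalg.eig` call), which
is the matrix exponential for diagonalizable matrices; offsets whose
eigenbasis is ill-conditioned (condition > 10¹²) fall back to
`scipy.linalg.expm`. The tests cross-check this propagator against
adaptive ODE integration of the same generator at 2.5×10⁻¹⁴ relative
tolerance; agreement is at machine precision (≤ 10⁻¹³ on the unit
intensity scale, asserted at 10⁻⁸).

**Per-residue fits** run over (ln p_B, ln k_ex, δ_A, Δω, R₁, R₂A, R₂B)
jointly across that residue's profiles (both B1 fields). R₁ is shared
between states — a minor-state R₁ is unidentifiable at percent-level
populations — while R₂A and R₂B are independent. Initialization reads
δ_A from the deepest dip, R₁ from the far-offset plateau
(I/I₀ → exp(−R₁T_ex)), and Δω from the deepest dip more than 1 ppm away;
both signs of Δω are tried and the lower-residual solution kept, with a
warning when the two differ by less than 5% (the ± ambiguity is then
real). Single-field data and |Δω| ≈ 0 are flagged, not refused.

**The global fit** shares (p_B, k_ex) across residues passing the
|Δω| > 1 ppm filter (profiles without a resolved shift difference carry no
exchange information; the filter threshold is exposed as `dw_min`), keeps
residue-specific spin parameters, and refuses to run with fewer than two
included residues. In the slow-exchange regime the likelihood has a long
curved valley along p_B·k_ex ≈ const (the dip depths pin the forward rate
k_AB much more tightly than its factors). Two numerical choices deal with
this: populations and rates are fitted on the log scale, which makes the
valley a straight line and keeps them positive without box constraints,
and the resulting unconstrained problem is solved with Levenberg–Marquardt
seeded from the per-residue fits (median k_ex; p_B from the median k_AB
divided by that k_ex). Standard errors come from the covariance at the
optimum, delta-method-transformed back to natural units; for p_B they are
honest about the valley (relative errors of tens of percent for an
8-residue dataset at σ(I/I₀) = 0.01 — consistent with the Cramér–Rao bound
for those conditions, and the reason recovery is judged in combined
standard errors rather than raw percent).

Minor-species shifts are δ_B = δ_A + Δω; the comparison against a
random-coil reference reports the squared Pearson correlation, the rmsd,
and the per-residue difference vector — near-unity R² with sub-ppm rmsd is
the signature of an essentially unfolded minor state, while localized
negative ¹⁵N / positive ¹³Cα deviations mark residual helical structure.

## Chemical shifts and H-bonds

Secondary shifts are Δδ = δ_obs − δ_rc − correction, with the deuterium
correction zero for protonated samples. Random-coil references are input
tables; the package ships none, because published reference sets differ
and the choice belongs to the user. Propensity calls use a centered
3-residue sliding mean with thresholds +/−0.7 ppm (Cα) and 0.5 ppm (CO) —
conventional cutoffs; both atoms must agree for a helix or extended call,
otherwise coil.

H-bond groups (structurally equivalent positions across domains) are
flagged "weaker" when at least k_min (default 2) reduced-stability domains
have |h3J_NC'| below the *minimum* over stable domains with data in that
group, and "stronger" by the mirrored rule against the stable maximum.
Comparing against the stable-group minimum is the strictest
order-invariant reading of "lower than the stable domains"; comparing
against the mean or each domain pairwise are defensible alternatives and
the comparison set is configurable. Missing measurements (peak overlap,
no HNCO peak, …) are excluded from comparisons and reported per group.
The packaged coupling table for the six KOW domains drives an end-to-end
test of the rule; the flags it produces are reported as computed, not
reconciled against any external highlighting.

## Synthetic data

Generators evaluate the forward models exactly and add iid Gaussian noise
on the signal axis (the noise model implied by unweighted least squares),
seeded via `numpy.random.default_rng`; the same seed reproduces a dataset
bit-for-bit, and changing only the seed changes only the noise. Default
grids mirror the experimental protocols: melts 20–95 °C at 0.5 K, 25-point
denaturation series over 0–10 M, DSC 5–130 °C at 0.2 K, CEST offsets
±8 ppm around the major dip at 0.25 ppm with ν₁ ∈ {13, 26} Hz and
T_ex = 0.5 s at a ¹⁵N frequency of 70.95 MHz. The scenario library holds
named (T_m, ΔH), (ΔG, m), and (p_B, k_ex) regimes for six NusG/Spt5/RfaH
KOW domains spanning hyperthermophile-stable to marginally stable.

What passing closed-loop tests shows — and what it does not: recovery on
model-generated data validates the estimators (no bias, correct
uncertainty calibration, correct handling of degenerate cases) at
realistic signal-to-noise. It does not validate the models against real
instruments: baseline curvature, heteroscedastic and correlated noise,
scan-rate kinetics in DSC, B1 inhomogeneity and incomplete water
suppression in CEST are all outside the generators, so agreement here is
necessary, not sufficient, for trusting a fit to real data.

## Benchmark problem sizes

The recovery benchmarks (`kowtherm.benchmarks`, also run by
`scripts/acceptance.py`) use: 8 CEST residues × 2 B1 fields × 65 offsets
(1040 points, ~40 s including per-residue seeding fits), one 626-point DSC
thermogram, one 151-point melt, and one 25-point denaturation series —
sizes matching the emulated experiments while keeping a full run under a
minute. The reduced-scale multi-regime recovery tests in the suite use 3–4
residues at 0.5 ppm offset spacing for the same reason.

## Known limitations

- No three-state or irreversible-unfolding models; multi-state behavior is
  detected, not fitted.
- GdmCl denaturation is analyzed with the same LEM as urea; the known
  deviations from linearity at low GdmCl are not modeled.
- The CEST model is strictly two-site; a third exchanging species biases
  p_B/k_ex rather than failing loudly (the residual diagnostics are the
  only guard).
- B1 inhomogeneity and calibration are out of scope; ν₁ is taken as exact.
- Asymptotic standard errors understate uncertainty when parameters sit
  near identifiability boundaries (Δω → 0, unresolved baselines); the
  warning flags are the intended signal in those regimes.
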