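# Methods

## Scattering model

**Solute term.** The three iodine atoms are parameterized by the I₂⁻
bond length r₁₂, the interfragment distance r₂₃ and the I–I–I angle α
(the third distance follows from the law of cosines). Isotropic
scattering is the Debye double sum over all atom pairs, including
self-terms, with sinc evaluated by its series limit below 10⁻⁸ to keep
q → 0 and d → 0 exact. Atomic form factors use the four-Gaussian
Cromer–Mann parameterization for neutral atoms (International Tables
Vol. C coefficients carried in `formfactors.py`); the −1 excess charge
of the ion (−0.25e / −0.5e / −0.25e across the atoms) is treated as
solvation-layer metadata, not a form-factor correction, since its
effect on the total 159-electron system is below the other model
uncertainties. Conformational heterogeneity enters as a Debye–Waller-
like damping exp(−q²σᵢ²/2) of the *atomic* form factors with fixed
σ = (0.5, 0.5, 0.7) Å for the two bonded and the leaving iodine.

**Anisotropy.** Linearly polarized excitation photoselects molecules
whose transition dipole is along the field, giving the 2D pattern a
P₂(cos θ) modulation. The solute S₂ sums the off-diagonal pairs with
P₂(cos ζᵢⱼ) j₂(q dᵢⱼ) weights, where ζᵢⱼ is the angle between the pair
vector and the transition dipole. Conventions, fixed in one place
(`scattering.py`):

* transition dipole along the I1→I3 end-to-end axis by default
  (configurable); the 400 nm transition of the quasi-linear ion is
  axis-polarized;
* overall positive sign of S₂; the photoselection magnitude c₂ is
  absorbed into the refinable amplitude A_ani(t), which also carries
  rotational dephasing, so only the product is ever identifiable;
* the ground state is isotropic, so each species' ΔS₂ is its excited-
  structure S₂ alone, and the azimuthal map uses cos θ = cos φ
  (flat detector, small scattering angle, vertical polarization;
  curvature corrections are below 1% for q ≤ 4.5 Å⁻¹ at hard-X-ray
  energies).

**Cage term.** ΔS_cage = ΔS_cross + ΔS_DV. The cross term integrates
r²(g_Iv(r) − 1) sinc(qr) against the iodine and solvent-atom form
factors and the type density ρ_v, by trapezoid on the library's radial
grid; (g − 1) is tapered by a cosine window over the last 10% of r to
suppress truncation ringing (the synthetic RDFs have reached bulk well
before the window, so the taper is inert in normal use). The
displaced-volume term places one Gaussian dummy-solvent sphere of the
iodine van der Waals radius (1.98 Å, configurable) at each atom site —
amplitude ρ_e V exp(−q²V^{2/3}/4π) — and Debye-sums the three spheres.
RDF libraries live on a regular (r₁₂, r₂₃, α) grid; off-node
geometries are evaluated by per-q trilinear interpolation, and
geometries outside the hull are clamped to the nearest face (at the
grid's maximal r₂₃ the fragments are cage-independent, which is what
makes clamping the right treatment for the 100 Å NG convention).

**Synthetic RDFs.** The frozen-solute molecular-dynamics library that
would normally populate the grid is emulated by a parametric model: an
excluded core (g = 0 below 2.8 Å), a Gaussian first shell (default
peak 3.6 Å, width 0.45 Å, amplitude 0.9 above bulk), and a bulk tail.
The terminal-atom shell position can track that atom's nearest-
neighbor distance through a linear coupling; the default coupling is
zero (geometry-independent shells), so in the default scenario the
structural cage signal flows through the displaced-volume term while
the cross-term machinery (library build, interpolation, quadrature) is
still exercised end to end. This emulation reproduces the *mechanics*
of a cage library, not solvent physics: passing tests demonstrate that
the pipeline recovers what the generator put in, not that the RDF model
matches any real solvent.

**Heating.** Bulk solvent heating is a fixed reference shape per
solvent with refinable amplitude A_heat; no kelvin calibration is
attempted. The synthetic reference is a derivative-of-peak shape
centered on the solvent's main diffraction peak — sign-changing and
near-zero in integral, like a measured isochoric heating difference —
and correlates < 0.9 with any solute difference shape on the default
grid, keeping the amplitudes identifiable.

## Refinement

Per time point, χ² sums both channels' uncertainty-weighted squared
residuals; the regularization penalty is quadratic in the parameter
jumps from the previously refined time point, f = λ Σ w_k Δx_k², with
unit scale weights (1 Å for distances, 1 rad for the angle, 1 for
amplitudes) and λ = 50 by default. The λ default was chosen by an
L-curve survey on synthetic data: small enough not to bias the
ballistic r₂₃ jumps (≈ 0.3 Å per step, penalty ≈ 4.5 versus χ²
curvatures of hundreds), large enough to pin parameters at delays where
the data carry no information (t ≤ 0, where the regularization
resolves the structural degeneracy of the unevolved geometry toward
continuity). Time points are processed in increasing order; the first
is unregularized.

Bounded parameters are reparameterized smoothly (logistic maps for the
geometry within physically feasible ranges and for A_GP ∈ [0, 1],
softplus for A_iso ≥ 0) and minimized unconstrained with L-BFGS from
10 random starts (plus a warm start at the previous solution when
regularizing); the lowest objective wins, ties to the earliest
restart. Uncertainties come from one-dimensional sensitivity scans: the
interval where χ² + f stays within 1 of its minimum (threshold
configurable), located by bisection; directions with no crossing inside
the scan range are flagged flat and reported unbounded.

## Synthetic ground truth

The generator implements the reaction scheme with geometry evaluated at
the nominal delay and all amplitude dynamics convolved with the
Gaussian IRF in closed form (erfcx-stabilized exponential ⊗ Gaussian):

* r₂₃ rises linearly at v (default 6 Å/ps) to the arrest distance
  (5.5 Å), then relaxes to the GP plateau (4 Å, τ = 1 ps);
* α decreases at ω (5 rad/ps) until arrest; r₁₂ starts stretched by
  0.25 Å (hot I₂⁻) and relaxes to 3.0 Å with τ = 5 ps;
* the GP amount is an IRF-convolved biexponential (τ₁ = 0.4 ps,
  τ₂ = 38 ps, 70% fast) scaled by (1 − Pe); the NG amount rises with
  τ = 0.3 ps to its plateau; heating rises with τ = 10 ps; A_ani decays
  with a 1.5 ps rotational dephasing time;
* excitation fraction 0.15, IRF FWHM 0.175 ps; noise is homoscedastic
  Gaussian at 1% of the peak |ΔS₀| by default, with the σ matrices
  recorded in the dataset.

These defaults follow the acetonitrile narrative of the reaction
(ballistic window ≈ 0.4 ps, travel ≈ 2.4 Å), so recovered trajectories
can be read against that regime.

**Cage-escape convention.** Pe is *defined operationally* as the NG
plateau amount divided by the peak surviving excitation fraction —
the same ratio the analysis applies to data. Because fast geminate
recombination (τ₁ comparable to the IRF) depresses the observable peak
of A_iso = n_GP + n_NG below the initially excited fraction, a Pe
defined against the initial excitation would not be recoverable by any
estimator of this form. The generator therefore scales the NG plateau
self-consistently (fixed-point iteration on a dense time grid) so that
the parameter and the estimator's definition coincide exactly at zero
noise.

## Kinetics estimators

* **GP decay:** least-squares biexponential ⊗ Gaussian in log-lifetime
  space from four deterministic starts; τ₁ < τ₂ by output ordering; a
  second component under 2% of the total amplitude collapses to a
  flagged single exponential. The fit uses t > 0 only: at and before
  time zero the refined GP amount is structurally degenerate (the
  unevolved geometry produces no difference signal), so those points
  carry no information about the decay.
* **Ballistic fits:** v_d and ω are slopes of least-squares lines from
  t = 0 to the cage-arrest point, taken as the *first* time point
  reaching 95% of the maximal deviation within a 2 ps window — using
  the first such point keeps post-arrest plateau noise out of the fit.
  Individual delays can be excluded (for outliers in sparse scans).
* **Energy partitioning:** E_trans = ½μv² with μ = 2m_I/3 (reduced mass
  of I + I₂); E_rot = ½Iω² with I = 2m_I(r₁₂/2)² (I₂⁻ about its own
  center), both per mole. The nominal mass 127 u is used: it reproduces
  the tabulated energies from the tabulated speeds at the printed
  precision, identifying it as the convention behind the table, and
  differs from the standard atomic weight by 0.075%, far below the
  quoted speed uncertainties. The rotational-energy convention cannot
  be validated the same way because the tabulated ω values are rounded
  to one digit.
* **IRF:** an error-function step (amplitude, t₀, width, baseline) fit
  to the early-time rise (t ≤ 1 ps) of the integrated difference
  magnitude, with the step amplitude optionally split into constant and
  IRF-convolved-decaying parts so immediate kinetics do not bias the
  width; for an ideal broadened step the extra component fits to zero.
  The pipeline estimates the width from the anisotropic channel when
  present: |ΔS₂| rises purely with photoselection, whereas the early
  |ΔS₀| rise is also shaped by the growing structural signal per
  excited molecule and reads ~9% too wide.

## Numerical choices and degenerate inputs

* sinc and j₂ by Taylor series below threshold arguments; exponential ⊗
  Gaussian via erfcx on the positive branch to avoid overflow.
* Trilinear interpolation is exact at nodes and for fields linear in
  the coordinates; continuity across cell faces is at the 10⁻¹⁰ level.
* Coincident atoms, zero-norm dipoles, non-positive uncertainties,
  featureless RDFs and empty estimator windows raise ValueError with a
  specific message; out-of-hull geometries clamp with a warning.
* Noiseless datasets carry a 10⁻¹² σ floor so χ² stays defined.
* Default problem sizes: 201 q-points (0.5–4.5 Å⁻¹, Δq = 0.02), 41
  delays (−0.1 to 0.5 ps in 0.05 ps steps, then log-spaced to 500 ps),
  a 5 × 7 × 5-node cage grid with 241 radial points. The full default
  refinement (41 delays × 11 starts) takes ~2.5 minutes on one CPU;
  library-scale grids (13 × 57 × 25 nodes) are supported but not needed
  for the synthetic study.

## Known limitations

* The cage library stands on parametric RDFs; no solvent–solvent
  structure change beyond displaced volume and bulk heating is modeled,
  and no MD is run or parsed.
* The GP interfragment disorder is a single sharp r₂₃ per delay; real
  ensembles broaden after ~1 ps, which in the original analysis shows
  up as growing structural error bars.
* No inelastic/Compton corrections, no detector-geometry effects, no
  optical-Kerr solvent anisotropy, no photon-counting noise model.
* The ground-state structure is a fixed input per solvent and is not
  co-refined (it is strongly correlated with the other parameters).
* The regularization form and λ are package choices exposed in
  configuration; different choices trade tracking speed against
  smoothness in the usual way.
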