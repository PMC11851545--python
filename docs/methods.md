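# Methods

This note documents the model, the numerical choices, and what the synthetic
studies do and do not establish. Everything quantitative stated here is
computed by the test suite or the pipeline itself.

## Physical model

**Flow.** Blood is an incompressible Newtonian fluid (density 1056 kg/m³,
viscosity 0.0035 Pa·s) in a rigid, no-slip vessel. The domain is a single
segment with one inlet and one outlet; branch vessels are not meshed — in a
multi-branch setting they would enter only through outlet flow splits, which
is why the idealization preserves the governing equations unchanged. The
inlet velocity is a cross-section mean waveform v(t), fitted as a truncated
Fourier series (default 8 harmonics) from sampled (t, v) pairs; the inlet
profile is the fully developed laminar profile of that series
(Poiseuille/parabolic for the mean, the oscillatory closed form per
harmonic), a standard choice when the upstream vessel is not modelled. The
outlet imposes zero axial gradient with the wall streamline pinned, so the
instantaneous flow rate is exact at every cross-section. Transients run for
five cardiac cycles and all analysis uses the fifth; the suite checks that
cycle-averaged wall shear drifts by < 1% between the last two cycles.

**NO transport.** The endothelium at the lumen–wall interface produces NO at
the shear-modulated rate R_NO(τ_w) = R_basal + R_max|τ_w|/(|τ_w| + b)
(R_basal = 2.13 nM/s, R_max = 457.5 nM/s, b = 3.5 Pa — a saturating law with
half-saturation at 3.5 Pa). The rate is volumetric; it is applied as an
interface flux R_NO·δ_en with an endothelial layer thickness δ_en = 2.5 µm
(configurable), which makes the interface condition well-posed without
meshing the endothelium. Lumen NO is advected and consumed by red blood
cells (k_ery = 2.3 s⁻¹, giving a reaction-diffusion wall layer
√(D_l/k_ery) ≈ 38 µm) and by a pseudo-second-order oxidation term
(k_oxgen = 7.56×10⁻⁶, interpreted as nM⁻¹s⁻¹ since the second-order form
requires it; at nanomolar levels this term is negligible either way). Wall
NO diffuses (D_w = 8.48×10⁻¹⁰ m²/s) and decays first-order
(k_w = 0.01 s⁻¹), giving the wall decay length √(D_w/k_w) ≈ 0.291 mm. The
wall reaction is a single first-order relation R_w = k_w c_w. Upstream blood
is treated as NO-free (inlet concentration 0: erythrocyte scavenging keeps
core blood NO near zero), the outlet is convective, and the outer wall is
zero-flux (no perivascular sink is modelled). Flow→NO coupling is one-way:
WSS fields are computed first and then drive production; there is no NO
feedback on the vessel (rigid wall, no vasodilation).

**Indices.** TAWSS, OSI, RRT, ECAP are the standard cycle-integral
definitions; all time integrals use the uniform trapezoid rule over exactly
the final cycle. The spatial WSS gradient (TAWSSG) is interpreted as the
magnitude of the surface-tangential derivative dτ_w/ds along the wall arc —
the only well-defined reduction of the 3D Cartesian gradient formula for a
field living on a 2D wall curve. Per-section TAcNO is the perimeter
(endothelial interface) average by default, with a lumen-area average as an
option.

## Geometry idealization

Patient anatomies are replaced by a parametric segment: radius
r(z) = R₀ + A·s(side)·exp(−(z−z_c)²/2w²) with a Gaussian fusiform bulge and
an asymmetry parameter splitting the bulge between two wall sides
(s = 1 ± asymmetry, mean-preserving). Axisymmetric meshes serve symmetric
bulges; planar-2D meshes give two independent wall sides that stand in for
the four anatomical directions of a real aneurysm (the API accepts any
direction count, so a 3D mode would not change interfaces). The wall is a
uniform 2 mm outward offset of the lumen. Note one consequence of the planar
stand-in: the cross-section measure scales with width rather than radius²,
so the sac-to-neck velocity (and WSS) contrast is structurally milder than
in a revolved or patient geometry. This matters for interpretation (below).

## Numerics

**Meshes.** Structured quadrilaterals with geometric near-wall grading
(default ratio 1.15), sized so the finest lumen cells at the endothelium are
~10 µm (several cells inside the 38 µm NO layer) and the wall cells resolve
the 0.291 mm decay length. The steady-state grid-refinement protocol (10%
refinement per step, accept when the volume-averaged NO concentration
changes < 5%) is implemented and exercised on the straight-tube
configuration; defaults were chosen by that criterion, not to mimic any
particular external mesh.

**Flow solver.** Streamfunction–vorticity on the mapped structured grid, so
the continuity equation holds to round-off (the flux between streamlines is
a ψ difference, audited in the tests as a per-cell divergence of ~10⁻²⁰).
Three choices matter for robustness and are worth recording:

- The Thom wall-vorticity closure is solved *implicitly*, as extra rows of a
  monolithic (ω, ψ) linear system per time step. A lagged closure is
  unstable once ν·Δt/δ_n² ≫ 1, which graded wall cells reach immediately.
- The flow uses its own mildly graded transverse node distribution (ratio
  1.05) rather than the transport mesh's aggressive grading: the viscous
  layer needs ~0.1 mm resolution, while 10 µm wall cells make the
  wall-vorticity closure ill-conditioned (the near-wall ψ signal scales with
  δ² and drowns in global truncation error). ψ is interpolated back to the
  transport nodes with local cubic weights; because advective fluxes are ψ
  differences, the interpolated field is still exactly divergence-free.
- In axisymmetric mode the radial operators are discretized in χ = r²:
  E²ψ = 4χ·∂²ψ/∂χ² and the vorticity diffusion via s = ω/r. The naive
  (r-based) stencils leave a non-vanishing near-axis bias (a delicate
  cancellation of ψ_rr against ψ_r/r); the χ form is exact for Poiseuille
  flow and reduced the centerline error from ~4% (resolution-independent) to
  ~0.2%.

Advection is first-order upwind (an M-matrix, robust through flow
reversal; it adds numerical diffusion, acceptable because the validated
quantities are wall shear and developed profiles). Time stepping is a
θ-scheme: Crank–Nicolson for pulsatile runs (second order; backward Euler's
O(ωΔt) damping alone costs ~3% of oscillatory amplitude at 200 steps/cycle),
backward Euler for pseudo-time marching to steady states. Validation:
steady tube WSS within 2% of 4μU/R (measured ~0.1–1%), pulsatile tube within
5% of the oscillatory closed form (measured ~0.2% at the test resolution,
against an independently discretized complex BVP oracle). The reduced axial
pressure profile is a centerline momentum integral provided for inspection
only; no downstream quantity uses it.

**NO solver.** Cell-centered finite volumes over both domains in one linear
system. Advective face fluxes are ψ differences of the face endpoints
(exactly telescoping, hence discretely conservative), upwinded; diffusion is
two-point flux with the series conductance across faces. The endothelial
source enters at interface faces split between the adjacent lumen and wall
cells in proportion to their conductances — algebraically identical to
concentration continuity plus a flux jump at an interface node, and the
implied interface concentration is recovered in closed form for TAcNO.
Implicit upwind stepping keeps the system an M-matrix, so concentrations
are non-negative without clipping (checked to −10⁻⁶ nM). The steady
source/sink audit (production = lumen sink + wall sink + boundary losses)
closes to ~10⁻¹² relative because the scheme is conservative by
construction. Transients are initialized from the steady field at the
cycle-averaged flow driven by the *cycle-averaged production rate* —
averaging R_NO rather than τ_w matters because the law is nonlinear, and it
puts the slow wall domain (time constant 1/k_w = 100 s) within ~0.1% of its
periodic state by the final cycle.

**Regression.** Ordinary least squares of per-section thrombus area (mm²)
on section TAcNO (nM) via statsmodels; R², the regression F statistic and
its two-sided p are reported, cross-checked in the tests against an
independent implementation. A constant response is defined to have R² = 0.

## Synthetic studies: what they emulate

The generator supplies everything patient data would: geometry, a triphasic
infrarenal waveform (systolic peak, one early-diastolic reversal interval,
weak late-diastolic forward flow; default peak 0.6 m/s, period 1 s), and an
ILT thickness map statistically tied to the *computed* NO field. Per
section inside a contiguous 60 mm window the thrombus area is drawn as
max(0, α + β·TAcNO + ε), with β = −30 mm²/nM by default, α anchored so the
smallest noiseless area is 30 mm² (keeping the zero-truncation inactive and
the areas anatomically feasible for a one-sided deposit in a ~10 mm lumen),
and the noise σ derived from a target R² (default 0.8) through
R² = var(βx)/(var(βx)+σ²).

Two placement rules exist. The default (`low-no`) places the window on the
contiguous run of sections with the lowest mean TAcNO and, in one-sided
mode, puts the deposit on the wall direction with the lower line-averaged
TAcNO — i.e., the generator *constructs* the qualitative associations
(thrombus where NO is low; thickest direction = lowest NO direction) that
the analysis stage then quantifies. The alternative (`bulge`) centres the
window geometrically on the dilation. The distinction is scientific, not
cosmetic: in this 2D idealization the emergent sac-vs-neck NO contrast is
weak (see the geometry note above) and its sign can depend on the balance
between reduced production (lower WSS in the sac) and reduced advective
washout (longer residence in the sac), so the `bulge` mode is a probe of
that competition rather than a guaranteed reproduction of the in-vivo
pattern. Consequently, passing tests demonstrate that the pipeline
*recovers imposed couplings correctly* — slope within a few percent of β
over 100 noise replicates, empirical R² within 0.1 of its analytic
expectation, group and directional contrasts detected — not that 2D
hemodynamics alone predicts where thrombus forms. A `couple_to: tawss` mode
generates WSS-coupled maps instead, for discriminability experiments.

Determinism: the seed fixes the only random element (the per-section noise
ε); the solvers are deterministic, so a bundle regenerated with the same
seed is byte-identical and downstream fits reproduce exactly.

## Tunable parameters (defaults)

| Parameter | Default | Units | Note |
|---|---|---|---|
| ρ_b, μ_b | 1056, 0.0035 | kg/m³, Pa·s | Newtonian blood |
| D_l, k_ery, k_oxgen | 3.3e-9, 2.3, 7.56e-6 | m²/s, s⁻¹, nM⁻¹s⁻¹ | lumen transport |
| D_w, k_w | 8.48e-10, 0.01 | m²/s, s⁻¹ | wall transport |
| R_basal, R_max, b | 2.13, 457.5, 3.5 | nM/s, nM/s, Pa | production law |
| δ_en | 2.5e-6 | m | endothelial layer |
| cycles, steps/cycle | 5, 100–200 | — | fifth cycle analysed |
| section spacing | 5 | mm | ILT protocol |
| representative spacing | 20 | mm | 3 directional sections |
| β, base area, target R² | −30, 30, 0.8 | mm²/nM, mm², — | generator coupling |

## Limitations

- 2D (axisymmetric / planar) only; no patient anatomies, no branches, rigid
  walls, Newtonian rheology, laminar flow. High-Reynolds steady solves in
  strongly dilated geometries may have no steady solution (use the pulsatile
  path, or a smaller pseudo-time step).
- First-order upwind advection is diffusive; WSS and developed-flow
  quantities are validated, fine free-shear-layer structure in the sac is
  not.
- The production law, consumption constants and δ_en are literature-scale
  constants, not fitted to data; absolute TAcNO levels should be read as
  order-of-magnitude (nanomolar), with spatial contrasts more trustworthy
  than absolute values.
- iNOS production, oxygen co-transport, hemoglobin kinetics beyond the
  lumped k_ery, perivascular uptake and any NO→tone feedback are out of
  scope, as is modelling thrombus formation itself (the ILT map is an input,
  generated or measured).
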