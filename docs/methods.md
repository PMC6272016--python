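# Methods

## Scope and observables

The package covers the quantitative STD-NMR chain downstream of peak
integration: per-proton fractional STD values η = (I₀ − I_sat)/I₀·100,
their growth with saturation time, epitope normalization, forward
prediction of S_calc,k(t) from a protonated complex structure with
two-site exchange, and NOE R-factor scoring.  Acquisition parameters
(pulse trains, on/off-resonance frequencies), hydrogen placement,
chemical-shift prediction and MD sampling are out of scope: structures
must arrive protonated, and shifts are an optional per-proton input
used only to pick the saturated set under a finite bandwidth.

## Build-up fitting

STD(t) = STD_max(1 − e^(−k_sat t)) is fitted by unweighted nonlinear
least squares (lmfit, trust-region reflective, xtol/ftol/gtol 1e-12)
with a deterministic start: STD_max⁰ = max observed STD and
k_sat⁰ = −ln(1 − STD(t₁)/STD_max⁰)/t₁ clipped to [0.01, 10] s⁻¹, under
bounds STD_max ∈ [0, 100] %, k_sat ∈ [0, 50] s⁻¹.  Unweighted residuals
are the weakest assumption consistent with an unknown error model and
match the additive homoscedastic noise of the generator.  STD₀ =
STD_max·k_sat is stored as the exact product, so the build-up-model
identity holds by construction; its standard error uses the delta
method on the fit covariance.  Fitting requires ≥3 strictly increasing
saturation times; the default grid is the nine standard values
0.5, 0.75, 1, 1.5, 2, 3, 4, 5, 6 s.

When initial slopes are unattainable (weak short-time signal, unstable
samples) fixed-time STD values — conventionally at 2 s — go through the
same `epitope_map` normalization: each value divided by the maximum,
×100, with ties broken to the first proton in input order.

## Proton basis

Hydrogens are read from the first MODEL of a PDB file (biotite; altloc
blank/'A'); the element column is used when present, else inferred from
the atom name.  A hydrogen is exchangeable iff its nearest heavy atom
within 1.2 Å is N, O or S — standard covalent-radius chemistry; these
protons are removed because D₂O experiments deuterate them.  The
protein basis is then truncated to protons within a proton-to-proton
cutoff (default 8 Å, boundary inclusive) of any ligand proton.  The
exchangeable filter is applied before the cutoff; both stages are
independent library calls, so the order can be changed by the caller.
Methyl and other degenerate protons are kept as individual sites; an
optional post-hoc averaging over user-declared equivalence groups
(`average_equivalent`) serves comparison with degenerate experimental
peaks.

## Relaxation and exchange engine

Dipolar rates for a rigid isotropic tumbler, with J(ω) = τc/(1+ω²τc²)
and q = (1/10)(μ₀/4π)²γ⁴ħ²:

- σ_ij = q r_ij⁻⁶ [6J(2ω₀) − J(0)]
- ρ_i = Σ_{j≠i} q r_ij⁻⁶ [6J(2ω₀) + 3J(ω₀) + J(0)] + leak

The leak rate (default 0 s⁻¹) stands in for external relaxation sinks.
The generator D = R + K acts on deviations m = M − M₀ (dm/dt = −Dm)
over the basis bound protons ⊕ free-state ligand protons.  R is block
diagonal: the full dipolar matrix of the complex at τc_bound, and the
free-ligand block computed on the same intra-ligand geometry at
τc_free with no protein terms (so the free state keeps its geminal/
vicinal self-relaxation).  K couples each bound ligand proton to its
free counterpart with k_off and k_on·[P]_free; with populations from
the 1:1 binding quadratic these rates satisfy detailed balance and
conserve total ligand magnetization.  Unligated protein protons are
not modelled as a separate species: they are saturation sources whose
coordinates are taken identical in both states.  When only K_d is
supplied, k_off defaults to 100 s⁻¹ (typical of the fast-exchange
regime where STD performs well) and is echoed in the output metadata;
zero exchange rates are accepted as the frozen-exchange limit (K = 0).

Saturation is instantaneous and complete: the saturated set (default:
every protein proton in the reduced basis, i.e. infinite bandwidth) is
clamped at m = −M₀ for t ≥ 0.  The remaining deviations obey
dm_r/dt = −D_rr m_r − D_rs m_s and are propagated in closed form,
m_r(t) = (I − e^(−D_rr t)) m_ss with D_rr m_ss = −D_rs m_s, using
scipy's matrix exponential.  A singular reduced generator triggers a
warned fallback to stiff numerical integration.  The observed ligand
signal is the fast-exchange population average f_b·bound + f_f·free,
reported as S_calc,k(t) percentages; S(0) = 0 and an empty saturated
set yields identically zero.

Correlation times are deliberately user-supplied (no defaults in
`ExchangeModel` construction beyond the toy kinetics): τc_bound should
reflect the complex's size (tens of ns for a ~35 kDa protein), τc_free
is sub-ns for small ligands.  Parameter "cycling" against experiment is
done by re-invoking the prediction with new `ExchangeModel` values; no
automated optimizer is provided, since convergence criteria for such
refinement are protocol-dependent.

## Synthetic data and oracles

The toy generator emulates the geometric essence of a bound complex:
ligand protons in a line at 2.5 Å spacing with a protein cluster at
2.5 Å contact distance (`linear_chain`, epitope decreasing along the
chain by r⁻⁶), or a rotationally symmetric `shell` in which all ligand
protons must receive identical saturation.  Default kinetics — K_d =
100 µM, k_off = 100 s⁻¹, 2 mM ligand, 50 µM protein, τc 15/0.2 ns,
500 MHz — sit inside the usual STD experimental window (mM ligand, tens
of µM protein, 500 MHz).  The seed only jitters the linear-chain
protein cluster transversely by ≤0.1 Å, giving families of generic but
topologically identical systems.  Build-up curves add homoscedastic
Gaussian noise (default 1 % absolute) to the mono-exponential model.

What the toys do **not** capture: real protein topology and spin
diffusion through hundreds of protons, internal motion and
order-parameter corrections, finite RF saturation profiles, >2-state
exchange and nonspecific binding, and heteroscedastic/peak-overlap
noise.  Passing tests therefore demonstrate correctness of the
computational chain, not the adequacy of the physical approximations
for any particular real complex.

`reference_ode_oracle` integrates the identical clamped linear system
with an independent solver path (Radau, rtol 1e-10, atol 1e-13); the
production propagator and the oracle agree to better than 1e-8
relative on randomized ≤12-spin systems, and both match the analytic
two-spin Solomon solution.

## Numerical choices and problem sizes

- Fit tolerances 1e-12; noiseless model data are recovered to ≤1e-6
  with residual sums of squares below 1e-10.
- Matrix propagation uses `scipy.linalg.expm` per time point; systems
  of interest (≤ a few hundred spins after the 8 Å cutoff) are far from
  the cost regime where a single eigendecomposition would matter.
- Monte-Carlo sizes: 500 replicates for parameter-recovery statistics,
  50 random systems for solver cross-validation — large enough for
  stable estimates at interactive runtimes.
- Degenerate inputs fail loudly: unprotonated structures, all-zero
  series, empty epitopes, mismatched comparison keys and missing shifts
  under finite bandwidth all raise with actionable messages.

## R-factor conventions

The unweighted NOE R-factor is the default; an optional non-negative
per-point weight vector is exposed.  Pooling over saturation times and
per-time blocks share the same denominator convention, so the pooled r²
is the weighted combination of block numerators over the common
denominator.  When comparing relative epitopes, both sides are
normalized independently before scoring, mirroring relative-STD plots.
Whether a published comparison pooled all saturation times or used one
point per proton is often unstated; both modes are available and the
choice is reported with the result.

## Known limitations

- The temperature at which initial slopes are analyzed is metadata
  only; published protocols sometimes quote inconsistent values (e.g.
  288 K acquisition vs 25 °C analysis) and the package does not model
  temperature dependence.
- The packaged reference tables encode only unambiguous cells of their
  sources; unmeasured or corrupted entries are NA and are dropped from
  comparisons rather than imputed.
- `STDPrediction.initial_slopes` is a first-point finite difference;
  for accurate predicted STD₀ use a fine early-time grid.
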