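# Methods

## The networks

### Full model (29 reactions, 16 species)

PhoR is modelled as a homodimer with three phosphorylation states.
Autophosphorylation is the signal input: reactions r01 (DiPhoR → DiPhoRp)
and r03 (DiPhoRp → DiPhoRpp) carry the `fc` tag, so scaling them by
fc ∈ [0, 1] encodes the external-Pi signal (fc = 1: starvation, maximal
kinase activity; fc = 0: Pi replete, no input). r02/r04 are the reverse
(autodephosphorylation) steps.

Phosphotransfer to PhoB runs through explicit encounter complexes
(r05–r10): either phosphorylated kinase state binds free PhoB, and the
complex either dissociates unproductively or transfers one phosphoryl
group, releasing PhoBp. PhoBp dimerises reversibly into the active
transcription factor DiPhoBpp (r11/r12). Unphosphorylated PhoR dimers act
as the phosphatase through a Michaelis-type complex with PhoBp (r13–r15);
this bifunctionality (same protein activates and deactivates the
regulator) is what makes the steady-state regulator level a function of
the input alone.

DiPhoBpp binds the *phoA* and *phoBR* promoters reversibly (r16–r19).
Binding reactions carry the `bf` tag and unbinding the `uf` tag — the
synthetic-promoter design knobs. Active promoters transcribe (r20, r21),
transcripts are translated into PhoA, PhoB and PhoR (r22–r24; the
PhoR translation step emits the dimer directly, standing in for fast
folding and dimerisation), and transcripts/proteins decay or dilute
(r25–r29). Only the unphosphorylated, unbound pools are subject to
dilution; the phospho-cycle is much faster than growth, so this
simplification does not affect the balance.

Two copy-number conservation laws hold exactly: pPhoA + pPhoAa and
pPhoB + pPhoBa, each equal to the plasmid count (10 by default; 1 in the
single-cell switch configuration at one-tenth volume).

### Parameterisation

The bundled rate constants are a synthetic re-parameterisation: they were
chosen once within physiological *E. coli* ranges and calibrated to the
documented dynamic regimes of the system — equilibrium well before the
16,200 s probe time, promoter occupancy spanning partial (≈ 0.44 at
fc = 0.1) to near-saturated (≈ 0.99 at fc = 1) across the input range, a
transient DiPhoBpp overshoot (≈ 1.8× steady state) in the full model, and
transcript dispersion close to Poissonian. They are not transcribed from a
published table, and absolute concentrations should not be compared
against any particular measurement. Key scales, with units:

| quantity | value | note |
|---|---|---|
| cell volume | 1 µm³ (0.1 µm³ single-cell config) | 1 µM ≈ 602 copies/µm³ |
| autophosphorylation | 0.05, 0.035 s⁻¹ (× fc) | reverse steps 0.01 s⁻¹ |
| phosphotransfer k_cat/K | ≈ 0.067 µM⁻¹s⁻¹ | via complex QSSA |
| phosphatase (dimer) | 0.05 µM⁻¹s⁻¹ assoc., 1 s⁻¹ cat. | two sites per dimer |
| TF–promoter kon₀ | 1.8 µM⁻¹s⁻¹ (× bf) | kon = kon₀·[DiPhoBpp] |
| TF–promoter koff | 0.1 s⁻¹ (× uf) | dwell ≈ 10 s; Kd = koff/kon₀ ≈ 56 nM |
| transcription (active promoter) | 0.03 s⁻¹ (phoA), 0.01 s⁻¹ (phoBR) | |
| mRNA decay | 0.03 s⁻¹ (phoA), 0.005 s⁻¹ (phoBR) | t½ ≈ 23 s / 2.3 min |
| translation | 0.08–0.2 s⁻¹ per transcript | |
| protein dilution | 3×10⁻⁴ s⁻¹ | ≈ 40 min half-life |

At the control condition this yields ≈ 2800 DiPhoBpp copies under full
starvation, ≈ 27 at fc = 0.1, ≈ 10 transcripts of *phoA* and ≈ 2600 PhoA
copies — few-to-hundreds-of-copies regimes where intrinsic noise is
meaningful.

### Reduced model (16 reactions, 10 species)

The reduction follows two standard steps, with constants derived
mechanically from the full set (`reduced_params_from_full`):

1. **mRNA elimination (QSSA).** Transcript dynamics are fast relative to
   protein turnover, so mRNA is set to its quasi-steady level
   (transcription/decay) and each lumped expression constant is
   translation × transcription / mRNA-decay. The reduced model therefore
   has no mRNA species.
2. **Two-state kinase and complex elimination.** The dimeric kinase
   collapses to PhoR (inactive; autophosphorylates and dephosphorylates
   PhoBp) and PhoRp (phosphotransfer-competent). Encounter complexes are
   eliminated into effective bimolecular constants
   k_eff = k_on·k_cat/(k_unbind + k_cat).

The phosphatase constant is derived **per monomer site** (half the
dimer's association rate); the exposed `k3_multiplier` (default 2)
restores the dimer's two-site capacity. With the multiplier at 2 the
reduced model matches the full model's PhoBp and DiPhoBpp steady states
within 5% over fc ∈ {0.1, 0.3, 1.0}; at 1 it overshoots DiPhoBpp roughly
threefold — keeping the uncalibrated reduction testable was the reason to
expose the multiplier rather than bake it in. The reduction also removes
the early DiPhoBpp activation peak: the peak arises from the
doubly-phosphorylated kinase pool discharging two phosphoryl groups into
a still-unbuffered PhoB pool, a mechanism the two-state kinase cannot
express. Reduced reaction ids are namespaced q01–q16 to avoid collision
with r01–r29.

## Simulation

**Deterministic.** The network is translated to dx/dt = S·v(x) with
mass-action fluxes (k, k[A], k[A][B], k[A]²) and integrated with LSODA
(stiff-capable) at rtol = 1e-8, atol = 1e-10 on a uniform output grid.
Conserved sums are invariant to integrator tolerance. `steady_state`
returns the state at a probe time (default 16,200 s, where the slowest
pools — set by dilution, τ ≈ 3300 s — are ≥ 99% equilibrated) and warns
when max |dx/dt| exceeds 1e-4 µM/s.

**Stochastic.** Exact SSA, direct method: total propensity a₀ gives an
exponential waiting time, the reaction is chosen proportionally to its
propensity. Deterministic second-order constants k (µM⁻¹s⁻¹) convert to
stochastic constants k/(N_A·V); homodimerisation 2A → · uses stochastic
constant 2k/(N_A·V) over x(x−1)/2 pairs, so the deterministic limit is
recovered at large copy number (the standard correspondence). The jump
process is recorded by piecewise-constant sampling on a uniform grid
(default 1 s). The core loop is numba-compiled; a run is a pure function
of (model, initial counts, grid, seed).

**Mid-run condition switch.** The external-Pi step experiment changes the
fc-scaled constants at t_switch. The pending unit-exponential waiting
time is rescaled by the old/new total propensity at the switch instant —
exact by memorylessness — so a "switch" to identical constants reproduces
the unswitched trajectory bit for bit, which is itself a regression test.

**Seeding counts from concentrations.** SSA initial states round the
deterministic concentrations to integers; the rounding residue of each
conservation law is absorbed into the law's free species so promoter
totals stay exact, and any positive concentration rounded to zero is
logged (extinction changes dynamics).

## The noise protocol

Per condition (fc, bf, uf): integrate the scaled model to 16,200 s,
convert to counts, run 5 SSA replicates of 1000 s sampled at 1 s
(replicate r of condition i is seeded base_seed + i·n_reps + r; all seeds
are logged), pool the 5 × 1001 samples, and compute CV and FF with the
unbiased (n−1) variance. Pooling across replicates (rather than averaging
per-replicate metrics) matches treating the joint sample as one
stationary pool; per-trajectory diagnostics, including an AR(1)
effective-sample-size estimate, are available but do not rescale the
reported moments.

**Estimator resolution.** Grid samples are serially correlated on the
timescale of the slowest fluctuation feeding the observable. For the
active-promoter count the relevant times are promoter dwell (~10 s), so
the pooled CV/FF estimates resolve percent-level contrasts. For the
transcript, the correlation time is its lifetime (1/d ≈ 33 s), leaving an
effective sample size of order 10² per condition and a per-condition FF
sampling SD of ≈ 0.1–0.15. The *extremes* of FF(mRNAa) over the 27
conditions therefore sit 1.5–2 SD outside the true range: with true
values ≈ 0.95–1.15, measured minima fall around 0.73–0.86 and maxima
around 1.22–1.47, varying with the base seed. Any analysis of extreme FF
values at this protocol size is dominated by this sampling spread; the
means and the CV orderings are robust to it.

## Experiments

- **Promoter scan**: deterministic steady-state pPhoAa over the 10 × 10
  grid of bf, uf ∈ {0.25, 0.50, …, 2.50} (the "0.25- to 2.5-fold in 10
  steps" reading of the design spectrum; configurable). Monotone:
  non-decreasing in bf, non-increasing in uf.
- **Noise grid**: the 27-condition protocol above, on either model
  (pPhoAa always; mRNAa in the full model only). `best_design` takes the
  argmin of a metric over (bf, uf) per fc, breaking ties toward smaller
  uf then larger bf.
- **Perturbation**: single promoter at 0.1 µm³; fc switches 1.0 → 0.3 and
  0.3 → 1.0 at 7000 s, runs to 40,000 s, 5 replicates per pair. The
  recovery gap compares the pooled mean over the final third of the
  post-switch window with the target condition's deterministic steady
  state; pooling matters because the slow-turnover yield protein PhoA has
  a window-mean SD of several percent in a single cell. DiPhoBpp and
  pPhoAa recover within ~1%, PhoA within ~5–7%.
- **Model comparison**: per-fc relative steady-state differences for
  PhoBp, DiPhoBpp, pPhoAa, PhoA, plus a transient-peak flag (max of the
  first 2000 s exceeding 1.05× the own steady state).

## Synthetic oracles

Three small networks with closed-form stationary laws validate the
SSA + metrics pipeline end to end, with no external data:

- **birth–death** (∅ → X at k, X → ∅ at γ): Poisson(k/γ), FF = 1;
- **telegraph promoter** (one gene copy switching off↔on, transcription
  when on): mRNA mean (k_tx/d)·k_on/(k_on+k_off),
  FF = 1 + k_tx·k_off/((k_on+k_off)(k_on+k_off+d));
- **N-copy promoter** (N independent two-state promoters): active count
  Binomial(N, p), p = k_on/(k_on+k_off), FF = 1 − p ≤ 1.

The third proves the mechanism behind the FF ≤ 1 bound for pPhoAa: a
conserved pool of two-state units cannot be over-dispersed, and slower
unbinding (higher p) pushes FF further below 1 — the direction of the
headline design result. Tests verify each analytic fact against batched
long-run SSA estimates (10 independent seeds, 3-SE bands), so the
formulas are checked by simulation before being used as references.

## What the synthetic setup does and does not show

The generator emulates intrinsic noise only: stochastic reaction timing
at fixed rate constants in a fixed volume. It does not emulate extrinsic
noise (cell-to-cell parameter variation, partitioning at division,
growth-rate coupling), decoy TF-binding sites, or upstream PhoU/ABC
transporter dynamics (the scalar fc stands in for that pathway). Passing
tests therefore demonstrate correctness of the simulators, estimators and
design trends *within* the intrinsic-noise model — not that a real
engineered strain would show these absolute noise magnitudes.

## Numerical choices and degenerate inputs

- Reactions above order 2 are rejected at construction; none occur here.
- Propensities are exactly 0 whenever a reactant count is below its
  stoichiometric requirement (x(x−1)/2 = 0 at x = 1).
- All-zero propensities are not an error: the trajectory is padded with
  the absorbing state.
- CV/FF on a zero-mean sample raise a typed error rather than return NaN.
- ODE/SSA reruns with identical inputs are bit-identical; the experiment
  drivers are deterministic functions of base_seed.
- fc = 0 drains the phospho-pool completely (no autophosphorylation
  input), giving DiPhoBpp → 0; the Pi-replete limit.

## Known limitations

- Rate constants are calibrated, not fitted to data; only relative
  trends and the documented regime properties are meaningful.
- The transcript-FF extremes carry the sampling spread quantified above.
- The QSSA reduction is conservative at steady state but intentionally
  distorts transients (faster response, no activation peak); it should
  not be used to study response times quantitatively.
- Tau-leaping/hybrid acceleration, SBML round-tripping, Hill-type
  kinetics and spatial effects are out of scope.
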