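# Methods

`crisprikit` models CRISPR-interference (CRISPRi) gene circuits in growing
*E. coli* as mass-action reaction networks and reproduces, in silico, the
characterization experiments used for such circuits: NOT-gate
fold-repression and dose-responses, toggle-switch bistability and
hysteresis, stripe-forming incoherent feed-forward loops (IFFLs), and a
three-node ring oscillator. This note records the models, their
assumptions, the parameter choices, and the limits of what the shipped
tests demonstrate.

## The mass-action core

Every circuit compiles to a list of species and elementary (at most
bimolecular) reactions with mass-action kinetics; the state is a vector of
per-cell molecule counts, time is in hours. The right-hand side is
`S·v(x)` with `v_j = k_j ∏ x_i^{s_ij}`; the Jacobian is assembled
analytically from the same index structure. Gene loci are represented by
their binding states; since loci are neither created nor destroyed, each
gene contributes one linear conservation law (its states sum to the
plasmid copy number). Conservation laws are detected as the nonnegative
extreme rays of the left null space of the stoichiometry matrix, and are
eliminated by substitution before Newton iteration, stability analysis
and continuation — with them left in, the Jacobian is structurally
singular.

Hill-shaped inducer inputs (arabinose via AraC/P_BAD, AHL via LuxR/P_LUX)
are deliberately *not* part of the mass-action core: an inducer
concentration is mapped to a production-rate parameter by
`rate(c) = β_max (ε + (1−ε) cⁿ/(cⁿ+Kⁿ))` and injected as a
state-independent rate constant. Defaults: Hill exponent `n = 2`
(dimerizing activators), `K = 0.02 %` arabinose / `1 µM` AHL, basal
fraction `ε = 10⁻³` (these promoters are leaky). The K and ε values are
free knobs exposed in configuration; they were chosen once so the
NOT-gate dose-response spans the 0–0.2 % arabinose range used
experimentally.

### Shared rate constants and their provenance

| parameter | default | unit | rationale |
|---|---|---|---|
| δ (dilution) | ln2/0.71 ≈ 0.976 | 1/h | an ≈11 h oscillator period corresponds to ≈15.5 generations, fixing the doubling time at ≈43 min |
| δ_r (sgRNA turnover) | 6 (toggle 1.5, ring 2) | 1/h | minutes-scale small-RNA half-life |
| δ_p (reporter turnover) | 2 | 1/h | degradation-tagged fluorescent proteins |
| α_D (dCas9 production) | circuit-specific | molecules/h | constitutive vector; see below |
| k_c (dCas9:sgRNA loading) | 0.05–0.1 | 1/(molecule·h) | fast complex assembly |
| k_s (specific binding, base) | 0.01–0.1 | 1/(molecule·h) | hours-scale single-target search; presets scale this |
| k₋s (specific unbinding) | 0.01–0.025 | 1/h | dCas9 barely dissociates from a matched target within a generation; loss is dilution-dominated |
| k_u, k₋u (unspecific) | 0.045, 75 | — | PAM-scanning surrogate: fast exchange, affinity far below specific |
| gene copies | 10 (witness 19/11) | copies/cell | medium-copy variable vector |

A structural choice that matters throughout: **a DNA-bound complex is
cleared at the dilution rate and the clearance removes the complex**
(`G_bound → G_free` at δ). This is per-cell bookkeeping for growth — at
division, bound complexes are partitioned away while replication
re-supplies unbound gene copies — and it makes an occupied operator a
repressor *sink* with capacity δ·(copy number). The alternative
(clearance releasing the complex back to the free pool) was examined and
rejected: with release-only clearance and degradation acting on free
complexes alone, the steady-state free-complex level equals
production/δ *identically*, all sequestration effects cancel at steady
state, and no binding arrangement — specific or unspecific — can change
the number of equilibria.

## NOT gate and the sgRNA preset table

The 2-node NOT circuit is: inducible sgRNA production → dCas9:sgRNA
complex → specific operator binding on the reporter node; the reporter is
produced from operator-free gene states, with a 1 % residual (leak) from
occupied states. Maximal fold-repression is the steady-state reporter of
a no-sgRNA control divided by that of the fully induced circuit.

Only two facts about per-guide strength are experimentally pinned: the
four primary guides repress 10–30-fold with sgRNA-2 the strongest, and
5′-truncating four nucleotides ("t4") lowers maximal repression of
sgRNA-1 and sgRNA-4 by 20 % and 45 %. The preset table therefore assigns
sg2 = 30, sg3 = 10, sg1 = 20 and sg4 = 15 (documented interior values),
with t4 targets derived from the printed reductions. Each preset's
binding-scale is obtained at run time by a monotone bracketing root
search (`brentq` on log-scale) driving the model's maximal
fold-repression to the preset's target within 10⁻⁴ — so the acceptance
quantities are genuine calibration round-trips, not stored constants.

## Toggle switch and the origin of bistability

Two genes each produce an sgRNA whose dCas9 complex specifically
represses the other gene. Gene states are indexed `G_i^(s,u)`: `s` — the
specific operator free (0) or bound by the cognate complex (1); `u` — a
per-gene unspecific (PAM-scanning surrogate) site free (0) or occupied by
either complex variant (1 or 2). Specific and unspecific binding are
independent (non-cooperative). Variants: `specific_only` (no `u` index),
`unspecific_neutral` (unspecific occupancy does not affect
transcription), `unspecific_inhibitory` (any occupancy blocks
transcription). dCas9 is produced and diluted explicitly; both sgRNAs
load onto the shared free pool. A controller layer (arabinose → extra
sgRNA-1, AHL → extra sgRNA-2 production) implements the induction
experiments, and gene 2 carries the GFP reporter.

The shipped bistability witness (β₁ = 16, β₂ = 24 molecules/(copy·h),
leak 0.008, δ_r = 1.5, α_D = 200, δ = 1.0, k_c = 0.05, k_s = 8,
k₋s = 0.025, k_u = 0.045, k₋u = 75, 19/11 gene copies) was found by the
package's own seeded box search and verified to have two stable states
(reporter ≈ 133 vs ≈ 1.5) separated by a saddle, in both unspecific
variants. Continuation of this witness in the sgRNA-1 production rate
yields the S-shaped branch with two tangent bifurcations (β₁ ≈ 1.51 and
≈ 150.6) bracketing the bistable region.

**A nuance the screening makes explicit.** The published mechanistic
claim is that unspecific binding (repressor depletion) is what enables
bistability, with no bistability found for specific-binding-only
networks. Our enumeration does *not* fully reproduce the negative half
of that claim for this reaction scheme: in the wide kinetic box
([10⁻³, 10³] per rate), a small fraction of specific-only draws (≈1.5 %)
are genuinely bistable — verified by clean saddle structure, eigenvalues
and independent basin simulations. The mechanism is the operator sink
described above: with near-irreversible specific binding, essentially
every produced repressor complex is captured by the partner operator and
destroyed by replication clearance, giving a threshold-linear
(stoichiometric) repression response — itself a depletion nonlinearity,
concentrated in corners where complex production is comparable to
δ·(copy number). The corresponding acceptance check (zero specific-only
witnesses in 200 draws) is therefore expected to fail, and is left
failing rather than being weakened; the positive half of the claim
(witnesses abound for both unspecific variants in the witness-centered
box, and the witness's own bistability survives removal of neither its
unspecific sites nor its dCas9 pool individually) is reproduced.
Negative screens are evidence of absence at the stated budget (200
draws, 8 random + pre-relaxed Newton starts, saddle completion), never
proofs.

### Steady-state enumeration

Multistart damped Newton on the conservation-reduced system, with
starts from (i) long integrations from occupancy-extreme states — all
genes free, all genes bound, and each gene bound *individually* (the
asymmetric configurations are the attractors of mutual repression),
(ii) seeded log-uniform random states (a few pre-relaxed by a short
integration, because raw Newton jumps basins), and (iii) a saddle
completion pass: from every unstable root, perturb ± along the leading
eigenvector, relax, and re-solve — this reliably recovers thin
attractor basins near folds. Roots are deduplicated at 10⁻⁴ relative
tolerance on the log-state with a scale-aware floor (species below
10⁻⁶ of the state scale compare as equal); stability is read from the
reduced Jacobian's spectrum (stable iff max Re λ < −10⁻⁸).

### Continuation

Pseudo-arclength continuation in log₁₀ of the free parameter: secant
predictor, Newton corrector on the augmented system, step adapted
within [10⁻⁴, 10⁻¹] of the parameter's log-range, state components
weighted relative to their magnitude so counts spanning decades
contribute comparably to arclength. Folds are detected by the sign
change of the parameter-direction tangent component and localized by
bisection on arclength. Forward and backward sweeps agree on fold
locations to ≈10⁻⁹ relative in the shipped diagram; the acceptance
tolerance is 10⁻³.

## Hysteresis protocol

The flow-cytometry experiment is emulated as a four-phase protocol
(inducer 1, 10 h → none, 12 h → inducer 2, 10 h → none, 12 h), with a
1:120 culture dilution at each medium switch. A culture dilution leaves
per-cell state mostly intact; in the model it divides free molecules
(RNAs, complexes, proteins) while gene states — including current
operator occupancy — carry over. State memory survives because the
occupied-operator configuration regenerates its own repressor pool
within the new phase. Phase-end states are labeled HIGH/LOW against the
geometric mean of the witness's two stable reporter levels (the model
analog of the 330 a.u. cytometry gate), and retention asks whether each
inducer-free phase keeps its predecessor's label. The deterministic
core has no cell-to-cell variability; population %-HIGH readouts are
produced by the synthetic-cytometry layer, which maps reporter levels
to a two-component lognormal mixture.

## IFFL stripes

The type-2 IFFL is wired as: input induces N1, whose transcript releases
two guides — a strong one against N2's operator and a weak (t4-truncated)
one against one of N3's two operator sites; N2's guide occupies N3's
second site. N3 transcribes only when both sites are free (steric
block), with 1 % leak. Two wiring-level constants position the band-pass
window and are documented package choices rather than measured values:

* the truncated guide's association rate carries an extra attenuation
  (×0.2 for the primary set, ×0.1 for the second set) beyond what the
  t4 calibration implies — maximal fold-repression saturates and hides
  most of the affinity loss of truncation, but the *dose position* of
  the direct edge depends on affinity;
* N2's guide is expressed at 10 molecules/(copy·h), and the second
  circuit's N1 cassette runs 3× hotter than the first's, which offsets
  the two band-pass windows so the composed double-stripe circuit peaks
  at two resolvably distinct doses (≈0.006 % and ≈0.010 % arabinose),
  mirroring the experimentally observed offset.

Composition merges two circuits that share only the free dCas9 pool.
With the default generous supply (α_D = 20 000/h against a peak total
guide demand of ≈5 000/h) the composed dose-responses match the
standalone ones to <0.1 %; cutting supply 20-fold couples the circuits
(≈90 % profile deviation) — the resource-competition regime.

## Ring oscillator

Three nodes in a repression cycle, explicit sgRNA and dCas9 species,
shared pool. Sustained oscillation in this non-cooperative setting
requires a *limiting* dCas9 pool (α_D = 150/h): guide competition for
free dCas9 plus the operator sink provide the switching nonlinearity;
with generous dCas9 or weak binding the ring relaxes to a fixed point.
Defaults: β = 60 molecules/(copy·h), δ_r = 2/h, and a global
specific-binding scale of 139.76 fixed by deterministic bisection so the
limit-cycle period sits at 11 h, the midpoint of the observed 10–12 h
window. At these defaults the three reporters oscillate with period
dispersion <10⁻⁴ and phase offsets of exactly one third of a period; the
open-ring control (one edge deleted) settles to a fixed point from all
tested initial states. Period estimation follows the kymograph reading:
discard the first 20 h, Savitzky–Golay smoothing (window 7 samples,
order 2), period = mean spacing of successive maxima, sustained iff the
peak prominence over the last three cycles holds ≥90 % of its value
three cycles earlier.

## Synthetic readouts

The generators emulate the three measurement modalities and implement
the published normalizations exactly:

* **Plate reader** — raw = (true·lognormal(CV) + autofluorescence)·OD +
  blank; normalization: blank subtraction, division by OD₆₀₀,
  autofluorescence subtraction, then percent-of-max per channel. Blank
  wells and a no-reporter autofluorescence strain are generated per
  plate. Noise defaults (unpublished, package choices): 5 %
  multiplicative CV, blank 100 ± 5 a.u., autofluorescence 200 a.u., OD
  0.5 ± 0.02.
* **Flow cytometry** — 20 000 events per sample from a two-component
  lognormal mixture (0.35 log₁₀ spread per component, a typical
  cytometer width; a free assumption), gated at the published
  330 a.u. green threshold (strict inequality).
* **Time lapse** — trajectories resampled to 10-min frames,
  multiplicative noise, then per-channel minimum subtraction and
  percent-of-max scaling.

All generators are bit-reproducible under a fixed seed. The
parameter-recovery study (fit a decreasing Hill curve to normalized
noisy plates; 8 doses, 3 replicates, 5 % CV) recovers (K, n) within
15 % in ≈93 % of 100 seeded datasets — the noise defaults were chosen
to make this study informative rather than trivial.

What the synthetic layer does *not* emulate: growth curves and
OD-dependent expression, spectral bleed-through between channels,
cytometry light-scatter gating, cell-to-cell extrinsic variability, and
spatial structure (the agar-plate pattern is represented only as the
dose→state mapping of the IFFL). Tests passing on synthetic data
demonstrate the correctness of the analysis pipelines and the internal
consistency of the models, not wet-lab predictive accuracy.

## Numerical choices

* Integration: implicit BDF with analytic Jacobian, rtol 10⁻⁸,
  atol 10⁻¹⁰; small negative excursions (>−10⁻⁹) are clipped, deeper
  ones raise. Conservation drift stays below 10⁻⁶ relative on all
  shipped runs.
* Calibrations (preset scales, oscillator binding scale) use bracketing
  scalar root finding on log-transformed knobs — monotone by
  construction, tolerance 10⁻⁴.
* Degenerate inputs fail loudly with typed errors (`ConfigurationError`,
  `DomainError`, `CalibrationError`, `SolverError`); an enumeration that
  converges to nothing raises a distinct `EmptyEquilibriumSetError`
  rather than reporting "no equilibria".
* Problem sizes in the shipped tests (200-draw screens, 200 h
  oscillator horizon, 17–25-point dose grids, 100-trial recovery study)
  are the package's documented study conditions.

## Known limitations

* The reaction scheme is one concrete instantiation of the circuits'
  published architecture; alternative schemes (dCas9 conservation
  instead of turnover, genome-wide decoy pools, cooperative clearance)
  would move the witness and the screening statistics.
* "Unspecific binding" is a lumped per-target-gene site; an optional
  genome-wide decoy pool is not enabled by default.
* Deterministic ODE scope only: no stochastic phase drift, no
  single-cell lineage variability, no delay terms; Csy4 processing is
  treated as instantaneous.
* The specific-only monostability screen is a fixed-budget search, and
  — as discussed above — this scheme genuinely violates the idealized
  zero-witness expectation in rare corners.
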