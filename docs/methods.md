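# Methods

## Model formulation

The model describes signaling at the rear of a cell migrating through a
polarized mechanical environment. Nineteen conserved moieties — twelve
proteins (Src, p190RhoGAP, Ect2, RhoA, ROCK1, PKN2, DRF, LIMK, cofilin,
CPI-17, MLCP, actin), the caveolae complex as a single node, and six
biophysical entities (polarized substrate stiffness, membrane tension,
F-actin alignment, p-MLC, actomyosin contractility, rear retraction) — are
each normalized to a 0–100 activity scale. Actin is a two-state moiety whose
active pool is F-actin and inactive pool G-actin. For the tension node the
*active* state encodes **decreased** rear membrane tension, so that
activation semantics are uniform across the network. p-MLC is a
phosphorylation state rather than a protein; it is the one species without
turnover (its inactivation is carried explicitly by MLCP) and, for balance,
its activation is one-step rather than bind-and-convert.

Interactions expand to elementary mass-action reactions under fixed rules
(two-step for protein/complex pairs, one-step catalytic when a biophysical
entity is involved, reverse steps at exactly 10% of forward on reversible
edges, first-order turnover for all but the input and p-MLC). The clamped
input is a boundary condition: its pools have structurally zero derivative
and change only through timed events. Where the wiring admits readings, we
chose: DRF is activated by *both* RhoA and ROCK1 (two edges); the
tension→caveolae, aligned-actin→contractility and p-MLC→contractility steps
are irreversible; all protein↔biophysical steps are irreversible, with
turnover supplying the return flux. The full canonical edge list has 28
signed interactions.

## Rate constants

All rates live on the decade grid 1×10⁻ⁿ (integer n ≥ 1): the kinetic data
needed for finer values do not exist, and order-of-magnitude rates avoid
over-determination. Units are s⁻¹ for unimolecular steps and
(activity·s)⁻¹ for bimolecular ones. Structural constraints enforced by
`check_parameter_constraints`: grid membership; reverse ≤ 10% of its paired
forward; and ordered class bands — protein-class forwards in [10⁻⁶, 10⁻¹],
biophysical-class forwards in [10⁻⁶, 10⁻²], turnover in [10⁻³, 10⁻²] — which
keep protein kinetics faster than biophysical kinetics at the ceiling while
allowing individual couplings to be weak. Turnover for the four
event-perturbed species (membrane tension, actin, ROCK1, PKN2) is anchored
at 0.01 s⁻¹, the baseline from which the perturbation protocols start.

### Calibration of the shipped profile

The default profile is a calibrated point on the grid, selected by
coordinate descent on the decade exponents against the behavior suite
(responsive with input, quiescent without, directional memory, knockdown,
osmotic-shock, kinase-inhibition and cytochalasin responses, steady-state
convergence, and halve/double robustness of the critical rates). Three
structural features of the calibrated regime matter more than any single
value:

1. **Quiescence despite basally active Src.** Src starts 50% active with no
   upstream activator. Its coupling to caveolae is made very weak
   (k_bind = 10⁻⁶) so the initial Src transient cannot ignite the feedback
   loop, while Src strongly charges p190RhoGAP, which gates RhoA during the
   transient. With pools of order 100 and turnover capped at 0.01 s⁻¹, an
   activation stage with binding ≥ 10⁻⁴ has small-signal gain ≥ 1, so a
   multi-stage loop cannot have a strongly attracting zero state *and* a
   high ON state; quiescence without input is achieved by keeping the
   loop's low-amplitude gain near or below unity (weak Src→caveolae,
   caveolae→Ect2 and GAP-gated Ect2→RhoA steps) rather than by a deep
   attractor. Without the input the system settles to negligible activity
   (retraction < 1 unit over the full 10 000 s window).
2. **Memory via the mechanochemical subloop.** Contractility→tension
   (10⁻⁴) plus tension→caveolae (10⁻³) sustain caveolae and RhoA signaling
   once contractility is high, so removing the stiffness input changes the
   retraction output by < 0.3 units. The input's own drive on tension is
   deliberately weak (10⁻⁵) — it ignites the loop but contributes little to
   the established plateau, which is what makes the memory near-perfect.
3. **Dual drive on retraction.** Rear retraction is fed by both alignment
   and contractility at 10⁻³, so halving either input (or doubling
   retraction turnover) moves the final value but not the classification —
   the halve/double sweep over the five most sensitive rates leaves the
   faithful behavior intact.

The calibrated ON state runs the kinase cascade at low occupancy (RhoA and
ROCK1 around 1% active, PKN2 a few %) while the mechanical outputs are
high (contractility ≈ 38, retraction ≈ 75). F-actin alignment plateaus
near 4 units; knockdown and cytochalasin effects on alignment are therefore
assessed relative to that baseline, not on an absolute scale.

## Simulation and events

Deterministic integration uses SciPy's LSODA (automatic stiff/non-stiff
switching) with an analytic Jacobian, relative tolerance 10⁻⁸ and absolute
tolerance 10⁻¹⁰ (tight, because sensitivity differencing needs headroom),
over 10 000 s with output every 25 s (401 points). Events are instantaneous:
integration stops at the event time, the parameter or species pool is
edited (species edits move the difference to the sibling pool, preserving
the moiety), and integration restarts; simultaneous events apply in list
order; a grid point coinciding with an event reports the post-event state.
Undershoot below −100× the absolute tolerance raises an error rather than
being clipped. Moiety conservation on the canonical runs holds to ~10⁻¹⁴
relative.

Steady state is declared when every pool's spread over a trailing window
(default 1000 s) is at most a relative tolerance (default 1% for behavior
classification, 10⁻⁶ for sensitivity preconditions) of its final value,
with a 10⁻³-unit floor on the scale so that empty pools cannot fail on
roundoff. Sensitivity evaluation uses a 100 000 s horizon, by which the
unperturbed model has converged to ~10⁻¹³.

## Scenarios

The ten catalog scenarios follow the perturbation protocols: stiffness
transitions at t = 4000 s; RhoA and caveolae knockdowns as initial-condition
edits (both pools rescaled to 12% of total — with default initial conditions
the active pools of both species are zero, so in practice the inactive pool
is reduced to 12); osmotic shock as tension-node turnover 0.01→10 at 4000 s
and back at 7000 s; Y-27632 as ROCK1/PKN2 turnover 0.01→10 at 5000 s;
global/local cytochalasin-D as F-actin turnover 0.01→1 / 0.01→0.2 at
5000 s. The qualitative words are operationalized as configurable
thresholds: responsive ≥ 50, negligible ≤ 5, "severely reduced" ≤ 50% of
unperturbed, "near identical" ≤ 5 units maximum divergence, shock recovery
≥ 80% of the pre-shock plateau.

## Sensitivity and robustness

Scaled sensitivities S_k = (k/R)·∂R/∂k are computed by 1% central
differences at the steady state of the unperturbed scenario, one rate at a
time, for all 100 rate constants. At steady state of a mass-action system
the S_k sum to zero (uniform rate scaling is a pure time rescaling), which
the implementation reproduces to ~5×10⁻⁵; the residual shrinks with the
differencing step. "Critical parameters" are the top 5 by |S_k|. The
robustness sweep halves and doubles each critical rate separately and
re-classifies the with/without-input behavior pair; classification order is
responsiveness first, then convergence, then quiescence, so a model that
fails to retract is labelled `non_responsive` whether or not it converged.

## The parameter ensemble: what it emulates and what it does not

`sample_parameter_profiles` emulates the study's parameter uncertainty: each
forward rate draws a decade exponent uniformly from its class range
(protein n ∈ {1..3}, biophysical n ∈ {2..4}, turnover n ∈ {2..3}), reverse
rates follow at 10%, and the four anchored turnovers stay at 0.01. The
draw is deterministic given the seed.

The ensemble deliberately does **not** emulate the iterative,
plausibility-guided calibration that produced the shipped profile — it
quantifies how special that profile is. The result is unambiguous: random
profiles from these ranges are overwhelmingly *constitutive* (the positive
feedback latches with or without input) and essentially never faithful.
The input-dependent switch is a calibrated, locally robust regime (it
survives halving/doubling of its critical rates) rather than a generic
property of the topology at arbitrary decade rates. Passing behavior tests
on the shipped profile therefore says nothing about arbitrary
parameterizations of the same wiring, and the ensemble report is the
honest statement of that scope.

## SBML interchange

Export writes SBML Level 3 Version 1 core: one species per pool (complex
pools `A:B` get sanitized ids with the original name in an annotation), one
reaction per elementary reaction with an explicit MathML mass-action
product, global parameters, and a single unit compartment; class/category
metadata rides in a small custom annotation namespace. Import accepts only
mass-action kinetic laws (a product of one parameter and the reactant
species) and rejects anything else by reaction id. Export → import → export
is byte-identical, and the re-imported model evaluates identical
derivatives, so the document is a faithful interchange format. Units are
left dimensionless (activity units), which standard validators report as
warnings, not errors.

## Known limitations

* The model is a single well-mixed compartment: "rear" localization is
  encoded in the wiring, not in space.
* Quiescence without input is a property of the 10 000 s study window under
  the calibrated rates; it is enforced by weak couplings and gating, not by
  a proof of global stability of the resting state.
* The alignment observable saturates low in the calibrated regime; analyses
  that need a high absolute alignment baseline would require re-calibration
  against additional data.
* The ensemble explores the stated decade ranges only; rates outside them
  (including the weak couplings the calibration itself uses) are not
  sampled.
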