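# Methods

This note documents the model, the numerical choices, the synthetic-data
generator and the known limitations of `ucmbalance`. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The analysis treats standing balance recovery as control of a single
performance variable per horizontal direction — the whole-body extrapolated
center of mass (xCoM) — by 14 redundant elemental variables, the relative
segmental xCoMs.

* **Linearized pendulum.** The velocity adjustment `xCoM = CoM + v/ω₀`
  assumes the body behaves as a (linearized) pendulum of constant length
  `l` within one trial. `l` is measured at the perturbation-onset sample
  as the 3-D distance from the midpoint of the two lateral-malleolus
  markers to the whole-body CoM, and `ω₀ = √(g/l)` is held constant for
  the trial. Averaging the malleoli is a symmetric, deterministic choice;
  a config switch could expose a single side but the difference is below
  marker noise for a hip-width stance. `g = 9.81 m/s²`, configurable.
* **Segmental CoM model.** Each segment CoM lies at a fixed fraction of
  the proximal→distal axis spanned by its endpoint markers (midpoints for
  trunk and head endpoints). The bundled table
  (`data/anthropometry_female.yaml`) carries de Leva-style adjusted
  Zatsiorsky fractions for an adult female; the head and trunk CoM
  fractions are re-expressed for this marker set's axes (acromion-midpoint
  → vertex, trochanter-midpoint → acromion-midpoint). Mass fractions are
  renormalized to sum to exactly 1 at load time, so published tables quoted
  to four decimals are accepted unchanged. Any table with the same
  14-segment topology can be substituted via YAML.
* **Constant Jacobian.** Because the whole-body xCoM is a fixed
  mass-weighted sum and the chain variables are partial sums along the
  five chains, the task Jacobian is time-invariant: entry *j* is the summed
  mass fraction of segment *j* and all segments distal to it (trunk = 1).
  No linearization error is involved — the task equation is exactly linear —
  which is what licenses a *within-trial* (moment-to-moment) variance
  decomposition rather than the trial-to-trial variant.
* **Two phases, two directions.** Deviations are referenced to the
  perturbation-onset posture in Phase I and to the posture at the
  base-of-support crossing in Phase II, then decomposed separately per
  direction with the same Jacobian row. The synergy index is computed
  exactly as defined, with degrees-of-freedom normalization in the
  numerator only; its bounds are therefore [−1, 1/13].

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| filter (zero-lag Butterworth) | on for recorded data, 6 Hz, effective 4th order | smoothing before central-difference differentiation; off for noise-free synthetic fixtures, where differentiation must be exact |
| gap interpolation | ≤ 5 samples | longer marker dropouts are fatal rather than guessed |
| BoS edge | contralateral toe tip at onset | heel→toe marker vector rescaled to the measured foot length; fixed in time because the stance foot does not move |
| BoS crossing | first strict `>` exceedance | deterministic tie-break, no hysteresis |
| foot contact | height within 1 cm of pre-onset baseline and vertical speed < 0.05 m/s, after the swing apex | kinematic stand-in for an instrumented contact event; annotated events override it |
| onset fallback | trunk-CoM AP velocity > 0.05 m/s sustained 50 ms | used only when no onset event is annotated; a smooth pull means kinematic onset trails the true trigger by up to ~0.15 s, so annotated onsets are strongly preferred |
| `n`, `d` | 14, 1 | elemental and performance variable counts; exposed for generic reuse |

Degenerate inputs: empty phase windows, zero Jacobians, a trial whose xCoM
never leaves the base of support, and trials with no detectable step are
all fatal with specific messages. A segment with zero deviation in both
subspaces gets `iSYN = NaN` (reported as missing) without aborting the run.

The null-space basis is computed by SVD. Tests verify that the projector —
not the basis — is the meaningful object: an independently constructed
Gram–Schmidt basis yields identical components to 1e-10.

## Synthetic generator

Level (a), `generate_deviations`, plants exact subspace structure:
`dev[t] = ε z[t] + (Jᵀ/‖J‖) w[t]` with `z ~ N(0, σ²_TIR I₁₃)`,
`w ~ N(0, σ²_TR)`, i.i.d. by default or stationary AR(1). Expected
recoveries are `MSD_TIR = 13σ²_TIR`, `MSD_TR = σ²_TR`,
`SYN = (σ²_TIR − σ²_TR)/(13σ²_TIR + σ²_TR)`; the defaults
σ_TIR = 0.02 m, σ_TR = 0.01 m give the recovery conditions used by the
acceptance checks.

Level (b), `generate_step_trial`, is a kinematic puppet built on a bundled
quiet-stance template for a 1.62 m, 50 kg subject (the cohort scale this
analysis targets): minimum-jerk anterior translation of head/arms/trunk/
pelvis (0.20 m over 0.9 s — strong enough that the xCoM exits the base of
support, the condition that obligates a recovery step), knees at half the
pelvis translation, and one scripted swing (0.30 m step, 0.08 m lift,
0.5 s) starting 0.45 s after onset. Segment-level wobble is specified in
chain-variable space (so its task-irrelevant/task-relevant split is exact
by construction) and mapped to marker displacements by solving, chain by
chain from the trunk outward, for the distal-marker displacement that
shifts each segment CoM by exactly the requested amount; feet, which share
no markers with the shank, are displaced rigidly. Because the whole
pipeline is linear, wobble planted in the null space stays in the null
space after differentiation and velocity adjustment. The default step
scenario uses smooth AR(1) wobble (ρ = 0.99, ~1 s time constant,
σ_TIR = 4 mm, σ_TR = 1 mm) plus 0.4 mm isotropic marker noise — values in
the range of postural sway and optical capture error. Ground-truth phase
boundaries are computed by running the same geometry on the noise-free,
wobble-free trajectory.

What the puppet does **not** emulate: dynamics (no forces, no ground
reaction, no momentum conservation), segment rotations (markers translate
rigidly), realistic arm counter-swing, soft-tissue artifact, and
multi-step or ML-directed recoveries. Passing tests therefore demonstrate
the correctness of the *analysis* — geometry, projections, detectors,
bookkeeping — not that real perturbation responses have any particular
synergy structure.

## Problem sizes

Test and acceptance computations use N = 10,000 samples for variance
recovery (chi-square concentration puts the 13-dimensional MSD estimate
well within the 5 % check at that size), 4 s puppet trials at 100 Hz
(~50-sample phase windows, matching a ~0.5 s stepping response), and
cohorts of four trials for pipeline-level tests.

## Design choices that were genuinely open

* **Aggregation order.** MSDs are computed within trial; when subjects
  contribute several trials, trials are averaged within subject before
  group statistics. Per-trial synergy indices remain available in the
  per-trial table.
* **Onset vs. crossing referencing.** Phase II deviations are referenced
  to the crossing posture, not the onset posture, so each phase measures
  dispersion around its own initial state.
* **C3D support** is provided through the optional `ezc3d` dependency;
  the tested, self-describing interchange format is the CSV + YAML sidecar
  dialect, chosen because it is diff-able and fixture-friendly.
* **No inferential statistics.** The summary CSV (means ± between-subject
  SE) is the hand-off point; repeated-measures designs belong in dedicated
  statistics software.

## Limitations

* CoM positions ignore segment orientation; for turning or twisting
  movements an orientation-aware model would be needed.
* The anthropometric table is an adult-female average; individual-specific
  scaling (or another published table) should be supplied for real cohorts.
* The kinematic foot-contact detector is a documented stand-in for an
  instrumented event and inherits a 1–2 sample uncertainty at 100 Hz.
* Single-step responses only; the phase logic assumes exactly one
  base-of-support exit before contact.
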