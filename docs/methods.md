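# Methods

## Model preparation

Models are read from SBML (Level 3, FBC for bounds and GPR strings) or
COBRA-JSON via COBRApy into a lightweight container holding stoichiometry,
bounds, GPR strings and the biomass reaction (taken from the model
objective unless overridden). Exchange reactions are detected structurally
as reactions with exactly one metabolite.

Every reaction with a negative lower bound is split into a forward
reaction (original stoichiometry, bounds `[0, ub]`, id suffix `__fwd`) and
a backward reaction (negated stoichiometry, bounds `[0, -lb]`, suffix
`__bwd`); both inherit the GPR rule. Irreversible reactions keep their id
unchanged. Backward-only reactions (`ub ≤ 0`) are split the same way,
leaving a forward direction with upper bound 0 — keeping the bookkeeping
uniform is worth the dead variable. The net flux of an original reaction
is `v_fwd − v_bwd`; splitting preserves the flux space (checked by
property tests in both directions).

Carbon-source exchanges are identified by parsing the boundary
metabolite's chemical formula for a carbon atom (a `C` not followed by a
lowercase letter, so `Ca` is not carbon but `CaCO3` is). When formulas are
missing, an explicit override set on the model is used instead. This
detection feeds the constraint that closes uptake of every carbon source
other than the designated one; how that enumeration should be done is not
fixed by the problem statement, so formula parsing with an explicit
fallback was chosen as the least surprising rule.

## GPR evaluation

GPR rules are parsed by a small recursive-descent parser (AND binds
tighter than OR, operators case-insensitive) that reports the position of
a syntax error. Evaluation against a proteomics profile replaces OR by
max (an isoenzyme set is as abundant as its best member) and AND by min
(a complex is limited by its scarcest subunit), applied uniformly at every
nesting level. Unmeasured genes evaluate to abundance 0: an AND with an
unmeasured subunit is inactive, an OR survives through its measured
members. Abundance exactly 0 in the data is treated as unmeasured, since
the active set Ra is defined by strictly nonzero effective abundance. No
abundance threshold is applied — any measured nonzero abundance activates
a rule. Rules whose leaf set is a single distinct gene (including
degenerate forms like `g and g`) count as single-gene for the homomeric
kapp filter.

## The optimization programs

Variables are the irreversible fluxes `v` plus one binary `y_j` per
reaction in Ra (penalized mode: per reaction in Ra ∪ Ri). Constraints:
steady state `N·v = 0`; bounds `0 ≤ v_i ≤ vmax_i` with `vmax = 1000
mmol/gDW/h` for unbounded reactions (the usual COBRA convention); biomass
fixed to the measured growth rate μ (default) or confined to
`[0.95μ, 1.05μ]` as a config switch; the designated carbon exchange's
uptake direction capped at the condition's uptake bound and the uptake
direction of every other carbon exchange closed (applied in step 1 as well
as step 2/FVA, for consistency); the indicator rows
`ε·y_j ≤ v_j ≤ y_j·vmax_j + ε·(1−y_j)` with the reaction's own upper bound
as big-M; and `y_fwd + y_bwd ≤ 1` per split pair carrying binaries.

The activation threshold ε defaults to `1e-4 mmol/gDW/h` — far below the
default vmax, comfortably above both the activity threshold (1e-10) and
solver tolerances — and is configurable; the fixture-level results are
stable for ε between 1e-6 and 1e-3 (asserted by test). Note the
formulation's deliberate semantics: `y_j = 0` does not force `v_j = 0` but
caps it at ε, so deactivated reactions may carry residual flux up to ε.

Step 1 maximizes `Σ y_j` (penalized: `Σ_{Ra} y_j − Σ_{Ri} y_j`); its
optimum z is an integer and solver-independent. Step 2 minimizes `Σ v_i`
with the signed activation count fixed exactly to z. pFBA drops all
integer structure and minimizes `Σ v_i` under the same physiology. FVA
minimizes and maximizes each target flux with `Σ y = z` held exactly and
`Σ v = q` (or `q'`) as a two-sided inequality with absolute slack 1e-6 —
standard practice to avoid infeasibility from a floating-point optimum.

All programs run on HiGHS (`scipy.optimize.milp` / `linprog`, zero MIP
gap, LP feasibility tolerances 1e-10). After each mixed-integer solve the
binaries are rounded at 0.5 and the LP is re-solved with them fixed
(`y = 1 ⇒ v ∈ [ε, vmax]`, `y = 0 ⇒ v ∈ [0, ε]`). This polish step yields
vertex-exact flux vectors with clean indicator semantics and the exact q
for the chosen activation pattern; it cannot change z or q beyond solver
tolerance because the MILP already optimized over activation patterns.
Alternative optima in v are real (the activation polytope is typically
degenerate) and are quantified by FVA rather than hidden; z, q and q' are
unique and reproducible across runs.

Infeasibility of a condition (μ unreachable under the uptake bound) is
reported as a solution status, not an exception, so multi-condition runs
can proceed.

## Rate estimation

A reaction qualifies for kapp when its GPR is a single gene (homomeric
enzyme), its net flux magnitude strictly exceeds the activity threshold
`1e-10 mmol/gDW/h` (`1e-5` is the alternate threshold for robustness
runs), and its gene has measured positive abundance; reactions carrying
flux without measured abundance are skipped with a log entry. With fluxes
in mmol/gDW/h and abundances in mmol/gDW, `kapp = |v|/E` is in 1/h and is
divided by 3600 to report 1/s; the proteomics loader accepts a units
declaration (mmol/µmol/nmol/pmol per gDW) and converts explicitly, never
silently. Reversible reactions contribute one kapp from the magnitude of
the net flux.

kvivomax is the maximum of kapp over conditions within each replicate,
then the arithmetic mean over replicates; the argmax condition is recorded
per replicate. Reactions with no kapp records are absent from the output
rather than zero. An expressed enzyme is *idle* in a condition when none
of its reactions with active GPR state is active; reports carry the idle
percentage and the abundance-weighted idle fraction.

Cross-method agreement uses Pearson correlation of log10-transformed
values with nonpositive pairs dropped and counted; fewer than three usable
pairs is an error. Interval coverage (for comparison against externally
supplied confidence intervals) counts closed-interval membership over the
shared reaction set. Summary statistics over conditions use the sample
standard deviation (n−1).

## Kinetic validation

Fluxes are reconstructed as `v = kmax·E·P/(1+P)` with
`P = Π_j (s_j/K_j)^{m_j}` — one product shared between numerator and
denominator, also for multi-substrate reactions; no substrate-specific
denominators, product inhibition or reversibility terms. K and s must be
declared in the same concentration units; nothing is converted. The
prediction is monotone in every `s_j`, in E and in kmax, bounded by
`3600·kmax·E`, exactly half the bound at `s = K` with `m = 1`, and zero
when any substrate is absent. Agreement with solver fluxes is measured by
the same log-Pearson statistic.

## Synthetic fixtures and what they show

The fixture generator emulates the *inputs* of a per-condition study —
a carbon-source exchange, a network with GPR rules, a growth rate, an
uptake bound and a proteomics table — at toy scale (≤ ~25 reactions). The
canonical instances T1–T4 cover parallel single-gene isozymes, a
reversible pair, an unmeasured isozyme (Ri membership) and a complex with
a missing subunit; their manifests (expected z and q) are computed by
brute-force enumeration of all activation patterns with per-pattern LP
feasibility checks, an oracle that shares no code with the big-M MILP
path, so the solver tests are non-circular. Randomized instances sample
motif counts, measured-gene subsets (75% coverage), lognormal abundances
(median ~1e-3 mmol/gDW), μ in 0.5–5 1/h and uptake bounds in 5–20
mmol/gDW/h, keeping the number of activation variables at or below 10 so
enumeration stays exact; a construction invariant (an always-open path to
biomass with μ ≤ uptake bound) guarantees feasibility.

These fixtures do not mimic the scale, loop structure, cofactor coupling
or realistic GPR complexity of a genome-scale reconstruction, and the
synthetic proteomics has no measurement noise model. Passing tests
therefore certify the correctness of the formulations, the estimators and
their invariants — not the biological findings one would obtain on a real
model with real proteomics, which require those datasets as inputs.

## Problem sizes and numerical choices

The test suite and the acceptance script use a 50-instance randomized
ensemble for oracle comparison and ~10–12 instances for the contract and
dominance checks — sizes at which exhaustive enumeration is exact and the
whole suite completes in well under a minute. Ties between alternative
optimal flux vectors are left to the solver and characterized by FVA.
Degenerate inputs are handled explicitly: empty Ra gives z = 0; an
activation-impossible direction (upper bound below ε) forces its binary to
0; stale fixed optima surface as infeasible statuses.

## Known limitations

No thermodynamic or loopless constraints — the activation objective can
exploit internal cycles to activate reaction pairs a loopless method would
reject. No enzyme-capacity coupling between abundance and flux magnitude
(by design: only the active/inactive state of a rule is used). Gene
identifiers must already match between model and proteomics; no namespace
mapping is attempted. FVA in the mixed-integer mode solves two MILPs per
target reaction and is meant for targeted queries at fixture scale.
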