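# Methods

## Model and conventions

A network is an m×n stoichiometric matrix S with finite per-reaction
bounds lb ≤ v ≤ ub (arbitrary but mutually consistent flux units). A
*mode* satisfies S·v = 0 within the bounds; reaction i is blocked when
|v_i| < ε in every mode. Reversibility is defined purely by lb_i < 0 —
the LPs consult nothing else — and a contradictory "reversible" file flag
is ignored with a warning. All indices are 0-based internally; every file
interface speaks reaction/metabolite id strings. Reactions with
lb = ub = 0 are blocked analytically at load time and never cost an LP.

Flux threshold ε defaults to 1e-4. Solver: HiGHS through scipy, with
primal/dual feasibility tolerances requested at 1e-9; any status other
than optimal/infeasible/unbounded raises immediately rather than letting
a near-feasible solution corrupt a partition. Fluxes are read back at
0.99·ε to absorb solutions sitting exactly on an ε constraint. Iteration
order is ascending reaction index everywhere the mathematics leaves the
order free, so LP counts and traces are reproducible.

## Consistency checkers

**Split-network single LP.** Each reversible reaction becomes two
irreversible copies (net flux = forward − backward) and one LP asks for a
steady state with every split flux ≥ ε. Kept as a documented negative
control: the two copies of a blocked reversible reaction can carry equal
flux and cancel, so the test can claim consistency wrongly.

**Capped sum-of-fluxes iteration.** Each round maximizes Σ_{i∈J} v_i over
the uncertified set J with each tested flux capped at ε (without the caps
the objective is unbounded on any cycle through J; the cap value mirrors
the published variant of this checker). Certification reads the solution
through its best uniform within-bounds scaling: steady state is
homogeneous, so c·v is again a mode for any admissible c, and a flux that
the caps or stoichiometry pinned below ε (e.g. an inflow with coefficient
2 runs at ε/2 when its consumer is capped at ε) still certifies. A noise
floor of 0.01·ε keeps solver residue from being scaled into a
certificate. Escalation when a round certifies nothing: flip the signs of
the uncertified reversibles and resume; once flips are exhausted, test
one reaction per LP in both orientations and declare it blocked only
after both fail.

**Cardinality surrogate.** The step function counting ε-active fluxes is
replaced by its concave majorant min(v_i, ε)/ε on the nonnegative
orthant; epigraph variables 0 ≤ z_i ≤ ε with z_i ≤ v_i turn the
maximization into one LP. The first LP tests all irreversible reactions
jointly; with generous bounds it certifies every unblocked one at once
(adding a witness mode to the solution would otherwise increase the
objective). Reversibles are handled by the same flip-and-resume loop as
above, and uncertified irreversibles are *kept* for the singleton pass
rather than declared blocked after the first LP, so completeness does not
depend on the typical-case argument. Certification here uses the plain
0.99·ε read-back; the surrogate already pushes every certifiable flux to
ε.

**FVA.** Per reaction, maximize (and for reversibles minimize) v_i;
blocked iff both extremes are below 0.99·ε in magnitude. At most 2n LPs;
this is the ground-truth oracle the other checkers are tested against,
alongside an independent implementation-and-solver route (cobrapy over
GLPK) in the test suite.

## Greedy extraction

The active set A starts from one mode dense in the irreversible core
(surrogate LP over J = C ∩ I) and sparse outside the core (L1 LP), and
grows by further sparse modes over the uncovered core J = C \ A, with the
penalty set P = non-core \ A shrinking as reactions enter A. The sparse
step minimizes Σ_{i∈P} |v_i| (epigraph variables t_i ≥ ±v_i) subject to
v_i ≥ scale·ε on the covered core K and bounds scaled by the same factor
(default 1e5).

Support read-back after the L1 step applies the 0.99·ε threshold to the
*scaled* fluxes. This is the entire point of the scaling: a supporting
flux structurally pinned at a fraction of the core flux sits at
scale·ε/coefficient — far above ε — whereas on the unscaled problem it
sits below ε and would be dropped, leaving a disconnected, inconsistent
reconstruction. The package exposes `scale` so the failure is
demonstrable: `scale=1` reproduces the dropped-inflow false negative on
the toy network, `scale=1e5` keeps the support complete.

No-progress escalation mirrors the checker: flip the reversible members
of J; then singleton mode (lowest uncovered index first, for
determinism); a singleton that fails in both orientations proves the
precondition (a consistent input network) was violated and raises with
the reaction named. On progress only the `flipped` flag is reset —
singleton mode stays sticky, which preserves the termination argument (J
never grows, and each singleton round either covers or indicts its head
element). Input-consistency checking is available behind `check_input`
but off by default: it costs a full consistency run, and the standard
pipeline (global model → consistent part → extraction) already
guarantees it. Sign flips are an internal device; results are index sets
in the original orientation. An empty core returns an empty
reconstruction without solving anything.

## Exact baseline

Any union of supports of modes induces a consistent subnetwork (truncated
modes remain modes of the induced model), so the minimal consistent
superset of C can be sought over sets of *elementary* modes, whose
supports cover the whole consistent part.

*Enumeration* tests each candidate support T in increasing size: T
carries an elementary mode iff ker(S[:,T]) is one-dimensional, its
generator has full support over T, and one orientation satisfies every
irreversibility constraint in T (a direction shut off entirely by the
bounds is discarded; with the symmetric default bounds this does not
occur). Supersets of accepted supports are pruned, enforcing minimality
directly. Exhaustive and deliberately naive — O(2^n) subsets, refused
above n = 20 — because this module is ground truth, not a tool.

*Set-cover MILP.* With incidence matrix M (n×r) of mode supports, binary
y selects reactions and continuous z ∈ [0,1]^r selects modes by
positivity: minimize Σ y_i subject to y ≥ (1/r)·M z (anything covered is
selected; the 1/r factor keeps the right-hand side ≤ 1 so binary y can
dominate it) and M z ≥ c (every core reaction covered). Continuous z
suffices since only positivity matters. Solved by HiGHS branch-and-bound
with a required relative gap of 0; a core reaction appearing in no mode
raises (it is blocked). A second, MILP-free oracle —
`minimal_consistent_superset_bruteforce`, direct subset enumeration with
the FVA check, capped at n = 12 — cross-validates the MILP in the tests.

## Synthetic data

The toy four-metabolite network (∅→2A, A↔B, A→C, C→D, A→D, D→∅) fixes
bounds at [0, 10] / [−10, 10]; every behaviour it is used to demonstrate
depends only on boundedness and the coefficient 2, not the bound values.
Under the ε-capped sum objective the A→C→D routing collects 3.5·ε versus
2.5·ε for the direct route, which is what delays certification of A→D to
a second LP.

The random generator draws sparse internal conversions (≥ 2 metabolite
slots per reaction, mean `density` = 3, integer coefficients in {1, 2}, a
`reversible_fraction` = 0.3 of reversible reactions) plus reversible
boundary exchanges on a random metabolite subset (about a quarter of the
reaction budget), bounds ±100. Consistency is enforced post hoc by
restriction to the FVA-consistent part — simple, and correct by the
union-of-modes argument (a witness mode of a consistent reaction survives
the restriction). The raw, unrestricted draw is also exposed, since
checker-equality tests need networks *with* blocked reactions. What the
generator does not emulate: gene–protein–reaction structure,
compartments, realistic degree distributions, or genome-scale size — so
passing tests demonstrate algorithmic correctness and the documented
failure modes, not biological fidelity or large-model performance.

The planted-module network is an irreversible linear chain (interior
steps = core) plus independent import/export decoy pairs; each interior
step is the unique route between its neighbours, so a reconstruction from
a sub-core must recover the left-out steps. The sub-sampling validation
reconstructs from a random 80% sub-core and computes, per repetition, the
exact upper-tail hypergeometric probability of recovering at least the
observed number of left-out core reactions (population = non-sub-core
reactions, draws = non-sub-core reactions in the reconstruction),
summed in exact integer arithmetic. Default 50 repetitions keep the
protocol inexpensive at desk scale; the repetition count is a parameter.

## Known limitations

- Completeness of the one-LP certification of irreversibles assumes
  bounds well above ε-scale fluxes, as in all published practice; the
  singleton fallback removes the assumption from the final partition but
  not from the LP-count advantage.
- Elementary-mode enumeration and the MILP are toy-scale by design; no
  double-description or nullspace-compression machinery is provided.
- The L1 support read-back on the scaled problem inherits the solver's
  absolute feasibility tolerance; with the default scale of 1e5 and
  ε = 1e-4 the margin between genuine support fluxes (≥ 1) and the
  read-back threshold (≈ 1e-4) is four orders of magnitude.
- SBML support is read-only (L3 + FBC bounds); gene rules, compartments
  and objectives are ignored.
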