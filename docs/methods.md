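# Methods

## Model

Each of the 50 panel biomarkers (35 plasma cytokines, 15 PBMC cell
phenotypes) is treated as a population `x_i(t)` whose rate of change is the
algebraic sum of candidate relationship terms — a generalized
Lotka–Volterra system written as a Kolmogorov–Gabor polynomial truncated at
the bi-linear term:

    dx_T/dt = Σ_j a_j · c_j(x),   c_j = x_S(j)  or  x_M(j) · x_S(j).

Truncation at second order keeps the inverse problem well scaled; no
constant (zeroth-order) term is carried, since every admissible
relationship names a source biomarker.  Concentrations enter on their
native scales (cytokines pg/mL-like, cells relative): the formulation is
scale-covariant column-by-column and the solver is rank-revealing, so no
standardization is applied; an optional per-biomarker scaling hook exists
but is off by default.

## Knowledge Model

Relationship types are data, not code: a YAML table of
(modulator domain, source domain, target domain, same-cell constraint)
signatures.  The shipped seven-type default encodes the admissibility
rules: every relationship carries a cell as source or target; bi-linear
relationships with two cellular components must use the same cell
(autocrine — paracrine is excluded), *except* that a cell may modulate a
different cell when the target is a cytokine; `n.a.` is admitted as an
additional, non-biomarker modulator in designated types.  Expansion over
the default panel gives per-type counts 18,375 / 7,875 / 1,050 / 540 /
525 / 225 / 15 — 28,605 relationships in total.

Relationship identity is per (type, modulator, source, target).  This is a
deliberate design choice: the 15 unmodulated autocrine loops
(`n.a.`, c, c) arise both as the `n.a.` variant of the cytokine-modulated
autocrine type and as the self-pairs of the unmodulated cell→cell type, and
an exhaustive search over every admissible seven-type table shows the
distinct-triple universe under these rules holds exactly 28,590 triples —
the totals 28,605 (relationships, and nonzero K entries per instant) are
only consistent with type-scoped identity.  The duplicated entries produce
two identical K columns each; at counting time their activity is merged by
logical OR, so no Quad is ever counted twice at one instant.
`validate_model` reports per-type counts, the distinct-triple count, and
the collision list.

## Sampling grid

Draws happen at days {0..4, 7..11}.  Linear interpolation between
consecutive draws makes `dx/dt` piecewise constant; six equally spaced
*strictly interior* points per interval (fractions j/7) avoid the slope
discontinuities at draw instants.  The exclude policy drops intervals
longer than `max_gap_days` = 2.5 days: it removes the Friday→Monday gap
(3 days) while keeping 2-day intervals that bridge a missed mid-week draw.
8 retained intervals × 6 points = 48 analysis instants; normalization
always uses the participant's actual grid size, not a hard-coded 48.

## SVD engine

The factorization is Golub–Kahan–Reinsch, authored in-package: Householder
bidiagonalization in tall orientation (wide K is factored via its
transpose), then implicit-shift QR with Wilkinson shifts on the bidiagonal,
Givens rotations accumulated into small square factors, economy-size
assembly (50 left singular vectors for a 50-row K).  Reflector applications
take a support-aware path when the reflector vector is sparse — for the
pipeline's single-nonzero-per-column K this cuts the per-instant cost
roughly eightfold without changing results on dense inputs.

Stopping policies:

* `full_convergence` — standard SVD; superdiagonal entries are neglected at
  `off_diagonal_tol` (default 1e-12, relative to the adjacent diagonals).
* `max_sweeps` — a fixed sweep budget; remaining sub-tolerance
  off-diagonals are zeroed and the diagonal is taken as the singular
  values.  Orthogonal transformations are exact to roundoff, so the
  accumulated factors with the *current* middle matrix still reproduce K;
  the diagonal-only `recon_error` records what the truncation gave up.
* `ill_conditioned_guard` (default) — a block whose adjacent diagonal
  entries differ by less than `near_equal_ratio` (default 1e-3 relative) is
  frozen: iterating on nearly equal singular values is the ill-conditioned
  step this policy avoids.  Frozen blocks leave the left singular vectors
  partially mixed, the mechanism by which one mode can carry several
  biomarkers' activity.

Sign convention: each U column is flipped so its largest-magnitude
component is positive (ties → lowest row index); with the deterministic
enumeration order this makes whole-pipeline reruns byte-identical.

Because K's columns have a single nonzero each, its rows are mutually
orthogonal, and the exact factorization has σ = sorted row norms with U a
signed permutation — the closed form the engine reproduces to 1e-10 and the
tests assert.  It also means fully converged runs on clean data produce
*Dominator-only* activity; Supporter activity (an LSV tagged with a
different biomarker than the target) appears under early-stopped policies
or row-coupled inputs, and the tests exercise it on constructed fixtures.

The minimum-norm solution is `a = V Σ⁺ Uᵀ dx/dt` with singular values below
`rank_tol` (default 1e-12 relative) treated as zero; with positive
concentrations K generically has full row rank, so rank deficiency flags
degenerate input.  The quality check back-computes K (bound 1e-8 relative
Frobenius) and `dx/dt` (bound 1e-6 relative, asserted only for fully
converged runs).

## Activity rules and counting

The thresholds are rules with free constants; the defaults are:
`lsv_threshold` 0.10 (absolute |U| component — a clear dominator plus a
modest number of supporters), `rsv_threshold` 0.05 (relative to the RSV
row maximum), and `zero_tol` 1e-12 × max|a| for the zero-unknown removal.
A 5-D record is active when all three conjuncts hold; each conjunct can be
disabled (threshold 0) for sensitivity analysis, and every output manifest
records the thresholds used.  The activity "value" carried per record is
the RSV component magnitude.  Name-tagging is recomputed at every instant
by greedy unique assignment on |U| (ties → panel order, then LSV index;
near-ties within 5% logged as ambiguous); Quad keys use the tag *name*, so
counts accumulate correctly across instants as column order changes.

Occurrence Counts are integers (distinct active instants per Quad);
normalized counts are `100 · raw / grid_size`.  Presentation rounding to
2 dp happens only at export; hierarchy sums that must match printed 2-dp
totals go through the integer raw counts and normalize once (a published
triplet prints 183.33 where naive 2-dp summation gives 183.32).

Cohort averages run over the union of quad keys with absent participants
contributing zero, divided by the participant count (an active-only mean is
available behind a flag).  Differences are elementwise and antisymmetric;
flow diagrams keep the 10 highest-value cellular sources and 15 highest
modulators plus `n.a.`, and map counts to node/edge sizes linearly with a
configurable scale constant.

## Synthetic cohorts

The sinusoid generator emulates the study conditions: 14 cancer + 27
healthy participants, 10 weekday draws, per-biomarker positive baselines
(cytokines log-uniform 1–500, cells uniform 0.5–40, mimicking the
orders-of-magnitude scale separation of mixed units), 20% oscillation
amplitude with per-participant periods of 2–7 days and random phases, and
5% Gaussian measurement noise (clipped at zero with a warning).  It
reproduces the *structure* the pipeline assumes — positive oscillatory
concentrations on the draw schedule — not any real interaction network, so
green tests demonstrate pipeline correctness and determinism, not clinical
findings.  The gLV mode integrates known sparse coefficients by explicit
Euler (default step 0.01 d, divergence cap 1e9) and returns the ground
truth; recovery of sparse truth by the minimum-norm solution is expressly
*not* promised (50 equations, 28,605 unknowns), but `K a*` at simulator
states must and does match the simulated rates, and a linear
self-relationship reproduces `exp(a t)` within the Euler error bound.

## Problem sizes and determinism

All randomness flows through seeded PCG64 generators, so every table and
diagram is reproducible byte-for-byte.  The default cohort analysis
(41 participants × 48 instants = 1,968 factorizations of 50 × 28,605)
completes in a few minutes on one CPU; unit and property tests run on small
matrices and a 3–6 biomarker toy panel, with the full-size pipeline
exercised once end to end.

## Known limitations

* The exact seven type signatures of the original study's template are
  reconstructed from the stated constraints and the printed total; other
  tables satisfying both exist in principle; the enumeration tests pin the
  per-type counts so any rule-table change is a conscious one.
* The original study's SVD variant is not published in implementable
  detail; the three stopping modes are this package's construction, and no
  attempt is made to replicate that solver's exact singular-vector mixing.
* Linear cell→cell terms between distinct cells are admitted (the paracrine
  exclusion is applied to bi-linear terms); narrowing them is a one-line
  rule-table edit.
* Euler integration in gLV mode is first-order; use small steps for stiff
  coefficient sets.
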