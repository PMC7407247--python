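# Methods

## The model

A cell's transcriptional identity is treated as a binary vector of
regulatory-element (RE) activity states. A **VEnCode** for a target cell
type is a set S of k REs such that (i) every RE in S is active in the
target and (ii) every other cell type has at least one member of S
inactive. In conjunctive normal form over the binarized database, with
`a[i, j]` the activity of RE i in cell type j and column t the target:

```
AND_{i in S} a[i, t]   AND   AND_{j != t} ( OR_{i in S} NOT a[i, j] )
```

The search space is C(r, k) candidate sets (`n_combinations`), and the CNF
truth table over c cell types has 2^(c·k) rows (`truth_table_rows`) — for
an atlas of ~2×10^5 promoters and 154 cell types at k = 4 that is ~7×10^19
combinations, which is why the package searches by sampling and greedy
heuristics rather than saturation.

### Assumptions

* Activity is binarizable: a TPM threshold separates "usable" from
  "unusable" REs. All conclusions inherit the thresholds' arbitrariness;
  they are configuration, not constants.
* Donors of the same cell type are replicates of one underlying activity
  state; donor disagreement is noise (technical or biological), which is
  exactly what the E and z scores quantify.
* Non-target cell types can be summarized by their donor mean, whereas the
  target requires per-donor consistency (see below).

## Binarization (deliberately asymmetric)

* **Target**: an RE must exceed the non-zero pre-filter in *every* donor,
  and its **minimum** over donors must exceed the activity threshold
  θ_act. Default θ_act: 0.5 TPM for promoters, 0.1 for enhancers (the
  settings with the highest selectivity at a strict inactivity threshold).
* **Non-target**: a cell type is active when its donor-**mean** TPM exceeds
  the inactivity threshold θ_inact (default 0).

Min-for-target vs mean-for-non-target is the conservative direction for an
AND gate: a falsely-usable target RE costs specificity, a falsely-active
non-target call only costs candidates. All comparisons are strict `>`
("above"), configurable to `>=`.

### Sparsity pre-filter

Before sampling, REs active in more than X% of the *non-target* cell types
are removed (the target column is active by construction and is excluded
from the denominator). X starts at 90 and moves in steps of 5 whenever
fewer than k REs survive. The published description of the retry step says
the cutoff is *decremented*, but lowering X removes strictly more REs and
can never recover from having too few; the retry direction is therefore
exposed as `relax_direction` with both readings implemented, and the
default is `"up"` (raise X toward 100, keeping more REs), the only reading
under which the retry loop can achieve its stated purpose. At X = 100 the
filter keeps everything; if fewer than k REs exist at all, the filter is
unsatisfiable and says so.

## Search strategies

* **Sampling** — uniform random k-subsets of the filtered landscape,
  rejection-tested against the VEnCode condition, deduplicated as
  unordered sets, stopping at an iteration cap or a hit quota. All
  randomness flows from one seeded generator; the seed is recorded in the
  report.
* **Heuristic** — a greedy decision tree ordered by *sparseness* (the
  number of non-target cell types in which an RE is active; ties broken by
  RE id so the search is fully deterministic). The sparsest RE becomes the
  first node; cell types it excludes are culled; remaining REs are
  re-ranked by co-activity over the surviving "problematic" cell types.
  Candidates whose restricted count is zero complete a code immediately;
  otherwise the `neighbors = 3` nearest candidates are branched into, to
  depth ≤ k. A partial code that is already exclusive with m < k REs is
  padded with the next k−m sparsest REs (supersets of valid codes remain
  valid, so padding only adds safety). First-level nodes are tried in
  global sparseness order until a quota of distinct codes (default 20,
  matching the 5–20-codes-per-cell-type regime the scores are built on) is
  reached; `nodes_per_level` optionally caps the number of first-level
  starts. An empty result is a legitimate outcome, not an error.
* **Heuristic2** — take the k₁ sparsest target-active enhancers. If already
  exclusive, return the minimal enhancer-only code (promoter padding only
  on request, `pad_to_full`). Otherwise restrict the promoter landscape to
  the cell types where all k₁ enhancers are co-active and run the heuristic
  there for k₂ promoters; each hit combines into a mixed code with
  per-RE classes preserved.

Every emitted code is re-checked against the validity predicate before it
leaves a search function.

## Quality scores

### E (intraindividual, false-negative robustness)

One simulation: flip a uniformly chosen currently-inactive entry of the
code's k × (c−1) non-target submatrix to active; repeat until some
non-target cell type has all k REs active (the code "fires" off-target);
record the number of flips e_i, including the breaking flip. E_raw is the
mean of e_i over `n_sims` (default 2000; the per-score standard error is
reported alongside). The flip universe is restricted to the code's own
submatrix because flips elsewhere cannot change the code's validity; the
restriction rescales E_raw and the best-case reference identically, so the
normalized score is unaffected while simulations shrink by orders of
magnitude.

E_best(c, k) runs the same simulation on an all-inactive k × (c−1)
submatrix (memoized per (c, k, n_sims, seed)), and E = 100·E_raw/E_best.
Best-case codes score 100 ± MC error; values above 100 from MC noise are
reported as-is with a warning, never clamped, because clamping would bias
rank comparisons. Flipping uniformly among remaining inactive entries is
equivalent to a uniform random permutation of the initially-inactive
entries, which is what the test suite's exact oracle (inclusion-exclusion
over saturated column sets, in exact rational arithmetic) integrates
against; the Monte-Carlo estimate is required to sit within 3 SE of the
exact expectation on every instance small enough to enumerate
(k·(c−1) ≤ 12).

A best-case code under independent per-RE false activation probability p
fires in a given non-target cell with probability p^k — each additional
intersection multiplies the leakage probability by p. The simulation
reproduces this closed form for p ∈ {0.1, 0.3}, k ≤ 4.

### z (interindividual, donor hold-out)

Rebuild the landscape using only a training subset of the target's donors,
generate codes, and require every held-out donor to express all k REs
above θ_act. z is the percentage of codes valid on all held-out donors;
with several training subsets of one size, the mean and the per-subset
values are both reported. A training subset that yields no codes raises
`NoVEnCodeError` rather than contributing a silent 0 or 100 — the score is
undefined there, and the caller decides. z is likewise not applicable to
the single-donor pooled single-cell column.

## Cross-validation

Overlap is the purely positional >0-nucleotide rule on half-open, 0-based
intervals; strand is ignored. Chromosome names are normalized ("chr1" ≡
"1", plus a configurable alias map); **genome-build mismatches are the
caller's responsibility** — nothing here lifts coordinates over. Lookups
go through a per-chromosome interval tree whose behaviour is contractually
identical to a linear scan (and is tested against a per-base set
intersection oracle). Validation counts, per code, the REs with at least
one overlapping external interval; restricting a landscape to validated
REs before searching yields pre-validated codes (fraction = 1 by
construction, idempotent). The specificity index divides the target's hit
percentage by the mean non-target hit percentage; a zero non-target mean
with a hit target returns `inf` as an explicit sentinel.

## Synthetic landscapes and what they do (not) show

The generator emulates the curated-atlas structure: c cell types × 2–6
donors × r REs, Bernoulli(background_sparsity) activity at the
(RE, cell type) level, and TPM values for active entries drawn from
θ_act + LogNormal(μ=0, σ=1) per donor — so pre-noise, an active call
survives binarization in every donor. Noise is applied per (RE, sample)
entry: false negatives zero active entries, false positives raise inactive
entries to a sentinel TPM of 10 (far above all default thresholds, since
the binary-to-TPM bridge carries no magnitude information); noise can be
restricted to chosen columns to model donor-level call noise.

Planted codes extend the alibi construction with **private columns**: each
planted RE p_i gets a non-target cell type B_i in which p_i is the only
target-active RE that is inactive, and every other non-target cell type
gets at least one planted RE forced inactive. Any valid code must then
contain every p_i, making the planted set the unique minimal valid code —
which is what makes "the search recovers the plant" a well-defined,
brute-force-checkable statement. Only k columns per plant carry special
structure; the rest of the matrix is plain background.

What passing on synthetic data does **not** show: real atlases have
correlated activity across related cell types (e.g. fibroblast subtypes),
heavy-tailed TPM distributions, donor counts confounded with cell type,
and batch structure. Results on synthetic landscapes validate the
*algorithms*, not the biological discoverability rates of any particular
atlas; the published landscape-percentage figures require the full atlas
and are out of scope here.

## Problem sizes used in tests and the acceptance script

Chosen to make enumeration oracles exact and runs fast while preserving
the regimes of interest: oracle-equivalence landscapes r ≤ 15, c ≤ 8,
k ≤ 4 (50 seeds); planted-recovery landscapes c = 12, r = 15, k = 3 (100
seeds; sampling budget 10,000 draws, the same order as the published
sampling runs); E calibration on all instances with k·(c−1) ≤ 12 at
n_sims = 2000; leakage with 20,000 simulated non-target cells; donor
hold-out on c = 10, r = 60, 3 donors, background 0.3, with a 2% per-donor
false-positive rate — a few percent of spurious single-donor calls, chosen
so that double-donor artifacts are rare, consistent with hold-out
robustness saturating once two donors are used.

## Known limitations

* E ranks codes on binarized data only; a TPM-magnitude-aware score (the
  weakest-link RE) is a natural extension and deliberately not implemented.
* False-positive (active-to-inactive) robustness simulations are not
  implemented; the z score covers that axis empirically.
* The heuristic does not saturate the code space and can miss codes a
  brute-force search would find; quota and branching width trade coverage
  for time.
* Exhaustive search at full-atlas scale is out of scope (O((c·r)^k)).
* Alternative Boolean gates (OR/NOT/NOR) are not explored.
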