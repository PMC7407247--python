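# vencodes

Tools for **intersectional genetics**: finding minimal combinations of
co-active regulatory elements (REs — promoters and enhancers) whose joint
activity distinguishes one target cell type from every other cell type in a
bulk RE-activity atlas. Such a combination acts as a k-input "AND" gate —
all k REs active in the target, at least one inactive in every non-target
cell type — and is called a **VEnCode** (versatile entry code). VEnCodes are
the starting point for cell-type-specific gene drivers: the sparser and more
exclusive the intersection, the safer the targeting.

The package is aimed at computational biologists working with CAGE-seq-style
activity matrices (e.g. the FANTOM5 promoter/enhancer atlases): rows are REs,
columns are `"cell type, donor"` samples, values are TPM.

## What it computes

For a target cell type with donors *d = 1..n* and a database of *c* cell
types and *r* REs:

1. **Binarization** — an RE enters the target landscape only if
   min*_d* TPM > θ_act (default 0.5 TPM promoters / 0.1 enhancers); a
   non-target cell type counts as active if its donor-mean TPM > θ_inact
   (default 0). A sparsity pre-filter removes REs active in more than X% of
   non-target cell types (X starts at 90, step 5).
2. **Search** — a set **S** of k REs is a VEnCode iff
   ∀ non-target cell type j: ∃ RE ∈ S inactive in j.
   Three strategies: uniform random sampling of k-subsets; a greedy
   sparseness-ordered decision tree (branching over the 3 nearest
   neighbours in sparseness, depth ≤ k); and a mixed strategy taking the k₁
   sparsest enhancers and resolving their residual "problematic" cell types
   with k₂ promoters.
3. **Quality ranking** — *E*: Monte-Carlo false-negative robustness. Flip
   inactive entries of the code's k × (c−1) non-target submatrix to active,
   one at a time, uniformly at random, until exclusivity breaks; *E*_raw is
   the mean number of flips survived, normalized as
   *E* = 100·*E*_raw/*E*_best(c, k) against a best-case code (all k REs
   inactive everywhere). *z*: donor hold-out robustness — the percentage of
   codes built from a donor subset that stay valid on every held-out donor.
4. **Cross-validation** — code REs are checked for >0-nt overlap (half-open
   coordinates) against external interval call sets (DNase/ATAC/STARR...),
   and code specificity is scored across an independent per-cell-type call
   collection.
5. **Single-cell pooling** — per-cell "ON" RE sets are pooled (union, with
   an optional minimum-support gate) and injected into the bulk table as a
   new single-donor cell type.
6. **Synthetic landscapes** — a generator with planted codes that are, by
   construction, the unique minimal valid code for their target, so every
   search and scoring path can be tested against known ground truth.

## Worked example

```bash
vencode simulate --c 12 --r 15 --plant "CT01:RE0001,RE0002,RE0003" \
                 --seed 11 --out sim/
vencode heuristic --input sim/landscape.tsv --target CT01 --k 3 --out heur/
vencode rank --input sim/landscape.tsv --target CT01 \
             --codes heur/vencodes.json --top 5 --seed 1 --out ranked/
```

`heur/vencodes.json` contains the recovered code — exactly the planted
triple:

```json
{"target": "CT01", "method": "heuristic", "n_iterations": 104,
 "vencodes": [{"target": "CT01", "method": "heuristic", "k": 3,
               "res": ["RE0001", "RE0002", "RE0003"], ...}]}
```

and `ranked/ranked.json` holds the ranked codes with their scores:

```json
[{"target": "CT01", "k": 3, "res": ["RE0001", "RE0002", "RE0003"],
  "e_raw": 4.298, "e_best": 13.2995, "e": 32.32, "se": 0.401}]
```

`e` = 32.3 means this code survives about a third as many random
false-negative flips as a perfectly exclusive code of the same size would —
its REs share activity with several non-target cell types, so a few
erroneous "inactive" calls in the atlas could make it fire elsewhere.

The same pipeline is available as library calls (`binarize_for_target`,
`sample_vencodes`, `heuristic_vencodes`, `heuristic2_vencodes`,
`score_vencode`, `z_score`, ...); the CLI subcommands `curate`, `binarize`,
`sample`, `heuristic`, `heuristic2`, `rank`, `zscore`, `crossval`,
`pool-sc`, `simulate` are thin wrappers over them. Exit codes: 0 success,
1 input error, 2 no VEnCode exists under the given settings (a scientific
result, not a failure).

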