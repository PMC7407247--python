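"""Synthetic RE activity landscapes with known ground truth.

The generator emulates the structure of a curated bulk CAGE-seq atlas: c
cell-type categories with 2-6 donors each, r REs, sparse Bernoulli activity,
and TPM values for active entries drawn from a log-normal shifted above the
activity threshold (so an active call survives binarization in every donor
pre-noise).  Planted codes give landscapes a known answer key.

Plant construction.  For a planted code P = {p_1 .. p_k} for target t, each
p_i is assigned a private non-target cell type B_i in which p_i is the ONLY
RE active in t that is inactive; every other non-target cell type gets at
least one member of P forced inactive (an "alibi").  Consequences, pre-noise:

* P is a valid code (every non-target cell type has an inactive member);
* any valid code must contain every p_i (nothing else excludes B_i), so P
  is the unique minimal valid code and the unique valid code of size k.

Only k columns per plant carry this special structure; everything else is
plain Bernoulli background, keeping the landscape statistically unremarkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InputError
from .expression import ExpressionTable, GenomicInterval, write_expression_table

#: TPM used when a false-positive flip activates an entry.
CORRUPT_SENTINEL_TPM = 10.0


@dataclass(frozen=True)
class PlantedCode:
    target: str
    res: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.res)


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults mirror a curated primary-cell atlas
    at desk scale (sparse activity, 2-6 donors per cell type, TPM-scale
    log-normal values)."""

    c: int = 12
    r: int = 100
    donors_per_type: int | tuple[int, int] = (2, 6)
    planted: tuple[PlantedCode, ...] = ()
    background_sparsity: float = 0.15
    tpm_mu: float = 0.0
    tpm_sigma: float = 1.0
    activity_threshold: float = 0.5
    false_negative_rate: float = 0.0
    false_positive_rate: float = 0.0
    seed: int | None = None
    re_class: str = "promoter"
    with_coordinates: bool = True

    def __post_init__(self) -> None:
        for name in ("background_sparsity", "false_negative_rate",
                     "false_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.c < 2 or self.r < 1:
            raise InputError("need c >= 2 and r >= 1")
        self.planted = tuple(self.planted)
        targets = [p.target for p in self.planted]
        if len(set(targets)) != len(targets):
            raise InputError(f"duplicate planted targets: {targets}")
        universe = set(self.re_ids())
        cts = set(self.cell_types())
        n_private = 0
        for p in self.planted:
            if p.target not in cts:
                raise InputError(f"planted target {p.target!r} not among cell types")
            if len(set(p.res)) != p.k:
                raise InputError(f"duplicate REs in planted code {p}")
            if not set(p.res) <= universe:
                raise InputError(
                    f"planted REs {sorted(set(p.res) - universe)} outside the "
                    f"generated id universe RE0001..RE{self.r:04d}"
                )
            if p.k > self.r:
                raise InputError("planted k exceeds r")
            n_private += p.k
        if self.planted and n_private > self.c - len(self.planted):
            raise InputError(
                "not enough non-target cell types for the private columns of "
                f"{len(self.planted)} planted code(s): need {n_private}, have "
                f"{self.c - len(self.planted)}"
            )

    def cell_types(self) -> list[str]:
        return [f"CT{i + 1:02d}" for i in range(self.c)]

    def re_ids(self) -> list[str]:
        return [f"RE{i + 1:04d}" for i in range(self.r)]


def _donor_counts(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    d = spec.donors_per_type
    if isinstance(d, int):
        if d < 1:
            raise InputError("donors_per_type must be >= 1")
        return np.full(spec.c, d, dtype=int)
    lo, hi = d
    if not 1 <= lo <= hi:
        raise InputError(f"bad donors_per_type range {d}")
    return rng.integers(lo, hi + 1, size=spec.c)


def _plant(act: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator,
           ct_index: dict, re_index: dict) -> None:
    """Impose planted-code structure on the binary cell-type matrix in place."""
    c = spec.c
    # private columns: disjoint across plants, never a planted target
    target_cols = {ct_index[p.target] for p in spec.planted}
    free = [j for j in range(c) if j not in target_cols]
    rng.shuffle(free)
    need = sum(p.k for p in spec.planted)
    if need > len(free):
        raise InputError(
            f"infeasible plant: {need} private columns needed, only "
            f"{len(free)} non-target cell types available"
        )
    private: dict[tuple[str, str], int] = {}
    pos = 0
    for p in spec.planted:
        for rid in p.res:
            private[(p.target, rid)] = free[pos]
            pos += 1
    private_cols = set(private.values())

    for p in spec.planted:
        t = ct_index[p.target]
        rows = [re_index[rid] for rid in p.res]
        act[rows, t] = True
        for rid in p.res:
            b = private[(p.target, rid)]
            act[re_index[rid], b] = False
    # uniqueness rule: every RE active in the plant's target is active in
    # each of the plant's private columns, except the column's own RE
    for p in spec.planted:
        t = ct_index[p.target]
        for rid in p.res:
            b = private[(p.target, rid)]
            mask = act[:, t].copy()
            mask[re_index[rid]] = False
            act[mask, b] = True
            act[re_index[rid], b] = False
    # alibis: every non-target column needs >= 1 planted RE inactive
    owner_of_col = {col: tgt for (tgt, _rid), col in private.items()}
    for p in spec.planted:
        t = ct_index[p.target]
        own_private = {private[(p.target, rid)] for rid in p.res}
        rows = np.array([re_index[rid] for rid in p.res])
        for j in range(c):
            if j == t or j in own_private:
                continue
            if act[rows, j].all():
                pick = int(rng.choice(rows))
                act[pick, j] = False
                if j in private_cols:
                    # j is another plant's private column: taking the alibi
                    # there requires leaving that plant's target landscape,
                    # or its uniqueness guarantee would break
                    other_t = ct_index[owner_of_col[j]]
                    act[pick, other_t] = False
    # verify the guarantees actually hold
    for p in spec.planted:
        t = ct_index[p.target]
        rows = np.array([re_index[rid] for rid in p.res])
        if not act[rows, t].all():
            raise InputError(f"infeasible plant for {p.target!r}: lost target activity")
        for j in range(c):
            if j != t and act[rows, j].all():
                raise InputError(
                    f"infeasible plant for {p.target!r}: no alibi in column {j}"
                )
        for rid in p.res:
            b = private[(p.target, rid)]
            others = act[:, t].copy()
            others[re_index[rid]] = False
            if not act[others, b].all():
                raise InputError(
                    f"infeasible plant for {p.target!r}: private column violated"
                )


def generate_landscape(spec: SyntheticSpec) -> ExpressionTable:
    """Generate a TPM table realizing the spec; deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    cts = spec.cell_types()
    res = spec.re_ids()
    ct_index = {ct: j for j, ct in enumerate(cts)}
    re_index = {rid: i for i, rid in enumerate(res)}
    act = rng.random((spec.r, spec.c)) < spec.background_sparsity
    if spec.planted:
        _plant(act, spec, rng, ct_index, re_index)
    donors = _donor_counts(spec, rng)
    cols = pd.MultiIndex.from_tuples(
        [(ct, f"donor{d + 1}") for j, ct in enumerate(cts) for d in range(donors[j])],
        names=["cell_type", "donor"],
    )
    n_cols = len(cols)
    col_ct = np.repeat(np.arange(spec.c), donors)
    active_per_sample = act[:, col_ct]
    tpm = np.zeros((spec.r, n_cols))
    n_active = int(active_per_sample.sum())
    draws = spec.activity_threshold + rng.lognormal(
        spec.tpm_mu, spec.tpm_sigma, size=n_active
    )
    tpm[active_per_sample] = draws
    intervals = {}
    if spec.with_coordinates:
        for i, rid in enumerate(res):
            intervals[rid] = GenomicInterval("chr1", 1000 * i, 1000 * i + 500)
    table = ExpressionTable(
        pd.DataFrame(tpm, index=res, columns=cols), spec.re_class, intervals
    )
    if spec.false_negative_rate > 0 or spec.false_positive_rate > 0:
        table = corrupt(
            table, spec.false_negative_rate, spec.false_positive_rate,
            seed=int(rng.integers(2**31)),
        )
    return table


def corrupt(
    table: ExpressionTable,
    fn_rate: float,
    fp_rate: float,
    seed: int | None = None,
    sentinel: float = CORRUPT_SENTINEL_TPM,
    samples=None,
) -> ExpressionTable:
    """Independently zero active entries (rate ``fn_rate``) and activate
    inactive entries at the sentinel TPM (rate ``fp_rate``).

    ``samples`` optionally restricts the noise to a subset of columns
    (e.g. only the target's donors, to model donor-level call noise).
    """
    for name, v in (("fn_rate", fn_rate), ("fp_rate", fp_rate)):
        if not 0.0 <= v <= 1.0:
            raise InputError(f"{name} must be in [0, 1], got {v}")
    rng = np.random.default_rng(seed)
    arr = table.tpm.to_numpy().copy()
    if samples is None:
        idx = np.arange(arr.shape[1])
    else:
        wanted = set(samples)
        idx = np.array([j for j, c in enumerate(table.tpm.columns) if c in wanted])
        if idx.size == 0:
            raise InputError("samples restriction matches no column")
    block = arr[:, idx]
    active = block > 0
    fn = active & (rng.random(block.shape) < fn_rate)
    fp = ~active & (rng.random(block.shape) < fp_rate)
    block[fn] = 0.0
    block[fp] = sentinel
    arr[:, idx] = block
    tpm = pd.DataFrame(arr, index=table.tpm.index, columns=table.tpm.columns)
    return ExpressionTable(tpm, table.re_class, dict(table.intervals))


def write_landscape(table: ExpressionTable, spec: SyntheticSpec, out_dir) -> None:
    """Emit the TSV matrix plus a ground-truth JSON for test harnesses."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_table(table, out / "landscape.tsv")
    truth = {
        "seed": spec.seed,
        "planted": [{"target": p.target, "res": list(p.res)} for p in spec.planted],
        "spec": {k: v for k, v in asdict(spec).items() if k != "planted"},
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
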