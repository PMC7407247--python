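"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's vectorized code paths:
exclusivity is re-derived from the CNF truth semantics with plain Python
loops, expected flip counts from an inclusion-exclusion closed form over
uniform flip permutations (exact, in Fractions), and interval overlap from
per-base set intersection.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from vencodes import (
    BinaryLandscape, ExpressionTable, ThresholdConfig, binarize_for_target,
)
from vencodes.synthetic import PlantedCode, SyntheticSpec, generate_landscape


# -- oracles -------------------------------------------------------------

def cnf_is_vencode(landscape: BinaryLandscape, res) -> bool:
    """Exclusivity via the CNF truth semantics, plain Python loops."""
    res = list(res)
    for rid in res:
        if not bool(landscape.active.at[rid, landscape.target]):
            return False
    for ct in landscape.nontarget_cell_types:
        if all(bool(landscape.active.at[rid, ct]) for rid in res):
            return False  # no NOT-clause satisfied for this cell type
    return True


def brute_force_vencodes(landscape: BinaryLandscape, k: int) -> set:
    """Every valid k-subset, by exhaustive enumeration over C(r, k)."""
    return {
        frozenset(c)
        for c in itertools.combinations(landscape.re_ids, k)
        if cnf_is_vencode(landscape, c)
    }


def exact_expected_flips(zeros_per_col) -> Fraction:
    """Exact E[flips until some column saturates] for uniform random flips.

    Flipping uniformly chosen inactive entries one at a time is a uniform
    random permutation of the initially inactive entries.  With z_j inactive
    entries in column j and Z in total, inclusion-exclusion over saturated
    column sets gives P(no column saturated after t flips), and
    E[T] = sum_t P(T > t).
    """
    z = [int(x) for x in zeros_per_col]
    assert all(x >= 1 for x in z), "a valid code has >=1 inactive per column"
    total = sum(z)
    m = len(z)
    e = Fraction(0)
    for t in range(total):
        p_gt = Fraction(0)
        for bits in range(2 ** m):
            subset = [z[j] for j in range(m) if bits >> j & 1]
            zs = sum(subset)
            if t < zs:
                term = Fraction(0) if subset else Fraction(1)
            else:
                term = Fraction(comb(total - zs, t - zs), comb(total, t))
            p_gt += (-1) ** len(subset) * term
        e += p_gt
    return e


def brute_force_overlap(a, b) -> bool:
    """Per-base intersection count > 0 (set-based, half-open)."""
    from vencodes.crossval import normalize_chrom

    if normalize_chrom(a.chrom) != normalize_chrom(b.chrom):
        return False
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end))) > 0


# -- construction helpers ------------------------------------------------

def landscape_from_matrix(matrix, target="T", ids=None, cts=None,
                          re_class=None, cfg=None) -> BinaryLandscape:
    """Binary landscape straight from a 0/1 matrix; column 0 is the target
    and must be all ones."""
    arr = np.asarray(matrix, dtype=bool)
    r, c = arr.shape
    ids = list(ids) if ids is not None else [f"RE{i + 1:03d}" for i in range(r)]
    cts = list(cts) if cts is not None else [target] + [f"N{j:02d}" for j in range(1, c)]
    df = pd.DataFrame(arr, index=ids, columns=cts)
    return BinaryLandscape(cts[0], df, cfg or ThresholdConfig(), re_class)


def random_landscape(rng, r, c, density=0.35, target="T") -> BinaryLandscape:
    """Random landscape with an all-active target column."""
    arr = rng.random((r, c)) < density
    arr[:, 0] = True
    return landscape_from_matrix(arr, target=target)


def table_from_tpm(values, cts_donors, ids=None, re_class=None) -> ExpressionTable:
    """ExpressionTable from a dense array and (cell_type, donor) pairs."""
    arr = np.asarray(values, dtype=float)
    ids = list(ids) if ids is not None else [f"RE{i + 1:03d}" for i in range(arr.shape[0])]
    cols = pd.MultiIndex.from_tuples(cts_donors, names=["cell_type", "donor"])
    return ExpressionTable(pd.DataFrame(arr, index=ids, columns=cols), re_class)


# -- fixtures ------------------------------------------------------------

PLANT = PlantedCode("CT01", ("RE0001", "RE0002", "RE0003"))


def planted_spec(seed, c=12, r=15, bg=0.15, **kw) -> SyntheticSpec:
    return SyntheticSpec(c=c, r=r, planted=(PLANT,), background_sparsity=bg,
                         seed=seed, **kw)


@pytest.fixture
def planted_table() -> ExpressionTable:
    return generate_landscape(planted_spec(seed=11))


@pytest.fixture
def planted_landscape(planted_table) -> BinaryLandscape:
    return binarize_for_target(planted_table, "CT01")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)
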