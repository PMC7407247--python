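"""Closed-form sizes of the intersection search space.

For a database of r REs, the number of candidate k-RE combinations for one
target cell type is C(r, k); asking the exclusivity question over c cell
types in conjunctive normal form has a truth table of 2**(c*k) rows.  These
numbers are why the search relies on sampling and heuristics rather than
saturation: a brute-force scan is O((c*r)**k).
"""

from __future__ import annotations

from math import comb

from .errors import InputError


def n_combinations(r: int, k: int) -> int:
    """C(r, k): candidate k-RE combinations out of r REs."""
    if r < 0 or k < 0:
        raise InputError("r and k must be non-negative")
    return comb(r, k)


def truth_table_rows(c: int, k: int) -> int:
    """Rows of the CNF exclusivity truth table over c cell types: 2**(c*k)."""
    if c < 1 or k < 1:
        raise InputError("c and k must be positive")
    return 2 ** (c * k)
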