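"""Pooling single-cell RE "ON" calls into a bulk-compatible profile.

Single-cell assays give a shallow, discontinuous view of RE activity, so
individual cells are pooled: an RE is ON for the pooled profile if it is ON
in at least ``min_cells`` cells (default 1, i.e. the plain union), and every
non-retrieved RE is OFF by definition.  The pooled profile is injected into
the bulk landscape as a new single-donor cell type, after which the search
machinery treats it exactly like any bulk cell type.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import InputError
from .expression import ExpressionTable

logger = logging.getLogger(__name__)

#: TPM assigned to pooled ON calls; far above every default activity
#: threshold, since the binary-to-TPM bridge carries no magnitude
#: information.
DEFAULT_SENTINEL_TPM = 10.0


@dataclass(frozen=True)
class PooledSingleCellProfile:
    cell_type: str
    n_cells: int
    on_res: frozenset

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InputError("n_cells must be >= 1")


def pool_cells(per_cell_on_sets, cell_type: str,
               min_cells: int = 1) -> PooledSingleCellProfile:
    """Union the per-cell ON sets (optionally requiring support in
    >= ``min_cells`` cells).  Order-invariant and idempotent."""
    sets = [frozenset(s) for s in per_cell_on_sets]
    if not sets:
        raise InputError("need at least one cell")
    if min_cells < 1:
        raise InputError("min_cells must be >= 1")
    support = Counter()
    for s in sets:
        support.update(s)
    on = frozenset(r for r, n in support.items() if n >= min_cells)
    return PooledSingleCellProfile(cell_type, len(sets), on)


def read_cell_matrix(path) -> list[frozenset]:
    """Cells x REs binary TSV (rows: cells, columns: RE ids) -> ON sets."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [frozenset(df.columns[row.to_numpy() > 0]) for _, row in df.iterrows()]


def inject_pooled_profile(
    table: ExpressionTable,
    profile: PooledSingleCellProfile,
    sentinel_tpm: float = DEFAULT_SENTINEL_TPM,
    donor: str = "pooled",
) -> ExpressionTable:
    """Add the pooled profile as a new single-donor cell-type column.

    ON REs outside the bulk RE universe are dropped (logged count); ON REs
    get the sentinel TPM, everything else 0.  The pooled column counts as a
    single donor, so the interindividual score z is not applicable to it.
    """
    if profile.cell_type in table.cell_types:
        raise InputError(f"cell type {profile.cell_type!r} already present")
    known = set(table.re_ids)
    dropped = len(profile.on_res - known)
    if dropped:
        logger.info(
            "inject_pooled_profile: %d pooled ON REs outside the bulk "
            "universe dropped", dropped,
        )
    col = pd.Series(0.0, index=table.tpm.index)
    col.loc[sorted(profile.on_res & known)] = sentinel_tpm
    new = table.tpm.copy()
    new[(profile.cell_type, donor)] = col
    return ExpressionTable(new, table.re_class, dict(table.intervals))


def remove_celltype(table: ExpressionTable, cell_type: str) -> ExpressionTable:
    """Inverse of injection: drop the cell type's columns."""
    return table.drop_cell_type(cell_type)
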