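"""Binarization of TPM landscapes and the sparse-RE pre-filter.

A target-specific binary landscape is built with deliberately conservative,
asymmetric criteria:

* an RE enters the landscape only if it is above the non-zero pre-filter in
  EVERY target donor, and is called target-active only if the MINIMUM over
  target donors clears the activity threshold (the per-donor intersection);
* each non-target cell type is called active if the MEAN over its donors
  clears the (much lower) inactivity threshold.

The min-vs-mean asymmetry raises the bar for calling an RE usable in the
target while keeping non-target activity calls sensitive, which is the safe
direction for an AND-gate: a missed target RE costs a candidate, a missed
non-target activity costs specificity.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyLandscapeError, InputError, UnsatisfiableFilterError
from .expression import ExpressionTable, GenomicInterval, collapse_nontarget_donors


@dataclass(frozen=True)
class ThresholdConfig:
    """Activity thresholds (TPM) and sparsity-filter settings.

    Defaults are the promoter settings with the highest selectivity
    (activity 0.5 TPM, strict inactivity at 0 TPM); use
    :meth:`for_enhancers` for the enhancer defaults (0.1 / 0).  All
    comparisons are strict ``>`` ("above") by default; set ``strict=False``
    for ``>=``.
    """

    activity_target: float = 0.5
    inactivity_nontarget: float = 0.0
    nonzero_prefilter: float = 0.0
    sparsity_start_pct: float = 90.0
    sparsity_step: float = 5.0
    strict: bool = True
    #: How to retry when the sparsity filter leaves fewer than k REs:
    #: "up" raises the cutoff X (keeps more REs, the reading that can
    #: actually recover); "down" lowers it (the literal text reading).
    relax_direction: str = "up"

    def __post_init__(self) -> None:
        if not self.activity_target > self.inactivity_nontarget >= 0:
            raise InputError("need activity_target > inactivity_nontarget >= 0")
        if not 0 < self.sparsity_start_pct <= 100:
            raise InputError("sparsity_start_pct must be in (0, 100]")
        if self.sparsity_step <= 0:
            raise InputError("sparsity_step must be positive")
        if self.relax_direction not in ("up", "down"):
            raise InputError("relax_direction must be 'up' or 'down'")

    @property
    def cmp(self):
        return operator.gt if self.strict else operator.ge

    @classmethod
    def for_promoters(cls, **kw) -> "ThresholdConfig":
        return cls(activity_target=kw.pop("activity_target", 0.5), **kw)

    @classmethod
    def for_enhancers(cls, **kw) -> "ThresholdConfig":
        return cls(activity_target=kw.pop("activity_target", 0.1), **kw)

    @classmethod
    def for_class(cls, re_class: str | None, **kw) -> "ThresholdConfig":
        if re_class == "enhancer":
            return cls.for_enhancers(**kw)
        return cls.for_promoters(**kw)


@dataclass
class BinaryLandscape:
    """Per-target binary RE x cell-type activity matrix.

    ``active`` is a boolean DataFrame (rows: REs, columns: the target plus
    every non-target cell type).  Every row is active in the target column
    by construction (rows that are not never enter the landscape).
    """

    target: str
    active: pd.DataFrame
    thresholds: ThresholdConfig
    re_class: str | None = None
    intervals: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target not in self.active.columns:
            raise InputError(f"target {self.target!r} missing from columns")
        if self.active.shape[0] < 1 or self.active.shape[1] < 2:
            raise InputError("landscape needs >= 1 RE and >= 2 cell types")
        if not self.active[self.target].all():
            bad = self.active.index[~self.active[self.target]].tolist()
            raise InputError(f"REs not active in target: {bad[:5]}")

    @property
    def r(self) -> int:
        return self.active.shape[0]

    @property
    def c(self) -> int:
        return self.active.shape[1]

    @property
    def re_ids(self) -> list[str]:
        return list(self.active.index)

    @property
    def nontarget_cell_types(self) -> list[str]:
        return [c for c in self.active.columns if c != self.target]

    @property
    def nontarget(self) -> pd.DataFrame:
        """Boolean activity over non-target columns only."""
        return self.active[self.nontarget_cell_types]

    def restrict_res(self, ids) -> "BinaryLandscape":
        ids = list(ids)
        missing = set(ids) - set(self.active.index)
        if missing:
            raise InputError(f"unknown RE ids: {sorted(missing)}")
        return BinaryLandscape(
            self.target, self.active.loc[ids], self.thresholds, self.re_class,
            {r: iv for r, iv in self.intervals.items() if r in set(ids)},
        )

    def restrict_cells(self, cell_types) -> "BinaryLandscape":
        """Keep the target plus the given non-target columns."""
        cols = [c for c in self.active.columns if c in set(cell_types) or c == self.target]
        if len(cols) < 2:
            raise InputError("restriction leaves no non-target cell type")
        return BinaryLandscape(
            self.target, self.active[cols], self.thresholds, self.re_class,
            dict(self.intervals),
        )

    def to_tsv(self, path) -> None:
        out = self.active.astype(int)
        out.index.name = "re_id"
        out.to_csv(path, sep="\t")


def binarize_for_target(
    table: ExpressionTable,
    target: str,
    cfg: ThresholdConfig | None = None,
) -> BinaryLandscape:
    """Build the binary landscape for one target cell type."""
    if cfg is None:
        cfg = ThresholdConfig.for_class(table.re_class)
    if target not in table.cell_types:
        raise InputError(
            f"target {target!r} not in table; available: {table.cell_types}"
        )
    cmp = cfg.cmp
    target_tpm = table.tpm[target]
    donor_min = target_tpm.min(axis=1)
    # consistently potentially ON in all donors, then the activity threshold
    keep = cmp(donor_min, cfg.nonzero_prefilter) & cmp(donor_min, cfg.activity_target)
    if not keep.any():
        raise EmptyLandscapeError(
            f"no RE passes the target-activity filter for {target!r} "
            f"(activity > {cfg.activity_target} TPM in all donors)"
        )
    nontarget_mean = collapse_nontarget_donors(table, target).loc[keep]
    active = cmp(nontarget_mean, cfg.inactivity_nontarget)
    active.insert(0, target, True)
    intervals = {r: iv for r, iv in table.intervals.items() if r in set(active.index)}
    return BinaryLandscape(target, active, cfg, table.re_class, intervals)


def sparsity_filter(landscape: BinaryLandscape, k: int) -> BinaryLandscape:
    """Drop broadly active REs, relaxing the cutoff until >= k REs survive.

    REs active in more than X% of the non-target cell types are removed
    (start X from ``sparsity_start_pct``).  When fewer than k REs survive
    the filter is re-applied to the pre-filter landscape at a new X: with
    ``relax_direction="up"`` X is raised by ``sparsity_step`` (keeps more
    REs) until 100%, with ``"down"`` it is lowered (the literal reading of
    the published procedure, which can only remove more).  The percentage
    denominator excludes the target column, which is active by construction.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    cfg = landscape.thresholds
    m = landscape.c - 1
    pct_active = landscape.nontarget.sum(axis=1) / m * 100.0
    x = cfg.sparsity_start_pct
    while True:
        keep = pct_active <= x
        if int(keep.sum()) >= k:
            return landscape.restrict_res(landscape.active.index[keep])
        if cfg.relax_direction == "up":
            if x >= 100:
                raise UnsatisfiableFilterError(
                    f"only {int(keep.sum())} REs at X=100%, need k={k}"
                )
            x = min(100.0, x + cfg.sparsity_step)
        else:
            x -= cfg.sparsity_step
            if x < cfg.sparsity_step:
                raise UnsatisfiableFilterError(
                    f"sparsity cutoff exhausted below {cfg.sparsity_step}% "
                    f"without retaining k={k} REs"
                )


def sort_by_sparseness(
    landscape: BinaryLandscape,
    restrict_to=None,
) -> list[str]:
    """RE ids ordered by ascending number of active non-target cell types.

    With ``restrict_to``, sparseness is counted only over those
    ("problematic") cell types.  Ties break lexicographically by RE id so
    the order — and everything built on it — is deterministic.
    """
    nt = landscape.nontarget
    if restrict_to is not None:
        cols = [c for c in nt.columns if c in set(restrict_to)]
        if not cols:
            raise InputError(
                f"restriction {sorted(set(restrict_to))} shares no cell type "
                "with the landscape"
            )
        nt = nt[cols]
    counts = nt.sum(axis=1)
    order = sorted(zip(counts.to_numpy(), counts.index), key=lambda t: (t[0], t[1]))
    return [rid for _, rid in order]
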