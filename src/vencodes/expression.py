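"""Reading, curating and addressing RE-by-sample TPM matrices.

The raw activity landscape is a tab-separated matrix whose rows are
regulatory elements (promoters or enhancers, identified by a unique id that
may embed genomic coordinates as ``chrN:start-end``) and whose columns are
biological samples labelled ``"cell type, donor"``.  Values are CAGE-seq
peak heights in normalized tags per million (TPM).

The in-memory container is :class:`ExpressionTable`, a thin wrapper around a
pandas DataFrame with a two-level column index ``(cell_type, donor)``.
"""

from __future__ import annotations

import logging
import re as _re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import InputError

logger = logging.getLogger(__name__)

#: Default parse rule for sample headers: free-text cell type, then the
#: last comma-separated token as the donor tag.
DEFAULT_SAMPLE_PATTERN = r"^(?P<cell_type>.+),\s*(?P<donor>[^,]+?)\s*$"

_COORD_RE = _re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InputError(f"negative start in interval {self}")
        if self.end <= self.start:
            raise InputError(
                f"interval end must exceed start ({self.chrom}:{self.start}-{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def parse_interval_from_id(re_id: str) -> GenomicInterval | None:
    """Extract a genomic interval from an id of the form ``chrN:start-end``."""
    m = _COORD_RE.match(re_id)
    if m is None:
        return None
    return GenomicInterval(m["chrom"], int(m["start"]), int(m["end"]))


@dataclass
class CurationSpec:
    """Which samples to drop and which cell-type categories to merge.

    ``exclude_samples`` holds regular-expression patterns matched (via
    ``re.search``) against both the full ``"cell_type, donor"`` label and the
    bare cell-type name.  ``merge_map`` maps original cell-type names to the
    merged category name (exact string match after whitespace trimming — no
    fuzzy matching, which would be a curation hazard).
    """

    exclude_samples: list[str] = field(default_factory=list)
    merge_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = set(self.merge_map.values())
        if merged & set(self.exclude_samples):
            raise InputError(
                "merge target names overlap exclusion patterns: "
                f"{sorted(merged & set(self.exclude_samples))}"
            )

    @classmethod
    def from_yaml(cls, path) -> "CurationSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            exclude_samples=list(raw.get("exclude_samples", [])),
            merge_map=dict(raw.get("merge_map", {})),
        )


@dataclass
class ExpressionTable:
    """An RE x sample TPM matrix with donor-aware column labels.

    ``tpm`` has the RE id as row index and a two-level
    ``(cell_type, donor)`` MultiIndex as columns.  ``intervals`` maps RE ids
    to genomic coordinates when known; ``re_class`` tags the whole table as
    promoter or enhancer data (the two classes live in separate atlases and
    are only mixed downstream, where each RE keeps its class).
    """

    tpm: pd.DataFrame
    re_class: str | None = None
    intervals: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.tpm
        if df.columns.nlevels != 2:
            raise InputError("columns must be a (cell_type, donor) MultiIndex")
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise InputError(f"duplicate RE ids: {dup}")
        dupc = df.columns[df.columns.duplicated()].unique().tolist()
        if dupc:
            raise InputError(f"duplicate (cell_type, donor) samples: {dupc}")
        if self.re_class not in (None, "promoter", "enhancer"):
            raise InputError(f"unknown re_class {self.re_class!r}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise InputError("TPM matrix contains non-numeric values")
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise InputError(
                f"negative or non-finite TPM at RE {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )

    # -- addressing ------------------------------------------------------
    @property
    def re_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def n_res(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tpm.shape[1]

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for ct in self.tpm.columns.get_level_values(0):
            seen.setdefault(ct, None)
        return list(seen)

    def donors(self, cell_type: str) -> list[str]:
        if cell_type not in self.tpm.columns.get_level_values(0):
            raise InputError(
                f"cell type {cell_type!r} not in table; available: {self.cell_types}"
            )
        return list(self.tpm[cell_type].columns)

    def copy(self) -> "ExpressionTable":
        return ExpressionTable(self.tpm.copy(), self.re_class, dict(self.intervals))

    def drop_cell_type(self, cell_type: str) -> "ExpressionTable":
        if cell_type not in self.cell_types:
            raise InputError(f"cell type {cell_type!r} not in table")
        return ExpressionTable(
            self.tpm.drop(columns=cell_type, level=0), self.re_class, dict(self.intervals)
        )

    def mean_donors_per_type(self) -> float:
        """Average number of donors (samples) per cell-type category."""
        return self.n_samples / len(self.cell_types)


def _parse_sample_labels(names, pattern: str) -> pd.MultiIndex:
    rx = _re.compile(pattern)
    pairs = []
    for name in names:
        m = rx.match(str(name).strip())
        if m is None:
            raise InputError(
                f"sample header {name!r} does not match pattern {pattern!r} "
                "(expected 'cell type, donor')"
            )
        pairs.append((m["cell_type"].strip(), m["donor"].strip()))
    return pd.MultiIndex.from_tuples(pairs, names=["cell_type", "donor"])


def read_expression_table(
    path,
    re_class: str | None = None,
    sample_pattern: str = DEFAULT_SAMPLE_PATTERN,
) -> ExpressionTable:
    """Read a tab-separated RE x sample TPM matrix.

    First column holds the RE id; the header row holds ``"cell type, donor"``
    sample names (dialect configurable through ``sample_pattern``).  RE ids of
    the form ``chrN:start-end`` get their genomic interval attached.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise InputError(f"duplicate RE ids in {path}: {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        i, j = map(int, np.argwhere(bad.to_numpy())[0])
        raise InputError(
            f"non-numeric TPM at RE {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = map(int, np.argwhere(numeric.isna().to_numpy())[0])
        raise InputError(f"missing TPM at RE {df.index[i]!r}, column {df.columns[j]!r}")
    numeric.columns = _parse_sample_labels(df.columns, sample_pattern)
    intervals = {}
    for rid in numeric.index:
        iv = parse_interval_from_id(rid)
        if iv is not None:
            intervals[rid] = iv
    return ExpressionTable(numeric, re_class=re_class, intervals=intervals)


def write_expression_table(table: ExpressionTable, path) -> None:
    """Write the table back in the same TSV dialect (round-trip safe)."""
    out = table.tpm.copy()
    out.columns = [f"{ct}, {d}" for ct, d in table.tpm.columns]
    out.index.name = "re_id"
    out.to_csv(path, sep="\t")


def load_bed_intervals(path) -> dict[str, GenomicInterval]:
    """Read RE coordinates from a BED6-style file (name column = RE id)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3],
    )
    out: dict[str, GenomicInterval] = {}
    for row in df.itertuples(index=False):
        out[str(row.name)] = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
    return out


# -- curation ------------------------------------------------------------

def curate(
    table: ExpressionTable,
    spec: CurationSpec,
    log: list[str] | None = None,
) -> ExpressionTable:
    """Drop excluded samples and pool merged categories under one name.

    Exclusion patterns that match nothing are ignorable but logged.  A merge
    that would create duplicate ``(cell_type, donor)`` pairs is a hard error
    with a suggested donor re-suffixing, because silently pooling two samples
    with the same donor tag would hide a labelling problem.
    """
    if log is None:
        log = []
    df = table.tpm
    keep = np.ones(df.shape[1], dtype=bool)
    for pat in spec.exclude_samples:
        rx = _re.compile(pat)
        hit = np.array(
            [bool(rx.search(f"{ct}, {d}") or rx.search(ct)) for ct, d in df.columns]
        )
        if not hit.any():
            msg = f"exclusion pattern {pat!r} matched no sample"
            log.append(msg)
            logger.warning(msg)
        else:
            for ct, d in df.columns[hit]:
                log.append(f"excluded sample '{ct}, {d}' (pattern {pat!r})")
        keep &= ~hit
    df = df.loc[:, keep]

    if spec.merge_map:
        merge = {k.strip(): v.strip() for k, v in spec.merge_map.items()}
        new_cols = []
        for ct, d in df.columns:
            tgt = merge.get(ct.strip())
            if tgt is not None and tgt != ct:
                log.append(f"merged '{ct}' -> '{tgt}' (donor {d})")
            new_cols.append((tgt if tgt is not None else ct, d))
        mi = pd.MultiIndex.from_tuples(new_cols, names=["cell_type", "donor"])
        dups = mi[mi.duplicated()].unique().tolist()
        if dups:
            raise InputError(
                f"merging creates duplicate (cell_type, donor) pairs: {dups}; "
                "re-suffix donors first, e.g. 'donor1' -> 'donor1b'"
            )
        df = df.copy()
        df.columns = mi

    return ExpressionTable(df, table.re_class, dict(table.intervals))


def collapse_nontarget_donors(table: ExpressionTable, target: str) -> pd.DataFrame:
    """Mean raw TPM per non-target cell type (one column per cell type).

    The target cell type's donors are deliberately NOT collapsed: target
    activity calls use the per-donor intersection, whereas non-target calls
    use the donor average.  The mean is taken on raw TPM, never on binarized
    values.
    """
    if target not in table.cell_types:
        raise InputError(
            f"target {target!r} not in table; available: {table.cell_types}"
        )
    nontarget = table.tpm.drop(columns=target, level=0)
    return nontarget.T.groupby(level=0, sort=False).mean().T


def add_external_celltype(
    table: ExpressionTable, extra: ExpressionTable
) -> ExpressionTable:
    """Graft an extra cell type (e.g. a cancer line) onto a primary table.

    The two tables are restricted to their shared RE universe; the number of
    REs dropped from each side is logged.  This subjects the added cell type
    to exactly the same exclusivity criteria as the primary cell types (the
    in-silico patient construction).
    """
    collision = set(table.cell_types) & set(extra.cell_types)
    if collision:
        raise InputError(f"cell type(s) already present: {sorted(collision)}")
    shared = table.tpm.index.intersection(extra.tpm.index)
    if len(shared) == 0:
        raise InputError("no shared RE ids between the two tables")
    n_drop_base = table.n_res - len(shared)
    n_drop_extra = extra.n_res - len(shared)
    if n_drop_base or n_drop_extra:
        logger.info(
            "add_external_celltype: dropped %d base and %d extra REs outside "
            "the shared universe of %d",
            n_drop_base, n_drop_extra, len(shared),
        )
    merged = pd.concat(
        [table.tpm.loc[shared], extra.tpm.loc[shared]], axis=1
    )
    intervals = {r: iv for r, iv in {**extra.intervals, **table.intervals}.items()
                 if r in set(shared)}
    return ExpressionTable(merged, table.re_class, intervals)
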