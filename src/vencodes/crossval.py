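"""Cross-validation of VEnCodes against external RE call sets.

External assays (DNase-seq, ATAC-seq, STARR-seq, ChIP, ...) deliver sets of
genomic intervals where an RE is called active in a given cell type.  A
CAGE-derived code RE counts as validated when its coordinates overlap any
external interval by more than 0 nucleotides (half-open coordinates, strand
ignored — the criterion is purely positional).  Chromosome names are
normalized so that ``chr1`` and ``1`` compare equal; reconciling genome
builds is the caller's responsibility and is NOT attempted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from intervaltree import IntervalTree

from .binarize import BinaryLandscape
from .errors import InputError, UnsatisfiableFilterError
from .expression import GenomicInterval
from .search import VEnCode


def normalize_chrom(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Canonical chromosome name: strip a leading ``chr`` (case-insensitive),
    then apply the optional alias map."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if aliases:
        s = aliases.get(s, s)
    return s


def overlaps(
    a: GenomicInterval, b: GenomicInterval,
    aliases: Mapping[str, str] | None = None,
) -> bool:
    """>0-nt overlap between two half-open intervals on the same chromosome."""
    if not isinstance(a, GenomicInterval) or not isinstance(b, GenomicInterval):
        raise InputError("overlaps expects GenomicInterval arguments")
    if normalize_chrom(a.chrom, aliases) != normalize_chrom(b.chrom, aliases):
        return False
    return min(a.end, b.end) - max(a.start, b.start) > 0


@dataclass
class ExternalRESet:
    """Deduplicated intervals from an independent assay for one cell type."""

    source: str
    cell_type: str
    intervals: frozenset = field(default_factory=frozenset)
    aliases: Mapping[str, str] | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.intervals = frozenset(self.intervals)  # collapses duplicates
        index: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            index.setdefault(normalize_chrom(iv.chrom, self.aliases),
                             IntervalTree()).addi(iv.start, iv.end)
        self._index = index

    @classmethod
    def from_bed(cls, path, source: str, cell_type: str,
                 aliases: Mapping[str, str] | None = None) -> "ExternalRESet":
        """Load BED3+/BroadPeak intervals (only the first 3 columns used)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        ivs = [GenomicInterval(str(r.chrom), int(r.start), int(r.end))
               for r in df.itertuples(index=False)]
        return cls(source, cell_type, frozenset(ivs), aliases)

    def has_overlap(self, iv: GenomicInterval) -> bool:
        """True iff any stored interval overlaps ``iv`` by > 0 nt.

        Interval-tree lookup with half-open semantics, behaviourally
        identical to a linear scan over :func:`overlaps`.
        """
        tree = self._index.get(normalize_chrom(iv.chrom, self.aliases))
        return bool(tree is not None and tree.overlap(iv.start, iv.end))


@dataclass
class ValidationReport:
    code: VEnCode
    validated_k: int
    fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.validated_k <= self.code.k:
            raise InputError("validated_k out of range")


def validate_code(
    code: VEnCode,
    ext: ExternalRESet,
    intervals: Mapping[str, GenomicInterval],
) -> ValidationReport:
    """Count code REs with at least one overlapping external interval."""
    validated = 0
    for rid in code.res:
        iv = intervals.get(rid)
        if iv is None:
            raise InputError(f"RE {rid!r} carries no genomic coordinates")
        if ext.has_overlap(iv):
            validated += 1
    return ValidationReport(code, validated, validated / code.k)


def restrict_to_validated(
    landscape: BinaryLandscape, ext: ExternalRESet
) -> BinaryLandscape:
    """Keep only externally supported REs, so any downstream search yields
    pre-validated codes (fraction = 1 by construction).  Idempotent."""
    keep = []
    for rid in landscape.re_ids:
        iv = landscape.intervals.get(rid)
        if iv is None:
            raise InputError(f"RE {rid!r} carries no genomic coordinates")
        if ext.has_overlap(iv):
            keep.append(rid)
    if not keep:
        raise UnsatisfiableFilterError(
            f"no RE of the landscape overlaps the {ext.source!r} call set"
        )
    return landscape.restrict_res(keep)


def specificity_index(code_hits: Mapping[str, float], target: str) -> float:
    """Target hit percentage over the mean non-target hit percentage.

    Returns ``float('inf')`` as a flagged sentinel when no non-target cell
    is ever hit but the target is (infinite specificity); a target that is
    never hit scores 0.0 regardless.
    """
    if target not in code_hits:
        raise InputError(f"target {target!r} missing from hit table")
    for ct, v in code_hits.items():
        if not 0.0 <= float(v) <= 100.0:
            raise InputError(f"hit percentage out of [0, 100] for {ct!r}: {v}")
    t = float(code_hits[target])
    others = [float(v) for ct, v in code_hits.items() if ct != target]
    if not others:
        raise InputError("no non-target cell types in hit table")
    if t == 0.0:
        return 0.0
    mean_nt = sum(others) / len(others)
    if mean_nt == 0.0:
        return float("inf")
    return t / mean_nt


def match_codes_across_database(
    codes,
    collection: Mapping[str, ExternalRESet],
    intervals: Mapping[str, GenomicInterval],
) -> pd.Series:
    """Percentage of codes whose k REs are all called active per cell type.

    ``collection`` maps cell-type names of the independent database to their
    active-interval sets; a code "matches" a cell type when every RE
    overlaps at least one active interval there.  Compare against random
    k-subsets drawn from the same target-active pool to judge specificity.
    """
    codes = list(codes)
    if not codes:
        raise InputError("no codes to match")
    hits = {}
    for ct, ext in collection.items():
        n = 0
        for code in codes:
            ok = True
            for rid in code.res:
                iv = intervals.get(rid)
                if iv is None:
                    raise InputError(f"RE {rid!r} carries no genomic coordinates")
                if not ext.has_overlap(iv):
                    ok = False
                    break
            n += ok
        hits[ct] = 100.0 * n / len(codes)
    return pd.Series(hits, name="hit_pct")
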