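"""VEnCode search: random sampling, greedy heuristic, mixed heuristic2.

A VEnCode is a set of k REs all active in the target cell type with, for
every non-target cell type, at least one member inactive — a k-input AND
gate that fires exclusively in the target.  Validity of a candidate set is
a pure Boolean test (:func:`is_vencode`); the three search strategies differ
only in how they walk the combination space:

* ``sample_vencodes`` — uniform random k-subsets of the sparsity-filtered
  landscape (rejection sampling with an iteration cap);
* ``heuristic_vencodes`` — a sparseness-ordered greedy decision tree: choose
  the sparsest RE, cull the cell types it already excludes, re-rank the rest
  by co-activity over the surviving ("problematic") cell types, and branch
  over the nearest neighbours in sparseness at each level (depth <= k);
* ``heuristic2_vencodes`` — take the k1 sparsest target-active enhancers and,
  if their intersection is still shared with some cell types, resolve those
  with a k2-promoter heuristic search restricted to the problematic columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binarize import BinaryLandscape, sort_by_sparseness
from .errors import InputError

__all__ = [
    "VEnCode", "SearchReport", "is_vencode", "sample_vencodes",
    "heuristic_vencodes", "heuristic2_vencodes", "top_vencodes",
]


@dataclass(frozen=True)
class VEnCode:
    """An ordered set of k RE ids claimed exclusive to one target cell type."""

    target: str
    res: tuple[str, ...]
    source_method: str
    re_classes: tuple[str, ...] | None = None
    k1: int | None = None  # enhancer count (heuristic2)
    k2: int | None = None  # promoter count (heuristic2)

    def __post_init__(self) -> None:
        if len(self.res) < 1:
            raise InputError("a VEnCode needs at least one RE")
        if len(set(self.res)) != len(self.res):
            raise InputError(f"duplicate REs in VEnCode: {self.res}")
        if self.re_classes is not None and len(self.re_classes) != len(self.res):
            raise InputError("re_classes must align with res")

    @property
    def k(self) -> int:
        return len(self.res)

    def as_set(self) -> frozenset:
        return frozenset(self.res)


@dataclass
class SearchReport:
    target: str
    method: str
    n_iterations: int
    vencodes: list[VEnCode] = field(default_factory=list)
    seed: int | None = None


def is_vencode(landscape: BinaryLandscape, res) -> bool:
    """True iff ``res`` is exclusive to the landscape's target cell type.

    All REs must be target-active and every non-target cell type must have
    at least one inactive member.  Pure function; unknown ids are an error.
    """
    ids = list(res)
    missing = set(ids) - set(landscape.active.index)
    if missing:
        raise InputError(f"unknown RE ids: {sorted(missing)}")
    sub = landscape.active.loc[ids]
    if not sub[landscape.target].all():
        return False
    nt = sub[landscape.nontarget_cell_types].to_numpy()
    return not nt.all(axis=0).any()


def _nontarget_bool(landscape: BinaryLandscape) -> np.ndarray:
    return landscape.nontarget.to_numpy(dtype=bool)


def sample_vencodes(
    landscape: BinaryLandscape,
    k: int,
    n_samples: int,
    seed: int | None = None,
    max_hits: int | None = None,
) -> SearchReport:
    """Uniform random k-subset sampling of the (sparsity-filtered) landscape.

    Draws k REs without replacement per iteration, tests exclusivity, and
    deduplicates hits (a VEnCode is an unordered RE set).  Stops after
    ``n_samples`` draws or ``max_hits`` distinct VEnCodes.  Reproducible
    under ``seed``.
    """
    if n_samples < 1:
        raise InputError("n_samples must be >= 1")
    if landscape.r < k:
        raise InputError(f"landscape has r={landscape.r} REs < k={k}")
    rng = np.random.default_rng(seed)
    A = _nontarget_bool(landscape)
    ids = np.asarray(landscape.re_ids)
    hits: list[VEnCode] = []
    seen: set[frozenset] = set()
    n_done = 0
    chunk = 20_000
    while n_done < n_samples:
        n = min(chunk, n_samples - n_done)
        # first k columns of a random argsort = uniform k-subset per row
        draws = np.argsort(rng.random((n, landscape.r)), axis=1)[:, :k]
        valid = ~A[draws].all(axis=1).any(axis=1)
        for i in range(n):
            n_done += 1
            if valid[i]:
                fs = frozenset(str(x) for x in ids[draws[i]])
                if fs not in seen:
                    seen.add(fs)
                    hits.append(
                        VEnCode(
                            landscape.target,
                            tuple(sorted(fs)),
                            "sampling",
                            re_classes=_classes(landscape, sorted(fs)),
                        )
                    )
                    if max_hits is not None and len(hits) >= max_hits:
                        return SearchReport(
                            landscape.target, "sampling", n_done, hits, seed
                        )
        if max_hits is not None and len(hits) >= max_hits:
            break
    return SearchReport(landscape.target, "sampling", n_done, hits, seed)


def _classes(landscape: BinaryLandscape, ids) -> tuple[str, ...] | None:
    if landscape.re_class is None:
        return None
    return tuple(landscape.re_class for _ in ids)


def heuristic_vencodes(
    landscape: BinaryLandscape,
    k: int,
    neighbors: int = 3,
    nodes_per_level: int | None = None,
    quota: int = 20,
) -> SearchReport:
    """Greedy sparseness-ordered decision-tree search.

    First-level nodes are tried in global sparseness order (up to
    ``nodes_per_level`` of them; all by default, so the search enumerates
    codes until ``quota`` distinct VEnCodes are collected).  Below the first
    level each node expands into the ``neighbors`` nearest REs by sparseness
    counted over the node's problematic cell types.  Whenever a partial
    combination of m < k REs is already exclusive, the next k-m globally
    sparsest REs are appended as extra safety layers (supersets of a valid
    code stay valid).  Node depth never exceeds k.  Finding nothing is a
    legitimate outcome, not an error.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    A = _nontarget_bool(landscape)
    ids = list(landscape.active.index)
    idx_of = {rid: i for i, rid in enumerate(ids)}
    global_order = [idx_of[rid] for rid in sort_by_sparseness(landscape)]
    results: list[VEnCode] = []
    seen: set[frozenset] = set()
    n_nodes = 0

    def pad(chosen: list[int]) -> tuple[str, ...]:
        out = list(chosen)
        for i in global_order:
            if len(out) >= k:
                break
            if i not in out:
                out.append(i)
        return tuple(ids[i] for i in out)

    def record(chosen: list[int]) -> None:
        res = pad(chosen)
        fs = frozenset(res)
        if fs in seen:
            return
        seen.add(fs)
        results.append(
            VEnCode(
                landscape.target, tuple(sorted(res)), "heuristic",
                re_classes=_classes(landscape, res),
            )
        )

    def expand(chosen: list[int], problematic: np.ndarray, depth: int) -> None:
        nonlocal n_nodes
        if len(results) >= quota:
            return
        n_nodes += 1
        if not problematic.any():
            record(chosen)
            return
        if depth >= k:
            return
        counts = A[:, problematic].sum(axis=1)
        chosen_set = set(chosen)
        order = sorted(
            (i for i in range(len(ids)) if i not in chosen_set),
            key=lambda i: (counts[i], ids[i]),
        )
        branched = 0
        for i in order:
            if len(results) >= quota:
                return
            if counts[i] == 0:
                # this RE excludes every remaining problematic cell type
                record(chosen + [i])
            elif branched < neighbors:
                branched += 1
                expand(chosen + [i], problematic & A[i], depth + 1)

    starts = global_order if nodes_per_level is None else global_order[:nodes_per_level]
    for i in starts:
        if len(results) >= quota:
            break
        expand([i], A[i].copy(), 1)

    for code in results:  # soundness guard: emitted codes must verify
        assert is_vencode(landscape, code.res)
    return SearchReport(landscape.target, "heuristic", n_nodes, results, None)


def heuristic2_vencodes(
    enh_landscape: BinaryLandscape,
    prom_landscape: BinaryLandscape,
    k1: int,
    k2: int,
    neighbors: int = 3,
    quota: int = 20,
    pad_to_full: bool = False,
) -> SearchReport:
    """Mixed enhancer + promoter search.

    Takes the k1 sparsest target-active enhancers.  If their intersection is
    already exclusive the minimal (enhancer-only) code is returned — unless
    ``pad_to_full`` asks for a fixed total size, in which case the k2
    sparsest promoters are appended.  Otherwise the cell types in which all
    k1 enhancers are co-active ("problematic") are handed to a promoter
    heuristic search restricted to those columns; each promoter hit combines
    with the enhancers into a mixed VEnCode.
    """
    if enh_landscape.target != prom_landscape.target:
        raise InputError(
            f"targets differ: {enh_landscape.target!r} vs {prom_landscape.target!r}"
        )
    if set(enh_landscape.active.columns) != set(prom_landscape.active.columns):
        raise InputError("enhancer and promoter landscapes must share the "
                         "same cell-type universe")
    if enh_landscape.r < k1:
        raise InputError(f"only {enh_landscape.r} enhancers, need k1={k1}")
    target = enh_landscape.target
    enh_sel = sort_by_sparseness(enh_landscape)[:k1]
    enh_classes = tuple("enhancer" for _ in enh_sel)

    def mixed(prom_ids) -> VEnCode:
        prom_ids = list(prom_ids)
        return VEnCode(
            target,
            tuple(enh_sel) + tuple(prom_ids),
            "heuristic2",
            re_classes=enh_classes + tuple("promoter" for _ in prom_ids),
            k1=len(enh_sel),
            k2=len(prom_ids),
        )

    if is_vencode(enh_landscape, enh_sel):
        if pad_to_full and k2 > 0:
            proms = sort_by_sparseness(prom_landscape)[:k2]
            code = mixed(proms)
        else:
            code = VEnCode(target, tuple(enh_sel), "heuristic2",
                           re_classes=enh_classes, k1=k1, k2=0)
        return SearchReport(target, "heuristic2", 1, [code], None)

    sub = enh_landscape.nontarget.loc[enh_sel].to_numpy()
    co_active = sub.all(axis=0)
    problematic = [
        ct for ct, bad in zip(enh_landscape.nontarget_cell_types, co_active) if bad
    ]
    restricted = prom_landscape.restrict_cells(problematic)
    prom_report = heuristic_vencodes(restricted, k2, neighbors=neighbors, quota=quota)
    codes = []
    for pc in prom_report.vencodes:
        code = mixed(pc.res)
        # combined exclusivity: enhancers kill every non-problematic column,
        # the promoter code kills every problematic one
        assert is_vencode(restricted, pc.res)
        codes.append(code)
    return SearchReport(target, "heuristic2", prom_report.n_iterations, codes, None)


def top_vencodes(reports, n: int, ranker) -> list[VEnCode]:
    """The n best VEnCodes by quality score E (ties: smaller k, then ids).

    ``ranker`` maps a VEnCode to its score (an object with an ``e``
    attribute, or a plain number).  Stable under report concatenation order:
    the key is (E desc, k asc, sorted ids asc) and deduplication treats a
    VEnCode as an unordered RE set.
    """
    reports = list(reports)
    targets = {r.target for r in reports}
    if len(targets) > 1:
        raise InputError(f"reports mix targets: {sorted(targets)}")
    pool: dict[frozenset, VEnCode] = {}
    for rep in reports:
        for code in rep.vencodes:
            pool.setdefault(code.as_set(), code)
    scored = []
    for code in pool.values():
        s = ranker(code)
        e = getattr(s, "e", s)
        scored.append((-float(e), code.k, tuple(sorted(code.res)), code))
    scored.sort(key=lambda t: t[:3])
    return [c for *_, c in scored[:n]]
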