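"""Quality ranking of VEnCodes.

Two complementary robustness measures:

* **E (intraindividual)** — Monte-Carlo simulation of false-negative
  artifacts.  Inactive entries of the code's k x (c-1) non-target submatrix
  are flipped to active one at a time, uniformly at random, until the code
  loses exclusivity; ``E_raw`` is the mean number of flips survived.  It is
  normalized against the best-case reference ``E_best(c, k)`` — the same
  simulation on a code whose k REs are inactive in every non-target cell
  type — giving ``E = 100 * E_raw / E_best``, comparable across landscapes
  and code sizes.

  Flips are restricted to the code's own submatrix: a flip anywhere else in
  the database can never change the code's validity, and the restriction
  rescales ``E_raw`` and ``E_best`` identically, leaving E unchanged while
  shrinking the simulation by orders of magnitude.

* **z (interindividual)** — donor hold-out cross-validation.  Codes are
  generated from a subset of the target's donors and each held-out donor
  must express all k REs above the activity threshold; z is the percentage
  of codes that satisfy every held-out donor.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .binarize import BinaryLandscape, ThresholdConfig, binarize_for_target, sparsity_filter
from .errors import InputError, NoVEnCodeError
from .expression import ExpressionTable
from .search import VEnCode, heuristic_vencodes, is_vencode, sample_vencodes

logger = logging.getLogger(__name__)

_E_BEST_CACHE: dict[tuple, float] = {}


@dataclass
class QualityScore:
    """Monte-Carlo intraindividual robustness of one VEnCode."""

    e_raw: float
    n_sims: int
    per_sim_flips: np.ndarray
    seed: int | None = None
    e_best: float | None = None
    e: float | None = None

    @property
    def se_raw(self) -> float:
        """Standard error of the E_raw estimate."""
        return float(np.std(self.per_sim_flips, ddof=1) / np.sqrt(self.n_sims))

    @property
    def se(self) -> float | None:
        """Standard error of normalized E (best-case reference held fixed)."""
        if self.e_best is None:
            return None
        return 100.0 * self.se_raw / self.e_best


@dataclass
class RobustnessScore:
    """Donor hold-out interindividual robustness."""

    z: float
    donors_train: tuple[str, ...]
    donors_test: tuple[str, ...]
    n_codes_tested: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.z <= 100.0:
            raise InputError(f"z out of range: {self.z}")


def _mean_flips_to_failure(
    zero_cols: np.ndarray, zeros_per_col: np.ndarray, n_sims: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Flips survived per simulation until some column saturates.

    Flipping a uniformly chosen currently-inactive entry at each step is
    equivalent to walking a uniform random permutation of the initially
    inactive entries; a column with no inactive entry left means the code
    fires in that cell type and the simulation stops (the breaking flip is
    counted).
    """
    nz = len(zero_cols)
    out = np.empty(n_sims, dtype=np.int64)
    for s in range(n_sims):
        order = zero_cols[rng.permutation(nz)]
        counts = zeros_per_col.copy()
        for t in range(nz):
            col = order[t]
            counts[col] -= 1
            if counts[col] == 0:
                out[s] = t + 1
                break
        else:  # pragma: no cover - a valid code always breaks by flip nz
            out[s] = nz
    return out


def e_raw(
    landscape: BinaryLandscape,
    code: VEnCode | tuple,
    n_sims: int = 2000,
    seed: int | None = None,
) -> QualityScore:
    """Unnormalized quality E_raw of a valid code (mean flips to failure)."""
    res = list(code.res) if isinstance(code, VEnCode) else list(code)
    if not is_vencode(landscape, res):
        raise InputError(
            f"code {res} is not a valid VEnCode in this landscape; E undefined"
        )
    if n_sims < 1:
        raise InputError("n_sims must be >= 1")
    sub = landscape.nontarget.loc[res].to_numpy(dtype=bool)
    zero_rows, zero_cols = np.nonzero(~sub)
    zeros_per_col = np.bincount(zero_cols, minlength=sub.shape[1])
    rng = np.random.default_rng(seed)
    flips = _mean_flips_to_failure(zero_cols, zeros_per_col, n_sims, rng)
    return QualityScore(
        e_raw=float(flips.mean()), n_sims=n_sims, per_sim_flips=flips, seed=seed
    )


def e_best(c: int, k: int, n_sims: int = 2000, seed: int | None = None) -> float:
    """Best-case reference E_best(c, k): all k REs inactive in every
    non-target cell type.  Memoized per (c, k, n_sims, seed)."""
    if c < 2 or k < 1:
        raise InputError("need c >= 2 and k >= 1")
    key = (c, k, n_sims, seed)
    if key not in _E_BEST_CACHE:
        m = c - 1
        zero_cols = np.repeat(np.arange(m), k)
        zeros_per_col = np.full(m, k, dtype=np.int64)
        rng = np.random.default_rng(seed)
        flips = _mean_flips_to_failure(zero_cols, zeros_per_col, n_sims, rng)
        _E_BEST_CACHE[key] = float(flips.mean())
    return _E_BEST_CACHE[key]


def normalize_e(score: QualityScore, e_best_value: float | None = None) -> QualityScore:
    """Fill in E = 100 * E_raw / E_best.  Best-case codes score ~= 100.

    Monte-Carlo noise can push E slightly above 100; such values are
    reported as-is with a warning (clamping would bias rank comparisons).
    """
    eb = e_best_value if e_best_value is not None else score.e_best
    if eb is None or eb <= 0:
        raise InputError("e_best must be a positive reference value")
    e = 100.0 * score.e_raw / eb
    if e > 100.0 + 3.0 * (100.0 * score.se_raw / eb):
        warnings.warn(
            f"normalized E = {e:.1f} exceeds 100 beyond MC noise", stacklevel=2
        )
    return replace(score, e_best=eb, e=e)


def score_vencode(
    landscape: BinaryLandscape,
    code: VEnCode | tuple,
    n_sims: int = 2000,
    seed: int | None = None,
) -> QualityScore:
    """E_raw + best-case reference + normalized E in one call."""
    raw = e_raw(landscape, code, n_sims=n_sims, seed=seed)
    k = len(code.res) if isinstance(code, VEnCode) else len(tuple(code))
    ref_seed = None if seed is None else seed + 1_000_003
    return normalize_e(raw, e_best(landscape.c, k, n_sims=n_sims, seed=ref_seed))


# -- interindividual robustness ------------------------------------------

def _generate_codes(
    landscape: BinaryLandscape, method: str, k: int,
    n_samples: int, quota: int, seed: int | None,
) -> list[VEnCode]:
    if method == "sampling":
        filtered = sparsity_filter(landscape, k)
        return sample_vencodes(
            filtered, k, n_samples=n_samples, seed=seed, max_hits=quota
        ).vencodes
    if method == "heuristic":
        return heuristic_vencodes(landscape, k, quota=quota).vencodes
    raise InputError(f"unknown method {method!r}")


def z_score(
    table: ExpressionTable,
    target: str,
    donors_train,
    method: str = "sampling",
    k: int = 4,
    cfg: ThresholdConfig | None = None,
    n_samples: int = 2000,
    quota: int = 50,
    seed: int | None = None,
) -> RobustnessScore:
    """Interindividual robustness of codes built from a donor subset.

    The landscape is rebuilt using only ``donors_train`` for the target
    (non-target cell types keep all their donors), codes are generated with
    the requested method, and each held-out target donor must express all k
    REs above the activity threshold.  z is the percentage of codes valid on
    ALL held-out donors.
    """
    if cfg is None:
        cfg = ThresholdConfig.for_class(table.re_class)
    donors = table.donors(target)
    if len(donors) < 2:
        raise InputError(f"target {target!r} has < 2 donors; z undefined")
    train = [str(d) for d in donors_train]
    if not train or not set(train) < set(donors):
        raise InputError(
            f"donors_train must be a proper nonempty subset of {donors}, got {train}"
        )
    test = [d for d in donors if d not in set(train)]
    drop = [(target, d) for d in test]
    train_table = ExpressionTable(
        table.tpm.drop(columns=drop), table.re_class, dict(table.intervals)
    )
    landscape = binarize_for_target(train_table, target, cfg)
    codes = _generate_codes(landscape, method, k, n_samples, quota, seed)
    if not codes:
        raise NoVEnCodeError(
            f"no VEnCode found for {target!r} from donors {train}; z undefined"
        )
    cmp = cfg.cmp
    n_pass = 0
    for code in codes:
        held = table.tpm.loc[list(code.res), [(target, d) for d in test]]
        if bool(cmp(held, cfg.activity_target).to_numpy().all()):
            n_pass += 1
    return RobustnessScore(
        z=100.0 * n_pass / len(codes),
        donors_train=tuple(train),
        donors_test=tuple(test),
        n_codes_tested=len(codes),
    )


def mean_z(
    table: ExpressionTable,
    target: str,
    train_size: int,
    **kwargs,
) -> tuple[float, list[RobustnessScore]]:
    """Average z over every train subset of the given size.

    Returns the mean together with the per-subset scores.
    """
    donors = table.donors(target)
    if not 1 <= train_size < len(donors):
        raise InputError(
            f"train_size must be in [1, {len(donors) - 1}] for {len(donors)} donors"
        )
    scores = [
        z_score(table, target, subset, **kwargs)
        for subset in itertools.combinations(donors, train_size)
    ]
    return float(np.mean([s.z for s in scores])), scores
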