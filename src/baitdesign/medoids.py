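"""PAM k-medoids clustering and minimal-k selection under a coverage criterion.

A gene is representable by a set of medoids when at least ``coverage_target``
(default 95%) of its sequences lie within ``divergence_threshold`` (default
30% p-distance) of the nearest medoid. :func:`select_minimal_medoids` walks k
upward from ``k_min`` to ``k_max`` and, for each k, runs PAM (BUILD + SWAP)
up to ``restarts`` times — the first restart is BUILD-seeded, later ones are
randomly initialised — accepting the first restart whose medoid set meets the
coverage target. This mirrors the design procedure used for universal
angiosperm bait kits: the minimum number of real representative sequences per
gene such that nearly all known diversity can hybridise to a probe.

The SWAP phase evaluates all k·(n−k) candidate exchanges per pass with the
FastPAM1 O(n²) delta computation (Schubert & Rousseeuw 2019), which visits
the same local optima as the classical swap search. A numba-compiled kernel
is used when numba is importable; a vectorised numpy path gives identical
results otherwise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .distance import DistanceMatrix
from .errors import ParameterError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# PAM kernels
# ---------------------------------------------------------------------------

_EPS = 1e-12  # a swap must improve cost by more than this to be applied


@njit(cache=True)
def _voronoi_refine_nb(D, med, max_iter):  # pragma: no cover - numba
    """Alternating refinement: assign to nearest medoid, recentre each cluster.

    Cheap pre-conditioning for randomly initialised restarts; the SWAP phase
    still runs afterwards, so the returned solution is a PAM local optimum.
    """
    n = D.shape[0]
    k = med.shape[0]
    assign = np.empty(n, dtype=np.int64)
    for _ in range(max_iter):
        changed = False
        for i in range(n):
            b = np.inf
            bt = 0
            Di = D[i]
            for t in range(k):
                d = Di[med[t]]
                if d < b:
                    b = d
                    bt = t
            assign[i] = bt
        for t in range(k):
            best_cost = np.inf
            best_j = med[t]
            for j in range(n):
                if assign[j] != t:
                    continue
                Dj = D[j]
                c = 0.0
                for i in range(n):
                    if assign[i] == t:
                        c += Dj[i]
                # strict improvement with lowest-index tie rule
                if c < best_cost - 1e-12:
                    best_cost = c
                    best_j = j
            if best_j != med[t]:
                med[t] = best_j
                changed = True
        if not changed:
            break
    return med


@njit(cache=True)
def _swap_until_converged_nb(D, med, max_passes):  # pragma: no cover - numba
    n = D.shape[0]
    k = med.shape[0]
    ismed = np.zeros(n, dtype=np.bool_)
    for t in range(k):
        ismed[med[t]] = True
    d1 = np.empty(n)
    d2 = np.empty(n)
    t1 = np.empty(n, dtype=np.int64)
    corr = np.empty(k)
    for _ in range(max_passes):
        for i in range(n):
            b1 = np.inf
            b2 = np.inf
            bt = 0
            for t in range(k):
                d = D[i, med[t]]
                if d < b1:
                    b2 = b1
                    b1 = d
                    bt = t
                elif d < b2:
                    b2 = d
            d1[i] = b1
            d2[i] = b2
            t1[i] = bt
        best_delta = -1e-12
        best_t = -1
        best_j = -1
        for j in range(n):
            if ismed[j]:
                continue
            Dj = D[j]  # D is symmetric: row access is contiguous
            shared = 0.0
            for t in range(k):
                corr[t] = 0.0
            for i in range(n):
                dij = Dj[i]
                g = dij - d1[i]
                s = g if g < 0.0 else 0.0
                shared += s
                v = (dij if dij < d2[i] else d2[i]) - d1[i]
                corr[t1[i]] += v - s
            for t in range(k):
                delta = shared + corr[t]
                if delta < best_delta:
                    best_delta = delta
                    best_t = t
                    best_j = j
        if best_t < 0:
            break
        ismed[med[best_t]] = False
        med[best_t] = best_j
        ismed[best_j] = True
    cost = 0.0
    for i in range(n):
        b1 = np.inf
        for t in range(k):
            d = D[i, med[t]]
            if d < b1:
                b1 = d
        cost += b1
    return med, cost


def _swap_until_converged_np(D, med, max_passes):
    n = D.shape[0]
    k = med.shape[0]
    for _ in range(max_passes):
        dmed = D[:, med]
        t1 = dmed.argmin(axis=1)
        rows = np.arange(n)
        d1 = dmed[rows, t1]
        dmed2 = dmed.copy()
        dmed2[rows, t1] = np.inf
        d2 = dmed2.min(axis=1)

        ismed = np.zeros(n, dtype=bool)
        ismed[med] = True
        cands = np.flatnonzero(~ismed)
        Dj = D[:, cands]
        g = Dj - d1[:, None]
        s = np.minimum(g, 0.0)
        shared = s.sum(axis=0)
        corr_term = np.minimum(Dj, d2[:, None]) - d1[:, None] - s
        corr = np.zeros((k, cands.size))
        np.add.at(corr, t1, corr_term)
        delta = shared[None, :] + corr
        # lowest (t, j) index wins among exact ties: argmin returns the first
        flat = int(delta.argmin())
        best_t, best_jc = divmod(flat, cands.size)
        if delta[best_t, best_jc] >= -_EPS:
            break
        med[best_t] = cands[best_jc]
    d1 = D[:, med].min(axis=1)
    return med, float(d1.sum())


def _voronoi_refine_np(D, med, max_iter):
    n = D.shape[0]
    k = med.shape[0]
    for _ in range(max_iter):
        assign = D[:, med].argmin(axis=1)
        changed = False
        for t in range(k):
            idx = np.flatnonzero(assign == t)
            if idx.size == 0:
                continue
            costs = D[np.ix_(idx, idx)].sum(axis=1)
            j = int(idx[int(costs.argmin())])
            if j != med[t]:
                med[t] = j
                changed = True
        if not changed:
            break
    return med


def _build_init(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD seeding: repeatedly add the medoid that cuts cost most."""
    n = D.shape[0]
    med = [int(D.sum(axis=1).argmin())]
    dnear = D[:, med[0]].copy()
    for _ in range(1, k):
        reduction = np.maximum(dnear[:, None] - D, 0.0).sum(axis=0)
        reduction[med] = -np.inf
        j = int(reduction.argmax())
        med.append(j)
        np.minimum(dnear, D[:, j], out=dnear)
    return np.array(med, dtype=np.int64)


def pam_kmedoids(
    dm: DistanceMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    *,
    init: str = "build",
    max_passes: int = 0,
) -> tuple[np.ndarray, float]:
    """PAM (BUILD + SWAP) on a precomputed distance matrix.

    Returns ``(medoid_indices, cost)`` with indices sorted ascending and
    ``cost`` the sum over all points of the distance to the nearest medoid.
    ``init='build'`` uses the deterministic greedy seeding; ``init='random'``
    draws k distinct start medoids from ``seed``. Deterministic given
    (matrix, k, seed, init); ties break toward the lowest matrix index.
    """
    D = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside [1, n={n}]")
    if k == n:
        return np.arange(n, dtype=np.int64), 0.0
    Dc = np.ascontiguousarray(D, dtype=np.float64)
    if init == "build":
        med = _build_init(Dc, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        med = np.sort(rng.choice(n, size=k, replace=False)).astype(np.int64)
        refine = _voronoi_refine_nb if _HAVE_NUMBA else _voronoi_refine_np
        med = refine(Dc, med, 20)
    else:
        raise ParameterError(f"unknown init {init!r}")
    if max_passes <= 0:
        max_passes = 2 + 20 * k
    swap = _swap_until_converged_nb if _HAVE_NUMBA else _swap_until_converged_np
    med, cost = swap(Dc, med, max_passes)
    return np.sort(np.asarray(med)), float(cost)


def pam_best_of(
    dm: DistanceMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 20,
) -> tuple[np.ndarray, float]:
    """Best-cost PAM solution over one BUILD-seeded and r−1 random restarts."""
    best_med, best_cost = pam_kmedoids(dm, k, seed, init="build")
    for r in range(1, restarts):
        med, cost = pam_kmedoids(dm, k, seed + r, init="random")
        if cost < best_cost - _EPS:
            best_med, best_cost = med, cost
    return best_med, best_cost


# ---------------------------------------------------------------------------
# Coverage criterion
# ---------------------------------------------------------------------------


def coverage_fraction(
    dm: DistanceMatrix | np.ndarray,
    rep_indices: Sequence[int] | np.ndarray,
    threshold: float,
) -> float:
    """Fraction of all sequences within ``threshold`` of a representative.

    Representatives count themselves (distance 0). The comparison is
    inclusive: distance == threshold is covered.
    """
    D = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    reps = np.asarray(list(rep_indices), dtype=np.int64)
    if reps.size == 0:
        raise ParameterError("representative set must be non-empty")
    dmin = D[:, reps].min(axis=1)
    return float((dmin <= threshold).mean())


@dataclass(frozen=True)
class SelectionParams:
    """Knobs of the minimal-k coverage search.

    ``divergence_threshold`` is the practical hybridization limit (fraction of
    mismatching sites); ``coverage_target`` the fraction of sequences that
    must fall within it; k is searched over [k_min, k_max] with up to
    ``restarts`` PAM runs per k.
    """

    divergence_threshold: float = 0.30
    coverage_target: float = 0.95
    k_min: int = 5
    k_max: int = 15
    restarts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.divergence_threshold < 1:
            raise ParameterError("divergence_threshold must be in (0, 1)")
        if not 0 < self.coverage_target <= 1:
            raise ParameterError("coverage_target must be in (0, 1]")
        if not 1 <= self.k_min <= self.k_max:
            raise ParameterError("need 1 <= k_min <= k_max")
        if self.restarts < 1:
            raise ParameterError("restarts must be >= 1")


@dataclass(frozen=True)
class MedoidSolution:
    """Outcome of minimal-k selection for one gene."""

    gene_id: str
    k: int
    medoid_ids: tuple[str, ...]
    coverage: float
    cost: float
    status: str  # "passed" | "failed"
    restarts_used: int
    seed: int  # derived seed of the restart that produced this solution

    @property
    def passed(self) -> bool:
        return self.status == "passed"


def derive_seed(master: int, *parts: object) -> int:
    """Deterministic cross-platform seed ladder (CRC32 of a tagged string)."""
    tag = "|".join([str(master), *map(str, parts)])
    return zlib.crc32(tag.encode("utf-8")) & 0x7FFFFFFF


def select_minimal_medoids(
    dm: DistanceMatrix,
    params: SelectionParams,
    gene_id: str = "",
) -> MedoidSolution:
    """Smallest k in [k_min, k_max] whose medoids meet the coverage target.

    For each k (ascending) up to ``restarts`` PAM runs are tried; the first
    restart whose medoid set reaches ``coverage_target`` is accepted (early
    stop). If no k qualifies, the best solution seen (highest coverage, then
    lowest cost) is returned with status ``"failed"``.
    """
    n = dm.n
    best: MedoidSolution | None = None
    for k in range(params.k_min, min(params.k_max, n) + 1):
        for r in range(params.restarts):
            run_seed = derive_seed(params.seed, gene_id, k, r)
            med, cost = pam_kmedoids(
                dm, k, run_seed, init="build" if r == 0 else "random"
            )
            cov = coverage_fraction(dm, med, params.divergence_threshold)
            sol = MedoidSolution(
                gene_id=gene_id,
                k=k,
                medoid_ids=tuple(dm.ids[i] for i in med),
                coverage=cov,
                cost=cost,
                status="passed" if cov >= params.coverage_target else "failed",
                restarts_used=r + 1,
                seed=run_seed,
            )
            if sol.passed:
                return sol
            if (
                best is None
                or sol.coverage > best.coverage
                or (sol.coverage == best.coverage and sol.cost < best.cost)
            ):
                best = sol
    assert best is not None
    return best


def evaluate_reference_set(
    dm: DistanceMatrix,
    reference_ids: Iterable[str],
    threshold: float,
) -> float:
    """Coverage of the non-reference sequences by a fixed reference set.

    Used to compare medoid selection against representation by available
    genome sequences alone: the fraction of transcripts (non-references)
    within ``threshold`` of their nearest reference.
    """
    refs = sorted(set(reference_ids))
    if not refs:
        raise ParameterError("reference set must be non-empty")
    ref_idx = np.array([dm.index(r) for r in refs], dtype=np.int64)
    if ref_idx.size >= dm.n:
        raise ParameterError("reference set must not contain every sequence")
    mask = np.ones(dm.n, dtype=bool)
    mask[ref_idx] = False
    dmin = dm.values[np.ix_(mask, ref_idx)].min(axis=1)
    return float((dmin <= threshold).mean())
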