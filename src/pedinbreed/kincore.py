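"""Relationship/kinship primitives and the classical inbreeding algorithms.

Everything here works on the LAP-sorted :class:`~pedinbreed.pedio.Pedigree`.
The additive relationship matrix factors as ``A = L D L'`` where row ``s``
of the unit lower-triangular ``L`` holds the fraction of genes animal ``s``
inherits from each ancestor and ``D`` holds within-family (Mendelian
sampling) variances.  Hence ``F_s = A_ss - 1 = sum_k L_sk^2 D_kk - 1``.

Two exact dense oracles (:func:`tabular_a`, :func:`kinship_recursive`) back
the property-test suites; :func:`inbreeding_ml` and :func:`inbreeding_si`
are the classical per-animal traversal algorithms that the indirect solvers
in :mod:`pedinbreed.indirect` are compared against.
"""

from __future__ import annotations

import heapq
import math
import sys
from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, OracleSizeError
from .pedio import Pedigree
from .results import Diagnostics, FResult

#: Default cap for dense-matrix oracles (memory contract ~200 MB).
ORACLE_CAP = 5000


def mendelian_variance(f_sire: float, f_dam: float) -> float:
    """Within-family additive variance ``0.5 - 0.25 (F_sire + F_dam)``.

    A metafounder parent contributes ``F = gamma - 1``; with both parents
    gamma-0 metafounders this yields 1.0, consistent with ``A_ii = 1`` for
    a classical founder.
    """
    return 0.5 - 0.25 * (f_sire + f_dam)


def d_vector(ped: Pedigree, f: np.ndarray) -> np.ndarray:
    """Mendelian-variance vector given finalized inbreeding coefficients."""
    d = ped.d_template()
    m = ped.n_meta
    d[m:] = 0.5 - 0.25 * (f[ped.sire[m:]] + f[ped.dam[m:]])
    return d


# ---------------------------------------------------------------------------
# dense oracles


def tabular_a(ped: Pedigree, cap: int = ORACLE_CAP) -> np.ndarray:
    """Dense additive relationship matrix built row by row (the oracle).

    ``A[m, m] = gamma_m`` for metafounders (distinct metafounders are
    unrelated); for a real animal ``i``:
    ``A[i, j] = 0.5 (A[s_i, j] + A[d_i, j])`` for ``j < i`` and
    ``A[i, i] = 1 + 0.5 A[s_i, d_i]``.
    """
    n = ped.n
    if n > cap:
        raise OracleSizeError(f"dense oracle capped at {cap} animals, got {n}")
    a = np.zeros((n, n), dtype=np.float64)
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        if ped.is_meta[i]:
            a[i, i] = ped.gamma[i]
            continue
        s, d = sire[i], dam[i]
        row = 0.5 * (a[s, :i] + a[d, :i])
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + 0.5 * a[s, d]
    return a


def kinship_recursive(
    ped: Pedigree, i: int, j: int, memo: dict | None = None
) -> float:
    """Additive relationship ``A[i, j]`` by memoized recursion.

    The standard descent recursion with metafounder base cases
    (``A[m, m] = gamma_m``, distinct metafounders unrelated).  Passing a
    shared ``memo`` across calls reuses previously computed pairs.
    """
    if memo is None:
        memo = {}
    sire, dam, is_meta, gamma = ped.sire, ped.dam, ped.is_meta, ped.gamma

    def kin(a: int, b: int) -> float:
        if a < b:
            a, b = b, a
        key = (a, b)
        v = memo.get(key)
        if v is not None:
            return v
        if a == b:
            v = gamma[a] if is_meta[a] else 1.0 + 0.5 * kin(sire[a], dam[a])
        elif is_meta[a]:
            v = 0.0  # a <= every real index, so b is a distinct metafounder
        else:
            v = 0.5 * (kin(sire[a], b) + kin(dam[a], b))
        memo[key] = v
        return v

    return kin(int(i), int(j))


def inbreeding_rec(ped: Pedigree) -> FResult:
    """F for all animals via memoized pair recursion (REC-style oracle)."""
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000 + 50 * ped.max_lap))
    try:
        f = ped.f_template()
        memo: dict = {}
        for i in range(ped.n_meta, ped.n):
            f[i] = 0.5 * kinship_recursive(ped, ped.sire[i], ped.dam[i], memo)
    finally:
        sys.setrecursionlimit(old)
    return FResult(f=f, algorithm="rec")


def inbreeding_tabular(ped: Pedigree, cap: int = ORACLE_CAP) -> FResult:
    """F as the diagonal of the dense tabular matrix minus one."""
    a = tabular_a(ped, cap=cap)
    f = np.diag(a).copy()
    f -= 1.0
    return FResult(f=f, algorithm="tabular")


# ---------------------------------------------------------------------------
# sparse L rows


@dataclass
class SparseLRow:
    """Nonzeros of one row of L, in descending-LAP emission order.

    Entries cover exactly the ancestors of ``owner`` (the animal itself
    included); ``L[owner, owner] = 1``.
    """

    owner: int
    indices: np.ndarray
    coefs: np.ndarray

    @property
    def entries(self) -> dict[int, float]:
        return dict(zip(self.indices.tolist(), self.coefs.tolist()))

    def dot_d(self, d: np.ndarray) -> float:
        """``sum_k L_sk^2 D_kk`` which equals ``A_ss = 1 + F_s``."""
        return float(np.dot(self.coefs**2, d[self.indices]))

    def __len__(self) -> int:
        return int(self.indices.shape[0])


def l_row(ped: Pedigree, s: int, d: np.ndarray | None = None) -> SparseLRow:
    """Compute row ``s`` of L by descending-LAP bucket traversal.

    Starting from coefficient 1 at ``s``, repeatedly pop the highest-LAP
    pending animal, emit its coefficient, and push half of it onto each
    parent.  Within a LAP bucket animals are popped in ascending index
    order, making the emission order deterministic.

    ``d`` is only used for a consistency check: if given, every emitted
    ancestor must have a finalized Mendelian variance.
    """
    lap, sire, dam = ped.lap, ped.sire, ped.dam
    top = int(lap[s])
    buckets: list[dict[int, float]] = [dict() for _ in range(top + 1)]
    buckets[top][int(s)] = 1.0
    out_idx: list[int] = []
    out_coef: list[float] = []
    for level in range(top, -1, -1):
        b = buckets[level]
        for k in sorted(b):
            c = b[k]
            out_idx.append(k)
            out_coef.append(c)
            sp = sire[k]
            if sp >= 0:
                bb = buckets[lap[sp]]
                bb[sp] = bb.get(sp, 0.0) + 0.5 * c
            dp = dam[k]
            if dp >= 0:
                bb = buckets[lap[dp]]
                bb[dp] = bb.get(dp, 0.0) + 0.5 * c
    idx = np.array(out_idx, dtype=np.int64)
    coef = np.array(out_coef, dtype=np.float64)
    if d is not None and np.isnan(d[idx]).any():
        bad = idx[np.isnan(d[idx])][0]
        raise ConsistencyError(
            f"Mendelian variance of ancestor {int(bad)} not finalized"
        )
    return SparseLRow(owner=int(s), indices=idx, coefs=coef)


# ---------------------------------------------------------------------------
# classical per-animal algorithms


def inbreeding_ml(ped: Pedigree) -> FResult:
    """Meuwissen & Luo style: per-animal ancestor traversal by descending
    identification number, accumulating ``L^2 D`` on the fly."""
    n = ped.n
    f = ped.f_template()
    d = ped.d_template()
    sire, dam = ped.sire, ped.dam
    for i in range(ped.n_meta, n):
        d[i] = mendelian_variance(f[sire[i]], f[dam[i]])
        coef: dict[int, float] = {i: 1.0}
        heap = [-i]
        acc = 0.0
        while heap:
            k = -heapq.heappop(heap)
            c = coef.pop(k, None)
            if c is None:
                continue  # lazily deleted duplicate
            dk = d[k]
            if math.isnan(dk):
                raise ConsistencyError(
                    f"Mendelian variance of ancestor {k} not finalized"
                )
            acc += c * c * dk
            for p in (sire[k], dam[k]):
                if p >= 0:
                    if p in coef:
                        coef[p] += 0.5 * c
                    else:
                        coef[p] = 0.5 * c
                        heapq.heappush(heap, -p)
        f[i] = acc - 1.0
    return FResult(f=f, algorithm="ml")


def inbreeding_si(ped: Pedigree) -> FResult:
    """Sargolzaei & Iwaisaki style: same contract as :func:`inbreeding_ml`
    but each traversal visits ancestors in descending LAP order via
    :func:`l_row`."""
    n = ped.n
    f = ped.f_template()
    d = ped.d_template()
    diag = Diagnostics()
    for i in range(ped.n_meta, n):
        d[i] = mendelian_variance(f[ped.sire[i]], f[ped.dam[i]])
        row = l_row(ped, i, d)
        diag.l_row_entries += len(row)
        f[i] = row.dot_d(d) - 1.0
    return FResult(f=f, algorithm="si", diagnostics=diag)
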