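"""Indirect inbreeding solvers: original (I) and modified (MI).

Both methods exploit the identity ``F_j = 0.5 * A[d_j, s]``: one solve of
``A^-1 y = x`` (unit vector at sire ``s``) yields the sire's column of A
and with it F for *all* progeny of ``s``, so large half-sib families share
the work.

The original method (:func:`inbreeding_i`) runs a backward substitution
over a reduced pedigree followed by a *full* forward substitution up to the
sire's highest-numbered mate.  The modified method (:func:`inbreeding_mi`)
replaces the backward pass by directly computing the sire's sparse row of L
(descending-LAP traversal) and replaces the full forward pass by a flagged
recursion that touches only the mates' ancestors, with a sparse workspace
reset whose cost is proportional to the entries actually written.

Animals are processed in ascending LAP blocks; equal-LAP animals share no
parent-progeny links, so sire groups inside a block are independent and can
be evaluated in parallel with bitwise-identical results.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import ConsistencyError, ValidationError
from .kincore import l_row
from .pedio import NO_PARENT, Pedigree
from .results import Diagnostics, FResult

__all__ = [
    "SireWorkspace",
    "ReducedPedigree",
    "build_reduced_pedigree",
    "iter_sire_groups",
    "evaluate_sire_group",
    "y_recurse",
    "reset_workspace",
    "inbreeding_i",
    "inbreeding_mi",
]


class SireWorkspace:
    """Reusable per-worker buffers for one sire evaluation.

    Outside an evaluation ``y`` is all-zero and ``flag``/``seeded`` are
    all-false; :func:`reset_workspace` restores that state by rewriting
    only the entries recorded in ``touched``.
    """

    __slots__ = ("n", "y", "flag", "seeded", "_touched", "n_touched",
                 "_stack", "owner_sire")

    def __init__(self, n: int):
        self.n = n
        self.y = np.zeros(n, dtype=np.float64)
        self.flag = np.zeros(n, dtype=bool)
        self.seeded = np.zeros(n, dtype=bool)
        self._touched = np.empty(n, dtype=np.int64)
        self.n_touched = 0
        self._stack = np.empty(2 * n + 4, dtype=np.int64)
        self.owner_sire = -1

    @property
    def touched(self) -> np.ndarray:
        """Indices written since the last reset (no duplicates)."""
        return self._touched[: self.n_touched]

    def seed(self, indices: np.ndarray, values: np.ndarray,
             meta_mask: np.ndarray) -> None:
        """Install D*L seed terms; metafounder seeds are final (flagged)."""
        self.y[indices] = values
        self.seeded[indices] = True
        self.flag[indices[meta_mask]] = True
        k = indices.shape[0]
        self._touched[self.n_touched : self.n_touched + k] = indices
        self.n_touched += k

    def assert_clean(self) -> None:
        """Debug full-array scan of the sparse-reset contract."""
        if self.y.any() or self.flag.any() or self.seeded.any():
            raise ConsistencyError("workspace not clean after reset")


def reset_workspace(ws: SireWorkspace) -> None:
    """Zero ``y``/``flag``/``seeded`` at touched entries only (O(touched))."""
    t = ws.touched
    ws.y[t] = 0.0
    ws.flag[t] = False
    ws.seeded[t] = False
    ws.n_touched = 0
    ws.owner_sire = -1


def y_recurse(ped: Pedigree, i: int, ws: SireWorkspace,
              diag: Diagnostics | None = None) -> float:
    """Return ``y[i] = A[i, s]`` for the currently seeded sire ``s``.

    Flagged entries are returned as-is; unflagged entries are computed as
    ``0.5 (y_sire + y_dam) + D L_s`` (the seed term, zero off the sire's
    ancestor set) exactly once, metafounders terminating the recursion.
    """
    mates = np.array([i], dtype=np.int64)
    ws.n_touched, computed = _kernels.recurse_y_many(
        mates, ped.sire, ped.dam, ws.y, ws.flag, ws.seeded,
        ws._touched, ws.n_touched, ws._stack,
    )
    if diag is not None:
        diag.elements_computed_forward += computed
    return float(ws.y[i])


def evaluate_sire_group(
    ped: Pedigree,
    s: int,
    mates,
    f: np.ndarray,
    d: np.ndarray,
    ws: SireWorkspace,
    diag: Diagnostics | None = None,
) -> dict[int, float]:
    """Evaluate one (sire, LAP-block) group; returns ``{mate: F_progeny}``.

    Preconditions: F and D finalized for every animal with LAP below the
    current block's LAP (checked against NaN sentinels), and the workspace
    clean.  The caller is responsible for :func:`reset_workspace`.
    """
    row = l_row(ped, s, d)  # raises if an ancestor's D is unfinalized
    ws.owner_sire = int(s)
    idx = row.indices
    ws.seed(idx, d[idx] * row.coefs, ped.is_meta[idx])
    mates_arr = np.asarray(sorted(int(m) for m in mates), dtype=np.int64)
    ws.n_touched, computed = _kernels.recurse_y_many(
        mates_arr, ped.sire, ped.dam, ws.y, ws.flag, ws.seeded,
        ws._touched, ws.n_touched, ws._stack,
    )
    if diag is not None:
        diag.elements_computed_forward += computed
        diag.l_row_entries += len(row)
        diag.sire_groups += 1
    return {int(m): 0.5 * float(ws.y[m]) for m in mates_arr}


def iter_sire_groups(ped: Pedigree):
    """Yield ``(block_start, block_stop, groups)`` per real LAP block.

    ``groups`` is ``[(sire, {dam: [progeny, ...]}), ...]`` in ascending
    sire order; dams within a group map to all their progeny by that sire
    inside the block.  Animals whose sire slot is a metafounder are grouped
    under that metafounder.
    """
    sire, dam = ped.sire, ped.dam
    for start, stop in ped.lap_blocks:
        if ped.lap[start] == 0:
            continue
        groups: dict[int, dict[int, list[int]]] = {}
        for j in range(start, stop):
            groups.setdefault(int(sire[j]), {}).setdefault(int(dam[j]), []).append(j)
        yield start, stop, [(s, groups[s]) for s in sorted(groups)]


def _run_mi_chunk(ped, chunk, f, d, ws, diag):
    for s, mates in chunk:
        res = evaluate_sire_group(ped, s, mates.keys(), f, d, ws, diag)
        for m, progeny in mates.items():
            fm = res[m]
            for j in progeny:
                f[j] = fm
        reset_workspace(ws)


def inbreeding_mi(ped: Pedigree, workers: int = 1) -> FResult:
    """Modified indirect method with LAP-block parallel scheduling.

    Within each ascending-LAP block, sire groups are partitioned into
    contiguous chunks across ``workers`` threads, each owning a private
    :class:`SireWorkspace`; progeny F writes are disjoint by construction
    so the result is bitwise-identical for any worker count.
    """
    if workers < 1:
        raise ValidationError("workers must be >= 1")
    n = ped.n
    f = ped.f_template()
    d = ped.d_template()
    wss = [SireWorkspace(n) for _ in range(workers)]
    diags = [Diagnostics() for _ in range(workers)]
    pool = ThreadPoolExecutor(max_workers=workers) if workers > 1 else None
    try:
        for start, stop, groups in iter_sire_groups(ped):
            if workers == 1 or len(groups) < 2 * workers:
                _run_mi_chunk(ped, groups, f, d, wss[0], diags[0])
            else:
                bounds = np.linspace(0, len(groups), workers + 1).astype(int)
                futures = [
                    pool.submit(_run_mi_chunk, ped,
                                groups[bounds[w] : bounds[w + 1]],
                                f, d, wss[w], diags[w])
                    for w in range(workers)
                ]
                for fut in futures:
                    fut.result()
            sl = slice(start, stop)
            d[sl] = 0.5 - 0.25 * (f[ped.sire[sl]] + f[ped.dam[sl]])
    finally:
        if pool is not None:
            pool.shutdown()
    diag = Diagnostics()
    for dg in diags:
        diag.merge(dg)
    return FResult(f=f, algorithm="mi", diagnostics=diag, workers=workers)


# ---------------------------------------------------------------------------
# original indirect method


@dataclass
class ReducedPedigree:
    """Closure of evaluated sires, their mates and all their ancestors.

    ``kept`` lists original indices in ascending (topological) order;
    ``red_of`` maps original index -> reduced index (-1 if dropped);
    ``mip`` maps each sire to its highest-reduced-index mate.
    """

    kept: np.ndarray
    red_of: np.ndarray
    r_sire: np.ndarray
    r_dam: np.ndarray
    mip: dict[int, int] = field(default_factory=dict)
    mates: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.kept.shape[0])


def build_reduced_pedigree(ped: Pedigree, sires) -> ReducedPedigree:
    """Transitive-closure extraction preserving topological order."""
    sires = sorted(int(s) for s in sires)
    if not sires:
        raise ValidationError("sires set must be non-empty")
    sire_set = set(sires)
    mates: dict[int, set[int]] = {s: set() for s in sires}
    for j in range(ped.n_meta, ped.n):
        s = int(ped.sire[j])
        if s in sire_set:
            mates[s].add(int(ped.dam[j]))
    keep = np.zeros(ped.n, dtype=bool)
    stack = list(sire_set)
    for ms in mates.values():
        stack.extend(ms)
    while stack:
        k = stack.pop()
        if keep[k]:
            continue
        keep[k] = True
        sp = ped.sire[k]
        if sp >= 0 and not keep[sp]:
            stack.append(int(sp))
        dp = ped.dam[k]
        if dp >= 0 and not keep[dp]:
            stack.append(int(dp))
    kept = np.nonzero(keep)[0].astype(np.int64)
    red_of = np.full(ped.n, -1, dtype=np.int64)
    red_of[kept] = np.arange(kept.shape[0])
    osire = ped.sire[kept]
    odam = ped.dam[kept]
    r_sire = np.where(osire >= 0, red_of[np.maximum(osire, 0)], NO_PARENT)
    r_dam = np.where(odam >= 0, red_of[np.maximum(odam, 0)], NO_PARENT)
    mip = {s: int(red_of[sorted(ms)].max()) if ms else -1
           for s, ms in mates.items()}
    return ReducedPedigree(
        kept=kept,
        red_of=red_of,
        r_sire=r_sire.astype(np.int64),
        r_dam=r_dam.astype(np.int64),
        mip=mip,
        mates={s: sorted(ms) for s, ms in mates.items()},
    )


def inbreeding_i(ped: Pedigree) -> FResult:
    """Original indirect method over one global reduced pedigree.

    Per (sire, LAP-block) group: backward substitution computes the
    nonzero ``z`` entries from the sire's reduced position down to the
    start of the reduced pedigree, then a full forward substitution runs
    over *every* reduced position up to the group's highest-numbered mate
    (each computed element is counted), and F of each progeny is half the
    ``y`` entry of its dam.
    """
    n = ped.n
    f = ped.f_template()
    d = ped.d_template()
    sires = np.unique(ped.sire[ped.n_meta :])
    red = build_reduced_pedigree(ped, sires.tolist())
    nred = red.n
    z = np.zeros(nred, dtype=np.float64)
    y = np.empty(nred, dtype=np.float64)
    dred = np.empty(nred, dtype=np.float64)
    diag = Diagnostics()
    for start, stop, groups in iter_sire_groups(ped):
        dred[:] = d[red.kept]  # D finalized for every earlier block
        for s, mates in groups:
            rs = int(red.red_of[s])
            _kernels.backward_scatter(rs, red.r_sire, red.r_dam, z)
            mip = max(int(red.red_of[m]) for m in mates)
            m_stop = mip + 1
            _kernels.forward_full(m_stop, red.r_sire, red.r_dam, dred, z, y)
            diag.elements_computed_forward += m_stop
            diag.sire_groups += 1
            for m, progeny in mates.items():
                fm = 0.5 * float(y[red.red_of[m]])
                for j in progeny:
                    f[j] = fm
            z[: rs + 1] = 0.0
        sl = slice(start, stop)
        d[sl] = 0.5 - 0.25 * (f[ped.sire[sl]] + f[ped.dam[sl]])
    return FResult(f=f, algorithm="i", diagnostics=diag)
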