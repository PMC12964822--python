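"""Hot loops, JIT-compiled with numba when available.

Each kernel operates on flat int64/float64/bool arrays so the same source
works compiled or interpreted (pure-Python fallback when numba is absent).
"""

from __future__ import annotations

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(nogil=True)
def recurse_y_many(mates, sire, dam, y, flag, seeded, touched, tptr, stack):
    # Flagged recursive forward substitution over the ancestors of every
    # mate, realized as an explicit stack (supports arbitrary depth).
    # y holds D*L seed terms at seeded positions; flag marks finalized
    # entries; newly written non-seed positions are appended to touched.
    # stack must have room for 2n + 2 entries (each node triggers at most
    # one push of each of its parents before it is finalized).
    # Returns (new touched length, number of elements computed).
    computed = 0
    for mi in range(mates.shape[0]):
        i = mates[mi]
        if flag[i]:
            continue
        top = 0
        stack[top] = i
        top = 1
        while top > 0:
            k = stack[top - 1]
            if flag[k]:
                top -= 1
                continue
            s = sire[k]
            if s < 0:  # metafounder: seed (or zero) is final
                flag[k] = True
                computed += 1
                if not seeded[k]:
                    touched[tptr] = k
                    tptr += 1
                top -= 1
                continue
            d = dam[k]
            fs = flag[s]
            fd = flag[d]
            if fs and fd:
                y[k] += 0.5 * (y[s] + y[d])
                flag[k] = True
                computed += 1
                if not seeded[k]:
                    touched[tptr] = k
                    tptr += 1
                top -= 1
            else:
                if not fd:
                    stack[top] = d
                    top += 1
                if not fs and s != d:
                    stack[top] = s
                    top += 1
    return tptr, computed


@njit(nogil=True)
def backward_scatter(rs, r_sire, r_dam, z):
    # z = L' x for unit x at reduced position rs: descending scatter of
    # half of each finalized z entry onto both parents.
    z[rs] = 1.0
    for j in range(rs, -1, -1):
        zj = z[j]
        if zj != 0.0:
            sp = r_sire[j]
            if sp >= 0:
                z[sp] += 0.5 * zj
            dp = r_dam[j]
            if dp >= 0:
                z[dp] += 0.5 * zj


@njit(nogil=True)
def forward_full(m, r_sire, r_dam, dred, z, y):
    # Full forward substitution y = L (D z) over reduced positions < m.
    for i in range(m):
        acc = dred[i] * z[i]
        sp = r_sire[i]
        if sp >= 0:
            acc += 0.5 * y[sp]
        dp = r_dam[i]
        if dp >= 0:
            acc += 0.5 * y[dp]
        y[i] = acc
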