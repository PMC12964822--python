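"""Pedigree I/O, cleaning, metafounder assignment and LAP sorting.

The pipeline implemented here turns a plain-text pedigree file into the
renumbered, longest-ancestral-path (LAP) sorted :class:`Pedigree` consumed
by every inbreeding algorithm in the package:

``read_pedigree`` -> ``add_missing_parents`` -> ``impute_birth_years`` ->
``fix_birth_order_errors`` -> ``assign_metafounders`` -> ``build_pedigree``

Unknown parents are represented by metafounders, pseudo-animals with a
configurable self-relationship ``gamma``; with ``gamma = 0`` a metafounder
behaves exactly like a classical unrelated founder and contributes nothing
to inbreeding.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import CycleError, ParseError, ValidationError
from .results import FResult

#: Sentinel used in index arrays for "no parent" (metafounders only).
NO_PARENT = -1

#: Tokens that denote an unknown parent or a missing birth year in files.
DEFAULT_UNKNOWN_TOKENS = ("0", "", ".", "NA")


@dataclass(frozen=True, slots=True)
class PedRecord:
    """One raw pedigree record; ``None`` marks an unknown parent/year."""

    animal: str
    sire: str | None
    dam: str | None
    year: int | None = None
    is_meta: bool = False


@dataclass
class RawPedigree:
    """Parsed but not yet renumbered pedigree.

    Records keep their file order.  ``meta_gamma`` maps metafounder ids to
    their self-relationship; it is empty until
    :func:`assign_metafounders` has run.
    """

    records: list[PedRecord]
    meta_gamma: dict[str, float] = field(default_factory=dict)

    @property
    def id_set(self) -> set[str]:
        return {r.animal for r in self.records}

    def index(self) -> dict[str, int]:
        """Map animal id -> position in ``records``."""
        return {r.animal: i for i, r in enumerate(self.records)}

    @property
    def n_meta(self) -> int:
        return sum(r.is_meta for r in self.records)


@dataclass(frozen=True)
class MetafounderPolicy:
    """How unknown parents are grouped into metafounders.

    One metafounder is created per occupied birth-year bin of width
    ``bin_width_years``; it serves as both sire and dam within its bin
    unless ``sex_split`` is set.  Unknown parents of animals without an
    establishable birth year fall back to the earliest occupied bin.
    """

    bin_width_years: int = 1
    gamma_default: float = 0.0
    per_metafounder_gamma: dict[int, float] | None = None
    sex_split: bool = False

    def __post_init__(self) -> None:
        if self.bin_width_years < 1:
            raise ValidationError("bin_width_years must be a positive integer")
        gammas = [self.gamma_default]
        if self.per_metafounder_gamma:
            gammas.extend(self.per_metafounder_gamma.values())
        for g in gammas:
            if not (0.0 <= g < 1.0):
                raise ValidationError(f"gamma must lie in [0, 1), got {g}")

    def gamma_for(self, bin_start: int) -> float:
        if self.per_metafounder_gamma:
            return self.per_metafounder_gamma.get(bin_start, self.gamma_default)
        return self.gamma_default


@dataclass
class Pedigree:
    """Renumbered, LAP-sorted pedigree.

    Indices are 0-based; metafounders occupy ``0 .. n_meta-1``.  For every
    real animal both ``sire`` and ``dam`` are valid indices smaller than
    the animal's own index; metafounders carry :data:`NO_PARENT`.
    """

    n: int
    n_meta: int
    sire: np.ndarray
    dam: np.ndarray
    lap: np.ndarray
    is_meta: np.ndarray
    gamma: np.ndarray
    orig_id: list[str]
    input_pos: np.ndarray
    lap_blocks: list[tuple[int, int]]

    @property
    def max_lap(self) -> int:
        return int(self.lap[-1]) if self.n else 0

    def f_template(self) -> np.ndarray:
        """F array with metafounder entries (= gamma - 1) pre-filled."""
        f = np.full(self.n, np.nan)
        f[: self.n_meta] = self.gamma[: self.n_meta] - 1.0
        return f

    def d_template(self) -> np.ndarray:
        """Mendelian-variance array with metafounder entries pre-filled."""
        d = np.full(self.n, np.nan)
        d[: self.n_meta] = self.gamma[: self.n_meta]
        return d


# ---------------------------------------------------------------------------
# reading / writing


def _sniff_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # any whitespace


def read_pedigree(
    path,
    delimiter: str | None = None,
    unknown_tokens: Sequence[str] = DEFAULT_UNKNOWN_TOKENS,
) -> RawPedigree:
    """Parse a delimited pedigree file.

    Each data line holds ``animal sire dam [birth_year]``.  The delimiter
    is auto-detected from the first data line (tab, comma, else any
    whitespace) unless given explicitly.  Lines starting with ``#`` and
    blank lines are skipped.

    Raises
    ------
    ParseError
        Malformed line (fewer than three columns, unparsable year),
        reported with its line number.
    ValidationError
        Duplicate animal id or an animal recorded as its own parent.
    """
    unknown = set(unknown_tokens)
    records: list[PedRecord] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is None:
                delimiter = _sniff_delimiter(line) or " "
            if delimiter == " ":
                cols = line.split()
            else:
                cols = [c.strip() for c in line.split(delimiter)]
            if len(cols) < 3:
                raise ParseError(
                    f"line {lineno}: expected at least 3 columns, got {len(cols)}"
                )
            animal = cols[0]
            if animal in unknown:
                raise ParseError(f"line {lineno}: invalid animal id {animal!r}")
            if animal in seen:
                raise ValidationError(f"line {lineno}: duplicate animal id {animal!r}")
            seen.add(animal)
            sire = None if cols[1] in unknown else cols[1]
            dam = None if cols[2] in unknown else cols[2]
            if animal in (sire, dam):
                raise ValidationError(
                    f"line {lineno}: animal {animal!r} is recorded as its own parent"
                )
            year: int | None = None
            if len(cols) >= 4 and cols[3] not in unknown:
                try:
                    year = int(cols[3])
                except ValueError as exc:
                    raise ParseError(
                        f"line {lineno}: unparsable birth year {cols[3]!r}"
                    ) from exc
            records.append(PedRecord(animal, sire, dam, year))
    return RawPedigree(records)


def write_pedigree(ped: RawPedigree, path, delimiter: str = "\t") -> None:
    """Write a raw pedigree back to disk (inverse of :func:`read_pedigree`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in ped.records:
            year = "" if r.year is None else str(r.year)
            fields = [r.animal, r.sire or "0", r.dam or "0", year]
            fh.write(delimiter.join(fields).rstrip(delimiter) + "\n")


def add_missing_parents(ped: RawPedigree) -> tuple[RawPedigree, int]:
    """Append founder records for parents referenced but not recorded."""
    ids = ped.id_set
    missing: list[str] = []
    seen: set[str] = set()
    for r in ped.records:
        for p in (r.sire, r.dam):
            if p is not None and p not in ids and p not in seen:
                missing.append(p)
                seen.add(p)
    new_records = list(ped.records) + [PedRecord(p, None, None, None) for p in missing]
    return RawPedigree(new_records, dict(ped.meta_gamma)), len(missing)


# ---------------------------------------------------------------------------
# cleaning


def impute_birth_years(
    ped: RawPedigree, interval: int = 3
) -> tuple[RawPedigree, int]:
    """Fill missing birth years from progeny.

    An animal with a missing year and at least one dated progeny (known or
    itself imputed) gets ``min(progeny years) - interval``.  Animals are
    processed progeny-first so chains of missing years resolve; animals
    with no dated descendants stay missing.
    """
    idx = ped.index()
    n = len(ped.records)
    children: list[list[int]] = [[] for _ in range(n)]
    pending = [0] * n
    for pos, r in enumerate(ped.records):
        for p in (r.sire, r.dam):
            if p is not None and p in idx:
                children[idx[p]].append(pos)
                pending[idx[p]] += 1
    years: list[int | None] = [r.year for r in ped.records]
    queue = deque(pos for pos in range(n) if pending[pos] == 0)
    n_imputed = 0
    while queue:
        pos = queue.popleft()
        if years[pos] is None:
            dated = [years[c] for c in children[pos] if years[c] is not None]
            if dated:
                years[pos] = min(dated) - interval
                n_imputed += 1
        r = ped.records[pos]
        for p in (r.sire, r.dam):
            if p is not None and p in idx:
                ppos = idx[p]
                pending[ppos] -= 1
                if pending[ppos] == 0:
                    queue.append(ppos)
    new_records = [
        replace(r, year=years[pos]) for pos, r in enumerate(ped.records)
    ]
    return RawPedigree(new_records, dict(ped.meta_gamma)), n_imputed


def fix_birth_order_errors(ped: RawPedigree) -> tuple[RawPedigree, int]:
    """Sever parent links born in the same year as, or later than, progeny.

    Each offending link (counted per link, not per animal) is replaced by
    an unknown parent.  Idempotent.
    """
    idx = ped.index()
    year_of = {r.animal: r.year for r in ped.records}
    n_fixed = 0
    new_records: list[PedRecord] = []
    for r in ped.records:
        sire, dam = r.sire, r.dam
        if r.year is not None:
            if sire is not None and sire in idx:
                py = year_of[sire]
                if py is not None and py >= r.year:
                    sire = None
                    n_fixed += 1
            if dam is not None and dam in idx:
                py = year_of[dam]
                if py is not None and py >= r.year:
                    dam = None
                    n_fixed += 1
        new_records.append(replace(r, sire=sire, dam=dam))
    return RawPedigree(new_records, dict(ped.meta_gamma)), n_fixed


# ---------------------------------------------------------------------------
# metafounders


def _meta_id(existing: set[str], bin_start: int, role: str | None) -> str:
    base = f"MF{bin_start}" if role is None else f"MF{bin_start}{role}"
    while base in existing:
        base = "_" + base
    return base


def assign_metafounders(
    ped: RawPedigree, policy: MetafounderPolicy | None = None
) -> RawPedigree:
    """Replace every unknown parent slot with a per-year-bin metafounder.

    One metafounder is created per occupied year bin (two when
    ``policy.sex_split`` is set, one per parental role); unknown parents of
    undated animals use the earliest occupied bin.  Metafounder records are
    prepended in ascending bin order, so afterwards every real animal has
    both parents present.
    """
    if policy is None:
        policy = MetafounderPolicy()
    w = policy.bin_width_years
    years = [r.year for r in ped.records if r.year is not None and not r.is_meta]
    min_year = min(years) if years else 0

    def bin_start(year: int) -> int:
        return min_year + ((year - min_year) // w) * w

    # which (bin, role) combinations are needed
    dated_bins: set[int] = set()
    has_undated_slot = False
    for r in ped.records:
        if r.is_meta or (r.sire is not None and r.dam is not None):
            continue
        if r.year is None:
            has_undated_slot = True
        else:
            dated_bins.add(bin_start(r.year))
    if not dated_bins and not has_undated_slot:
        return RawPedigree(list(ped.records), dict(ped.meta_gamma))
    fallback = min(dated_bins) if dated_bins else min_year
    bins = sorted(dated_bins | ({fallback} if has_undated_slot else set()))

    existing = ped.id_set
    roles = ("S", "D") if policy.sex_split else (None,)
    mf_id: dict[tuple[int, str | None], str] = {}
    meta_records: list[PedRecord] = []
    meta_gamma = dict(ped.meta_gamma)
    for b in bins:
        for role in roles:
            mid = _meta_id(existing, b, role)
            existing.add(mid)
            mf_id[(b, role)] = mid
            meta_records.append(PedRecord(mid, None, None, None, is_meta=True))
            meta_gamma[mid] = policy.gamma_for(b)

    new_records: list[PedRecord] = []
    for r in ped.records:
        if r.is_meta:
            new_records.append(r)
            continue
        b = fallback if r.year is None else bin_start(r.year)
        sire = r.sire if r.sire is not None else mf_id[(b, roles[0])]
        dam = r.dam if r.dam is not None else mf_id[(b, roles[-1])]
        new_records.append(replace(r, sire=sire, dam=dam))
    return RawPedigree(meta_records + new_records, meta_gamma)


# ---------------------------------------------------------------------------
# renumbering and LAP sorting


def build_pedigree(ped: RawPedigree) -> Pedigree:
    """Renumber and LAP-sort a fully parent-assigned raw pedigree.

    LAP is 0 for metafounders and ``max(LAP_sire, LAP_dam) + 1`` for real
    animals.  Records are stably sorted by ascending LAP (ties keep input
    order), so parents always precede progeny and equal-LAP animals share
    no parent-progeny link.

    Raises
    ------
    ValidationError
        A real animal with an unassigned or unrecorded parent.
    CycleError
        The parentage graph is cyclic (names a cycle member).
    """
    idx = ped.index()
    n = len(ped.records)
    sire_pos = np.full(n, NO_PARENT, dtype=np.int64)
    dam_pos = np.full(n, NO_PARENT, dtype=np.int64)
    for pos, r in enumerate(ped.records):
        if r.is_meta:
            continue
        if r.sire is None or r.dam is None:
            raise ValidationError(
                f"animal {r.animal!r} has an unassigned parent; "
                "run assign_metafounders first"
            )
        for p in (r.sire, r.dam):
            if p not in idx:
                raise ValidationError(
                    f"parent {p!r} of animal {r.animal!r} has no record"
                )
        sire_pos[pos] = idx[r.sire]
        dam_pos[pos] = idx[r.dam]

    # Kahn topological pass computes LAP and detects cycles in O(n).
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for pos in range(n):
        for p in (sire_pos[pos], dam_pos[pos]):
            if p >= 0:
                children[p].append(pos)
                indeg[pos] += 1
    lap = np.zeros(n, dtype=np.int64)
    queue = deque(int(pos) for pos in np.nonzero(indeg == 0)[0])
    n_done = 0
    done = np.zeros(n, dtype=bool)
    while queue:
        v = queue.popleft()
        done[v] = True
        n_done += 1
        for c in children[v]:
            if lap[v] + 1 > lap[c]:
                lap[c] = lap[v] + 1
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if n_done != n:
        member = ped.records[int(np.nonzero(~done)[0][0])].animal
        raise CycleError(f"pedigree contains a parentage cycle through {member!r}")

    order = sorted(range(n), key=lambda pos: (lap[pos], pos))  # stable
    new_of = np.empty(n, dtype=np.int64)
    for new, pos in enumerate(order):
        new_of[pos] = new

    sire = np.full(n, NO_PARENT, dtype=np.int64)
    dam = np.full(n, NO_PARENT, dtype=np.int64)
    is_meta = np.zeros(n, dtype=bool)
    gamma = np.zeros(n, dtype=np.float64)
    orig_id = [""] * n
    input_pos = np.empty(n, dtype=np.int64)
    lap_sorted = np.empty(n, dtype=np.int64)
    for new, pos in enumerate(order):
        r = ped.records[pos]
        orig_id[new] = r.animal
        input_pos[new] = pos
        lap_sorted[new] = lap[pos]
        if r.is_meta:
            is_meta[new] = True
            gamma[new] = ped.meta_gamma.get(r.animal, 0.0)
        else:
            sire[new] = new_of[sire_pos[pos]]
            dam[new] = new_of[dam_pos[pos]]
    n_meta = int(is_meta.sum())

    blocks: list[tuple[int, int]] = []
    if n:
        starts = [0] + list(np.nonzero(np.diff(lap_sorted))[0] + 1)
        stops = starts[1:] + [n]
        blocks = list(zip(starts, stops))

    return Pedigree(
        n=n,
        n_meta=n_meta,
        sire=sire,
        dam=dam,
        lap=lap_sorted,
        is_meta=is_meta,
        gamma=gamma,
        orig_id=orig_id,
        input_pos=input_pos,
        lap_blocks=blocks,
    )


def pedigree_from_parent_indices(
    sire: np.ndarray,
    dam: np.ndarray,
    gamma: float = 0.0,
    ids: Sequence[str] | None = None,
) -> Pedigree:
    """Fast path from topologically ordered parent-index arrays.

    ``sire``/``dam`` use -1 for unknown; parents must precede progeny.
    A single shared metafounder (self-relationship ``gamma``) is prepended
    and fills every unknown slot.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n0 = sire.shape[0]
    if dam.shape[0] != n0:
        raise ValidationError("sire and dam arrays must have equal length")
    pos = np.arange(n0)
    if np.any(sire >= pos) or np.any(dam >= pos):
        raise ValidationError("parents must precede progeny in the input arrays")
    n = n0 + 1
    new_sire = np.empty(n, dtype=np.int64)
    new_dam = np.empty(n, dtype=np.int64)
    new_sire[0] = new_dam[0] = NO_PARENT
    new_sire[1:] = np.where(sire < 0, 0, sire + 1)
    new_dam[1:] = np.where(dam < 0, 0, dam + 1)
    lap = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        lap[i] = max(lap[new_sire[i]], lap[new_dam[i]]) + 1

    order = np.argsort(lap, kind="stable")
    new_of = np.empty(n, dtype=np.int64)
    new_of[order] = np.arange(n)
    s_sire = np.where(new_sire[order] < 0, NO_PARENT, new_of[new_sire[order]])
    s_dam = np.where(new_dam[order] < 0, NO_PARENT, new_of[new_dam[order]])
    s_lap = lap[order]
    is_meta = np.zeros(n, dtype=bool)
    is_meta[new_of[0]] = True
    g = np.zeros(n, dtype=np.float64)
    g[new_of[0]] = gamma
    if ids is None:
        names = ["MF0"] + [str(i + 1) for i in range(n0)]
    else:
        names = ["MF0"] + list(ids)
    orig_id = [names[i] for i in order]

    starts = [0] + list(np.nonzero(np.diff(s_lap))[0] + 1)
    stops = starts[1:] + [n]
    return Pedigree(
        n=n,
        n_meta=1,
        sire=s_sire,
        dam=s_dam,
        lap=s_lap,
        is_meta=is_meta,
        gamma=g,
        orig_id=orig_id,
        input_pos=order.astype(np.int64),
        lap_blocks=list(zip(starts, stops)),
    )


# ---------------------------------------------------------------------------
# results output


def write_results(
    ped: Pedigree,
    result: FResult,
    path,
    include_metafounders: bool = False,
) -> None:
    """Write a TSV of ``animal  F  LAP`` in original input order.

    Metafounders (F = gamma - 1, LAP 0) are excluded unless requested, in
    which case they come first.
    """
    f = result.f
    if f.shape[0] != ped.n:
        raise ValidationError("result length does not match pedigree size")
    real = [i for i in range(ped.n) if not ped.is_meta[i]]
    real.sort(key=lambda i: ped.input_pos[i])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("animal\tF\tLAP\n")
        if include_metafounders:
            for i in range(ped.n_meta):
                fh.write(f"{ped.orig_id[i]}\t{f[i]:.12g}\t{ped.lap[i]}\n")
        for i in real:
            fh.write(f"{ped.orig_id[i]}\t{f[i]:.12g}\t{ped.lap[i]}\n")
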