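"""Shared fixtures and helpers for the pedinbreed test suite."""

from __future__ import annotations

import numpy as np
import pytest

import pedinbreed as pb

#: Algorithms that must agree on F, keyed by tag.
ALL_ALGORITHMS = {
    "ml": pb.inbreeding_ml,
    "si": pb.inbreeding_si,
    "rec": pb.inbreeding_rec,
    "tabular": pb.inbreeding_tabular,
    "i": pb.inbreeding_i,
    "mi": pb.inbreeding_mi,
}


def make_raw(rows):
    """Build a RawPedigree from (animal, sire, dam[, year]) tuples;
    None marks unknown."""
    records = []
    for row in rows:
        animal, sire, dam = row[:3]
        year = row[3] if len(row) > 3 else None
        records.append(pb.PedRecord(str(animal),
                                    None if sire is None else str(sire),
                                    None if dam is None else str(dam),
                                    year))
    return pb.RawPedigree(records)


def build(raw, gamma=0.0, bin_width=1, sex_split=False):
    """Metafounder-augment and LAP-sort a raw pedigree."""
    policy = pb.MetafounderPolicy(bin_width_years=bin_width,
                                  gamma_default=gamma, sex_split=sex_split)
    return pb.build_pedigree(pb.assign_metafounders(raw, policy))


def index_of(ped, animal_id):
    return ped.orig_id.index(str(animal_id))


def wright_line(generations):
    """Repeated full-sib line: founders (pair 0) then `generations` sib
    pairs, each pair the parents of the next.  Returns (Pedigree,
    expected F per pair) where pair t>=1 carries the recurrence value
    F_t with F_1 = 0 (children of unrelated founders), then
    F_t = 0.25 (1 + 2 F_{t-1} + F_{t-2})."""
    sire, dam = [-1, -1], [-1, -1]
    for t in range(1, generations + 1):
        a = 2 * t
        sire += [a - 2] * 2
        dam += [a - 1] * 2
    ped = pb.pedigree_from_parent_indices(np.array(sire), np.array(dam))
    expected = [0.0, 0.0]  # recurrence seeds F_{-1} = F_0 = 0
    for _ in range(generations):
        expected.append(0.25 * (1 + 2 * expected[-1] + expected[-2]))
    return ped, expected[1 : generations + 1]


def wright_pair_f(ped, result_f, t):
    """F of the animals in sib pair t (1-based) of a wright_line pedigree."""
    i = index_of(ped, str(2 * t + 1))
    j = index_of(ped, str(2 * t + 2))
    assert result_f[i] == result_f[j]
    return result_f[i]


@pytest.fixture
def fullsib_raw():
    """Founders 1,2; full sibs 3,4; inbred child 5 (F = 0.25)."""
    return make_raw([
        ("1", None, None, 2000),
        ("2", None, None, 2000),
        ("3", "1", "2", 2001),
        ("4", "1", "2", 2001),
        ("5", "3", "4", 2002),
    ])


@pytest.fixture
def fullsib_ped(fullsib_raw):
    return build(fullsib_raw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


def random_built(rng, n=None, gamma=0.0, p_unknown=0.3, n_levels=None):
    """Random LAP-sorted pedigree with metafounders."""
    if n is None:
        n = int(rng.integers(20, 200))
    if n_levels is None:
        n_levels = int(rng.integers(3, 12))
    raw = pb.random_pedigree(n, rng, p_unknown=p_unknown, n_levels=n_levels)
    return build(raw, gamma=gamma)
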