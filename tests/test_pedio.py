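"""Tests for pedigree I/O, cleaning, metafounders and LAP sorting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pedinbreed as pb
from conftest import build, index_of, make_raw


# ---------------------------------------------------------------------------
# read_pedigree


def _write(tmp_path, text, name="ped.txt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPedigree:
    def test_basic_whitespace(self, tmp_path):
        raw = pb.read_pedigree(_write(tmp_path, "1 0 0\n2 0 0\n3 1 2\n"))
        assert len(raw.records) == 3
        r3 = raw.records[2]
        assert (r3.animal, r3.sire, r3.dam) == ("3", "1", "2")
        assert raw.records[0].sire is None

    def test_self_parentage_rejected(self, tmp_path):
        with pytest.raises(pb.ValidationError, match="own parent"):
            pb.read_pedigree(_write(tmp_path, "5 5 0\n"))

    def test_birth_year_column(self, tmp_path):
        raw = pb.read_pedigree(_write(tmp_path, "1 0 0 1990\n2 0 0\n"))
        assert raw.records[0].year == 1990
        assert raw.records[1].year is None

    def test_duplicate_id_rejected(self, tmp_path):
        with pytest.raises(pb.ValidationError, match="duplicate"):
            pb.read_pedigree(_write(tmp_path, "1 0 0\n1 0 0\n"))

    def test_malformed_line_reports_number(self, tmp_path):
        with pytest.raises(pb.ParseError, match="line 2"):
            pb.read_pedigree(_write(tmp_path, "1 0 0\n2 0\n"))

    def test_bad_year_reports_number(self, tmp_path):
        with pytest.raises(pb.ParseError, match="line 1"):
            pb.read_pedigree(_write(tmp_path, "1 0 0 abc\n"))

    @pytest.mark.parametrize("delim,sample", [
        ("\t", "1\t0\t0\n3\t1\t0\n"),
        (",", "1,0,0\n3,1,0\n"),
    ])
    def test_delimiter_autodetect(self, tmp_path, delim, sample):
        raw = pb.read_pedigree(_write(tmp_path, sample))
        assert raw.records[1].sire == "1"

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        raw = pb.read_pedigree(_write(tmp_path, "# header\n\n1 0 0\n"))
        assert len(raw.records) == 1

    def test_roundtrip(self, tmp_path):
        raw = make_raw([("1", None, None, 1990), ("2", "1", None), ("3", "1", "2", 1995)])
        path = tmp_path / "rt.txt"
        pb.write_pedigree(raw, path)
        back = pb.read_pedigree(path)
        assert [(r.animal, r.sire, r.dam, r.year) for r in back.records] == \
               [(r.animal, r.sire, r.dam, r.year) for r in raw.records]


def test_add_missing_parents():
    raw = make_raw([("3", "1", "2")])
    fixed, n = pb.add_missing_parents(raw)
    assert n == 2
    assert fixed.id_set == {"1", "2", "3"}


# ---------------------------------------------------------------------------
# impute_birth_years


class TestImputeBirthYears:
    def test_oldest_progeny_minus_interval(self):
        raw = make_raw([("P", None, None), ("A", "P", None, 1990),
                        ("B", "P", None, 1994)])
        out, n = pb.impute_birth_years(raw)
        assert n == 1
        assert out.records[0].year == 1987  # min(1990, 1994) - 3

    def test_chain_resolves_in_reverse_topological_order(self):
        raw = make_raw([("G", None, None), ("P", "G", None), ("C", "P", None, 2000)])
        out, n = pb.impute_birth_years(raw)
        years = {r.animal: r.year for r in out.records}
        assert n == 2
        assert years == {"C": 2000, "P": 1997, "G": 1994}

    def test_no_information_stays_missing(self):
        raw = make_raw([("X", None, None), ("Y", None, None, 1990)])
        out, n = pb.impute_birth_years(raw)
        assert n == 0
        assert out.records[0].year is None

    def test_custom_interval(self):
        raw = make_raw([("P", None, None), ("A", "P", None, 1990)])
        out, _ = pb.impute_birth_years(raw, interval=5)
        assert out.records[0].year == 1985


# ---------------------------------------------------------------------------
# fix_birth_order_errors


class TestFixBirthOrder:
    def test_same_year_severed(self):
        raw = make_raw([("S", None, None, 2000), ("C", "S", None, 2000)])
        out, n = pb.fix_birth_order_errors(raw)
        assert n == 1
        assert out.records[1].sire is None

    def test_valid_order_unchanged(self):
        raw = make_raw([("S", None, None, 1995), ("C", "S", None, 2000)])
        out, n = pb.fix_birth_order_errors(raw)
        assert n == 0
        assert out.records[1].sire == "S"

    def test_both_parents_counted_per_link(self):
        raw = make_raw([("S", None, None, 2005), ("D", None, None, 2001),
                        ("C", "S", "D", 2000)])
        out, n = pb.fix_birth_order_errors(raw)
        assert n == 2
        assert out.records[2].sire is None and out.records[2].dam is None

    def test_idempotent(self):
        raw = make_raw([("S", None, None, 2000), ("D", None, None, 1990),
                        ("C", "S", "D", 2000)])
        once, n1 = pb.fix_birth_order_errors(raw)
        twice, n2 = pb.fix_birth_order_errors(once)
        assert n1 == 1 and n2 == 0
        assert once.records == twice.records


# ---------------------------------------------------------------------------
# assign_metafounders


class TestAssignMetafounders:
    def test_one_metafounder_per_occupied_bin(self):
        raw = make_raw([("A", None, None, 1901), ("B", None, None, 1950),
                        ("C", "A", "B", 1980), ("D", None, "C", 1981)])
        out = pb.assign_metafounders(raw)
        metas = [r for r in out.records if r.is_meta]
        assert len(metas) == 3  # bins 1901, 1950, 1981
        assert all(r.sire is not None and r.dam is not None
                   for r in out.records if not r.is_meta)

    def test_shared_metafounder_for_founder_pair(self):
        raw = make_raw([("1", None, None, 2000), ("2", None, None, 2000)])
        out = pb.assign_metafounders(raw)
        metas = [r for r in out.records if r.is_meta]
        assert len(metas) == 1
        mf = metas[0].animal
        assert all(r.sire == mf and r.dam == mf
                   for r in out.records if not r.is_meta)

    def test_no_unknown_parents_no_metafounders(self):
        raw = make_raw([("1", "X", "Y", 2000)])
        raw = pb.RawPedigree(raw.records)  # parents unrecorded but present tokens
        out = pb.assign_metafounders(raw)
        assert out.n_meta == 0

    def test_fallback_bin_is_earliest(self):
        raw = make_raw([("A", None, None, 1950), ("U", None, None)])  # U undated
        out = pb.assign_metafounders(raw)
        metas = [r for r in out.records if r.is_meta]
        assert len(metas) == 1  # undated shares the 1950 bin
        undated = next(r for r in out.records if r.animal == "U")
        assert undated.sire == metas[0].animal

    def test_bin_width(self):
        raw = make_raw([("A", None, None, 1990), ("B", None, None, 1994),
                        ("C", None, None, 1995)])
        out = pb.assign_metafounders(raw, pb.MetafounderPolicy(bin_width_years=5))
        assert out.n_meta == 2  # [1990, 1995) and [1995, 2000)

    def test_sex_split(self):
        raw = make_raw([("A", None, None, 1990)])
        out = pb.assign_metafounders(raw, pb.MetafounderPolicy(sex_split=True))
        assert out.n_meta == 2
        a = next(r for r in out.records if r.animal == "A")
        assert a.sire != a.dam

    def test_gamma_recorded(self):
        raw = make_raw([("A", None, None, 1990)])
        out = pb.assign_metafounders(raw, pb.MetafounderPolicy(gamma_default=0.2))
        assert set(out.meta_gamma.values()) == {0.2}

    def test_gamma_range_validated(self):
        with pytest.raises(pb.ValidationError, match="gamma"):
            pb.MetafounderPolicy(gamma_default=1.0)


# ---------------------------------------------------------------------------
# build_pedigree


class TestBuildPedigree:
    def test_metafounder_lap_zero_chain(self):
        raw = make_raw([("A", None, None, 1990), ("B", "A", "A", 1991),
                        ("C", "B", "B", 1992)])
        ped = build(raw)
        assert ped.lap[0] == 0 and ped.is_meta[0]
        assert [int(ped.lap[index_of(ped, x)]) for x in "ABC"] == [1, 2, 3]

    def test_lap_is_max_plus_one(self):
        # A has parents MF (via founder chain of LAP 4) and a founder (LAP 1)
        rows = [("1", None, None, 1990)]
        for k in range(2, 6):
            rows.append((str(k), str(k - 1), str(k - 1), 1990 + k))
        rows.append(("A", "5", "1", 1999))
        ped = build(make_raw(rows))
        assert ped.lap[index_of(ped, "A")] == ped.lap[index_of(ped, "5")] + 1 == 6

    def test_sorted_and_parents_precede(self, rng):
        ped = build(pb.random_pedigree(150, rng))
        assert np.all(np.diff(ped.lap) >= 0)
        m = ped.n_meta
        assert np.all(ped.sire[m:] < np.arange(m, ped.n))
        assert np.all(ped.dam[m:] < np.arange(m, ped.n))
        assert np.all(ped.lap[ped.sire[m:]] < ped.lap[m:])
        assert np.all(ped.lap[ped.dam[m:]] < ped.lap[m:])

    def test_sort_is_permutation(self, rng):
        raw = pb.assign_metafounders(pb.random_pedigree(80, rng))
        ped = pb.build_pedigree(raw)
        assert sorted(ped.orig_id) == sorted(r.animal for r in raw.records)
        assert sorted(ped.input_pos.tolist()) == list(range(ped.n))

    def test_stable_tiebreak_within_lap_block(self, rng):
        raw = pb.assign_metafounders(pb.random_pedigree(60, rng))
        ped = pb.build_pedigree(raw)
        for start, stop in ped.lap_blocks:
            assert np.all(np.diff(ped.input_pos[start:stop]) > 0)

    def test_lap_blocks_partition(self, rng):
        ped = build(pb.random_pedigree(70, rng))
        bounds = [b for b, _ in ped.lap_blocks] + [ped.n]
        assert bounds[0] == 0
        assert all(bounds[i] < bounds[i + 1] for i in range(len(bounds) - 1))
        assert ped.lap_blocks[-1][1] == ped.n

    def test_cycle_detected(self):
        records = [pb.PedRecord("A", "B", "B"), pb.PedRecord("B", "A", "A")]
        with pytest.raises(pb.CycleError, match="cycle"):
            pb.build_pedigree(pb.RawPedigree(records))

    def test_unassigned_parent_rejected(self):
        raw = make_raw([("A", None, None, 1990)])
        with pytest.raises(pb.ValidationError, match="unassigned"):
            pb.build_pedigree(raw)

    def test_missing_parent_record_rejected(self):
        raw = make_raw([("A", "X", "Y", 1990)])
        with pytest.raises(pb.ValidationError, match="no record"):
            pb.build_pedigree(raw)


def test_pedigree_from_parent_indices_matches_pipeline(rng):
    sire = np.array([-1, -1, 0, 0, 2])
    dam = np.array([-1, -1, 1, 1, 3])
    ped = pb.pedigree_from_parent_indices(sire, dam)
    f = pb.inbreeding_tabular(ped).f
    assert f[index_of(ped, "5")] == pytest.approx(0.25, abs=1e-15)
    with pytest.raises(pb.ValidationError):
        pb.pedigree_from_parent_indices(np.array([1]), np.array([-1]))


# ---------------------------------------------------------------------------
# write_results


class TestWriteResults:
    def test_rows_in_input_order(self, tmp_path, fullsib_ped):
        res = pb.inbreeding_mi(fullsib_ped)
        out = tmp_path / "f.tsv"
        pb.write_results(fullsib_ped, res, out)
        lines = out.read_text().strip().split("\n")
        assert lines[0] == "animal\tF\tLAP"
        ids = [l.split("\t")[0] for l in lines[1:]]
        assert ids == ["1", "2", "3", "4", "5"]
        f5 = float(lines[-1].split("\t")[1])
        assert f5 == pytest.approx(0.25)

    def test_metafounders_first_with_gamma_minus_one(self, tmp_path, fullsib_raw):
        ped = build(fullsib_raw, gamma=0.2)
        res = pb.inbreeding_mi(ped)
        out = tmp_path / "f.tsv"
        pb.write_results(ped, res, out, include_metafounders=True)
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 1 + ped.n
        first = lines[1].split("\t")
        assert float(first[1]) == pytest.approx(0.2 - 1.0)
        assert first[2] == "0"

    def test_empty_pedigree_header_only(self, tmp_path):
        ped = pb.build_pedigree(pb.RawPedigree([]))
        res = pb.FResult(f=np.empty(0), algorithm="mi")
        out = tmp_path / "f.tsv"
        pb.write_results(ped, res, out)
        assert out.read_text() == "animal\tF\tLAP\n"


# ---------------------------------------------------------------------------
# properties


def test_gamma_zero_equals_separate_founders(rng):
    """With gamma = 0, shared per-bin metafounders reproduce the classical
    F computed when every unknown slot gets its own unrelated founder."""
    for _ in range(10):
        n = int(rng.integers(15, 80))
        raw = pb.random_pedigree(n, rng)
        f_meta = pb.inbreeding_tabular(build(raw, gamma=0.0)).f
        # variant: one fresh founder per unknown slot
        rows, extra = [], 0
        for r in raw.records:
            sire, dam = r.sire, r.dam
            if sire is None:
                extra += 1
                sire = f"U{extra}"
            if dam is None:
                extra += 1
                dam = f"U{extra}"
            rows.append((r.animal, sire, dam, r.year))
        variant = make_raw([(f"U{k}", None, None) for k in range(1, extra + 1)]
                           + rows)
        ped_b = build(variant, gamma=0.0)
        f_sep = pb.inbreeding_tabular(ped_b).f
        ped_a = build(raw, gamma=0.0)
        fa = {ped_a.orig_id[i]: f_meta[i]
              for i in range(ped_a.n) if not ped_a.is_meta[i]}
        fb = {ped_b.orig_id[i]: f_sep[i]
              for i in range(ped_b.n) if not ped_b.is_meta[i]}
        for animal, fv in fa.items():
            assert abs(fv - fb[animal]) < 1e-12


@settings(max_examples=30, deadline=None)
@given(st.integers(1960, 2020), st.integers(1960, 2020), st.integers(1960, 2020))
def test_fix_birth_order_idempotent_property(y1, y2, y3):
    raw = make_raw([("S", None, None, y1), ("D", None, None, y2),
                    ("C", "S", "D", y3)])
    once, _ = pb.fix_birth_order_errors(raw)
    twice, n2 = pb.fix_birth_order_errors(once)
    assert n2 == 0 and once.records == twice.records
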