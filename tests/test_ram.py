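import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rampgk import (
    Dataset,
    ProteinRecord,
    SiteRecord,
    build_ram,
    collect_row_distances,
    encode_dataset,
    flatten,
)
from rampgk.alphabet import RESIDUE_ORDER, row_index
from rampgk.ram import FeatureSchema, eliminated_schema, full_schema


def sites_with_lysine():
    """(sequence, 1-based lysine position) pairs over the 20-letter alphabet."""
    return (
        st.tuples(
            st.text(alphabet=RESIDUE_ORDER, min_size=0, max_size=29),
            st.integers(min_value=0, max_value=29),
        )
        .map(lambda t: (t[0][: t[1]] + "K" + t[0][t[1] :], min(t[1], len(t[0])) + 1))
    )


class TestCollectRowDistances:
    @pytest.mark.parametrize(
        "residue, expected",
        [("A", [1, 1, 3]), ("K", [0, 2]), ("Y", [])],
    )
    def test_dummy_sequence(self, residue, expected):
        assert collect_row_distances("MAKAKAA", 3, residue, 3) == expected

    def test_not_a_lysine_raises(self):
        with pytest.raises(ValueError, match="not 'K'"):
            collect_row_distances("MAKAKAA", 2, "A", 3)

    @settings(derandomize=True, max_examples=60)
    @given(site=sites_with_lysine(), residue=st.sampled_from(RESIDUE_ORDER),
           n=st.integers(min_value=1, max_value=8))
    def test_matches_brute_force_sort(self, site, residue, n):
        """Each row's raw values are the sorted |idx - k| list, truncated."""
        sequence, k = site
        expected = sorted(
            abs(i + 1 - k) for i, c in enumerate(sequence) if c == residue
        )[:n]
        assert collect_row_distances(sequence, k, residue, n) == expected


class TestBuildRam:
    def test_dummy_sequence_imputed_matrix(self):
        ram = build_ram("MAKAKAA", 3, n=3)
        assert ram.row("A").tolist() == [1, 1, 3]
        assert ram.row("K").tolist() == [0, 2, 1]  # rule A: mean(0, 2)
        assert ram.row("M").tolist() == [2, 2, 2]  # rule A: mean(2)
        assert ram.row("Y").tolist() == [1.5, 1.5, 1.5]  # rule B: global mean

    def test_absent_types_all_get_global_mean(self):
        ram = build_ram("MAKAKAA", 3, n=3)
        for residue in set(RESIDUE_ORDER) - set("MAK"):
            assert ram.row(residue).tolist() == [1.5, 1.5, 1.5]
            assert ram.imputed_mask[row_index(residue)].all()

    def test_rule_a_from_single_occurrence(self):
        # raw distances A:{1,1}, K:{0}; K's empty slot takes mean(0)=0;
        # absent rows take (1+1+0)/3 = 2/3 excluding imputed values
        ram = build_ram("AAKAA", 3, n=2)
        assert ram.row("A").tolist() == [1, 1]
        assert ram.row("K").tolist() == [0, 0]
        assert ram.row("C").tolist() == pytest.approx([2 / 3, 2 / 3])

    def test_mask_marks_only_filled_slots(self):
        ram = build_ram("MAKAKAA", 3, n=3)
        assert not ram.imputed_mask[row_index("A")].any()
        assert ram.imputed_mask[row_index("K")].tolist() == [False, False, True]

    def test_nonstandard_residues_occupy_indices_but_no_row(self):
        # X shifts the M two positions away but contributes nothing itself
        ram = build_ram("MXXKA", 4, n=2)
        assert ram.row("M")[0] == 3.0
        assert ram.row("A")[0] == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(site=sites_with_lysine(), n=st.integers(min_value=1, max_value=6))
    def test_reversal_symmetry(self, site, n):
        """Distances are absolute: reversing the sequence preserves the RAM."""
        sequence, k = site
        ram = build_ram(sequence, k, n=n)
        mirrored = build_ram(sequence[::-1], len(sequence) + 1 - k, n=n)
        np.testing.assert_allclose(ram.values, mirrored.values)

    @settings(derandomize=True, max_examples=50)
    @given(site=sites_with_lysine(), n=st.integers(min_value=1, max_value=6))
    def test_absent_rows_share_one_value(self, site, n):
        sequence, k = site
        ram = build_ram(sequence, k, n=n)
        absent = [r for r in RESIDUE_ORDER if r not in sequence]
        values = {float(v) for r in absent for v in ram.row(r)}
        assert len(values) <= 1

    def test_flank_translation_shifts_only_new_type_and_absent_rows(self):
        """Padding both ends with an otherwise-absent type leaves every
        present row's raw distances unchanged."""
        base, k, n = "MAKAKAA", 3, 3
        padded = "WW" + base + "WW"
        ram_a = build_ram(base, k, n=n)
        ram_b = build_ram(padded, k + 2, n=n)
        for residue in "AKM":
            i = row_index(residue)
            raw = ~ram_a.imputed_mask[i]
            np.testing.assert_allclose(
                ram_a.values[i][raw], ram_b.values[i][raw]
            )


class TestFlatten:
    def test_full_alphabet_length(self):
        assert len(flatten(build_ram("MAKAKAA", 3, n=6)).values) == 120

    def test_published_elimination_gives_84_features(self):
        schema = eliminated_schema(("E", "D", "L", "V", "F", "T"), n=6)
        assert len(schema.retained) == 14
        ram = build_ram("MAKAKAA", 3, n=6)
        assert len(flatten(ram, schema.retained).values) == 84

    def test_row_major_order_on_dummy_matrix(self):
        ram = build_ram("MAKAKAA", 3, n=3)
        vec = flatten(ram, retained=("A", "K", "M", "Y"))
        assert vec.values.tolist() == [1, 1, 3, 0, 2, 1, 2, 2, 2, 1.5, 1.5, 1.5]

    def test_empty_retained_rejected(self):
        ram = build_ram("MAKAKAA", 3, n=3)
        with pytest.raises(ValueError):
            flatten(ram, retained=())

    def test_retained_set_is_reordered_to_alphabet_order(self):
        schema = FeatureSchema(retained=("Y", "A"), n=2)
        assert schema.retained == ("A", "Y")


class TestEncodeDataset:
    def test_shapes_and_order(self):
        protein = ProteinRecord("P1", "MAKAKAA")
        ds = Dataset(
            proteins={"P1": protein},
            sites=[SiteRecord("P1", 3, 1), SiteRecord("P1", 5, 0)],
        )
        table, labels = encode_dataset(ds, n=6)
        assert table.X.shape == (2, 120)
        assert labels.tolist() == [1, 0]
        assert table.sites["position"].tolist() == [3, 5]

    def test_empty_site_list_keeps_schema(self):
        protein = ProteinRecord("P1", "MAKAKAA")
        ds = Dataset(proteins={"P1": protein}, sites=[])
        table, labels = encode_dataset(ds, n=4)
        assert table.X.shape == (0, 80)
        assert table.schema == full_schema(4)

    def test_worked_example_row_matches_dummy_matrix(self, worked_example):
        table, labels = encode_dataset(worked_example, n=3)
        row = table.X[0]
        schema = table.schema
        assert row[schema.column_slice("A")].tolist() == [1, 1, 3]
        assert row[schema.column_slice("K")].tolist() == [0, 2, 1]
        assert row[schema.column_slice("M")].tolist() == [2, 2, 2]
        assert row[schema.column_slice("Y")].tolist() == [1.5, 1.5, 1.5]

    def test_select_rows_equals_direct_encoding(self, worked_example):
        table, _ = encode_dataset(worked_example, n=3)
        sub = table.select_rows(("A", "M", "Y"))
        direct, _ = encode_dataset(worked_example, n=3, retained=("A", "M", "Y"))
        np.testing.assert_allclose(sub.X, direct.X)
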