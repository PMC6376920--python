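"""Domain types and tabular round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from winefp import (
    Dataset,
    Locus,
    Panel,
    VarietyGenotype,
    WineProfile,
    default_panel,
    merge_datasets,
    read_genotype_table,
    read_peak_table,
    write_genotype_table,
)
from winefp.errors import ConflictError, ParseError, UsageError
from winefp.io import dataset_from_json, dataset_to_json

HEADER = "sample_id,sample_type,locus,alleles\n"


class TestTypes:
    def test_locus_invariants(self):
        with pytest.raises(UsageError):
            Locus("", 2, 80, 400)
        with pytest.raises(UsageError):
            Locus("X", 0, 80, 400)
        with pytest.raises(UsageError):
            Locus("X", 2, 400, 80)

    def test_panel_rejects_duplicates(self):
        locus = Locus("VVS2", 2, 110, 180)
        with pytest.raises(UsageError):
            Panel([locus, locus])

    def test_genotype_normalises_pair_order(self):
        a = VarietyGenotype("V", {"VVS2": (152, 150)})
        b = VarietyGenotype("V", {"VVS2": (150, 152)})
        assert a == b
        assert a.allele_set("VVS2") == frozenset({150, 152})

    def test_wine_profile_rejects_empty_locus(self):
        with pytest.raises(UsageError):
            WineProfile("W", {"VVS2": frozenset()})

    def test_dataset_rejects_unknown_locus_and_duplicate_ids(self, panel):
        with pytest.raises(UsageError):
            Dataset(panel, varieties=[VarietyGenotype("V", {"NOPE": (1, 2)})])
        v = VarietyGenotype("X", {"VVS2": (150, 152)})
        w = WineProfile("X", {"VVS2": frozenset({150})})
        with pytest.raises(UsageError):
            Dataset(panel, varieties=[v], wines=[w])


class TestGenotypeTable:
    def test_single_wine_row(self, panel):
        ds = read_genotype_table(HEADER + "W1,wine,VVS2,150/152\n", panel)
        assert ds.wine("W1").calls == {"VVS2": frozenset({150, 152})}

    def test_homozygous_grapevine_row(self, panel):
        ds = read_genotype_table(HEADER + "G1,grapevine,VVS2,150/150\n", panel)
        assert ds.variety("G1").calls["VVS2"] == (150, 150)

    def test_wine_rows_union_alleles(self, panel):
        text = HEADER + "W1,wine,VVS2,150/152\nW1,wine,VVS2,154/154\n"
        ds = read_genotype_table(text, panel)
        assert ds.wine("W1").calls["VVS2"] == frozenset({150, 152, 154})

    def test_blank_alleles_mean_untyped(self, panel):
        ds = read_genotype_table(HEADER + "W1,wine,VVS2,\nW1,wine,VVMD21,250/252\n", panel)
        assert "VVS2" not in ds.wine("W1").calls

    @pytest.mark.parametrize(
        "row,err",
        [
            ("G1,grapevine,VVS2,150/152/154", ParseError),  # != 2 alleles
            ("W1,juice,VVS2,150/152", ParseError),  # unknown sample_type
            ("W1,wine,NOPE,150/152", ParseError),  # locus not in panel
            ("W1,wine,VVS2,abc", ParseError),  # malformed alleles
        ],
    )
    def test_bad_rows_rejected(self, panel, row, err):
        with pytest.raises(err):
            read_genotype_table(HEADER + row + "\n", panel)

    def test_duplicate_grapevine_call_conflicts(self, panel):
        text = HEADER + "G1,grapevine,VVS2,150/152\nG1,grapevine,VVS2,150/154\n"
        with pytest.raises(ConflictError):
            read_genotype_table(text, panel)

    def test_empty_dataset_writes_header_only(self, panel):
        assert write_genotype_table(Dataset(panel)) == HEADER

    def test_round_trip(self, panel):
        ds = read_genotype_table(
            HEADER
            + "G1,grapevine,VVS2,150/152\n"
            + "G1,grapevine,VVMD21,250/250\n"
            + "W1,wine,VVS2,150/152\n"
            + "W1,wine,VVMD27,180/184\n",
            panel,
        )
        assert read_genotype_table(write_genotype_table(ds), panel) == ds


@st.composite
def datasets(draw):
    panel = default_panel()
    loci = panel.names[: draw(st.integers(2, 5))]
    alleles_for = {
        loc: list(range(panel.locus(loc).size_min + 10, panel.locus(loc).size_min + 26, 2))
        for loc in loci
    }
    n_varieties = draw(st.integers(0, 3))
    n_wines = draw(st.integers(0, 3))
    varieties = []
    for k in range(n_varieties):
        calls = {}
        for loc in loci:
            if draw(st.booleans()):
                pair = draw(st.tuples(st.sampled_from(alleles_for[loc]),
                                      st.sampled_from(alleles_for[loc])))
                calls[loc] = pair
        if calls:
            varieties.append(VarietyGenotype(f"G{k}", calls))
    wines = []
    for k in range(n_wines):
        calls = {}
        for loc in loci:
            subset = draw(st.sets(st.sampled_from(alleles_for[loc]), min_size=0, max_size=4))
            if subset:
                calls[loc] = frozenset(subset)
        if calls:
            wines.append(WineProfile(f"W{k}", calls))
    return Dataset(panel, varieties=varieties, wines=wines)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(datasets())
def test_genotype_round_trip_property(ds):
    """write then read is the identity on any valid dataset."""
    assert read_genotype_table(write_genotype_table(ds), ds.panel) == ds


@settings(max_examples=25, deadline=None, derandomize=True)
@given(datasets())
def test_json_round_trip_property(ds):
    assert dataset_from_json(dataset_to_json(ds)) == ds


class TestPeakTable:
    HEADER = "sample_id\treplicate\tmarker\tsize\theight\n"

    def test_single_peak(self, panel):
        obs = read_peak_table(self.HEADER + "W1\t1\tVVS2\t149.7\t1200\n", panel)
        assert len(obs) == 1
        (peak,) = obs[0].peaks["VVS2"]
        assert peak.size == pytest.approx(149.7)
        assert not peak.out_of_bounds

    def test_grouping_by_sample_replicate(self, panel):
        text = (
            self.HEADER
            + "W1\t1\tVVS2\t149.7\t1200\n"
            + "W1\t1\tVVS2\t151.8\t900\n"
            + "W1\t2\tVVS2\t149.6\t1100\n"
        )
        obs = read_peak_table(text, panel)
        assert [(o.sample_id, o.replicate_index) for o in obs] == [("W1", 1), ("W1", 2)]
        assert len(obs[0].peaks["VVS2"]) == 2

    def test_out_of_bounds_flagged_not_dropped(self, panel):
        obs = read_peak_table(self.HEADER + "W1\t1\tVVS2\t9999\t100\n", panel)
        assert obs[0].peaks["VVS2"][0].out_of_bounds

    @pytest.mark.parametrize(
        "row",
        [
            "W1\t1\tVVS2\t-4\t100",  # negative size
            "W1\t1\tVVS2\t150\t-5",  # negative height
            "W1\tfoo\tVVS2\t150\t100",  # non-integer replicate
        ],
    )
    def test_bad_peak_rows(self, panel, row):
        with pytest.raises(ParseError):
            read_peak_table(self.HEADER + row + "\n", panel)


class TestMerge:
    def test_identity(self, panel):
        ds = read_genotype_table(HEADER + "G1,grapevine,VVS2,150/152\n", panel)
        assert merge_datasets([ds]) == ds

    def test_disjoint_samples_add(self, panel):
        d1 = read_genotype_table(HEADER + "G1,grapevine,VVS2,150/152\n", panel)
        d2 = read_genotype_table(HEADER + "G2,grapevine,VVS2,150/154\n", panel)
        merged = merge_datasets([d1, d2])
        assert sorted(merged.sample_ids) == ["G1", "G2"]

    def test_intersection_policy_keeps_common_loci(self):
        pa = Panel([Locus("A", 2, 80, 200), Locus("B", 2, 80, 200)])
        pb = Panel([Locus("B", 2, 80, 200), Locus("C", 2, 80, 200)])
        d1 = Dataset(pa, varieties=[VarietyGenotype("G1", {"A": (100, 102), "B": (110, 112)})])
        d2 = Dataset(pb, varieties=[VarietyGenotype("G2", {"B": (110, 114), "C": (120, 120)})])
        merged = merge_datasets([d1, d2], policy="intersection")
        assert merged.panel.names == ["B"]
        assert merged.variety("G1").calls == {"B": (110, 112)}

    def test_conflicting_duplicate_raises(self, panel):
        d1 = read_genotype_table(HEADER + "G1,grapevine,VVS2,150/152\n", panel)
        d2 = read_genotype_table(HEADER + "G1,grapevine,VVS2,150/154\n", panel)
        with pytest.raises(ConflictError):
            merge_datasets([d1, d2])

    def test_identical_duplicate_deduplicated(self, panel):
        d1 = read_genotype_table(HEADER + "G1,grapevine,VVS2,150/152\n", panel)
        merged = merge_datasets([d1, d1])
        assert merged.sample_ids == ["G1"]

    def test_associativity_on_conflict_free_inputs(self, panel):
        d1 = read_genotype_table(HEADER + "G1,grapevine,VVS2,150/152\n", panel)
        d2 = read_genotype_table(HEADER + "G2,grapevine,VVS2,150/154\n", panel)
        d3 = read_genotype_table(HEADER + "W1,wine,VVMD21,250/252\n", panel)
        left = merge_datasets([merge_datasets([d1, d2]), d3])
        right = merge_datasets([d1, merge_datasets([d2, d3])])
        assert left == right

    def test_empty_input_rejected(self):
        with pytest.raises(UsageError):
            merge_datasets([])
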