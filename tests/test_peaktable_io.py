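"""Peak-table / sample-sheet / spike-mixture I/O and bundled fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import urimex as ux
from urimex.peaktable_io import DEFAULT_INTERNAL_STANDARD

from conftest import make_table


class TestReadPeakTable:
    def test_long_basic(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("Sample,Compound,Area\nS1,urea,10\nS1,glucose,0\n")
        table = ux.read_peak_table(p, dialect="long")
        assert table.sample_ids == ["S1"]
        assert table.compound_ids == ["urea", "glucose"]
        assert table.intensities.tolist() == [[10.0, 0.0]]
        assert table.normalization_state is ux.NormalizationState.RAW

    def test_long_missing_cell_is_zero(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "Sample,Compound,Area\nS1,urea,10\nS1,glucose,3\nS2,urea,5\n"
        )
        table = ux.read_peak_table(p, dialect="long")
        assert table.data.loc["S2", "glucose"] == 0.0

    def test_long_duplicate_record_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("Sample,Compound,Area\nS1,urea,10\nS1,urea,12\n")
        with pytest.raises(ux.UrimexError, match="duplicate"):
            ux.read_peak_table(p, dialect="long")

    def test_negative_area_names_cell(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("Sample,Compound,Area\nS1,urea,-1\n")
        with pytest.raises(ux.UrimexError, match="urea"):
            ux.read_peak_table(p, dialect="long")

    def test_wide_empty_cell_is_zero(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("Sample,urea,glucose\nS1,10,2\nS2,5,\n")
        table = ux.read_peak_table(p, dialect="wide")
        assert table.data.loc["S2", "glucose"] == 0.0

    def test_wide_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("Sample,urea\nS1,10\nS1,5\n")
        with pytest.raises(ux.UrimexError, match="duplicate"):
            ux.read_peak_table(p, dialect="wide")


@pytest.mark.parametrize("dialect", ["long", "wide"])
def test_round_trip_bit_exact(tmp_path, dialect):
    """Write-then-read reproduces intensities bit-exactly, order preserved."""
    rng = np.random.default_rng(3)
    table = make_table(
        rng.uniform(0, 1e6, size=(4, 7)) * (rng.random((4, 7)) > 0.3),
        samples=["Zeta", "Alpha", "Mid", "S4"],
        compounds=[f"Compound {j}" for j in "gacbdef"[:7]],
        state=ux.NormalizationState.IS_NORMALIZED,
    )
    path = tmp_path / "t.csv"
    ux.write_peak_table(table, path, dialect=dialect)
    back = ux.read_peak_table(path, dialect=dialect)
    assert back.sample_ids == table.sample_ids
    assert back.compound_ids == table.compound_ids
    assert np.array_equal(back.intensities, table.intensities)
    assert back.normalization_state is table.normalization_state  # sidecar


class TestSampleSheet:
    def test_basic_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "Sample,Method,SpikeGroup,Replicate,Tags,Creatinine\n"
            'M5_pre_1,Method 5,pre,1,,1.2\n'
        )
        (meta,) = ux.read_sample_sheet(p)
        assert meta.creatinine_value == 1.2
        assert meta.spike_group is ux.SpikeGroup.PRE
        assert meta.treatment_tags == frozenset()

    def test_case_insensitive_group_and_tags(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "Sample,Method,SpikeGroup,Replicate,Tags,Creatinine\n"
            "A,UT-H,PRE,2,urease; heating,\n"
        )
        (meta,) = ux.read_sample_sheet(p)
        assert meta.spike_group is ux.SpikeGroup.PRE
        assert meta.treatment_tags == {"urease", "heating"}
        assert meta.creatinine_value is None

    def test_unknown_group_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "Sample,Method,SpikeGroup,Replicate,Tags,Creatinine\nA,M,spiked,1,,\n"
        )
        with pytest.raises(ux.UrimexError, match="spike group"):
            ux.read_sample_sheet(p)

    def test_zero_replicate_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "Sample,Method,SpikeGroup,Replicate,Tags,Creatinine\nA,M,pre,0,,\n"
        )
        with pytest.raises(ux.UrimexError, match="replicate"):
            ux.read_sample_sheet(p)

    def test_round_trip(self, tmp_path):
        metas = [
            ux.SampleMeta("A", "M", ux.SpikeGroup.PRE, 1,
                          frozenset({"urease"}), 1.5),
            ux.SampleMeta("B", "M", ux.SpikeGroup.NONE, 2, frozenset(), None),
        ]
        p = tmp_path / "s.csv"
        ux.write_sample_sheet(metas, p)
        assert ux.read_sample_sheet(p) == metas


class TestSpikeMixture:
    def test_default_composition(self):
        mix = ux.default_spike_mixture()
        assert len(mix) == 10
        by_class = {}
        for e in mix:
            by_class.setdefault(e.compound_class, []).append(e)
            assert e.concentration_ppm == 50.0
        assert len(by_class[ux.CompoundClass.AMINO_ACID]) == 6
        assert len(by_class[ux.CompoundClass.ORGANIC_ACID]) == 3
        assert len(by_class[ux.CompoundClass.FATTY_ACID]) == 1

    def test_round_trip(self, tmp_path):
        mix = ux.default_spike_mixture()
        p = tmp_path / "spike.csv"
        ux.write_spike_mixture(mix, p)
        assert ux.read_spike_mixture(p) == mix

    def test_duplicate_names_rejected(self):
        e = ux.SpikeEntry("X", ux.CompoundClass.AMINO_ACID, 50.0)
        e2 = ux.SpikeEntry(" x ", ux.CompoundClass.AMINO_ACID, 50.0)
        with pytest.raises(ux.UrimexError, match="duplicate"):
            ux.SpikeMixture((e, e2))


class TestFixtures:
    def test_table1_set_sizes(self):
        fx = ux.load_fixture("table1_unique_lists")
        sizes = [len(fx.methods[f"Method {i}"]) for i in range(1, 6)]
        assert sizes == [0, 13, 1, 7, 91]
        assert len(fx.group) == 58

    def test_table2_shape_and_cells(self):
        df = ux.load_fixture("table2_recovery")
        assert len(df) == 10 * 5
        assert set(df.columns) >= {"Compound", "Method", "PreAverage",
                                   "PostAverage", "RecoveryPercent"}
        cell = df[(df.Compound == "Citric acid") & (df.Method == "Method 5")]
        assert cell.PreAverage.item() == 1.63
        assert cell.PostAverage.item() == 1.38

    def test_table3_ranks_row(self):
        fx = ux.load_fixture("table3_ranks")
        row = fx.ranks.loc["Method 2 (acetonitrile addition)"]
        assert row.tolist() == [5, 2, 2]

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ux.UrimexError, match="unknown fixture"):
            ux.load_fixture("table9")


class TestPeakTableInvariants:
    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["S1", "S1"], columns=["c"])
        with pytest.raises(ux.UrimexError, match="duplicate sample"):
            ux.PeakTable(df)

    def test_compound_resolution_case_insensitive(self):
        table = make_table([[1.0, 2.0]], compounds=["Citric acid", "Urea"])
        assert table.resolve_compound("  citric ACID ") == "Citric acid"
        with pytest.raises(ux.UrimexError, match="not present"):
            table.resolve_compound("citrate")

    @given(st.integers(0, 2**31 - 1))
    def test_arbitrary_nonneg_matrices_accepted(self, seed):
        rng = np.random.default_rng(seed)
        table = make_table(rng.uniform(0, 10, size=(3, 4)))
        assert table.n_samples == 3 and table.n_compounds == 4
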