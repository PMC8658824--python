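import numpy as np
import pandas as pd
import pytest

from thermoramp.assay_io import (
    AssayDesign,
    ColumnMap,
    CsvFormat,
    convert_units,
    parse_instrument_csv,
    to_concentrations,
    traces_from_readings,
)
from thermoramp.errors import ConfigurationError, ParseError, ValidationError


def write_csv(tmp_path, text, name="in.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParse:
    def test_minutes_and_celsius_are_normalised(self, tmp_path):
        p = write_csv(
            tmp_path,
            "sample,time,temperature,absorbance\n"
            "a,0.5,10,0.1\na,1.0,10.5,0.2\na,1.5,11,0.3\n",
        )
        groups = parse_instrument_csv(p)
        g = groups["a"]
        assert np.allclose(g["time_s"], [30.0, 60.0, 90.0])
        assert np.allclose(g["temperature_K"], [283.15, 283.65, 284.15])

    def test_interleaved_cuvettes_grouped_and_time_sorted(self, tmp_path):
        p = write_csv(
            tmp_path,
            "sample,time,temperature,absorbance\n"
            "b,2.0,12,0.4\na,1.0,11,0.1\nb,1.0,11,0.2\na,2.0,12,0.3\n",
        )
        groups = parse_instrument_csv(p)
        assert set(groups) == {"a", "b"}
        for g in groups.values():
            assert g["time_s"].is_monotonic_increasing

    def test_positional_column_mapping(self, tmp_path):
        p = write_csv(tmp_path, "id,t,T,A\nx,1,20,0.5\nx,2,21,0.6\n")
        fmt = CsvFormat(columns=ColumnMap(sample=0, time=1, temperature=2, absorbance=3))
        groups = parse_instrument_csv(p, fmt)
        assert np.allclose(groups["x"]["temperature_K"], [293.15, 294.15])

    def test_missing_column_names_the_column(self, tmp_path):
        p = write_csv(tmp_path, "sample,time,absorbance\na,1,0.1\n")
        with pytest.raises(ConfigurationError, match="temperature"):
            parse_instrument_csv(p)

    def test_non_numeric_cell_reports_row_number(self, tmp_path):
        p = write_csv(
            tmp_path,
            "sample,time,temperature,absorbance\na,1,10,0.1\na,2,oops,0.2\n",
        )
        with pytest.raises(ParseError, match="row 3"):
            parse_instrument_csv(p)

    def test_duplicate_time_within_cuvette_rejected(self, tmp_path):
        p = write_csv(
            tmp_path,
            "sample,time,temperature,absorbance\na,1,10,0.1\na,1,10.5,0.2\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            parse_instrument_csv(p)

    def test_empty_file_raises_parse_error(self, tmp_path):
        with pytest.raises(ParseError):
            parse_instrument_csv(write_csv(tmp_path, ""))

    def test_unit_conversion_idempotent_on_si_data(self):
        fmt = CsvFormat(time_unit="s", temperature_unit="auto")
        t, temp = convert_units([10.0, 20.0], [283.15, 290.0], fmt)
        assert np.array_equal(t, [10.0, 20.0])
        assert np.array_equal(temp, [283.15, 290.0])


DESIGN = AssayDesign(
    extinction_coefficient=17800.0,
    path_length=1.0,
    enzyme_concentration=1e-9,
    s0={"a": 1e-3},
    baseline={"a": 0.0},
)


def readings(absorbances):
    n = len(absorbances)
    return pd.DataFrame(
        {
            "time_s": 30.0 * np.arange(n),
            "temperature_K": 283.15 + 0.1 * np.arange(n),
            "absorbance": absorbances,
        }
    )


class TestConcentrations:
    def test_beer_lambert_esterase_coefficient(self):
        # A = 0.178 over epsilon*l = 17800 -> 10 uM product
        tr = to_concentrations(readings([0.0, 0.178]), "a", DESIGN)
        assert tr.data["product_M"].iloc[1] == pytest.approx(1.0e-5, rel=1e-12)
        assert tr.data["substrate_M"].iloc[1] == pytest.approx(1e-3 - 1e-5, rel=1e-12)

    def test_beer_lambert_amylase_coefficient(self):
        design = AssayDesign(
            extinction_coefficient=12900.0,
            path_length=1.0,
            enzyme_concentration=1e-9,
            s0={"a": 1e-3},
            baseline={"a": 0.0},
        )
        tr = to_concentrations(readings([0.0, 0.129]), "a", design)
        assert tr.data["product_M"].iloc[1] == pytest.approx(1.0e-5, rel=1e-12)

    def test_absorbance_at_baseline_gives_zero_product(self):
        design = AssayDesign(
            extinction_coefficient=17800.0,
            path_length=1.0,
            enzyme_concentration=1e-9,
            s0={"a": 1e-3},
        )
        tr = to_concentrations(readings([0.3, 0.3]), "a", design)
        assert tr.data["product_M"].iloc[0] == 0.0  # default baseline = first point
        assert tr.data["substrate_M"].iloc[0] == pytest.approx(1e-3)

    def test_linearity_in_net_absorbance(self):
        tr1 = to_concentrations(readings([0.0, 0.1, 0.2]), "a", DESIGN)
        tr2 = to_concentrations(readings([0.0, 0.2, 0.4]), "a", DESIGN)
        assert np.allclose(2 * tr1.data["product_M"], tr2.data["product_M"])

    def test_out_of_range_flagged_not_dropped(self, caplog):
        big = 17800.0 * 1e-3 * 1.2  # 120% conversion
        with caplog.at_level("WARNING"):
            tr = to_concentrations(readings([0.0, big]), "a", DESIGN, tolerance=0.05)
        assert len(tr.data) == 2
        assert tr.data["out_of_range"].tolist() == [False, True]

    def test_unknown_cuvette_rejected(self):
        with pytest.raises(ValidationError, match="S0"):
            to_concentrations(readings([0.0, 0.1]), "zz", DESIGN)

    def test_design_validation(self):
        with pytest.raises(ConfigurationError):
            AssayDesign(
                extinction_coefficient=-1.0,
                path_length=1.0,
                enzyme_concentration=1e-9,
                s0={"a": 1e-3},
            )


class TestRoundTrip:
    def test_simulator_csv_round_trips(self, clean_assay, tmp_path):
        """parse(write(readings)) reproduces times/temperatures/absorbances (6 sig figs)."""
        path = clean_assay.write_csv(tmp_path / "ramp.csv")
        groups = parse_instrument_csv(path)
        si = clean_assay.readings_si
        for cid, g in groups.items():
            ref = si[si["cuvette_id"] == cid].reset_index(drop=True)
            assert np.allclose(g["time_s"], ref["time_s"], rtol=1e-6, atol=1e-9)
            assert np.allclose(g["temperature_K"], ref["temperature_K"], rtol=1e-6)
            assert np.allclose(g["absorbance"], ref["absorbance"], rtol=1e-6, atol=1e-12)

    def test_traces_satisfy_mass_balance(self, clean_traces):
        for tr in clean_traces:
            total = tr.data["product_M"] + tr.data["substrate_M"]
            assert np.allclose(total, tr.s0, rtol=1e-9)
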