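"""Record validation, long-CSV round-tripping, and fixture fidelity."""
import math

import pytest
from hypothesis import given, settings, strategies as st

from mycotrace import (
    ELEMENT_REGISTRY,
    Compartment,
    ConcentrationRecord,
    Dataset,
    FormatError,
    FruitingBody,
    ValidationError,
    load_fixture,
    read_long_csv,
    write_long_csv,
)

CSV_HEADER = "sample_id,site,date,compartment,element,value,censored,detection_limit\n"


class TestRecordValidation:
    def test_plain_row_parses(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(CSV_HEADER + "M1,granite,2021-07,cap,Cd,3.20,no,\n")
        ds = read_long_csv(path)
        assert len(ds) == 1
        rec = ds.records[0]
        assert rec.value == 3.20 and not rec.censored
        assert rec.compartment is Compartment.CAP

    def test_bdl_token_row_parses_as_censored(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(CSV_HEADER + "S1,granite,2021-07,soil_free,Se,bdl,yes,0.20\n")
        rec = read_long_csv(path).records[0]
        assert rec.censored and rec.value is None
        assert rec.detection_limit == 0.20

    def test_negative_value_names_row(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(CSV_HEADER + "M1,granite,2021-07,cap,Cd,-1.0,no,\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_long_csv(path)

    def test_nonstrict_mode_drops_bad_rows(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(CSV_HEADER
                        + "M1,granite,2021-07,cap,Cd,3.20,no,\n"
                        + "M2,granite,2021-07,cap,Cd,-1.0,no,\n")
        assert len(read_long_csv(path, strict=False)) == 1

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text("sample_id,site,date,element,value,censored,detection_limit\n")
        with pytest.raises(FormatError, match="compartment"):
            read_long_csv(path)

    def test_unknown_element_rejected(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(CSV_HEADER + "M1,granite,2021-07,cap,Xx,1.0,no,\n")
        with pytest.raises(ValidationError, match="Xx"):
            read_long_csv(path)

    def test_censored_record_needs_detection_limit(self):
        with pytest.raises(ValidationError):
            ConcentrationRecord("S", "granite", "2021-07", Compartment.SOIL_FREE,
                                "Se", censored=True)

    def test_duplicate_keys_rejected(self):
        rec = ConcentrationRecord("M1", "granite", "2021-07", Compartment.CAP,
                                  "Cd", value=1.0)
        with pytest.raises(ValidationError, match="duplicate"):
            Dataset(records=[rec, rec])

    def test_bad_date_rejected(self):
        with pytest.raises(ValidationError, match="YYYY-MM"):
            ConcentrationRecord("M1", "granite", "2021-13", Compartment.CAP,
                                "Cd", value=1.0)


class TestFruitingBody:
    def test_weight_fractions_renormalized(self):
        fb = FruitingBody("m", "granite", "2021-07", {},
                          {"stipe": 0.40, "cap": 0.30, "sporophore": 0.31})
        assert math.isclose(sum(fb.weight_fractions.values()), 1.0)

    def test_weight_sum_outside_tolerance_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            FruitingBody("m", "granite", "2021-07", {},
                         {"stipe": 0.5, "cap": 0.3, "sporophore": 0.3})

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValidationError):
            FruitingBody("m", "granite", "2021-07", {},
                         {"stipe": 1.0, "cap": 0.0, "sporophore": 0.0})

    def test_parts_representable_as_records(self):
        fb = FruitingBody("m", "granite", "2021-07",
                          {"Cd": {"stipe": 2.09, "cap": 3.20, "sporophore": None}},
                          {"stipe": 0.407, "cap": 0.291, "sporophore": 0.302})
        recs = fb.as_records()
        assert {r.compartment for r in recs} == {
            Compartment.STIPE, Compartment.CAP, Compartment.SPOROPHORE}
        spor = next(r for r in recs if r.compartment is Compartment.SPOROPHORE)
        assert spor.censored and spor.detection_limit > 0


_elements = st.sampled_from(ELEMENT_REGISTRY)
_values = st.floats(min_value=0.0, max_value=1e6, allow_nan=False,
                    allow_infinity=False)


@st.composite
def datasets(draw):
    n = draw(st.integers(min_value=0, max_value=8))
    records, used = [], set()
    for i in range(n):
        censored = draw(st.booleans())
        comp = draw(st.sampled_from(list(Compartment)))
        el = draw(_elements)
        key = (f"s{i % 3}", el, comp.value)
        if key in used:
            continue
        used.add(key)
        records.append(ConcentrationRecord(
            sample_id=key[0], site="granite", date="2021-07", compartment=comp,
            element=el,
            value=None if censored else draw(_values),
            censored=censored,
            detection_limit=draw(st.floats(0.001, 10.0)) if censored else None))
    return Dataset(records=records)


class TestRoundTrip:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(datasets())
    def test_read_write_round_trip(self, tmp_path_factory, ds):
        path = tmp_path_factory.mktemp("rt") / "ds.csv"
        write_long_csv(ds, path)
        back = read_long_csv(path)
        assert [r.key for r in back.records] == [r.key for r in ds.records]
        for a, b in zip(ds.records, back.records):
            assert a == b

    def test_empty_dataset_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_long_csv(Dataset(), path)
        assert path.read_text().strip() == CSV_HEADER.strip()

    def test_fixture_round_trips(self, tmp_path, table1):
        path = tmp_path / "t1.csv"
        write_long_csv(table1, path)
        back = read_long_csv(path)
        assert len(back) == len(table1)
        rb = back.get("granite-mean", "Rb", "soil_bearing")
        assert rb.value == 455.0
        se = back.get("granite-mean", "Se", "soil_free")
        assert se.censored and se.detection_limit == 0.20


class TestFixtures:
    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError):
            load_fixture("table9")

    @pytest.mark.parametrize("sample,element,compartment,value", [
        ("granite-mean", "Rb", "soil_bearing", 455.0),
        ("granite-mean", "Rb", "soil_free", 535.0),
        ("serpentinite-mean", "Ni", "soil_bearing", 230.0),
        ("amphibolite-mean", "K", "soil_free", 10212.0),
    ])
    def test_soil_table_cells(self, table1, sample, element, compartment, value):
        assert table1.get(sample, element, compartment).value == value

    @pytest.mark.parametrize("sample,element,part,value", [
        ("serpentinite-mean", "Se", "cap", 3.33),
        ("granite-mean", "Cd", "sporophore", 7.69),
        ("granite-mean", "P", "fb_bulk", 4895.0),
        ("amphibolite-mean", "Rb", "stipe", 415.0),
    ])
    def test_mushroom_table_cells(self, table2, sample, element, part, value):
        assert table2.get(sample, element, part).value == value

    def test_mushroom_table_part_weights(self, table2):
        granite = next(fb for fb in table2.fruiting_bodies if fb.site == "granite")
        assert granite.weight_fractions[Compartment.STIPE] == pytest.approx(0.407)

    def test_mass_balance_table_cells(self, table3):
        assert table3.get("study-mean", "Ag", "soil_free").value == 0.92
        amounts = table3.reported_amounts
        ag = amounts[amounts["element"] == "Ag"].iloc[0]
        assert ag["stock_free"] == 2.55 and ag["fb_amount"] == 0.022

    def test_soil_fixture_censoring_matches_print(self, table1):
        # Se below detection in every soil; Mo only on the serpentinite site
        se = table1.summaries[table1.summaries["element"] == "Se"]
        assert se["censored"].all()
        mo = table1.summaries[table1.summaries["element"] == "Mo"]
        assert mo[mo["site"] == "serpentinite"]["censored"].all()
        assert not mo[mo["site"] == "granite"]["censored"].any()
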