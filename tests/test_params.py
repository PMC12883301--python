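"""Built-in tariffs and probability sets, validation, serialization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from milancost import (
    CostTable,
    Currency,
    MilanCategory as M,
    ModelParameters,
    Procedure as P,
    builtin_cost_table,
    builtin_parameters,
    load_parameters,
    save_parameters,
    weighted_rom,
)
from milancost.params import (
    SUM_TOL,
    category_table_to_csv,
    cost_table_from_csv,
    cost_table_to_csv,
)

# published 2025 tariffs, transcribed cell-for-cell
USD_TARIFF = {
    P.partial_parotidectomy: 13316.0,
    P.submandibulectomy: 8707.0,
    P.total_parotidectomy_nd: 18456.0,
    P.submandibulectomy_nd: 24103.0,
    P.neck_dissection: 15396.0,
    P.fnac: 141.0,
}
EUR_TARIFF = {
    P.partial_parotidectomy: 5047.34,
    P.submandibulectomy: 3808.19,
    P.total_parotidectomy_nd: 11931.02,
    P.submandibulectomy_nd: 11931.02,
    P.neck_dissection: 9864.74,
    P.fnac: 15.37,
}

# real-world cohort: category counts (n = 1289) and observed ROM
RWD_COUNTS = {M.I: 314, M.II: 182, M.III: 113, M.IVa: 501, M.IVb: 72, M.V: 54, M.VI: 53}
RWD_ROM = {M.I: 0.239, M.II: 0.044, M.III: 0.345, M.IVa: 0.010, M.IVb: 0.153, M.V: 0.741, M.VI: 0.962}


@pytest.mark.parametrize(
    "currency,tariff", [("USD", USD_TARIFF), ("EUR", EUR_TARIFF)], ids=["USD", "EUR"]
)
def test_builtin_cost_tables_match_published_tariffs(currency, tariff):
    table = builtin_cost_table(currency)
    for proc, cost in tariff.items():
        assert table[proc] == cost
    # supplementary entries: frozen section bundled, repeat FNAC = FNAC
    assert table[P.frozen_section] == 0.0
    assert table[P.repeat_fnac] == table[P.fnac]
    assert table[P.follow_up] == 0.0
    assert all(v >= 0 for v in table.entries.values())


def test_rwd_parameters_use_exact_category_counts(params_1c):
    total = sum(RWD_COUNTS.values())
    assert total == 1289
    for cat, count in RWD_COUNTS.items():
        assert params_1c.category_dist[cat] == pytest.approx(count / total, abs=1e-12)
    # the table's rounded percentage (38.7 %) agrees with the count ratio
    assert params_1c.category_dist[M.IVa] == pytest.approx(0.387, abs=2e-3)
    assert params_1c.rom == RWD_ROM
    assert params_1c.rom[M.V] == 0.741


@pytest.mark.parametrize("model_id", ["1a", "1b", "1c"])
def test_category_distributions_sum_to_one(model_id):
    p = builtin_parameters(model_id)
    assert abs(sum(p.category_dist.values()) - 1.0) <= SUM_TOL
    assert abs(sum(p.second_fnac_dist.values()) - 1.0) <= SUM_TOL
    assert all(0.0 <= v <= 1.0 for v in p.rom.values())


def test_msrsgc_estimates_are_renormalized_range_midpoints(params_1a, params_1b):
    # independent recomputation: midpoints of the published frequency ranges
    mids = {M.I: 15.0, M.II: 20.0, M.III: 5.0, M.IVa: 35.0, M.IVb: 5.0, M.V: 2.5, M.VI: 12.5}
    total = sum(mids.values())
    for cat, mid in mids.items():
        assert params_1a.category_dist[cat] == pytest.approx(mid / total, abs=1e-12)
    # 1a and 1b share probabilities; they differ only in tariff downstream
    assert params_1a.category_dist == params_1b.category_dist
    assert params_1a.rom == params_1b.rom
    assert params_1a.rom[M.IVa] == 0.015  # "< 3 %" -> 1.5 %
    assert params_1a.rom[M.VI] == 0.99  # "> 98 %" -> 99 %


def test_unknown_model_id_lists_valid_ids():
    with pytest.raises(ValueError, match=r"1a.*1b.*1c"):
        builtin_parameters("2z")


def test_weighted_rom_is_category_weighted_mean(params_1c):
    expect = sum(
        params_1c.category_dist[c] * params_1c.rom[c] for c in M
    )
    assert weighted_rom(params_1c) == pytest.approx(expect)
    assert 0.0 < weighted_rom(params_1c) < 1.0


@pytest.mark.parametrize("suffix", [".json", ".yaml"])
@pytest.mark.parametrize("model_id", ["1a", "1b", "1c"])
def test_parameter_round_trip_is_lossless(tmp_path, model_id, suffix):
    original = builtin_parameters(model_id)
    path = save_parameters(original, tmp_path / f"params{suffix}")
    loaded = load_parameters(path, "model")
    assert loaded == original


@pytest.mark.parametrize("currency", ["USD", "EUR"])
def test_cost_table_round_trip_json_and_csv(tmp_path, currency):
    original = builtin_cost_table(currency)
    loaded = load_parameters(save_parameters(original, tmp_path / "c.json"), "cost")
    assert loaded == original
    from_csv = cost_table_from_csv(cost_table_to_csv(original, tmp_path / "c.csv"))
    assert from_csv == original


def test_category_table_csv_written(tmp_path, params_1c):
    path = category_table_to_csv(params_1c, tmp_path / "cats.csv")
    text = path.read_text()
    assert text.splitlines()[0] == "category,frequency,rom"
    assert len(text.splitlines()) == 8


def test_distribution_not_summing_to_one_names_field(params_1c):
    bad = {c: v * 0.8 for c, v in params_1c.category_dist.items()}
    with pytest.raises((ValidationError, ValueError), match="category_dist"):
        ModelParameters(
            model_id="x",
            category_dist=bad,
            rom=params_1c.rom,
            site_mix=0.8,
            iva_surgery_rate=1.0,
            second_fnac_dist=params_1c.second_fnac_dist,
            upfront_malignancy_rate=0.25,
        )


def test_out_of_range_rom_names_offending_cell(params_1c):
    bad_rom = dict(params_1c.rom)
    bad_rom[M.VI] = 1.2
    with pytest.raises(ValidationError, match=r"rom\.VI"):
        ModelParameters(
            model_id="x",
            category_dist=params_1c.category_dist,
            rom=bad_rom,
            site_mix=0.8,
            iva_surgery_rate=1.0,
            second_fnac_dist=params_1c.second_fnac_dist,
            upfront_malignancy_rate=0.25,
        )


def test_negative_cost_and_missing_procedure_rejected(usd_costs):
    entries = dict(usd_costs.entries)
    entries[P.fnac] = -1.0
    with pytest.raises(ValidationError):
        CostTable(currency=Currency.USD, entries=entries)
    entries = dict(usd_costs.entries)
    del entries[P.neck_dissection]
    with pytest.raises(ValidationError, match="neck_dissection"):
        CostTable(currency=Currency.USD, entries=entries)


def test_load_parameters_missing_file_and_bad_schema(tmp_path, params_1c):
    with pytest.raises(FileNotFoundError):
        load_parameters(tmp_path / "absent.json", "model")
    path = save_parameters(params_1c, tmp_path / "p.json")
    with pytest.raises(ValueError, match="schema"):
        load_parameters(path, "weights")


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    scale=st.floats(min_value=0.1, max_value=2.0),
    value=st.floats(min_value=-0.5, max_value=1.5),
)
def test_fuzzed_invalid_distributions_and_probabilities_rejected(scale, value):
    """Any scaled-away-from-one distribution or out-of-range probability
    is rejected; valid inputs are accepted unchanged."""
    base = builtin_parameters("1c")
    dist = {c: v * scale for c, v in base.category_dist.items()}
    dist_valid = abs(sum(dist.values()) - 1.0) <= SUM_TOL
    site_valid = 0.0 <= value <= 1.0
    try:
        ModelParameters(
            model_id="fuzz",
            category_dist=dist,
            rom=base.rom,
            site_mix=value,
            iva_surgery_rate=1.0,
            second_fnac_dist=base.second_fnac_dist,
            upfront_malignancy_rate=0.25,
        )
        accepted = True
    except (ValidationError, ValueError):
        accepted = False
    assert accepted == (dist_valid and site_valid)
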