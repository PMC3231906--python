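"""Domain types, scenario validation, and serialization round-trips."""

import copy
import json

import pytest

import childimpact as ci
from childimpact.core import ALL_BANDS, AgeBand, default_causes
from childimpact.io import (
    load_csv_dir,
    load_json,
    save_csv_dir,
    save_json,
    scenario_from_dict,
    scenario_to_dict,
)


class TestAgeBands:
    def test_bands_partition_five_years(self):
        assert ALL_BANDS[0].start_months == 0
        assert ALL_BANDS[-1].end_months == 60
        for earlier, later in zip(ALL_BANDS, ALL_BANDS[1:]):
            assert earlier.end_months == later.start_months
            assert earlier < later

    def test_label_round_trip(self):
        for band in ALL_BANDS:
            assert AgeBand.from_label(band.label) is band
        with pytest.raises(KeyError):
            AgeBand.from_label("5-9y")


class TestDefaultCauses:
    def test_registry_structure(self):
        causes = default_causes()
        neonatal_only = {"birth asphyxia", "prematurity", "sepsis/pneumonia",
                         "congenital anomalies", "tetanus"}
        for name in neonatal_only:
            assert causes[name].age_bands == frozenset({AgeBand.NEONATAL})
        assert causes["diarrhoea"].age_bands == frozenset(ALL_BANDS)
        assert causes["pneumonia"].age_bands == frozenset(ALL_BANDS[1:])
        assert causes["other"].is_residual
        assert not causes["AIDS"].active


class TestValidateScenario:
    def test_wellformed_fixture_is_clean(self, worked_scenario):
        assert ci.validate_scenario(worked_scenario) == []

    def test_validation_is_pure(self, worked_scenario):
        first = ci.validate_scenario(worked_scenario)
        second = ci.validate_scenario(worked_scenario)
        assert first == second == []

    def test_out_of_range_coverage_names_trajectory(self, worked_scenario):
        scenario = copy.deepcopy(worked_scenario)
        year = scenario.baseline_year + 1
        scenario.coverage["ors"].coverage[year] = 1.2
        diagnostics = ci.validate_scenario(scenario)
        assert len(diagnostics) == 1
        assert "ors" in diagnostics[0].field and str(year) in diagnostics[0].field

    def test_unnormalised_cause_fractions_name_band(self, worked_scenario):
        scenario = copy.deepcopy(worked_scenario)
        fractions = scenario.mortality.cause_fractions[AgeBand.M6_11]
        fractions["diarrhoea"] -= 0.1
        diagnostics = ci.validate_scenario(scenario)
        assert len(diagnostics) == 1
        assert "6-11m" in diagnostics[0].field

    def test_residual_cause_cannot_be_targeted(self, worked_scenario):
        scenario = copy.deepcopy(worked_scenario)
        scenario.interventions["ors"].effects[("other", AgeBand.M1_5)] = ci.Effect(0.5)
        diagnostics = ci.validate_scenario(scenario)
        assert any("residual" in d.message for d in diagnostics)

    def test_missing_trajectory_reported(self, worked_scenario):
        scenario = copy.deepcopy(worked_scenario)
        del scenario.coverage["ors"]
        diagnostics = ci.validate_scenario(scenario)
        assert any("coverage[ors]" == d.field for d in diagnostics)


class TestSerialization:
    def test_dict_round_trip_is_identity(self, worked_scenario):
        first = scenario_to_dict(worked_scenario)
        second = scenario_to_dict(scenario_from_dict(first))
        assert json.dumps(first, sort_keys=True) == json.dumps(second, sort_keys=True)

    def test_json_file_round_trip(self, worked_scenario, tmp_path):
        path = tmp_path / "scenario.json"
        save_json(worked_scenario, path)
        # a second save of the parsed scenario is byte-identical
        reparsed = load_json(path)
        path2 = tmp_path / "scenario2.json"
        save_json(reparsed, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_csv_dir_round_trip(self, worked_scenario, tmp_path):
        save_csv_dir(worked_scenario, tmp_path / "bundle")
        reparsed = load_csv_dir(tmp_path / "bundle")
        assert scenario_to_dict(reparsed) == scenario_to_dict(worked_scenario)

    def test_random_scenario_round_trips(self, random_scenario, tmp_path):
        path = tmp_path / "random.json"
        save_json(random_scenario, path)
        assert scenario_to_dict(load_json(path)) == scenario_to_dict(random_scenario)
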