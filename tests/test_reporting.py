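import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from faerspv.cli import main as cli_main
from faerspv.faers_ingest import CaseData
from faerspv.reporting_cli import (
    PipelineConfig, concomitant_frequency, fatal_pt_ranking, rank_terms,
    run_pipeline, table1_summary,
)
from faerspv.reporting_util import percent, round_half_up
from faerspv.synthetic_faers import DEFAULT_CONCOMITANT_PROBS, SyntheticConfig, generate_cohort


def make_cases(rows):
    """rows: dicts with any of the CaseData columns; missing ones defaulted."""
    defaults = dict(caseid=0, fda_dt=20200101, event_dt="", sex="", age_years=float("nan"),
                    age_group="Missing", weight_kg=float("nan"), weight_band="Missing",
                    occp_cod="", occp_class="Missing", reporter_country="",
                    outcomes=frozenset(), reactions=frozenset(), indications=frozenset(),
                    concomitants=(), start_dt=None, is_target=True, analyzable=True)
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults, primaryid=i + 1, **row)
        rec["analyzable"] = len(rec["reactions"]) > 0
        records.append(rec)
    return CaseData(cases=pd.DataFrame(records))


class TestRounding:
    @pytest.mark.parametrize("value,expected", [(2.45, 2.5), (2.44, 2.4), (0.05, 0.1), (84.049, 84.0)])
    def test_half_up(self, value, expected):
        assert round_half_up(value) == expected

    def test_percent(self):
        assert percent(83_928, 130_818) == 64.2


class TestTable1:
    def test_toy_enumeration(self):
        data = make_cases([{"sex": "F"}, {"sex": "F"}, {"sex": "M"}, {"sex": ""}])
        out = table1_summary(data)["sex"].set_index("category")
        assert out.loc["F", "pct"] == 50.0
        assert out.loc["M", "pct"] == 25.0
        assert out.loc["Missing", "pct"] == 25.0
        assert out["count"].sum() == 4

    def test_counts_sum_to_total_and_pcts_to_100(self, case_data):
        total = len(case_data.target)
        for dim, frame in table1_summary(case_data).items():
            assert frame["count"].sum() == total, dim
            assert abs(frame["pct"].sum() - 100.0) <= 0.2 + 1e-9, dim

    def test_most_severe_outcome_wins(self):
        data = make_cases([{"outcomes": frozenset({"OT", "DE"})}])
        out = table1_summary(data)["outcome"]
        assert out.iloc[0]["category"] == "DE"


class TestRanking:
    FRAME = pd.DataFrame({
        "term": ["Alpha", "Beta", "Gamma"],
        "a": [5, 3, 3],
        "ror": [2.0, 8.0, 1.5],
    })

    def test_tie_broken_alphabetically(self):
        out = rank_terms(self.FRAME, "n_reports", 10)
        assert out["term"].tolist() == ["Alpha", "Beta", "Gamma"]

    def test_top_k_zero_empty(self):
        assert len(rank_terms(self.FRAME, "n_reports", 0)) == 0

    def test_ror_ranking_applies_count_gate(self):
        frame = self.FRAME.copy()
        frame.loc[1, "a"] = 2  # Beta below the gate
        out = rank_terms(frame, "ror", 10)
        assert out["term"].tolist() == ["Alpha", "Gamma"]

    def test_unknown_key_rejected(self):
        with pytest.raises(Exception):
            rank_terms(self.FRAME, "banana", 5)


class TestConcomitants:
    def test_counts_once_per_case(self):
        data = make_cases([
            {"concomitants": ("PREDNISONE", "PREDNISONE")},
            {"concomitants": ("PREDNISONE", "ENBREL")},
            {"concomitants": ()},
        ])
        out = concomitant_frequency(data).set_index("drug")
        assert out.loc["PREDNISONE", "count"] == 2
        assert out.loc["ENBREL", "count"] == 1

    def test_synthetic_frequencies_binomial(self, case_data):
        n = len(case_data.target)
        out = concomitant_frequency(case_data).set_index("drug")
        for drug, p in DEFAULT_CONCOMITANT_PROBS.items():
            count = int(out.loc[drug.upper(), "count"]) if drug.upper() in out.index else 0
            sd = np.sqrt(n * p * (1 - p))
            assert abs(count - n * p) < 4 * sd, drug


class TestFatalRanking:
    def test_no_death_cases_empty(self):
        data = make_cases([{"outcomes": frozenset({"HO"}), "reactions": frozenset({"X"})}])
        assert len(fatal_pt_ranking(data)) == 0

    def test_toy_enumeration(self):
        data = make_cases([
            {"outcomes": frozenset({"DE"}), "reactions": frozenset({"Death"})},
            {"outcomes": frozenset({"DE"}), "reactions": frozenset({"Death", "Sepsis"})},
            {"outcomes": frozenset({"HO"}), "reactions": frozenset({"Sepsis"})},
        ])
        out = fatal_pt_ranking(data)
        assert out.iloc[0]["display"] == "2/2" and out.iloc[0]["pt"] == "Death"
        assert out.iloc[1]["display"] == "1/2" and out.iloc[1]["pt"] == "Sepsis"


class TestPipeline:
    def test_smoke_run_outputs_consistent(self, tmp_path):
        config = PipelineConfig(mode="generate", n_reports=3000, seed=1,
                                output_dir=str(tmp_path / "run1"))
        manifest = run_pipeline(config)
        for name in manifest["outputs"]:
            assert (tmp_path / "run1" / name).exists()
        flow = manifest["flow_counts"]
        assert flow["cases"] == 3000
        assert flow["demo_rows_read"] - flow["duplicates_removed"] == flow["cases"]
        assert 0 < flow["target_cases"] < flow["cases"]

    def test_rerun_byte_identical(self, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            run_pipeline(PipelineConfig(mode="generate", n_reports=1500, seed=9,
                                        output_dir=str(out)))
        for name in sorted(p.name for p in out1.glob("*.tsv")):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name

    def test_duplicate_injection_does_not_change_selected_cases(self, tmp_path):
        manifests = []
        for rate, out in [(0.0, "r0"), (0.5, "r5")]:
            manifests.append(run_pipeline(PipelineConfig(
                mode="generate", n_reports=1500, seed=4, duplicate_rate=rate,
                output_dir=str(tmp_path / out))))
        assert manifests[0]["flow_counts"]["target_cases"] == manifests[1]["flow_counts"]["target_cases"]
        assert manifests[1]["flow_counts"]["duplicates_removed"] > 0

    def test_ingest_mode_round_trip(self, tmp_path, meddra_map):
        gen_dir = tmp_path / "gen"
        run_pipeline(PipelineConfig(mode="generate", n_reports=1000, seed=2,
                                    output_dir=str(gen_dir)))
        map_path = tmp_path / "meddra.tsv"
        meddra_map.to_tsv(map_path)
        manifest = run_pipeline(PipelineConfig(
            mode="ingest", input_dir=str(gen_dir / "faers_tables"),
            meddra_map_path=str(map_path), output_dir=str(tmp_path / "re")))
        assert manifest["flow_counts"]["cases"] == 1000

    def test_toml_config_round_trip(self, tmp_path):
        config_path = tmp_path / "run.toml"
        config_path.write_text(
            'mode = "generate"\n'
            f'output_dir = "{tmp_path / "out"}"\n'
            "n_reports = 800\nseed = 3\n"
            'planted_signals = [["Rash", 4.0]]\n'
            "[thresholds]\nebgm05_min = 1.5\n"
        )
        config = PipelineConfig.from_toml(config_path)
        assert config.thresholds.ebgm05_min == 1.5
        manifest = run_pipeline(config)
        assert manifest["flow_counts"]["cases"] == 800


class TestCLI:
    def test_generate_and_ingest(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["generate", "--n-reports", "300", "--seed", "2",
                                          "--out", str(tmp_path / "gen")])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "gen" / "DEMO.txt").exists()
        result = runner.invoke(cli_main, ["ingest", "--input-dir", str(tmp_path / "gen")])
        assert result.exit_code == 0, result.output
        assert json.loads(result.output)["cases"] == 300

    def test_signals_subcommand(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["signals", "--n-reports", "800", "--seed", "1",
                                          "--out", str(tmp_path / "sig")])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "sig" / "signals_pt.tsv").exists()
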