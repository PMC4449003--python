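"""File formats, configuration, pipeline orchestration and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from foragefit import (
    GambleSetConfig,
    PipelineConfig,
    generate_gamble_set,
    load_config,
    run_pipeline,
    simulate_cohort,
    simulate_rts,
)
from foragefit.cli import main as cli_main
from foragefit.config import config_hash
from foragefit.inference import FitOptions
from foragefit.io import (
    dataset_summary,
    load_dataset,
    read_gamble_set,
    write_dataset,
    write_gamble_set,
)
from foragefit.synthetic_cohort import RtGeneratorSpec, records_to_frame


@pytest.fixture(scope="module")
def tiny_dataset():
    ds, _ = simulate_cohort(
        n_agents=4, seed=21, missed_rate=0.02,
        gamble_config=GambleSetConfig(pairs_per_combo=10),
    )
    return simulate_rts(ds, seed=22)


class TestCsvRoundTrips:
    def test_gamble_set_round_trip(self, tmp_path):
        pairs = generate_gamble_set(GambleSetConfig(pairs_per_combo=5), seed=1)
        path = tmp_path / "gambles.csv"
        write_gamble_set(pairs, path)
        assert read_gamble_set(path) == pairs

    def test_dataset_round_trip(self, tmp_path, tiny_dataset):
        path = tmp_path / "ds.csv"
        write_dataset(tiny_dataset, path)
        records = load_dataset(path, format="csv")
        assert records_to_frame(records).pipe(len) == len(tiny_dataset)
        # loss-free: writing the reloaded records reproduces the table
        again = records_to_frame(records)
        pd.testing.assert_frame_equal(
            again.reset_index(drop=True),
            tiny_dataset.reset_index(drop=True),
            check_dtype=False,
        )

    def test_load_summary_counts_participants(self, tmp_path, tiny_dataset):
        path = tmp_path / "ds.csv"
        write_dataset(tiny_dataset, path)
        records = load_dataset(path)
        summary = dataset_summary(records)
        assert summary["n_participants"] == 4
        assert summary["n_trials"] == len(tiny_dataset)

    def test_nonpositive_rt_rejected_with_line_number(self, tmp_path, tiny_dataset):
        bad = tiny_dataset.copy()
        first_kept = bad.index[bad["choice"] != "missed"][0]
        bad.loc[first_kept, "rt_ms"] = -1.0
        path = tmp_path / "bad.csv"
        write_dataset(bad, path)
        with pytest.raises(ValueError, match="line"):
            load_dataset(path)


class TestMatLoader:
    def test_field_map_required(self, tmp_path):
        from scipy.io import savemat

        path = tmp_path / "synthetic_trials.mat"
        savemat(path, {"x": np.arange(3)})
        with pytest.raises(ValueError, match="field_map"):
            load_dataset(path, format="mat")

    def test_synthetic_mat_round_trip(self, tmp_path, tiny_dataset):
        # synthetic stand-in for an externally deposited MAT file
        from scipy.io import savemat

        sub = tiny_dataset[tiny_dataset["choice"] != "missed"].head(50)
        variables = {f"v_{c}": sub[c].to_numpy() for c in sub.columns}
        path = tmp_path / "synthetic_trials.mat"
        savemat(path, variables)
        field_map = {c: f"v_{c}" for c in sub.columns}
        records = load_dataset(path, format="mat", field_map=field_map)
        assert len(records) == 50
        assert records[0].participant_id == str(sub.iloc[0]["participant_id"])

    def test_missing_variable_reported(self, tmp_path, tiny_dataset):
        from scipy.io import savemat

        sub = tiny_dataset.head(5)
        variables = {f"v_{c}": sub[c].to_numpy() for c in sub.columns}
        del variables["v_choice"]
        path = tmp_path / "synthetic_trials.mat"
        savemat(path, variables)
        field_map = {c: f"v_{c}" for c in sub.columns}
        with pytest.raises(ValueError, match="v_choice"):
            load_dataset(path, format="mat", field_map=field_map)


class TestConfig:
    def test_yaml_round_trip_and_validation(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "seed: 3\n"
            "models: [1, 7, 10]\n"
            "gamble: {pairs_per_combo: 10}\n"
            "optimizer: {xatol: 1.0e-5}\n"
            "rt: {gamma: [7.0, -0.1, -0.4, 0.1], re_sd: [0.2, 0, 0, 0],"
            " resid_sd: 0.3}\n"
        )
        cfg = load_config(path)
        assert cfg.seed == 3
        assert cfg.models == (1, 7, 10)
        assert cfg.gamble.pairs_per_combo == 10
        assert cfg.optimizer.xatol == pytest.approx(1e-5)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("bogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            load_config(path)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(ic="dic")
        with pytest.raises(ValueError):
            PipelineConfig(models=(1, 99))

    def test_hash_stable_and_sensitive(self):
        a = PipelineConfig(seed=1)
        b = PipelineConfig(seed=1)
        c = PipelineConfig(seed=2)
        assert config_hash(a) == config_hash(b)
        assert config_hash(a) != config_hash(c)


@pytest.fixture(scope="module")
def demo_config():
    return PipelineConfig(
        seed=5,
        gamble=GambleSetConfig(pairs_per_combo=10),
        n_agents=5,
        generating_model=10,
        models=(1, 7, 10),
        optimizer=FitOptions(),
        bms_samples=50_000,
        rt=RtGeneratorSpec(
            gamma=(7.2, -0.08, -0.5, 0.2), re_sd=(0.2, 0, 0, 0), resid_sd=0.3
        ),
        rt_re_structure="intercept",
    )


class TestPipeline:
    def test_end_to_end_smoke_and_resume(self, tmp_path, demo_config):
        outdir = tmp_path / "run"
        manifest = run_pipeline(demo_config, outdir)
        for name in ("gambles.csv", "dataset.csv", "fits.csv",
                     "comparison.json", "comparison.txt", "rt.json",
                     "ground_truth.json", "manifest.json"):
            assert (outdir / name).exists(), name
        assert all(s["status"] == "done" for s in manifest["stages"].values())

        report = json.loads((outdir / "comparison.json").read_text())
        assert report["config_hash"] == config_hash(demo_config)
        assert set(report["sign_tests"]) == {
            "xi_foraging", "xi_casino", "xi_foraging_vs_casino"
        }

        # second run with the same config hash skips every stage
        dataset_bytes = (outdir / "dataset.csv").read_bytes()
        manifest2 = run_pipeline(demo_config, outdir)
        assert (outdir / "dataset.csv").read_bytes() == dataset_bytes
        assert manifest2["stages"] == manifest["stages"]

    def test_deterministic_stage_outputs_reproduce(self, tmp_path, demo_config):
        out_a = tmp_path / "a"
        out_b = tmp_path / "b"
        run_pipeline(demo_config, out_a)
        run_pipeline(demo_config, out_b)
        for name in ("gambles.csv", "dataset.csv"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()


class TestCli:
    def test_gen_gambles_and_simulate_and_fit(self, tmp_path):
        runner = CliRunner()
        gpath = tmp_path / "g.csv"
        res = runner.invoke(
            cli_main,
            ["gen-gambles", "--seed", "1", "--pairs-per-combo", "5",
             "--out", str(gpath)],
        )
        assert res.exit_code == 0, res.output
        assert len(read_gamble_set(gpath)) == 20

        dpath = tmp_path / "d.csv"
        res = runner.invoke(
            cli_main,
            ["simulate", "--seed", "2", "--n-agents", "2",
             "--pairs-per-combo", "5", "--out", str(dpath)],
        )
        assert res.exit_code == 0, res.output

        fpath = tmp_path / "f.csv"
        res = runner.invoke(
            cli_main,
            ["fit", str(dpath), "--models", "1,EV+pstarve", "--out", str(fpath)],
        )
        assert res.exit_code == 0, res.output
        fits = pd.read_csv(fpath)
        assert sorted(fits["model_id"].unique()) == [1, 7]

    def test_compare_ic_switch_keeps_dominant_order(self, tmp_path):
        # construct fits where one model dominates under BIC and AIC alike
        rng = np.random.default_rng(0)
        rows = []
        for i in range(6):
            base = rng.normal(400, 5)
            for mid, negll, k in ((1, base, 1), (7, base - 40, 2)):
                rows.append({
                    "participant_id": f"s{i}",
                    "model_id": mid,
                    "negll": negll,
                    "bic": negll + 0.5 * k * np.log(960),
                    "aic": negll + k,
                })
        fpath = tmp_path / "fits.csv"
        pd.DataFrame(rows).to_csv(fpath, index=False)
        runner = CliRunner()
        winners = {}
        for ic in ("bic", "aic"):
            out = tmp_path / f"cmp_{ic}.json"
            res = runner.invoke(
                cli_main, ["compare", str(fpath), "--ic", ic, "--out", str(out)]
            )
            assert res.exit_code == 0, res.output
            report = json.loads(out.read_text())
            winners[ic] = min(
                report["log_group_bayes_factors"],
                key=report["log_group_bayes_factors"].get,
            )
        assert winners["bic"] == winners["aic"] == "7"

    def test_recover_command_reports_medians(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "rec.json"
        res = runner.invoke(
            cli_main,
            ["recover", "--model", "7", "--n-agents", "3", "--seed", "4",
             "--pairs-per-combo", "10", "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        report = json.loads(out.read_text())
        assert set(report["params"]) == {"beta", "xi"}
        assert report["params"]["xi"]["recovered_median"] < 0
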