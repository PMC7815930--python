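import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import fnirsflow as ff
from fnirsflow import io as fio
from fnirsflow.cli import main as cli_main
from fnirsflow.config import PipelineConfig, config_hash, load_config
from fnirsflow.io import SchemaError
from fnirsflow.pipeline import PipelineError, run_pipeline

FS = 15.625


def random_recording(seed=0, n=60):
    rng = np.random.default_rng(seed)
    return ff.OpticalRecording(rng.uniform(0.5, 2.0, size=(n, 12, 2)), fs=FS)


def random_hemo(seed=0, n=60):
    rng = np.random.default_rng(seed)
    return ff.HemoSeries(rng.normal(size=(n, 12)), rng.normal(size=(n, 12)), fs=FS)


SMALL_RUN = {
    "seed": 3,
    "epochs": {"window_len": 128, "stride": 100, "max_windows_per_trial": 2},
    "network": {"variant": "CNN1-a"},
    "train": {"epochs": 2, "batch_size": 16, "learning_rate": 0.001},
}


class TestCsvRoundTrips:
    def test_intensity(self, tmp_path):
        rec = random_recording()
        p = tmp_path / "i.csv"
        fio.write_intensity_csv(rec, p)
        back = fio.read_intensity_csv(p)
        assert np.allclose(back.intensity, rec.intensity, rtol=1e-9)
        assert back.fs == pytest.approx(FS, rel=1e-6)

    def test_hemo(self, tmp_path):
        hemo = random_hemo()
        p = tmp_path / "h.csv"
        fio.write_hemo_csv(hemo, p)
        back = fio.read_hemo_csv(p)
        assert np.allclose(back.dhbo, hemo.dhbo, rtol=1e-9, atol=1e-12)
        assert np.allclose(back.dhbr, hemo.dhbr, rtol=1e-9, atol=1e-12)

    def test_missing_channel_named_in_error(self, tmp_path):
        hemo = random_hemo()
        p = tmp_path / "h.csv"
        fio.write_hemo_csv(hemo, p)
        text = p.read_text()
        broken = tmp_path / "b.csv"
        broken.write_text(text.replace("ch12_HbR", "ch12_XXX"))
        with pytest.raises(SchemaError, match="ch12_HbR"):
            fio.read_hemo_csv(broken)

    def test_schedule_roundtrip(self, tmp_path, paper_schedule):
        events, _ = paper_schedule
        p = tmp_path / "s.tsv"
        fio.write_schedule_tsv(events, p)
        assert fio.read_schedule_tsv(p) == events


SNIRF_REQUIRED = [
    "formatVersion",
    "nirs/data1/dataTimeSeries",
    "nirs/data1/time",
    "nirs/data1/measurementList1/sourceIndex",
    "nirs/data1/measurementList1/detectorIndex",
    "nirs/data1/measurementList1/wavelengthIndex",
    "nirs/data1/measurementList1/dataType",
    "nirs/data1/measurementList1/dataTypeIndex",
    "nirs/probe/wavelengths",
    "nirs/probe/sourcePos3D",
    "nirs/probe/detectorPos3D",
    "nirs/metaDataTags/SubjectID",
    "nirs/metaDataTags/MeasurementDate",
    "nirs/metaDataTags/MeasurementTime",
    "nirs/metaDataTags/LengthUnit",
    "nirs/metaDataTags/TimeUnit",
    "nirs/metaDataTags/FrequencyUnit",
]


class TestSnirf:
    def test_intensity_roundtrip(self, tmp_path):
        rec = random_recording()
        p = tmp_path / "r.snirf"
        fio.write_snirf(rec, p)
        back = fio.read_snirf(p)
        assert isinstance(back, ff.OpticalRecording)
        assert np.allclose(back.intensity, rec.intensity)

    def test_hemo_roundtrip(self, tmp_path):
        hemo = random_hemo()
        p = tmp_path / "h.snirf"
        fio.write_snirf(hemo, p)
        back = fio.read_snirf(p)
        assert isinstance(back, ff.HemoSeries)
        assert np.allclose(back.dhbo, hemo.dhbo)
        assert np.allclose(back.dhbr, hemo.dhbr)

    def test_required_fields_present(self, tmp_path):
        import h5py

        p = tmp_path / "r.snirf"
        fio.write_snirf(random_recording(), p)
        with h5py.File(p) as f:
            for field in SNIRF_REQUIRED:
                assert field in f, f"missing SNIRF field {field}"

    def test_dispatch(self, tmp_path):
        hemo = random_hemo()
        p = tmp_path / "h.snirf"
        fio.write_recording(hemo, p, "snirf")
        assert isinstance(fio.read_recording(p, "snirf"), ff.HemoSeries)
        with pytest.raises(SchemaError):
            fio.read_recording(p, "bogus")


class TestConfig:
    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text(yaml.safe_dump({"seed": 1, "bogus_section": {}}))
        with pytest.raises(Exception):
            load_config(p)

    def test_hash_stable_and_sensitive(self):
        a = PipelineConfig(seed=1)
        b = PipelineConfig(seed=1)
        c = PipelineConfig(seed=2)
        assert config_hash(a) == config_hash(b)
        assert config_hash(a) != config_hash(c)

    def test_defaults_load_from_empty_file(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("")
        cfg = load_config(p)
        assert cfg.fs == FS


class TestRunPipeline:
    def test_smoke_emits_all_artifacts(self, tmp_path):
        cfg = PipelineConfig.model_validate(SMALL_RUN)
        res = run_pipeline(cfg, tmp_path / "out")
        names = set(res["artifacts"])
        assert {"hemo_raw.csv", "hemo_preprocessed.csv", "schedule.tsv",
                "labels.tsv", "cv_report.tsv", "summary.json", "tmap.tsv",
                "pca_scores.tsv"} <= names
        summary = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert summary["seed"] == 3 and "config_hash" in summary

    def test_rerun_is_bit_identical(self, tmp_path):
        cfg = PipelineConfig.model_validate(SMALL_RUN)
        run_pipeline(cfg, tmp_path / "a")
        run_pipeline(cfg, tmp_path / "b")
        for name in ("summary.json", "cv_report.tsv", "tmap.tsv", "pca_scores.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_bad_filter_aborts_in_preprocess_stage(self, tmp_path):
        cfg = PipelineConfig.model_validate({**SMALL_RUN,
                                             "filter": {"fc_hz": 20.0}})
        with pytest.raises(PipelineError, match="preprocess"):
            run_pipeline(cfg, tmp_path / "out")


class TestCli:
    def test_all_subcommands_end_to_end(self, tmp_path):
        runner = CliRunner()
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump({
            "epochs": {"window_len": 128, "stride": 100, "max_windows_per_trial": 2},
            "network": {"variant": "CNN1-a"},
            "train": {"epochs": 2, "batch_size": 16, "learning_rate": 0.001},
        }))
        out = tmp_path / "sim"

        r = runner.invoke(cli_main, ["simulate", "--config", str(cfg_path),
                                     "--seed", "4", "--out-dir", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "hemo_raw.csv").exists()

        r = runner.invoke(cli_main, ["preprocess", "--config", str(cfg_path),
                                     str(out / "hemo_raw.csv"),
                                     str(out / "hemo_pp.csv")])
        assert r.exit_code == 0, r.output

        r = runner.invoke(cli_main, ["tensorize", "--config", str(cfg_path),
                                     "--hemo", str(out / "hemo_pp.csv"),
                                     "--schedule", str(out / "schedule.tsv")])
        assert r.exit_code == 0 and "tensors" in r.output

        r = runner.invoke(cli_main, ["train", "--config", str(cfg_path),
                                     "--hemo", str(out / "hemo_pp.csv"),
                                     "--schedule", str(out / "schedule.tsv"),
                                     "--model-out", str(out / "model.npz"),
                                     "--seed", "4"])
        assert r.exit_code == 0, r.output
        assert (out / "model.npz").exists()

        r = runner.invoke(cli_main, ["evaluate", "--config", str(cfg_path),
                                     "--hemo", str(out / "hemo_pp.csv"),
                                     "--schedule", str(out / "schedule.tsv"),
                                     "--k", "8", "--seed", "4"])
        assert r.exit_code == 0, r.output
        assert "mean" in r.output

        r = runner.invoke(cli_main, ["tmap", "--config", str(cfg_path),
                                     "--hemo", str(out / "hemo_pp.csv"),
                                     "--schedule", str(out / "schedule.tsv")])
        assert r.exit_code == 0 and "t_crit" in r.output

        r = runner.invoke(cli_main, ["shapes", "--variant", "CNN3-a",
                                     "--m-samples", "208", "--compat-table3"])
        assert r.exit_code == 0
        assert "312\t52" in r.output

        r = runner.invoke(cli_main, ["run", "--config", str(cfg_path),
                                     "--seed", "4", "--out-dir", str(tmp_path / "run")])
        assert r.exit_code == 0, r.output

    def test_convert_roundtrip(self, tmp_path):
        runner = CliRunner()
        big = random_hemo(n=120)
        hemo = ff.HemoSeries(0.01 * big.dhbo, 0.01 * big.dhbr, fs=big.fs)
        # zero-mean hemo -> forward optical -> CLI convert recovers (approx.,
        # baseline is whole-series mean intensity)
        rec = ff.simulate_optical(hemo)
        fio.write_intensity_csv(rec, tmp_path / "i.csv")
        r = runner.invoke(cli_main, ["convert", str(tmp_path / "i.csv"),
                                     str(tmp_path / "h.csv")])
        assert r.exit_code == 0, r.output
        back = fio.read_hemo_csv(tmp_path / "h.csv")
        # recovery up to the per-channel baseline offset
        resid = (back.dhbo - hemo.dhbo) - (back.dhbo - hemo.dhbo).mean(axis=0)
        assert np.max(np.abs(resid)) < 1e-6
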