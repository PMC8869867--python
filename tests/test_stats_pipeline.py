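"""Tests for the shared t-test, the end-to-end pipeline, IO round trips and CLI."""

import dataclasses
import json
import math

import numpy as np
import pandas as pd
import pytest

from proteaphagy import PipelineConfig, run_pipeline, two_sample_ttest
from proteaphagy import io as pio
from proteaphagy import synth
from proteaphagy.pipeline import report_json, validate_report
from proteaphagy.stats import significance_stars


def closed_form_student_t(a, b):
    """Textbook pooled-variance t-test, independent of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


class TestTTest:
    def test_identical_groups(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p_value == 1.0

    def test_within_group_permutation_invariance(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert res.t == 0.0 and res.p_value == 1.0

    def test_matches_closed_form_to_1e10(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 1.5, rng.integers(3, 12))
            res = two_sample_ttest(a, b)
            t_ref, p_ref = closed_form_student_t(a, b)
            assert res.t == pytest.approx(t_ref, rel=1e-10)
            assert res.p_value == pytest.approx(p_ref, rel=1e-10)

    def test_near_constant_groups_highly_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, 4)
        b = 1 + rng.normal(0, 0.01, 4)
        assert two_sample_ttest(a, b).p_value < 1e-6

    def test_zero_variance_unequal_means_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = two_sample_ttest([1.0, 1.0], [2.0, 2.0])
        assert res.p_value == 0.0

    def test_welch_variant_differs_under_heteroscedasticity(self):
        a = [0.0, 0.1, -0.1, 0.05, -0.05]
        b = [1.0, 3.0, -2.0, 4.0, -1.0]
        student = two_sample_ttest(a, b, variant="student")
        welch = two_sample_ttest(a, b, variant="welch")
        assert student.df == 8.0
        assert welch.df != student.df

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])

    def test_star_convention(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(5e-5) == "****"


@pytest.fixture(scope="module")
def fast_config(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    return PipelineConfig(
        seed=11,
        outdir=str(outdir),
        counts=synth.SynthCountConfig(n_proteins=300, seed=0, categorize=True),
        image=dataclasses.replace(
            PipelineConfig().image, n_spots=10, size=(128, 128), threshold=400.0
        ),
    )


class TestPipeline:
    def test_report_structure_and_files(self, fast_config):
        report = run_pipeline(fast_config)
        validate_report(report)
        assert set(report["stages"]) == {"quantify", "differential", "annotate", "coloc", "ci"}
        out = pio.ensure_dir(fast_config.outdir)
        for name in ("report.json", "matrix_normalized.tsv", "differential.tsv", "dose_response.csv"):
            assert (out / name).exists()

    def test_same_seed_gives_byte_identical_reports(self, fast_config):
        a = report_json(run_pipeline(fast_config, write_outputs=False))
        b = report_json(run_pipeline(fast_config, write_outputs=False))
        assert a == b

    def test_category_signs_follow_the_plant(self, fast_config):
        report = run_pipeline(fast_config, write_outputs=False)
        diffs = report["stages"]["annotate"]["category_difference"]
        for name, value in diffs.items():
            if name in ("20S alpha", "20S beta", "19S base", "19S lid"):
                assert value < 0, name
            else:
                assert value > 0, name

    def test_all_stages_disabled_gives_config_echo_only(self, tmp_path):
        cfg = PipelineConfig(stages=(), outdir=str(tmp_path / "empty"))
        report = run_pipeline(cfg, write_outputs=False)
        assert report["stages"] == {}
        assert report["seed"] == cfg.seed

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = PipelineConfig(seed=3)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        loaded = PipelineConfig.from_yaml(path)
        assert loaded == cfg

    def test_invalid_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stages"):
            PipelineConfig(stages=("quantify", "nope"))

    def test_schema_validation_catches_missing_keys(self):
        with pytest.raises(ValueError, match="missing required key"):
            validate_report({"version": "0.1.0", "seed": 0, "config": {}})


class TestIO:
    def test_counts_round_trip(self, tmp_path, default_counts):
        scm, _ = default_counts
        pio.write_counts_tsv(scm, tmp_path / "c.tsv", tmp_path / "s.tsv")
        psm, samples = pio.read_counts_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        from proteaphagy.quant import aggregate_psm_counts

        back = aggregate_psm_counts(psm, samples)
        pd.testing.assert_frame_equal(
            back.data.sort_index(), scm.data.sort_index(), check_like=True
        )

    def test_tiff_round_trip(self, tmp_path):
        image, _ = synth.generate_two_channel_image(n_spots=5, overlap_fraction=0.5, seed=0)
        pio.write_two_channel_tiff(image, tmp_path / "r.tif", tmp_path / "p.tif")
        back = pio.read_two_channel_tiff(tmp_path / "r.tif", tmp_path / "p.tif")
        np.testing.assert_allclose(back.reference, np.round(image.reference), atol=0.5)

    def test_dose_response_round_trip(self, tmp_path):
        truth = synth.DoseResponseTruth(m_a=1.5, dm_a=10.0, m_b=2.0, dm_b=5.0)
        dr = synth.generate_dose_response(truth, doses=[5, 10], seed=0)
        pio.write_dose_response_csv(dr, tmp_path / "dr.csv")
        back = pio.read_dose_response_csv(tmp_path / "dr.csv", ratio=1.0)
        pd.testing.assert_frame_equal(back, dr, check_dtype=False)


class TestCLI:
    def test_simulate_then_quantify_then_differential(self, tmp_path):
        from click.testing import CliRunner

        from proteaphagy.cli import main

        runner = CliRunner()
        sim = tmp_path / "sim"
        r = runner.invoke(main, ["simulate", "--seed", "1", "--out", str(sim), "--n-proteins", "200"])
        assert r.exit_code == 0, r.output
        q = tmp_path / "quant"
        r = runner.invoke(
            main,
            ["quantify", "--counts", str(sim / "counts.tsv"), "--samples", str(sim / "samples.tsv"), "--out", str(q)],
        )
        assert r.exit_code == 0, r.output
        d = tmp_path / "diff"
        r = runner.invoke(
            main,
            [
                "differential",
                "--normalized", str(q / "matrix_normalized.tsv"),
                "--samples", str(sim / "samples.tsv"),
                "--out", str(d),
            ],
        )
        assert r.exit_code == 0, r.output
        summary = json.loads((d / "summary.json").read_text())
        assert summary["n_total_differential"] > 0

    def test_run_subcommand_writes_report(self, tmp_path):
        from click.testing import CliRunner

        from proteaphagy.cli import main

        # small config to keep the smoke test quick
        import yaml

        cfg = PipelineConfig(
            counts=synth.SynthCountConfig(n_proteins=100, categorize=True),
            image=dataclasses.replace(PipelineConfig().image, n_spots=6, size=(96, 96), threshold=400.0),
        ).to_dict()
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg))
        out = tmp_path / "run"
        r = CliRunner().invoke(
            main, ["run", "--config", str(path), "--seed", "2", "--out", str(out)]
        )
        assert r.exit_code == 0, r.output
        report = json.loads((out / "report.json").read_text())
        assert report["seed"] == 2
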