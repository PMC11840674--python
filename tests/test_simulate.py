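"""Synthetic-cohort generator: determinism, marginals, ground truth."""

import json

import numpy as np
import pandas as pd
import pytest

from allotrace.calling import call_drtc
from allotrace.io import read_manifest
from allotrace.simulate import (
    ConfigError,
    SimulationConfig,
    simulate_cohort,
    simulate_subject,
    write_cohort,
)


class TestConfig:
    def test_defaults_validate(self):
        SimulationConfig().validate()

    @pytest.mark.parametrize(
        "kw",
        [
            {"alloreactive_fraction": 1.5},
            {"depth_pbmc": 0},
            {"depth_pbmc": 10**9, "n_clones": 100},
            {"zipf_exponent": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimulationConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_clones=500, depth_pbmc=5000, depth_mlr=2000)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SimulationConfig.from_yaml(p) == cfg


class TestSubjectSimulation:
    def test_fixed_seed_is_bit_identical(self, small_config):
        a = simulate_subject(small_config, 0)
        b = simulate_subject(small_config, 0)
        for role in a.samples:
            pd.testing.assert_frame_equal(a.samples[role].table, b.samples[role].table)
        assert a.truth.allo_cd4 == b.truth.allo_cd4

    def test_distinct_subjects_have_distinct_repertoires(self, small_cohort):
        keys0 = set(small_cohort[0].samples["pre_pbmc"].table.index)
        keys1 = set(small_cohort[1].samples["pre_pbmc"].table.index)
        assert not (keys0 & keys1)

    def test_sample_set_complete(self, small_cohort):
        expected = {"pre_pbmc", "mlr_cd4", "mlr_cd8", "post_pbmc", "biopsy", "urine"}
        for subj in small_cohort:
            assert set(subj.samples) == expected

    def test_truth_never_leaks_into_sample_tables(self, rejection_subject):
        # ground-truth keys must simply be ordinary clones of the repertoire
        pre_keys = set(rejection_subject.samples["pre_pbmc"].table.index)
        allo = set(rejection_subject.truth.allo_cd4) | set(rejection_subject.truth.allo_cd8)
        assert allo - pre_keys  # some alloreactive clones fall below depth: no flagging

    def test_null_construction_no_expansion(self):
        # expansion factor pinned to 1: the MLR is a plain resample, so the
        # caller finds nothing in the clear majority of replicates
        cfg = SimulationConfig(
            n_subjects=1,
            seed=3,
            n_clones=2000,
            mlr_expansion_median=1.0,
            mlr_expansion_sigma=0.0,
            depth_pbmc=20_000,
            depth_mlr=8_000,
        )
        calls = []
        for i in range(20):
            cfg.seed = 1000 + i
            subj = simulate_subject(cfg, 0)
            drtc = call_drtc(subj.samples["mlr_cd4"], subj.samples["pre_pbmc"])
            calls.append(len(drtc))
        assert np.median(calls) == 0

    def test_alloreactive_fraction_zero(self):
        cfg = SimulationConfig(
            n_subjects=1, seed=2, n_clones=1000, alloreactive_fraction=0.0,
            depth_pbmc=10_000, depth_mlr=4_000, depth_biopsy=1_000, depth_urine=300,
        )
        subj = simulate_subject(cfg, 0)
        assert subj.truth.allo_cd4 == [] and subj.truth.allo_cd8 == []

    def test_zipf_slope_recoverable(self, small_config):
        subj = simulate_subject(small_config, 1)
        gen = subj.truth.generative_freqs[f"{subj.subject_id}_pre_pbmc"]
        f = np.sort(gen.to_numpy())[::-1][:200]
        ranks = np.arange(1, f.size + 1)
        slope = np.polyfit(np.log(ranks), np.log(f), 1)[0]
        assert slope == pytest.approx(-small_config.zipf_exponent, abs=0.2)

    def test_multinomial_preserves_expected_frequencies(self, small_config):
        # top-100 clones: mean |sampled - generative| under 3 binomial SEs
        subj = simulate_subject(small_config, 2)
        s = subj.samples["pre_pbmc"]
        gen = subj.truth.generative_freqs[s.sample_id]
        obs = s.table["templates"] / s.table["templates"].sum()
        top = gen.sort_values(ascending=False).head(100)
        err, se = [], []
        n = s.table["templates"].sum()
        for clone, f in top.items():
            err.append(abs(obs.get(clone, 0.0) - f))
            se.append(np.sqrt(f * (1 - f) / n))
        assert np.mean(err) < 3 * np.mean(se)

    def test_campath_contracts_repertoire(self, small_cohort):
        from allotrace.metrics import morisita_index

        def mi(s):
            return morisita_index(s.samples["pre_pbmc"], s.samples["post_pbmc"])

        campath = [s for s in small_cohort if s.induction_group == "campath"]
        non = [s for s in small_cohort if s.induction_group == "non_campath"]
        assert max(mi(s) for s in campath) < min(mi(s) for s in non)
        for s in campath:
            pre_unique = s.samples["pre_pbmc"].n_productive_clonotypes
            post_unique = s.samples["post_pbmc"].n_productive_clonotypes
            assert post_unique < pre_unique

    def test_rejection_biopsy_enriched_for_alloreactive(
        self, rejection_subject, stable_subject
    ):
        def biopsy_allo_count(subj):
            allo = set(subj.truth.allo_cd4) | set(subj.truth.allo_cd8)
            counts = subj.samples["biopsy"].counts
            return len(set(counts.index[counts >= 1]) & allo)

        assert biopsy_allo_count(rejection_subject) > biopsy_allo_count(stable_subject)

    def test_stable_urine_contains_no_alloreactive_clones(self, stable_subject):
        allo = set(stable_subject.truth.allo_cd4) | set(stable_subject.truth.allo_cd8)
        urine_keys = set(stable_subject.samples["urine"].table.index)
        assert not (urine_keys & allo)


class TestCohortWriting:
    def test_write_and_reload(self, tmp_path, small_config, small_cohort):
        manifest = write_cohort(small_cohort, tmp_path / "cohort")
        assert len(manifest) == 6 * small_config.n_subjects
        reloaded = read_manifest(tmp_path / "cohort" / "manifest.tsv")
        s = reloaded.load_sample(small_cohort[0].samples["pre_pbmc"].sample_id)
        assert s.total_templates == small_cohort[0].samples["pre_pbmc"].total_templates
        truth = json.loads((tmp_path / "cohort" / "ground_truth.json").read_text())
        assert set(truth) == {subj.subject_id for subj in small_cohort}

    def test_empty_cohort_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            manifest = write_cohort([], tmp_path / "empty")
        assert len(manifest) == 0

    def test_seed_changes_clones_not_structure(self, small_config):
        import dataclasses

        cfg2 = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a = simulate_subject(small_config, 0)
        b = simulate_subject(cfg2, 0)
        assert set(a.samples["pre_pbmc"].table.index) != set(
            b.samples["pre_pbmc"].table.index
        )
        gen = b.truth.generative_freqs[f"{b.subject_id}_pre_pbmc"]
        f = np.sort(gen.to_numpy())[::-1][:200]
        slope = np.polyfit(np.log(np.arange(1, f.size + 1)), np.log(f), 1)[0]
        assert slope == pytest.approx(-small_config.zipf_exponent, abs=0.2)
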