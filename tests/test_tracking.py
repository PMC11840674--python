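"""Clone tracking grids, graft-clone categorization and urine overlap."""

import numpy as np
import pandas as pd
import pytest

from allotrace.calling import call_drtc
from allotrace.io import RepertoireSample
from allotrace.tracking import (
    GRAFT_CATEGORIES,
    build_tracking,
    categorize_graft_clones,
    longitudinal_drtc_summary,
    urine_graft_overlap,
)


def mk(counts, sample_id="s", subject_id="P", **kw):
    return RepertoireSample.from_counts(sample_id, counts, subject_id=subject_id, **kw)


class FakeDRTC:
    """Minimal stand-in carrying a fixed member set (synthetic)."""

    def __init__(self, members, subject_id="P", subset="cd8"):
        self.members = frozenset(members)
        self.subject_id = subject_id
        self.subset = subset


@pytest.fixture
def called_drtc():
    mlr = mk({"a": 200, "b": 150, "c": 120, "d": 100, "bg": 500}, sample_id="mlr", subset="cd8")
    unstim = mk({"bg": 50_000, "e": 100}, sample_id="unstim")
    return call_drtc(mlr, unstim)


class TestBuildTracking:
    def test_grid_completeness(self, called_drtc):
        samples = [
            mk({"a": 3, "bg": 100}, sample_id="pre", timepoint="pre_tx", compartment="pbmc"),
            mk({"b": 1, "bg": 50}, sample_id="m3", timepoint="m3", compartment="pbmc"),
            mk({"a": 2, "c": 4, "bg": 10}, sample_id="bx", timepoint="m3", compartment="biopsy"),
            mk({"bg": 20}, sample_id="u", timepoint="wk2", compartment="urine"),
        ]
        track = build_tracking(called_drtc, samples)
        n = len(called_drtc.members)
        assert track.counts.shape == (n, 4)
        assert track.presence.shape == (n, 4)
        # absent clones recorded as explicit zeros
        assert (track.counts["u"] == 0).all()
        long = track.to_long()
        assert len(long) == n * 4

    def test_presence_follows_counts(self, called_drtc):
        pre = mk({"a": 3, "bg": 100}, sample_id="pre", timepoint="pre_tx", compartment="pbmc")
        m3 = mk({"bg": 50}, sample_id="m3", timepoint="m3", compartment="pbmc")
        track = build_tracking(called_drtc, [pre, m3])
        assert bool(track.presence.loc["a", "pre"])
        assert not bool(track.presence.loc["a", "m3"])
        assert track.counts.loc["a", "m3"] == 0

    def test_samples_ordered_by_timepoint(self, called_drtc):
        m3 = mk({"bg": 5}, sample_id="m3", timepoint="m3", compartment="pbmc")
        pre = mk({"bg": 5}, sample_id="pre", timepoint="pre_tx", compartment="pbmc")
        track = build_tracking(called_drtc, [m3, pre])
        assert list(track.counts.columns) == ["pre", "m3"]

    def test_foreign_subject_rejected(self, called_drtc):
        other = mk({"a": 1}, sample_id="x", subject_id="OTHER")
        with pytest.raises(ValueError, match="OTHER"):
            build_tracking(called_drtc, [other])

    def test_empty_drtc_set(self):
        drtc = FakeDRTC(set())
        track = build_tracking(drtc, [mk({"a": 1}, sample_id="pre")])
        assert track.counts.shape == (0, 1)


class TestCategorizeGraftClones:
    def test_forced_partition_example(self):
        drtc = FakeDRTC({"a", "b", "c", "d"})
        graft = mk({"a": 1, "b": 2, "c": 3, "d": 4}, sample_id="bx")
        pre = mk({"a": 5, "b": 5, "z": 10}, sample_id="pre")
        post = mk({"b": 5, "c": 5, "z": 10}, sample_id="post")
        cat = categorize_graft_clones(drtc, graft, pre, post)
        assert dict(cat.labels) == {
            "a": "pre_only",
            "b": "pre_and_post",
            "c": "post_only",
            "d": "graft_only",
        }
        assert cat.shares == pytest.approx({c: 0.25 for c in GRAFT_CATEGORIES})
        assert cat.cumulative_pre_share == pytest.approx(0.5)

    def test_all_clones_in_both_blood_samples(self):
        drtc = FakeDRTC({"a", "b"})
        graft = mk({"a": 1, "b": 1})
        blood = mk({"a": 1, "b": 1})
        cat = categorize_graft_clones(drtc, graft, blood, blood)
        assert cat.shares["pre_and_post"] == 1.0
        assert cat.cumulative_pre_share == 1.0

    def test_kidney_only_clones(self):
        drtc = FakeDRTC({"a", "b"})
        graft = mk({"a": 1, "b": 1})
        blood = mk({"z": 10})
        cat = categorize_graft_clones(drtc, graft, blood, blood)
        assert cat.shares["graft_only"] == 1.0

    def test_empty_universe_signalled(self):
        drtc = FakeDRTC({"a"})
        graft = mk({"z": 10})
        blood = mk({"a": 1})
        cat = categorize_graft_clones(drtc, graft, blood, blood)
        assert cat.n_graft_drtc == 0
        assert cat.shares is None
        assert cat.cumulative_pre_share is None

    def test_missing_post_degrades_to_three_way(self):
        drtc = FakeDRTC({"a", "b"})
        graft = mk({"a": 1, "b": 1})
        pre = mk({"a": 1, "z": 5})
        cat = categorize_graft_clones(drtc, graft, pre, None)
        assert cat.three_way
        assert dict(cat.labels) == {"a": "pre_only", "b": "undetermined"}

    def test_randomized_partition_property(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = int(rng.integers(1, 30))
            clones = [f"c{i}" for i in range(n)]
            drtc = FakeDRTC(clones)
            graft = mk({c: 1 for c in clones})
            pre = mk({c: 1 for c in clones if rng.random() < 0.5} or {"z": 1})
            post = mk({c: 1 for c in clones if rng.random() < 0.5} or {"z": 1})
            cat = categorize_graft_clones(drtc, graft, pre, post)
            assert sum(cat.shares.values()) == pytest.approx(1.0, abs=1e-9)
            assert cat.cumulative_pre_share == pytest.approx(
                cat.shares["pre_only"] + cat.shares["pre_and_post"]
            )


class TestUrineGraftOverlap:
    def test_counts_and_detail(self):
        drtc = FakeDRTC({f"c{i}" for i in range(10)})
        urine = mk(
            {f"c{i}": 1 for i in range(5)},
            sample_id="u",
            timepoint="wk2",
            compartment="urine",
        )
        bx = mk(
            {"c0": 3, "c1": 2, "z": 10},
            sample_id="bx",
            timepoint="m3",
            compartment="biopsy",
        )
        rep = urine_graft_overlap(drtc, urine, [bx])
        assert (rep.n_urine_detected, rep.n_also_in_biopsy) == (5, 2)
        assert set(rep.detail["clone"]) == {"c0", "c1"}
        # consistency: every intersection row is present in both samples
        for _, row in rep.detail.iterrows():
            assert urine.counts[row["clone"]] >= 1
            assert bx.counts[row["clone"]] >= 1

    def test_no_urine_drtc(self):
        drtc = FakeDRTC({"a"})
        urine = mk({"z": 5}, timepoint="wk2")
        bx = mk({"a": 1}, timepoint="m3")
        rep = urine_graft_overlap(drtc, urine, [bx])
        assert (rep.n_urine_detected, rep.n_also_in_biopsy) == (0, 0)

    def test_urine_drtc_absent_from_biopsy(self):
        drtc = FakeDRTC({"a", "b"})
        urine = mk({"a": 1, "b": 1}, timepoint="wk2")
        bx = mk({"z": 10}, timepoint="rejection")
        rep = urine_graft_overlap(drtc, urine, [bx])
        assert (rep.n_urine_detected, rep.n_also_in_biopsy) == (2, 0)

    def test_chronology_enforced(self):
        drtc = FakeDRTC({"a"})
        urine = mk({"a": 1}, timepoint="m3")
        bx = mk({"a": 1}, timepoint="wk2")
        with pytest.raises(ValueError, match="follow"):
            urine_graft_overlap(drtc, urine, [bx])


class TestLongitudinalSummary:
    def test_depletion_reduces_detection(self, small_cohort):
        campath = next(
            s
            for s in small_cohort
            if s.induction_group == "campath" and s.biopsy_status == "stable"
        )
        pre = campath.samples["pre_pbmc"]
        drtc = call_drtc(campath.samples["mlr_cd4"], pre)
        series = longitudinal_drtc_summary(drtc, [pre, campath.samples["post_pbmc"]])
        assert len(series) == 2
        assert series[1].n_detected < series[0].n_detected

    def test_identical_samples_identical_metrics(self):
        drtc = FakeDRTC({"a", "b"})
        s1 = mk({"a": 5, "b": 5, "z": 90}, sample_id="pre", timepoint="pre_tx")
        s2 = mk({"a": 5, "b": 5, "z": 90}, sample_id="post", timepoint="m3")
        m1, m2 = longitudinal_drtc_summary(drtc, [s1, s2])
        assert (m1.n_detected, m1.breadth, m1.depth) == (m2.n_detected, m2.breadth, m2.depth)

    def test_missing_sample_leaves_gap(self):
        drtc = FakeDRTC({"a"})
        only_pre = mk({"a": 1}, sample_id="pre", timepoint="pre_tx")
        series = longitudinal_drtc_summary(drtc, [only_pre])
        assert [m.sample_id for m in series] == ["pre"]
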