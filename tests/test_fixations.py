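"""Preprocessing contracts: parsing, exclusion cascade, density maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gazersa as gz
from gazersa.fixations import smooth_counts, mat2gray, gaussian_kernel


def fix(i, x, y, dur):
    return gz.FixationRecord(index_in_trial=i, x_px=x, y_px=y, duration_ms=dur)


def trial(pid, tidx, fixes, center=True, scene="s0"):
    return gz.Trial(participant_id=pid, scene_id=scene, trial_index=tidx,
                    fixations=tuple(fixes), started_at_center=center)


def good_trial(pid, tidx, n=3, dur=400.0, scene="s0"):
    return trial(pid, tidx, [fix(i, 100 + 10 * i, 100, dur) for i in range(n)],
                 scene=scene)


PARAMS = gz.DensityMapParams(image_h=200, image_w=200, sigma_px=3.0)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestReadFixationReport:
    def _write(self, path, drop_col=None, extra_rows=()):
        header = ["participant_id", "age_group", "trial_index", "scene_id",
                  "index_in_trial", "x_px", "y_px", "duration_ms",
                  "started_at_center"]
        rows = [["p1", "young", "0", "s0", "0", "10", "20", "300", "true"],
                ["p1", "young", "0", "s0", "1", "30", "40", "400", "true"],
                *extra_rows]
        if drop_col:
            k = header.index(drop_col)
            header = header[:k] + header[k + 1:]
            rows = [r[:k] + r[k + 1:] for r in rows]
        path.write_text("\n".join("\t".join(r) for r in [header, *rows]) + "\n")

    def test_parses_sessions_and_orders_fixations(self, tmp_path):
        p = tmp_path / "f.tsv"
        self._write(p)
        sessions = gz.read_fixation_report(p)
        assert len(sessions) == 1
        assert sessions[0].age_group == "young"
        assert [f.index_in_trial for f in sessions[0].trials[0].fixations] == [0, 1]

    def test_missing_duration_column_is_schema_error(self, tmp_path):
        p = tmp_path / "f.tsv"
        self._write(p, drop_col="duration_ms")
        with pytest.raises(ValueError, match="duration_ms"):
            gz.read_fixation_report(p)

    def test_duplicate_trial_index_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        # same trial_index 0 under two different scenes for one participant
        self._write(p, extra_rows=[["p1", "young", "0", "s1", "0", "5", "5",
                                    "200", "true"]])
        with pytest.raises(ValueError, match="duplicate trial"):
            gz.read_fixation_report(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            gz.read_fixation_report(p)

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        p = tmp_path / "f.tsv"
        self._write(p, extra_rows=[["p1", "young", "1", "s1", "0", "oops", "5",
                                    "200", "true"]])
        with pytest.raises(ValueError, match="lines \\[4\\]"):
            gz.read_fixation_report(p)


# ---------------------------------------------------------------------------
# exclusion cascade
# ---------------------------------------------------------------------------

class TestTrialExclusions:
    def test_rule_attribution_matches_hand_enumeration(self):
        """20-trial fixture with known violations: kept/excluded counts and
        the first-violated-rule attribution must match exact enumeration."""
        trials = []
        # 2 trials: no central start (rule 1) -- even though also <3 fixations
        for t in range(2):
            trials.append(trial("p", t, [fix(0, 10, 10, 2000)], center=False))
        # 3 trials: every fixation off-image (rule 2)
        for t in range(2, 5):
            trials.append(trial("p", t, [fix(0, -50, 10, 600), fix(1, 300, 10, 600),
                                         fix(2, 10, 250, 600)]))
        # 4 trials: fewer than three fixations (rule 3)
        for t in range(5, 9):
            trials.append(trial("p", t, [fix(0, 10, 10, 900), fix(1, 20, 20, 900)]))
        # 1 trial: 3 fixations summing to 950 ms (rule 4)
        trials.append(trial("p", 9, [fix(0, 10, 10, 400), fix(1, 20, 20, 300),
                                     fix(2, 30, 30, 250)]))
        # 10 good trials
        for t in range(10, 20):
            trials.append(good_trial("p", t))
        session = gz.SubjectSession("p", "young", tuple(trials))
        kept, report = gz.apply_trial_exclusions(session, PARAMS)
        assert len(kept.trials) == 10
        assert report.rule_counts == {"center_start_fail": 2,
                                      "outside_image_only": 3,
                                      "lt3_fixations": 4,
                                      "sum_dur_lt_1000ms": 1}
        assert report.trial_outcomes[("p", 0)] == "center_start_fail"
        assert report.trial_outcomes[("p", 2)] == "outside_image_only"
        assert report.trial_outcomes[("p", 5)] == "lt3_fixations"
        assert report.trial_outcomes[("p", 9)] == "sum_dur_lt_1000ms"
        assert report.trial_outcomes[("p", 19)] == "kept"
        # rules 3-4 percentages are relative to remaining trials (15, then 11)
        assert report.rule_percentages["lt3_fixations"] == pytest.approx(100 * 4 / 15)
        assert report.rule_percentages["sum_dur_lt_1000ms"] == pytest.approx(100 * 1 / 11)

    def test_sub_second_trial_excluded_under_rule_4(self):
        t = trial("p", 0, [fix(0, 10, 10, 400), fix(1, 20, 20, 300),
                           fix(2, 30, 30, 250)])
        _, rep = gz.apply_trial_exclusions(gz.SubjectSession("p", "young", (t,)), PARAMS)
        assert rep.trial_outcomes[("p", 0)] == "sum_dur_lt_1000ms"

    def test_compliant_trial_kept(self):
        kept, rep = gz.apply_trial_exclusions(
            gz.SubjectSession("p", "young", (good_trial("p", 0),)), PARAMS)
        assert len(kept.trials) == 1 and rep.n_trials_kept == 1

    def test_exclusions_are_idempotent(self):
        trials = tuple([good_trial("p", t) for t in range(5)]
                       + [trial("p", 5, [fix(0, 1, 1, 100)], center=False)])
        session = gz.SubjectSession("p", "young", trials)
        once, _ = gz.apply_trial_exclusions(session, PARAMS)
        twice, rep2 = gz.apply_trial_exclusions(once, PARAMS)
        assert once.trials == twice.trials
        assert rep2.n_trials_kept == rep2.n_trials_total


class TestSubjectExclusion:
    @pytest.mark.parametrize("n_trials,kept", [(17, 0), (18, 1)])
    def test_eighteen_usable_trials_required(self, n_trials, kept):
        s = gz.SubjectSession("p", "young",
                              tuple(good_trial("p", t) for t in range(n_trials)))
        remaining, rep = gz.apply_subject_exclusion([s])
        assert len(remaining) == kept
        assert ("p" in rep.excluded_subjects) == (kept == 0)

    def test_all_removed_yields_empty_list(self):
        s = gz.SubjectSession("p", "young", (good_trial("p", 0),))
        remaining, _ = gz.apply_subject_exclusion([s])
        assert remaining == []


class TestLookingStats:
    def test_single_trial_arithmetic(self):
        s = gz.SubjectSession("p", "young", (good_trial("p", 0, n=3, dur=400.0),))
        stats = gz.compute_looking_stats([s]).table
        row = stats.loc["young"]
        assert row["fixations_per_trial_mean"] == 3
        assert row["fixation_duration_mean"] == 400.0
        assert row["total_look_mean"] == 1200.0

    def test_mean_over_trials(self):
        s = gz.SubjectSession("p", "young", (good_trial("p", 0, n=2),
                                             good_trial("p", 1, n=4)))
        assert gz.compute_looking_stats([s]).table.loc[
            "young", "fixations_per_trial_mean"] == 3.0

    def test_generator_means_recovered_from_synthetic_study(self, tiny_study,
                                                            tiny_run_config):
        """Observed per-group fixation counts and durations must sit near the
        generator's configured means (Monte-Carlo, 3 SE)."""
        sessions = gz.simulate_sessions(tiny_study)
        kept, _, _ = gz.pipeline.preprocess(sessions, tiny_run_config)
        stats = gz.compute_looking_stats(kept).table
        for prof in tiny_study.profiles:
            row = stats.loc[prof.name]
            se_fix = row["fixations_per_trial_sd"] / np.sqrt(row["n"])
            # exclusions trim low-fixation trials, biasing the mean slightly up
            assert abs(row["fixations_per_trial_mean"]
                       - prof.fixations_per_trial_mean) < max(3 * se_fix, 1.0)
            se_dur = row["fixation_duration_sd"] / np.sqrt(row["n"])
            assert abs(row["fixation_duration_mean"]
                       - prof.fixation_duration_mean_ms) < max(3 * se_dur, 30.0)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

def dense_gaussian_convolution(counts, sigma):
    """Brute-force dense 2-D convolution oracle (no separability, no FFT)."""
    x = np.arange(-counts.shape[0], counts.shape[0] + 1, dtype=float)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    k2 = np.outer(k1, k1)
    kh = len(x) // 2
    padded = np.pad(counts, kh)
    out = np.empty_like(counts, dtype=float)
    H, W = counts.shape
    for i in range(H):
        for j in range(W):
            out[i, j] = (padded[i:i + 2 * kh + 1, j:j + 2 * kh + 1] * k2).sum()
    return out


class TestDensityMap:
    def test_single_center_fixation_peaks_at_center(self):
        p = gz.DensityMapParams(image_h=101, image_w=101, sigma_px=5.0)
        t = trial("p", 0, [fix(0, 50, 50, 100), fix(1, 50, 50, 400)])
        m = gz.density_map(t, p).values
        assert m[50, 50] == 1.0
        # strictly decreasing with radius within the kernel's support
        assert np.all(np.diff(m[50, 50:90]) < 0)
        assert np.all(np.diff(m[50:90, 50]) < 0)

    def test_two_distant_fixations_give_two_unit_maxima(self):
        """Fixations far apart (>20 sigma) each form an independent Gaussian,
        so both local maxima rescale to 1; verified against the dense oracle."""
        p = gz.DensityMapParams(image_h=200, image_w=200, sigma_px=3.0)
        t = trial("p", 0, [fix(0, 0, 0, 100), fix(1, 50, 60, 400),
                           fix(2, 150, 160, 400)])
        m = gz.density_map(t, p).values
        assert m[60, 50] == pytest.approx(1.0, abs=1e-9)
        assert m[160, 150] == pytest.approx(1.0, abs=1e-9)
        counts = np.zeros((200, 200))
        counts[60, 50] = counts[160, 150] = 1
        oracle = mat2gray(dense_gaussian_convolution(counts, 3.0))
        np.testing.assert_allclose(m, oracle, atol=1e-8)

    def test_fixation_order_does_not_matter(self):
        p = PARAMS
        fixes = [fix(1, 20, 30, 100), fix(2, 100, 120, 100), fix(3, 60, 80, 100)]
        t1 = trial("p", 0, [fix(0, 99, 99, 100)] + fixes)
        t2 = trial("p", 0, [fix(0, 99, 99, 100)] + [
            gz.FixationRecord(i + 1, f.x_px, f.y_px, f.duration_ms)
            for i, f in enumerate(reversed(fixes))])
        np.testing.assert_array_equal(gz.density_map(t1, p).values,
                                      gz.density_map(t2, p).values)

    def test_first_fixation_dropped_and_offimage_skipped(self):
        p = PARAMS
        t = trial("p", 0, [fix(0, 100, 100, 100), fix(1, -20, 10, 100),
                           fix(2, 40, 40, 100)])
        m = gz.density_map(t, p).values
        assert m[40, 40] == 1.0
        assert m[100, 100] < 1.0  # first fixation contributed nothing

    def test_no_countable_fixations_is_error(self):
        t = trial("p", 0, [fix(0, 100, 100, 100), fix(1, -20, -20, 100)])
        with pytest.raises(ValueError, match="no countable fixations"):
            gz.density_map(t, PARAMS)

    def test_smoothing_matches_dense_oracle(self):
        """Separable smoothing equals brute-force dense convolution (64x64)."""
        rng = np.random.default_rng(4)
        counts = (rng.random((64, 64)) < 0.01).astype(float)
        counts[10, 17] += 2
        got = smooth_counts(counts, 7.21)
        want = dense_gaussian_convolution(counts, 7.21)
        assert np.abs(got - want).max() < 1e-8

    def test_mass_preserved_away_from_borders(self):
        """Pre-normalization mass equals the countable fixation count up to
        <=0.1% truncation loss when fixations sit >=4 sigma inside."""
        p = gz.DensityMapParams(image_h=128, image_w=128, sigma_px=4.0)
        counts = np.zeros((128, 128))
        for (y, x) in [(20, 20), (60, 90), (100, 40)]:
            counts[y, x] += 1
        smoothed = smooth_counts(counts, p.sigma_px)
        assert abs(smoothed.sum() - 3.0) / 3.0 < 1e-3

    def test_mat2gray_degenerate_input_maps_to_zeros(self):
        np.testing.assert_array_equal(mat2gray(np.full((4, 4), 2.5)),
                                      np.zeros((4, 4)))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 99), st.integers(0, 99)),
                    min_size=1, max_size=12))
    def test_map_spans_unit_range(self, points):
        """Every non-degenerate density map has min exactly 0 and max 1."""
        p = gz.DensityMapParams(image_h=100, image_w=100, sigma_px=3.0)
        fixes = [fix(0, 50, 50, 100)] + [fix(i + 1, x, y, 100)
                                         for i, (x, y) in enumerate(points)]
        m = gz.density_map(trial("p", 0, fixes), p).values
        assert m.min() == 0.0
        assert m.max() == 1.0
        assert np.isfinite(m).all()
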