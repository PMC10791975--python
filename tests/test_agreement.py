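"""Agreement suite: Dice, distance stats, Bland–Altman, ICC, failures."""

import numpy as np
import pandas as pd
import pytest

from fluorotrack import (
    CorruptionSpec,
    LandmarkLabel,
    ValidationError,
    bland_altman,
    compare_raters,
    dice,
    distance_stats,
    encode_sequence,
    failure_table,
    icc,
    landmarks_to_mask,
    largest_component_filter,
    mask_to_landmarks,
    oracle_predict,
)
from conftest import SEPARATED_POSITIONS, SEPARATED_RADII, brute_force_disc, make_set


class TestDice:
    def test_identical_masks_give_one(self):
        s = make_set({LandmarkLabel.GLENOID_SUPERIOR: (50.0, 50.0)})
        m = landmarks_to_mask(s, (100, 100))
        assert dice(m, m, 2) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = landmarks_to_mask(make_set({LandmarkLabel.GLENOID_SUPERIOR: (20.0, 20.0)}), (100, 100))
        b = landmarks_to_mask(make_set({LandmarkLabel.GLENOID_SUPERIOR: (80.0, 80.0)}), (100, 100))
        assert dice(a, b, 2) == 0.0

    def test_one_pixel_shift_matches_lattice_oracle(self):
        a = landmarks_to_mask(make_set({LandmarkLabel.GLENOID_SUPERIOR: (100.0, 100.0)}), (200, 200))
        b = landmarks_to_mask(make_set({LandmarkLabel.GLENOID_SUPERIOR: (101.0, 100.0)}), (200, 200))
        assert dice(a, b, 2) == pytest.approx(360 / 394, abs=1e-15)
        # independent set-based computation
        sa = brute_force_disc(100, 100, 8)
        sb = brute_force_disc(101, 100, 8)
        assert dice(a, b, 2) == pytest.approx(2 * len(sa & sb) / (len(sa) + len(sb)), abs=1e-15)

    def test_empty_in_both_is_one_empty_in_one_is_zero(self):
        empty = np.zeros((10, 10), dtype=np.uint8)
        some = empty.copy()
        some[3, 3] = 4
        assert dice(empty, empty, 4) == 1.0
        assert dice(empty, some, 4) == 0.0

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.integers(0, 7, (12, 12)).astype(np.uint8)
            b = rng.integers(0, 7, (12, 12)).astype(np.uint8)
            lab = int(rng.integers(1, 7))
            sa = {tuple(p) for p in np.argwhere(a == lab)}
            sb = {tuple(p) for p in np.argwhere(b == lab)}
            expected = 1.0 if not sa and not sb else (
                0.0 if not sa or not sb else 2 * len(sa & sb) / (len(sa) + len(sb))
            )
            assert dice(a, b, lab) == pytest.approx(expected, abs=1e-12)
            assert dice(a, b, lab) == dice(b, a, lab)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            dice(np.zeros((5, 5)), np.zeros((6, 6)), 1)


class TestDistanceStats:
    def _sets(self, n=5, shift=(0.0, 0.0), fail_b_at=()):
        a, b = [], []
        for f in range(n):
            a.append(make_set(SEPARATED_POSITIONS, SEPARATED_RADII, frame=f))
            if f in fail_b_at:
                pos = {k: v for k, v in SEPARATED_POSITIONS.items()
                       if k is not LandmarkLabel.ACROMION_LATERAL}
                b.append(make_set(pos, SEPARATED_RADII, frame=f,
                                  failures={LandmarkLabel.ACROMION_LATERAL}))
            else:
                pos = {k: (v[0] + shift[0], v[1] + shift[1])
                       for k, v in SEPARATED_POSITIONS.items()}
                b.append(make_set(pos, SEPARATED_RADII, frame=f))
        return a, b

    def test_identical_annotations_give_zero(self):
        a, _ = self._sets()
        df = distance_stats(a, a)
        assert (df["mean_euclidean_px"] == 0).all()

    def test_three_four_five_shift_in_mm(self):
        a, b = self._sets(shift=(3.0, 4.0))
        df = distance_stats(a, b, mm_per_px=0.35)
        row = df[(df["landmark"] == "glenoid_superior") & (df["stratum"] == "all")].iloc[0]
        assert row["mean_abs_dx_mm"] == pytest.approx(1.05, abs=1e-12)
        assert row["mean_abs_dy_mm"] == pytest.approx(1.40, abs=1e-12)
        assert row["mean_euclidean_mm"] == pytest.approx(1.75, abs=1e-12)
        assert row["sd_euclidean_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_failed_frames_excluded_and_counted(self):
        a, b = self._sets(n=6, fail_b_at={1, 4})
        df = distance_stats(a, b)
        row = df[(df["landmark"] == "acromion_lateral") & (df["stratum"] == "all")].iloc[0]
        assert row["n"] == 4 and row["n_excluded"] == 2

    def test_euclidean_at_least_each_axis_mean(self):
        rng = np.random.default_rng(9)
        a, b = [], []
        for f in range(20):
            a.append(make_set(SEPARATED_POSITIONS, SEPARATED_RADII, frame=f))
            pos = {k: (v[0] + rng.normal(0, 2), v[1] + rng.normal(0, 2))
                   for k, v in SEPARATED_POSITIONS.items()}
            b.append(make_set(pos, SEPARATED_RADII, frame=f))
        df = distance_stats(a, b)
        assert (df["mean_euclidean_px"] >= df["mean_abs_dx_px"] - 1e-12).all()
        assert (df["mean_euclidean_px"] >= df["mean_abs_dy_px"] - 1e-12).all()

    def test_pulse_rate_stratification(self):
        a = [make_set(SEPARATED_POSITIONS, SEPARATED_RADII, frame=f, pulse_rate=3.0)
             for f in range(3)]
        a += [make_set(SEPARATED_POSITIONS, SEPARATED_RADII, frame=f + 3, pulse_rate=10.0)
              for f in range(4)]
        df = distance_stats(a, a, stratify_by_pulse_rate=True)
        strata = set(df["stratum"])
        assert strata == {"all", "3 Hz", "10 Hz"}
        row3 = df[(df["landmark"] == "humeral_shaft") & (df["stratum"] == "3 Hz")].iloc[0]
        assert row3["n"] == 3


class TestBlandAltman:
    def test_plus_minus_one(self):
        ba = bland_altman([1.0, -1.0])
        assert ba.mean_diff == 0.0
        assert ba.loa_upper == pytest.approx(1.96 * np.sqrt(2), abs=1e-9)
        assert ba.loa_lower == pytest.approx(-1.96 * np.sqrt(2), abs=1e-9)

    def test_constant_differences_collapse_limits(self):
        ba = bland_altman([2.5, 2.5, 2.5])
        assert ba.mean_diff == 2.5
        assert ba.loa_lower == ba.loa_upper == 2.5

    def test_all_zero(self):
        ba = bland_altman([0.0, 0.0, 0.0])
        assert (ba.mean_diff, ba.loa_lower, ba.loa_upper) == (0.0, 0.0, 0.0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0])

    def test_limits_cover_95_percent_of_gaussian_differences(self):
        rng = np.random.default_rng(12345)
        diffs = rng.normal(0.3, 1.7, 10_000)
        ba = bland_altman(diffs)
        coverage = np.mean((diffs >= ba.loa_lower) & (diffs <= ba.loa_upper))
        assert coverage == pytest.approx(0.95, abs=0.01)


def icc_oracle(x: np.ndarray) -> float:
    """Independent variance-components computation of ICC(2,1).

    Estimates subject, rater and error variance from the two-way ANOVA
    expected mean squares (explicit loops, no shared code path)."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    sse = sum((x[i][j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    var_subject = (msr - mse) / k
    var_rater = (msc - mse) / n
    return var_subject / (var_subject + var_rater + mse)


class TestICC:
    def test_worked_example_two_thirds(self):
        r = icc(np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]]))
        assert r.value == pytest.approx(2 / 3, abs=1e-12)

    def test_perfect_agreement_is_degenerate_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        r = icc(x)
        assert r.value == 1.0 and r.degenerate
        assert r.ci_lower <= r.value <= r.ci_upper

    def test_zero_variance_input_is_degenerate_one(self):
        r = icc(np.full((4, 2), 7.0))
        assert r.value == 1.0 and r.degenerate

    def test_matches_variance_components_oracle_on_random_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = int(rng.integers(3, 7))
            k = int(rng.integers(2, 4))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            assert icc(x).value == pytest.approx(icc_oracle(x), abs=1e-9)

    def test_matches_pingouin_value_and_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n, k = 12, 3
        x = rng.normal(size=(n, 1)) + rng.normal(scale=0.5, size=(1, k)) + rng.normal(
            scale=0.3, size=(n, k)
        )
        mine = icc(x)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": x.ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        row = res[res["Type"] == "ICC(A,1)"]
        if row.empty:
            row = res[res["Type"] == "ICC2"]
        row = row.iloc[0]
        assert mine.value == pytest.approx(row["ICC"], abs=1e-9)
        ci_col = "CI95" if "CI95" in res.columns else "CI95%"
        assert mine.ci_lower == pytest.approx(row[ci_col][0], abs=0.005)
        assert mine.ci_upper == pytest.approx(row[ci_col][1], abs=0.005)

    def test_independent_ratings_give_near_zero(self):
        rng = np.random.default_rng(777)
        x = rng.normal(size=(1000, 2))
        assert abs(icc(x).value) < 0.1

    def test_point_estimate_within_ci(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(size=(6, 2)) + rng.normal(size=(6, 1))
            r = icc(x)
            assert r.ci_lower <= r.value <= r.ci_upper
            assert -1 <= r.value <= 1

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0], [3.0, 4.0]])
        with pytest.raises(ValidationError, match="missing"):
            icc(x)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValidationError):
            icc(np.zeros((2, 2)))


class TestFailureTable:
    def test_injected_dropout_count_appears_in_stratum(self):
        truth = [make_set(SEPARATED_POSITIONS, SEPARATED_RADII, frame=f) for f in range(20)]
        drop_frames = frozenset(range(9))
        vol = oracle_predict(truth, (300, 300),
                             CorruptionSpec(dropout={LandmarkLabel.ACROMION_LATERAL: drop_frames}))
        rec = mask_to_landmarks(largest_component_filter(vol, mode="2d"))
        table = failure_table(rec)
        assert table.loc["acromion_lateral", "10 Hz"] == 9
        assert table.loc["acromion_lateral", "total"] == 9
        assert table.drop("acromion_lateral")["total"].sum() == 0

    def test_no_failures_gives_all_zero(self):
        sets = [make_set(SEPARATED_POSITIONS, SEPARATED_RADII, frame=f) for f in range(3)]
        assert (failure_table(sets)["total"] == 0).all()

    def test_totals_equal_sum_of_strata(self):
        sets = []
        for f in range(6):
            rate = 3.0 if f < 3 else 10.0
            fails = {LandmarkLabel.HUMERAL_SHAFT} if f % 2 == 0 else set()
            pos = {k: v for k, v in SEPARATED_POSITIONS.items()
                   if not (f % 2 == 0 and k is LandmarkLabel.HUMERAL_SHAFT)}
            sets.append(make_set(pos, SEPARATED_RADII, frame=f, failures=fails,
                                 pulse_rate=rate))
        table = failure_table(sets)
        assert (table["total"] == table[["3 Hz", "10 Hz"]].sum(axis=1)).all()
        assert table.loc["humeral_shaft", "3 Hz"] == 2
        assert table.loc["humeral_shaft", "10 Hz"] == 1


class TestCompareRaters:
    def _pair(self, n=6, sigma=1.0, seed=4):
        rng = np.random.default_rng(seed)
        a, b = [], []
        for f in range(n):
            a.append(make_set(SEPARATED_POSITIONS, SEPARATED_RADII, frame=f))
            pos = {k: (v[0] + rng.normal(0, sigma), v[1] + rng.normal(0, sigma))
                   for k, v in SEPARATED_POSITIONS.items()}
            b.append(make_set(pos, SEPARATED_RADII, frame=f))
        return a, b

    def test_self_comparison_is_perfect(self):
        a, _ = self._pair()
        masks = encode_sequence(a, (300, 300))
        report = compare_raters(a, a, masks, masks, mm_per_px=0.35)
        assert (report.distances["mean_euclidean_px"] == 0).all()
        assert all(v == 1.0 for v in report.dice_per_label.values())
        assert report.icc_table["degenerate"].all()
        assert report.failures_a["total"].sum() == 0

    def test_swapping_inputs_negates_signed_differences(self):
        a, b = self._pair()
        r_ab = compare_raters(a, b)
        r_ba = compare_raters(b, a)
        merged = r_ab.loa.merge(r_ba.loa, on=["landmark", "axis"], suffixes=("_ab", "_ba"))
        assert np.allclose(merged["mean_diff_ab"], -merged["mean_diff_ba"], atol=1e-12)
        d_ab = r_ab.distances[r_ab.distances["stratum"] == "all"]["mean_euclidean_px"]
        d_ba = r_ba.distances[r_ba.distances["stratum"] == "all"]["mean_euclidean_px"]
        assert np.allclose(d_ab.to_numpy(), d_ba.to_numpy(), atol=1e-12)

    def test_jittered_oracle_matches_rayleigh_mean(self):
        # mean Euclidean distance of an isotropic 2D Gaussian displacement
        sigma = 2.0
        truth = [make_set(SEPARATED_POSITIONS, SEPARATED_RADII, frame=f) for f in range(60)]
        vol = oracle_predict(truth, (300, 300), CorruptionSpec(jitter_sigma_px=sigma, seed=6))
        rec = mask_to_landmarks(largest_component_filter(vol))
        report = compare_raters(rec, truth)
        overall = report.distances[report.distances["stratum"] == "all"]
        n = int(overall["n"].sum())
        mean_eucl = float(
            (overall["mean_euclidean_px"] * overall["n"]).sum() / n
        )
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((4 - np.pi) / 2) / np.sqrt(n)
        assert abs(mean_eucl - expected) < 3 * se + 0.05

    def test_report_saves_all_tables(self, tmp_path):
        a, b = self._pair()
        report = compare_raters(a, b, mm_per_px=0.35)
        report.save(tmp_path / "rep")
        for name in ("distances.csv", "limits_of_agreement.csv", "icc.csv",
                     "failures_a.csv", "failures_b.csv", "summary.json"):
            assert (tmp_path / "rep" / name).exists()
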