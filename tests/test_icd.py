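"""Cosupport detection strategies and the outer ICD loop."""

import numpy as np
import pytest

from icdrecon.icd import (
    DetectionConfig,
    detect_threshold,
    detect_truncated,
    detection_report,
    run_icd,
)
from icdrecon.metrics import rlne
from icdrecon.operators import FiniteDifferenceOperator, true_cosupport
from icdrecon.phantoms import piecewise_constant_image, simulate_measurements
from icdrecon.sampling import variable_density_mask
from icdrecon.solver import ReconConfig, solve_truncated_l1


class TestDetectTruncated:
    def test_smallest_magnitudes_selected(self):
        assert detect_truncated(np.array([3.0, 1.0, 2.0]), 2).tolist() == [1, 2]

    def test_full_length_returns_everything(self):
        assert detect_truncated(np.arange(5.0), 5).tolist() == [0, 1, 2, 3, 4]

    def test_stable_tie_break(self):
        assert detect_truncated(np.array([1.0, 1.0, 5.0]), 1).tolist() == [0]

    def test_out_of_range_l(self):
        with pytest.raises(ValueError):
            detect_truncated(np.arange(3.0), 0)
        with pytest.raises(ValueError):
            detect_truncated(np.arange(3.0), 4)


class TestDetectThreshold:
    def test_direct_evaluation(self):
        idx = detect_threshold(np.array([0.0, 0.5, 1.0]), t=2, w=2)
        assert idx.tolist() == [0]

    def test_first_iteration_excludes_only_the_maximum(self):
        """At t=1 the threshold equals the max magnitude: no cosupport
        knowledge beyond excluding the maximal entries is imposed."""
        idx = detect_threshold(np.array([0.0, 0.5, 1.0]), t=1, w=3)
        assert idx.tolist() == [0, 1]

    def test_all_zero_coefficients_give_full_set(self):
        assert detect_threshold(np.zeros(4), t=3, w=2).tolist() == [0, 1, 2, 3]

    def test_threshold_strictly_decreasing_in_t(self, rng):
        coeffs = rng.normal(size=32)
        sizes = [detect_threshold(coeffs, t, w=2).size for t in range(1, 8)]
        # sets shrink (weakly) for a fixed coefficient vector
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        beta = [np.abs(coeffs).max() / 2 ** (t - 1) for t in range(1, 8)]
        assert all(a > b for a, b in zip(beta, beta[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            detect_threshold(np.ones(3), t=0, w=2)
        with pytest.raises(ValueError):
            detect_threshold(np.ones(3), t=1, w=1)


class TestDetectionConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            DetectionConfig(strategy="magic")
        with pytest.raises(ValueError):
            DetectionConfig(strategy="threshold", w=1)
        with pytest.raises(ValueError):
            DetectionConfig(strategy="truncated", L=0)
        with pytest.raises(ValueError):
            DetectionConfig(t_max=0)


class TestRunIcd:
    def test_fixed_cosupport_degenerates_to_single_solve(self):
        image, cs = piecewise_constant_image((16, 16), 4, seed=21)
        mask = variable_density_mask((16, 16), 0.6, seed=22)
        y = simulate_measurements(image, mask)
        rc = ReconConfig(lam=5e-4)
        x_icd, history = run_icd(
            y, mask, rc, DetectionConfig(), fixed_cosupport=cs
        )
        x_direct, _ = solve_truncated_l1(y, mask, cs, rc)
        assert history.num_iterations == 1
        assert np.array_equal(x_icd, x_direct)

    def test_recovers_piecewise_constant_fixture(self):
        image, _ = piecewise_constant_image((32, 32), 4, seed=31)
        mask = variable_density_mask((32, 32), 0.5, seed=32)
        y = simulate_measurements(image, mask)
        x, history = run_icd(
            y,
            mask,
            ReconConfig(lam=5e-4),
            DetectionConfig(strategy="threshold", w=2, t_max=8),
            ground_truth=image,
        )
        assert rlne(x, image) <= 1e-2
        traces = [rec["rlne"] for rec in history.iterations]
        assert traces[-1] <= traces[0]

    def test_history_records_detection_counts(self):
        image, _ = piecewise_constant_image((16, 16), 3, seed=41)
        mask = variable_density_mask((16, 16), 0.5, seed=42)
        y = simulate_measurements(image, mask)
        _, history = run_icd(
            y,
            mask,
            ReconConfig(lam=5e-4),
            DetectionConfig(strategy="threshold", w=2, t_max=3),
            ground_truth=image,
        )
        for rec in history.iterations:
            for d in history.directions:
                assert (
                    rec["true_detections"][d] + rec["false_detections"][d]
                    == rec["cosupport_size"][d]
                )

    def test_self_correction_reduces_false_detections(self):
        """On 32x32 fixtures at 50% sampling, the final false-detection
        count is no worse than the first iteration's in >= 90% of seeds."""
        improved = 0
        for seed in range(20):
            image, _ = piecewise_constant_image((32, 32), 4, seed=seed)
            mask = variable_density_mask((32, 32), 0.5, seed=500 + seed)
            y = simulate_measurements(image, mask)
            _, history = run_icd(
                y,
                mask,
                ReconConfig(lam=5e-4),
                DetectionConfig(strategy="threshold", w=2, t_max=6),
                ground_truth=image,
            )
            first = sum(history.iterations[0]["false_detections"].values())
            last = sum(history.iterations[-1]["false_detections"].values())
            if last <= first:
                improved += 1
        assert improved >= 18

    def test_serialization_round_trips(self):
        image, _ = piecewise_constant_image((16, 16), 3, seed=51)
        mask = variable_density_mask((16, 16), 0.5, seed=52)
        y = simulate_measurements(image, mask)
        _, history = run_icd(
            y,
            mask,
            ReconConfig(lam=5e-4),
            DetectionConfig(t_max=2),
            ground_truth=image,
        )
        import json

        payload = json.loads(history.to_json())
        assert len(payload["iterations"]) == history.num_iterations
        csv_text = history.to_csv()
        assert csv_text.splitlines()[0].startswith("iteration,direction")


class TestDetectionReport:
    def test_partition_identity(self):
        image, _ = piecewise_constant_image((16, 16), 3, seed=61)
        mask = variable_density_mask((16, 16), 0.5, seed=62)
        y = simulate_measurements(image, mask)
        op = FiniteDifferenceOperator((16, 16))
        truth_cs = true_cosupport(image, op, tol=0.0)
        _, history = run_icd(
            y, mask, ReconConfig(lam=5e-4), DetectionConfig(t_max=3)
        )
        rows = detection_report(history, truth_cs)
        assert rows, "report should not be empty"
        for row in rows:
            assert row["true"] + row["false"] == row["size"]
            assert row["true"] >= 0 and row["false"] >= 0

    def test_identity_and_empty_cases(self):
        from icdrecon.icd import _detection_counts
        from icdrecon.operators import CosupportSet

        dirs = ("vertical",)
        truth = CosupportSet({"vertical": [0, 2, 5]}, 8)
        same = CosupportSet({"vertical": [0, 2, 5]}, 8)
        empty = CosupportSet({"vertical": []}, 8)
        tc, fc = _detection_counts(same, truth)
        assert tc["vertical"] == 3 and fc["vertical"] == 0
        tc, fc = _detection_counts(empty, truth)
        assert tc["vertical"] == 0 and fc["vertical"] == 0
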