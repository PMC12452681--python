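"""ΔZ embedding, bend angles, decay reversal, and the detection verdict."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfoscan import (
    ArrayFamily,
    DetectorConfig,
    EFIMatrix,
    InsufficientContactsError,
    decay_reversal,
    detect_tfo,
    embed_delta_z,
    symmetry_score,
)
from tfoscan.tfo_detector import _interior_angles, _row_reversal

from conftest import simulated_matrix


class TestInteriorAngles:
    """Oracle: hand-constructed polylines with known geometry."""

    def test_straight_line_is_180(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        angles = _interior_angles(pts, (1, 2, 3, 4))
        assert angles == pytest.approx({2: 180.0, 3: 180.0})

    def test_right_angle_corner(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        assert _interior_angles(pts, (1, 2, 3))[2] == pytest.approx(90.0)

    def test_fold_back_is_near_zero(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.1, 0.05]])
        assert _interior_angles(pts, (1, 2, 3))[2] < 5.0

    def test_degenerate_segment_yields_no_turn(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        angles = _interior_angles(pts, (1, 2, 3, 4))
        assert angles[2] == 180.0 and angles[3] == 180.0


class TestEmbedding:
    def test_normal_polyline_is_smooth(self):
        """All interior angles of a normal insertion stay obtuse."""
        for fam in ArrayFamily:
            emb = embed_delta_z(simulated_matrix(family=fam))
            assert min(emb.turning_angle_deg.values()) >= 90.0

    def test_fold_at_5_gives_minimum_angle_at_5(self):
        emb = embed_delta_z(simulated_matrix(fold_at=5))
        label, angle = emb.min_angle()
        assert label == 5 and angle < 90.0

    def test_variance_explained_valid_fractions(self, fold5_matrix):
        emb = embed_delta_z(fold5_matrix)
        v1, v2 = emb.variance_explained
        assert 0.0 <= v2 <= v1 <= 1.0 and v1 + v2 <= 1.0

    def test_four_contacts_rejected(self):
        vals = np.full((4, 4), 1.0)
        np.fill_diagonal(vals, 5.0)
        m = EFIMatrix(values=vals, labels=(1, 2, 3, 4))
        with pytest.raises(InsufficientContactsError, match="insufficient"):
            embed_delta_z(m)

    def test_sign_convention_fixed(self, fold5_matrix):
        emb = embed_delta_z(fold5_matrix)
        assert emb.points[0, 0] <= emb.points[-1, 0]

    def test_angles_invariant_to_pc_sign(self, fold5_matrix):
        """Flipping either PC's sign leaves every turning angle unchanged."""
        emb = embed_delta_z(fold5_matrix)
        flipped = emb.points * np.array([-1.0, 1.0])
        assert _interior_angles(flipped, emb.labels) == pytest.approx(
            emb.turning_angle_deg
        )


def brute_force_reversal(row, i):
    """Independent oracle: exhaustive scan for decay-then-rise toward the
    apex, using a 5% off-diagonal-range guard."""
    off = np.delete(row, i)
    guard = 0.05 * (off.max() - off.min())
    seq = [row[i]] + list(row[:i][::-1])  # index k -> contact position i-k
    best = None
    for m in range(1, len(seq) - 1):
        decreasing_into = seq[m] < seq[m - 1] and seq[m] == min(seq[: m + 1])
        rises_after = seq[m + 1] > seq[m] and max(seq[m + 1 :]) - seq[m] > guard
        if decreasing_into and rises_after:
            best = i - m
            break
    return best


class TestDecayReversal:
    def test_monotone_rows_have_no_reversal(self, normal_matrix):
        profile = decay_reversal(normal_matrix)
        assert not any(profile.reversal_flags.values())
        assert profile.consensus is None

    def test_flat_rows_suppressed_by_guard(self):
        vals = np.full((6, 6), 1.0)
        np.fill_diagonal(vals, 5.0)
        m = EFIMatrix(values=vals, labels=tuple(range(1, 7)))
        profile = decay_reversal(m)
        assert not any(profile.reversal_flags.values())

    @pytest.mark.parametrize("fold", [3, 5, 7])
    def test_consensus_matches_simulated_fold(self, fold):
        m = simulated_matrix(fold_at=fold)
        profile = decay_reversal(m)
        assert profile.consensus == fold

    @pytest.mark.parametrize("fold", [4, 6])
    def test_agrees_with_brute_force_oracle(self, fold):
        m = simulated_matrix(fold_at=fold, noise_sigma=0.02, seed=3)
        profile = decay_reversal(m)
        for i, lbl in enumerate(m.labels):
            expected = brute_force_reversal(m.values[i], i)
            got = profile.reversal_index.get(lbl)
            got_pos = None if got is None else m.labels.index(got)
            assert got_pos == (None if expected is None else expected), (
                f"row {lbl}: oracle {expected}, detector {got_pos}"
            )


class TestSymmetryScore:
    def test_noiseless_fold_scores_high(self, fold5_matrix):
        assert symmetry_score(fold5_matrix, 5) >= 0.95

    def test_normal_matrix_scores_materially_lower(self, normal_matrix, fold5_matrix):
        s_fold = symmetry_score(fold5_matrix, 5)
        s_norm = symmetry_score(normal_matrix, 5)
        assert s_norm is not None and s_fold - s_norm > 0.2

    def test_fold_at_2_undefined(self):
        m = simulated_matrix(fold_at=2)
        assert symmetry_score(m, 2) is None


class TestDetection:
    @pytest.mark.parametrize("family", list(ArrayFamily))
    def test_normal_insertion_negative(self, family):
        r = detect_tfo(simulated_matrix(family=family))
        assert r.ran and not r.tfo_detected and r.fold_electrode is None

    @pytest.mark.parametrize("fold,family", [(5, ArrayFamily.PRE_CURVED),
                                             (4, ArrayFamily.PRE_CURVED),
                                             (5, ArrayFamily.STRAIGHT_LATERAL_WALL)])
    def test_fold_detected_at_true_contact(self, fold, family):
        r = detect_tfo(simulated_matrix(fold_at=fold, family=family))
        assert r.tfo_detected and r.fold_electrode == fold
        assert r.decay_reversal_electrode == fold

    def test_qc_abort_reports_not_run(self):
        from tfoscan import FaultSpec

        r = detect_tfo(simulated_matrix(faults=FaultSpec(airpocket=True)))
        assert not r.ran and not r.tfo_detected
        assert any("not run" in n for n in r.notes)

    def test_bend_only_mode(self):
        cfg = DetectorConfig(require_decay_reversal=False)
        r = detect_tfo(simulated_matrix(fold_at=6), cfg=cfg)
        assert r.tfo_detected and r.fold_electrode == 6

    def test_label_reversal_of_normal_matrix_stays_negative(self, normal_matrix):
        flipped = EFIMatrix(
            values=normal_matrix.values[::-1, ::-1].copy(),
            labels=normal_matrix.labels[::-1],
        )
        # relabel ascending so QC/detector see a conventional ordering
        relabeled = EFIMatrix(values=flipped.values, labels=tuple(range(1, 17)))
        r = detect_tfo(relabeled)
        assert not r.tfo_detected

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        fold=st.sampled_from([None, 3, 5, 7]),
    )
    def test_scale_invariance_of_verdict(self, c, fold):
        """Z -> cZ changes neither the verdict nor the localization.

        QC thresholds are absolute, so they are rescaled alongside; the
        invariance under test is the detector's."""
        from tfoscan import QCThresholds

        m = simulated_matrix(fold_at=fold, noise_sigma=0.02, seed=11)
        scaled = EFIMatrix(values=m.values * c, labels=m.labels)
        t = QCThresholds(open_kohm=30.0 * c, short_kohm=0.5 * c, firstrow_kohm=5.0 * c)
        r0 = detect_tfo(m)
        r1 = detect_tfo(scaled, qc_t=t)
        assert r0.tfo_detected == r1.tfo_detected
        assert r0.fold_electrode == r1.fold_electrode
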