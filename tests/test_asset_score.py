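"""MCA scoring, tertile splitting and cutoff projection."""

import numpy as np
import pandas as pd
import pytest

from sescra.asset_score import (
    labels_from_cutoffs,
    mca_score,
    project_cutoffs,
    tertile_split,
    weighted_quantile,
)
from sescra.synthetic import ASSET_COLUMNS


def _brute_force_ca_scores(z: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit standardized-residual SVD of the
    disjunctive matrix; among leading dimensions of equal inertia, the
    axis is the combination aligned with the ownership counts."""
    p = z / z.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, _ = np.linalg.svd(s, full_matrices=False)
    k = int(np.argmax(sv > 1e-12 * sv[0]))
    tied = [j for j in range(k, len(sv)) if abs(sv[j] - sv[k]) <= 1e-9 * sv[k]]
    coords = u[:, tied] * sv[tied] / np.sqrt(r)[:, None]
    centred = counts - counts.mean()
    alpha = coords.T @ centred
    alpha = alpha / np.linalg.norm(alpha)
    return coords @ alpha


class TestMcaScore:
    def test_matches_brute_force_svd_and_orders_by_ownership(self):
        records = pd.DataFrame(
            {"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]}
        )
        scores = mca_score(records)
        # ownership counts 0,1,1,2 -> strictly increasing in count
        assert scores[0] < scores[1]
        assert scores[0] < scores[2]
        assert scores[1] < scores[3]
        assert scores[2] < scores[3]
        # oracle on the explicitly constructed 4x4 indicator matrix
        z = np.array(
            [[1, 0, 1, 0], [1, 0, 0, 1], [0, 1, 1, 0], [0, 1, 0, 1]], float
        )
        oracle = _brute_force_ca_scores(z, np.array([0.0, 1.0, 1.0, 2.0]))
        if np.corrcoef(oracle, scores)[0, 1] < 0:
            oracle = -oracle
        np.testing.assert_allclose(scores, oracle, atol=1e-10)

    def test_rejects_constant_indicator(self):
        records = pd.DataFrame({"a": [1, 1, 1, 1], "b": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="single observed category"):
            mca_score(records)

    def test_identical_records_rejected(self):
        records = pd.DataFrame({"a": [1, 1, 1], "b": [0, 0, 0]})
        with pytest.raises(ValueError):
            mca_score(records)

    def test_weighted_mean_is_zero(self):
        rng = np.random.default_rng(5)
        records = pd.DataFrame(
            rng.integers(0, 2, size=(200, 6)), columns=list("abcdef")
        )
        w = rng.uniform(0.5, 2.0, 200)
        scores = mca_score(records, w)
        assert abs(np.average(scores, weights=w)) < 1e-9
        assert abs(mca_score(records).mean()) < 1e-9

    def test_invariant_to_record_and_column_permutation(self):
        rng = np.random.default_rng(6)
        records = pd.DataFrame(
            rng.integers(0, 2, size=(80, 5)), columns=list("abcde")
        )
        base = mca_score(records)
        perm = rng.permutation(80)
        assert np.allclose(mca_score(records.iloc[perm].reset_index(drop=True)), base[perm], atol=1e-9)
        cols = ["c", "a", "e", "b", "d"]
        assert np.allclose(mca_score(records[cols]), base, atol=1e-9)


class TestTertileSplit:
    def test_exact_thirds(self):
        split = tertile_split(np.arange(1.0, 10.0))
        assert list(split.label) == ["low"] * 3 + ["middle"] * 3 + ["high"] * 3
        assert split.cutoffs == (3.0, 6.0)

    def test_all_equal_is_degenerate_single_group(self):
        with pytest.warns(UserWarning, match="degenerate"):
            split = tertile_split(np.ones(5))
        assert split.degenerate
        assert len(set(split.label)) == 1

    def test_weight_concentration_shifts_mass_to_high(self):
        scores = np.arange(10.0)
        weights = np.ones(10)
        weights[-1] = 90.0
        split = tertile_split(scores, weights)
        # brute-force weighted CDF: 90/99 of mass sits on the top score
        high_mass = weights[split.label == "high"].sum() / weights.sum()
        assert high_mass == pytest.approx(90 / 99, abs=0.05)

    def test_labels_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=500)
        w = rng.uniform(0.5, 2, 500)
        base = tertile_split(scores, w).label
        trans = tertile_split(np.exp(3 * scores) + 1, w).label
        assert (base == trans).all()

    def test_ties_at_cutoff_go_to_lower_group(self):
        scores = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0])
        split = tertile_split(scores)
        assert (split.label[scores == split.cutoffs[0]] == "low").all() or (
            split.label[scores == split.cutoffs[0]] == "middle"
        ).all()
        # the record exactly at the first cutoff is never in the group above
        c1 = split.cutoffs[0]
        assert not np.any((scores == c1) & (split.label == "high"))


class TestProjection:
    def test_reference_equal_to_national_is_identity(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=2000)
        national = tertile_split(scores)
        out = project_cutoffs(scores, None, national.cutoffs, scores)
        assert out[0] == pytest.approx(national.cutoffs[0], abs=1e-12)
        assert out[1] == pytest.approx(national.cutoffs[1], abs=1e-12)

    def test_uniform_shift_moves_cutoffs_accordingly(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=5000)
        shift = 1.7
        reference = base + shift  # reference is richer by +c than target
        national = tertile_split(reference)
        out = project_cutoffs(reference, None, national.cutoffs, base)
        # explicit rank computation: cutoffs land at the same ranks, so
        # the target cutoffs equal national cutoffs minus the shift
        assert out[0] == pytest.approx(national.cutoffs[0] - shift, abs=1e-9)
        assert out[1] == pytest.approx(national.cutoffs[1] - shift, abs=1e-9)

    def test_reference_below_cutoffs_labels_everything_low(self):
        reference = np.linspace(-5, -4, 100)
        target = np.linspace(0, 1, 50)
        with pytest.warns(UserWarning, match="clamped"):
            cutoffs = project_cutoffs(reference, None, (0.0, 1.0), target)
        labels = labels_from_cutoffs(target, cutoffs)
        assert (labels == "low").all()


class TestPlantedGradient:
    def test_label_agreement_with_generating_tertile(self, survey_10k):
        scores = mca_score(survey_10k[ASSET_COLUMNS])
        split = tertile_split(scores, survey_10k["weight"].to_numpy(float))
        agreement = (split.label == survey_10k["_latent_ses"]).mean()
        assert agreement > 0.90


def test_weighted_quantile_is_largest_value_within_rank():
    values = np.array([1.0, 2.0, 3.0, 4.0])
    w = np.array([1.0, 1.0, 1.0, 1.0])
    assert weighted_quantile(values, 0.25, w) == 1.0
    assert weighted_quantile(values, 0.26, w) == 1.0
    assert weighted_quantile(values, 0.5, w) == 2.0
    assert weighted_quantile(values, 1.0, w) == 4.0
    # rank below the smallest value's mass: cutoff strictly below the range
    assert weighted_quantile(values, 0.1, w) < 1.0
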