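"""Connectome correction pipeline: normalization, thresholding, banding."""

import numpy as np
import pandas as pd
import pytest

from strokeconn import (
    Connectome,
    DegenerateInputError,
    UndefinedRatioError,
    ValidationError,
    compute_distance_bands,
    fibre_length_profile,
    symmetrize_and_normalize,
    threshold_connectome,
)
from strokeconn.atlas import LONG, MEDIUM, SHORT
from strokeconn.connectome import nearest_rank_cutoff

from conftest import make_atlas


def normalized_from_upper(upper_by_pair, n, region_ids=None):
    """Build a normalized-stage connectome with given upper-triangle values."""
    w = np.zeros((n, n))
    for (i, j), v in upper_by_pair.items():
        w[i, j] = w[j, i] = v
    return Connectome(
        weights=w,
        region_ids=region_ids if region_ids is not None else np.arange(1, n + 1),
        stage="normalized",
    )


class TestSymmetrizeAndNormalize:
    def test_hand_worked_pair(self):
        # counts 10 and 20 between two regions of volumes 100 and 200:
        # mean count 15, volume sum 300 -> weight 0.05
        atlas = make_atlas(
            [[-1, 0, 0], [-2, 0, 0], [-3, 0, 0], [-4, 0, 0]],
            volumes=[100, 200, 300, 400],
            hemispheres=["L"] * 4,
        )
        raw = np.zeros((4, 4))
        raw[0, 1], raw[1, 0] = 10.0, 20.0
        conn = Connectome(raw, np.arange(1, 5), stage="raw")
        out = symmetrize_and_normalize(conn, atlas)
        assert out.stage == "normalized"
        assert out.weights[0, 1] == pytest.approx(15.0 / 300.0)
        assert np.allclose(out.weights, out.weights.T)

    def test_identity_when_volumes_sum_to_one(self):
        atlas = make_atlas(
            [[-1, 0, 0], [-2, 0, 0], [-3, 0, 0], [-4, 0, 0]],
            volumes=[0.5] * 4,
            hemispheres=["L"] * 4,
        )
        rng = np.random.default_rng(0)
        sym = rng.uniform(1, 5, (4, 4))
        sym = (sym + sym.T) / 2
        conn = Connectome(sym, np.arange(1, 5), stage="raw")
        out = symmetrize_and_normalize(conn, atlas)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(out.weights[off], sym[off])

    def test_nonzero_diagonal_zeroed(self):
        atlas = make_atlas(
            [[-1, 0, 0], [-2, 0, 0], [-3, 0, 0], [-4, 0, 0]], hemispheres=["L"] * 4
        )
        raw = np.full((4, 4), 2.0)
        conn = Connectome(raw, np.arange(1, 5), stage="raw")
        out = symmetrize_and_normalize(conn, atlas)
        assert np.all(np.diagonal(out.weights) == 0)

    def test_region_mismatch_rejected(self, square_atlas):
        conn = Connectome(np.ones((4, 4)), np.array([7, 8, 9, 10]), stage="raw")
        with pytest.raises(ValidationError, match="do not match the atlas"):
            symmetrize_and_normalize(conn, square_atlas)

    @pytest.mark.parametrize("bad", [-1.0, np.nan, np.inf])
    def test_invalid_weights_rejected_at_construction(self, bad):
        w = np.ones((4, 4))
        w[0, 1] = bad
        with pytest.raises(ValidationError):
            Connectome(w, np.arange(4), stage="raw")


class TestThreshold:
    def test_nearest_rank_on_one_to_ten(self):
        # nonzero weights 1..10 at percentile 0.20: cutoff is the 2nd order
        # statistic (2); only the weight 1 falls strictly below it
        pairs = {}
        vals = list(range(1, 11))
        k = 0
        for i in range(5):
            for j in range(i + 1, 5):
                if k < len(vals):
                    pairs[(i, j)] = float(vals[k])
                    k += 1
        c = normalized_from_upper(pairs, 5)
        out = threshold_connectome(c, 0.20)
        assert out.threshold_cutoff == 2.0
        survivors = sorted(out.weights[np.triu_indices(5, 1)][
            out.weights[np.triu_indices(5, 1)] > 0
        ])
        assert survivors == [float(v) for v in range(2, 11)]

    def test_equal_weights_unchanged(self):
        c = normalized_from_upper({(0, 1): 3.0, (1, 2): 3.0, (2, 3): 3.0}, 4)
        out = threshold_connectome(c, 0.20)
        assert np.array_equal(out.weights, c.weights)

    def test_zero_percentile_is_noop(self):
        c = normalized_from_upper({(0, 1): 1.0, (1, 2): 5.0, (2, 3): 9.0}, 4)
        out = threshold_connectome(c, 0.0)
        assert np.array_equal(out.weights, c.weights)

    def test_all_zero_matrix_is_degenerate(self):
        c = normalized_from_upper({}, 4)
        with pytest.raises(DegenerateInputError, match="no nonzero"):
            threshold_connectome(c, 0.20)

    def test_wrong_stage_rejected(self):
        c = Connectome(np.zeros((4, 4)), np.arange(4), stage="raw")
        with pytest.raises(ValidationError, match="normalized"):
            threshold_connectome(c, 0.20)

    def test_linear_method_uses_interpolated_quantile(self):
        pairs = {(0, 1): 1.0, (0, 2): 2.0, (1, 2): 3.0, (2, 3): 4.0}
        c = normalized_from_upper(pairs, 4)
        out = threshold_connectome(c, 0.5, method="linear")
        assert out.threshold_cutoff == pytest.approx(2.5)
        assert np.count_nonzero(out.weights[np.triu_indices(4, 1)]) == 2


class TestDistanceBands:
    def test_square_geometry(self, square_atlas):
        # 4 side pairs of length 10 and 2 diagonals of length 10*sqrt(2):
        # sides are short (d <= Q1 = 10), diagonals long (d > Q3)
        bands = compute_distance_bands(square_atlas)
        iu = np.triu_indices(4, 1)
        b = bands.band[iu]
        d = bands.distance[iu]
        assert bands.q1_cutoff == pytest.approx(10.0)
        assert np.all(b[np.isclose(d, 10.0)] == SHORT)
        assert np.all(b[np.isclose(d, 10.0 * np.sqrt(2))] == LONG)
        assert np.count_nonzero(b == SHORT) == 4
        assert np.count_nonzero(b == LONG) == 2

    def test_identical_centroids_degenerate_all_short(self):
        atlas = make_atlas([[-5, 0, 0]] * 4, hemispheres=["L"] * 4)
        with pytest.warns(UserWarning, match="degenerate"):
            bands = compute_distance_bands(atlas)
        assert bands.degenerate
        iu = np.triu_indices(4, 1)
        assert np.all(bands.band[iu] == SHORT)

    def test_ruler_cutoffs_match_hand_quantile(self):
        # 8 collinear points with 28 distinct pair distances; the Q1/Q3
        # cutoffs must match the interpolated-quantile formula evaluated
        # by hand on the sorted distance list
        pos = np.cumsum([0, 1, 2, 4, 8, 16, 32, 64]).astype(float)
        atlas = make_atlas(
            [[-1, p, 0] for p in pos], hemispheres=["L"] * 8
        )
        dists = sorted(
            abs(pos[i] - pos[j]) for i in range(8) for j in range(i + 1, 8)
        )
        assert len(set(dists)) == 28

        def hand_quantile(sorted_vals, p):
            h = (len(sorted_vals) - 1) * p
            lo = int(np.floor(h))
            return sorted_vals[lo] + (h - lo) * (
                sorted_vals[min(lo + 1, len(sorted_vals) - 1)] - sorted_vals[lo]
            )

        bands = compute_distance_bands(atlas)
        assert bands.q1_cutoff == pytest.approx(hand_quantile(dists, 0.25))
        assert bands.q3_cutoff == pytest.approx(hand_quantile(dists, 0.75))
        iu = np.triu_indices(8, 1)
        for d, b in zip(bands.distance[iu], bands.band[iu]):
            if d <= bands.q1_cutoff:
                assert b == SHORT
            elif d > bands.q3_cutoff:
                assert b == LONG
            else:
                assert b == MEDIUM


class TestFibreLengthProfile:
    def _random_instance(self, rng, n=12, density=0.5):
        atlas = make_atlas(
            rng.uniform(-60, 60, (n, 3)), hemispheres=["L"] * n
        )
        w = rng.uniform(0.1, 5.0, (n, n)) * (rng.random((n, n)) < density)
        w = np.triu(w, 1)
        w = w + w.T
        c = Connectome(w, atlas.region_ids, stage="normalized")
        return atlas, c

    def test_balanced_bands_give_unit_ratio(self, square_atlas):
        bands = compute_distance_bands(square_atlas)
        # connect 2 short pairs and both long pairs, then drop one long:
        # use all 4 sides and both diagonals scaled so none is thresholded
        c = normalized_from_upper(
            {(0, 1): 1.0, (2, 3): 1.0, (0, 3): 1.0, (1, 2): 1.0}, 4
        )
        thr = threshold_connectome(c, 0.0)
        p = fibre_length_profile(thr, bands)
        # square corners order: (0,3) and (1,2) are the diagonals
        assert p.n_short == 2 and p.n_long == 2
        assert p.long_short_ratio == 1.0

    def test_no_short_survivors_is_undefined(self, square_atlas):
        bands = compute_distance_bands(square_atlas)
        c = normalized_from_upper({(0, 3): 1.0, (1, 2): 1.0}, 4)  # diagonals only
        thr = threshold_connectome(c, 0.0)
        with pytest.raises(UndefinedRatioError):
            fibre_length_profile(thr, bands)

    def test_counts_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            atlas, c = self._random_instance(rng)
            bands = compute_distance_bands(atlas)
            thr = threshold_connectome(c, 0.20)
            # brute-force loop over all pairs
            counts = {SHORT: 0, MEDIUM: 0, LONG: 0}
            n = atlas.n_regions
            for i in range(n):
                for j in range(i + 1, n):
                    if thr.weights[i, j] > 0:
                        counts[bands.band[i, j]] += 1
            if counts[SHORT] == 0:
                continue
            p = fibre_length_profile(thr, bands)
            assert (p.n_short, p.n_medium, p.n_long) == (
                counts[SHORT], counts[MEDIUM], counts[LONG]
            )
            assert p.long_short_ratio == counts[LONG] / counts[SHORT]

    def test_weight_mode_ratios_summed_weights(self, square_atlas):
        bands = compute_distance_bands(square_atlas)
        c = normalized_from_upper(
            {(0, 1): 2.0, (0, 3): 3.0, (1, 2): 5.0}, 4
        )
        thr = threshold_connectome(c, 0.0)
        p = fibre_length_profile(thr, bands, mode="weights")
        assert p.long_short_ratio == pytest.approx((3.0 + 5.0) / 2.0)


class TestPipelineInvariants:
    """Label-permutation equivariance, scale invariance, conservation."""

    def _random_raw(self, rng, n):
        atlas = make_atlas(
            rng.uniform(-60, 60, (n, 3)),
            volumes=rng.uniform(500, 5000, n),
            hemispheres=["L"] * n,
        )
        w = rng.uniform(0, 10, (n, n)) * (rng.random((n, n)) < 0.6)
        np.fill_diagonal(w, 0)
        return atlas, Connectome(w, atlas.region_ids, stage="raw")

    def _ratio(self, raw, atlas, percentile=0.20):
        bands = compute_distance_bands(atlas)
        thr = threshold_connectome(
            symmetrize_and_normalize(raw, atlas), percentile
        )
        return fibre_length_profile(thr, bands)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(6, 14))
            atlas, raw = self._random_raw(rng, n)
            perm = rng.permutation(n)
            atlas_p = make_atlas(
                atlas.centroids[perm],
                volumes=atlas.volumes[perm],
                hemispheres=["L"] * n,
                region_ids=atlas.region_ids[perm],
            )
            raw_p = Connectome(
                raw.weights[np.ix_(perm, perm)],
                atlas.region_ids[perm],
                stage="raw",
            )
            try:
                p = self._ratio(raw, atlas)
            except UndefinedRatioError:
                continue
            q = self._ratio(raw_p, atlas_p)
            assert (p.n_short, p.n_medium, p.n_long) == (q.n_short, q.n_medium, q.n_long)
            assert p.long_short_ratio == q.long_short_ratio

    def test_global_scaling_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(6, 14))
            atlas, raw = self._random_raw(rng, n)
            k = float(rng.uniform(0.01, 100))
            scaled = Connectome(raw.weights * k, raw.region_ids, stage="raw")
            try:
                p = self._ratio(raw, atlas)
            except UndefinedRatioError:
                continue
            q = self._ratio(scaled, atlas)
            assert (p.n_short, p.n_medium, p.n_long) == (q.n_short, q.n_medium, q.n_long)
            assert p.long_short_ratio == q.long_short_ratio

    def test_removing_medium_connection_preserves_ratio(self):
        rng = np.random.default_rng(9)
        done = 0
        while done < 10:
            n = int(rng.integers(8, 14))
            atlas, raw = self._random_raw(rng, n)
            bands = compute_distance_bands(atlas)
            thr = threshold_connectome(
                symmetrize_and_normalize(raw, atlas), 0.20
            )
            iu = np.triu_indices(n, 1)
            medium_alive = [
                (i, j)
                for i, j in zip(*iu)
                if thr.weights[i, j] > 0 and bands.band[i, j] == MEDIUM
            ]
            if not medium_alive:
                continue
            try:
                before = fibre_length_profile(thr, bands)
            except UndefinedRatioError:
                continue
            i, j = medium_alive[0]
            w2 = thr.weights.copy()
            w2[i, j] = w2[j, i] = 0.0
            thr2 = Connectome(
                w2, thr.region_ids, stage="thresholded",
                threshold_cutoff=thr.threshold_cutoff,
            )
            after = fibre_length_profile(thr2, bands)
            assert after.long_short_ratio == before.long_short_ratio
            done += 1

    def test_band_counts_conserve_survivors(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(6, 14))
            atlas, raw = self._random_raw(rng, n)
            bands = compute_distance_bands(atlas)
            thr = threshold_connectome(
                symmetrize_and_normalize(raw, atlas), 0.20
            )
            iu = np.triu_indices(n, 1)
            alive = int(np.count_nonzero(thr.weights[iu] > 0))
            try:
                p = fibre_length_profile(thr, bands)
            except UndefinedRatioError:
                continue
            assert p.n_total == alive


def test_nearest_rank_cutoff_matches_brute_force():
    rng = np.random.default_rng(3)
    for _ in range(50):
        vals = rng.uniform(0.01, 1, size=int(rng.integers(1, 40)))
        p = float(rng.uniform(0, 0.95))
        got = nearest_rank_cutoff(vals, p)
        srt = sorted(vals)
        k = max(int(np.ceil(p * len(srt))), 1)
        assert got == srt[k - 1]
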