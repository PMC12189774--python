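"""Texture-descriptor tests: hand-derived worked examples, brute-force
oracle equivalence for the three matrix builders, and structural
invariants (conservation, rotation consistency, feature ranges)."""

import numpy as np
import pytest

from nucleotex.segmentation import RegionPatch
from nucleotex.texture import (ANGLE_OFFSETS, BACKGROUND, FeatureVector,
                               TextureConfig, aggregate_features, fos_features,
                               glcm, glcm_features, glrlm, glrlm_features,
                               glszm, glszm_features, nucleus_feature_vector,
                               quantize)

# ---------------------------------------------------------------- oracles


def brute_glcm(levels, d, theta, g):
    """Enumerate every ordered pixel pair at the (d, θ) offset."""
    dr, dc = ANGLE_OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = levels.shape
    counts = np.zeros((g, g), dtype=int)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = levels[r, c], levels[r2, c2]
                if a != BACKGROUND and b != BACKGROUND:
                    counts[a, b] += 1
    return counts


def brute_glrlm(levels, theta, g):
    """Walk every scan line in direction θ and split into maximal runs."""
    dr, dc = ANGLE_OFFSETS[theta]
    h, w = levels.shape
    counts = np.zeros((g, max(h, w)), dtype=int)
    starts = [(r, c) for r in range(h) for c in range(w)
              if not (0 <= r - dr < h and 0 <= c - dc < w)]
    for r0, c0 in starts:
        line = []
        r, c = r0, c0
        while 0 <= r < h and 0 <= c < w:
            line.append(levels[r, c])
            r, c = r + dr, c + dc
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            if line[i] != BACKGROUND:
                counts[line[i], j - i - 1] += 1
            i = j
    return counts


def brute_glszm(levels, connectivity, g):
    """Flood-fill zones of equal level under the given adjacency."""
    h, w = levels.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    seen = np.zeros((h, w), dtype=bool)
    counts = np.zeros((g, h * w), dtype=int)
    for r in range(h):
        for c in range(w):
            if seen[r, c] or levels[r, c] == BACKGROUND:
                continue
            lvl, stack, size = levels[r, c], [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in nbrs:
                    r2, c2 = rr + dr, cc + dc
                    if (0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2]
                            and levels[r2, c2] == lvl):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            counts[lvl, size - 1] += 1
    return counts


def random_masked_patches(n, side=6, g=4, seed=5150):
    rng = np.random.default_rng(seed)
    patches = []
    for _ in range(n):
        levels = rng.integers(0, g, size=(side, side)).astype(np.int32)
        mask = rng.uniform(size=(side, side)) < 0.7
        if not mask.any():
            mask[rng.integers(side), rng.integers(side)] = True
        levels[~mask] = BACKGROUND
        patches.append(levels)
    return patches


# -------------------------------------------------------------- quantize


class TestQuantize:
    def test_three_values_two_levels(self):
        levels = quantize(np.array([0.0, 0.5, 1.0]), n_levels=2)
        assert levels.tolist() == [0, 1, 1]

    def test_constant_patch_level_zero(self):
        assert np.all(quantize(np.full((3, 3), 0.4), 8) == 0)

    def test_full_range_identity(self):
        vals = np.arange(256, dtype=np.float64)
        assert np.array_equal(quantize(vals, 256), np.arange(256))

    def test_background_sentinel(self):
        gray = np.ones((2, 2))
        gray[0, 0] = 0.0
        mask = np.array([[True, True], [True, False]])
        q = quantize(gray, 4, mask=mask)
        assert q[1, 1] == BACKGROUND and q[0, 0] == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.ones((2, 2)), 4, mask=np.zeros((2, 2), bool))


# ------------------------------------------------------------------- FOS


class TestFos:
    def test_population_moments_worked_example(self):
        fv = fos_features(np.array([0.0, 1.0, 1.0, 2.0])).as_dict()
        assert fv["fos_mean"] == 1.0
        assert fv["fos_variance"] == 0.5
        assert fv["fos_skewness"] == 0.0
        assert fv["fos_kurtosis"] == 2.0
        assert (fv["fos_min"], fv["fos_max"], fv["fos_median"]) == (0, 2, 1)

    def test_constant_patch(self):
        fv = fos_features(np.full(9, 0.3)).as_dict()
        assert fv["fos_variance"] == 0.0 and fv["fos_entropy"] == 0.0

    def test_two_equiprobable_levels_one_bit(self):
        fv = fos_features(np.array([0.0, 0.0, 1.0, 1.0])).as_dict()
        assert fv["fos_entropy"] == pytest.approx(1.0)

    def test_single_pixel_convention(self):
        fv = fos_features(np.array([0.7])).as_dict()
        assert fv["fos_variance"] == 0.0
        assert fv["fos_skewness"] == 0.0 and fv["fos_kurtosis"] == 0.0


# ------------------------------------------------------------------ GLCM


class TestGlcm:
    def test_worked_counts(self, stair_patch):
        m = glcm(stair_patch, d=1, theta=0, n_levels=2)
        assert m.counts.tolist() == [[1, 2], [0, 3]]

    def test_normalized_sums_to_one(self, stair_patch):
        p = glcm(stair_patch, 1, 0, n_levels=2).normalize()
        assert p.counts.sum() == pytest.approx(1.0)

    def test_constant_patch_all_mass_at_origin(self):
        m = glcm(np.zeros((4, 4), dtype=np.int32), 1, 0, n_levels=4)
        assert m.counts[0, 0] == m.counts.sum() == 12

    def test_degenerate_offset_flagged(self):
        m = glcm(np.zeros((1, 2), dtype=np.int32), 3, 90, n_levels=2)
        assert m.degenerate

    def test_mask_pairs_excluded(self):
        levels = np.array([[0, BACKGROUND, 1]], dtype=np.int32)
        m = glcm(levels, 1, 0, n_levels=2)
        assert m.counts.sum() == 0

    def test_features_worked_example(self, stair_patch):
        fv = glcm_features(glcm(stair_patch, 1, 0, n_levels=2)).as_dict()
        assert fv["contrast"] == pytest.approx(1 / 3)
        assert fv["energy"] == pytest.approx(7 / 18)

    def test_diagonal_matrix_features(self):
        from nucleotex.texture import CooccurrenceMatrix

        p = CooccurrenceMatrix(np.diag([0.5, 0.5]), 1, 0, normalized=True)
        fv = glcm_features(p).as_dict()
        assert fv["contrast"] == 0.0 and fv["homogeneity"] == 1.0

    def test_single_cell_energy_one(self):
        from nucleotex.texture import CooccurrenceMatrix

        p = CooccurrenceMatrix(np.array([[1.0, 0], [0, 0]]), 1, 0, True)
        fv = glcm_features(p).as_dict()
        assert fv["energy"] == 1.0 and fv["correlation"] == 0.0

    def test_rotation_consistency(self, rng):
        levels = rng.integers(0, 4, size=(6, 6)).astype(np.int32)
        for d in (1, 2):
            rot = np.rot90(levels).copy()
            assert np.array_equal(glcm(rot, d, 0, n_levels=4).counts,
                                  glcm(levels, d, 90, n_levels=4).counts.T)


# ----------------------------------------------------------------- GLRLM


class TestGlrlm:
    def test_row_runs(self):
        row = np.array([[0, 0, 1, 1, 1]], dtype=np.int32)
        r = glrlm(row, 0, n_levels=2)
        assert r.counts[0, 1] == 1 and r.counts[1, 2] == 1
        assert r.counts.sum() == 2

    def test_all_distinct_unit_runs(self):
        r = glrlm(np.array([[0, 1, 2]], dtype=np.int32), 0, n_levels=3)
        assert r.counts[:, 0].sum() == 3

    def test_vertical_scan_of_single_row(self):
        r = glrlm(np.array([[0, 1, 2]], dtype=np.int32), 90, n_levels=3)
        assert r.counts[:, 0].sum() == 3

    def test_features_worked_example(self):
        row = np.array([[0, 0, 1, 1, 1]], dtype=np.int32)
        fv = glrlm_features(glrlm(row, 0, n_levels=2)).as_dict()
        assert fv["sre"] == pytest.approx(13 / 72)
        assert fv["lre"] == pytest.approx(6.5)

    def test_unit_runs_emphases_equal_one(self):
        fv = glrlm_features(glrlm(np.array([[0, 1, 0, 1]], dtype=np.int32),
                                  0, n_levels=2)).as_dict()
        assert fv["sre"] == 1.0 and fv["lre"] == 1.0

    def test_single_run_lre_r_squared(self):
        fv = glrlm_features(glrlm(np.full((1, 4), 0, dtype=np.int32),
                                  0, n_levels=1)).as_dict()
        assert fv["lre"] == 16.0


# ----------------------------------------------------------------- GLSZM


class TestGlszm:
    PATCH = np.array([[0, 0, 1], [0, 1, 1], [1, 0, 0]], dtype=np.int32)

    @staticmethod
    def _zone_sizes(z):
        return sorted(s + 1 for g in range(z.counts.shape[0])
                      for s in range(z.counts.shape[1])
                      for _ in range(z.counts[g, s]))

    def test_4_connectivity_zone_sizes(self):
        assert self._zone_sizes(glszm(self.PATCH, 4, n_levels=2)) == [1, 2, 3, 3]

    def test_8_connectivity_merges_diagonals(self):
        assert self._zone_sizes(glszm(self.PATCH, 8, n_levels=2)) == [4, 5]

    def test_constant_patch_single_zone(self):
        z = glszm(np.zeros((3, 4), dtype=np.int32), 4, n_levels=1)
        assert self._zone_sizes(z) == [12]

    def test_features_worked_example(self):
        fv = glszm_features(glszm(self.PATCH, 4, n_levels=2)).as_dict()
        assert fv["sze"] == pytest.approx(53 / 144)
        assert fv["lze"] == pytest.approx(5.75)

    def test_unit_zones(self):
        patch = np.array([[0, 1], [1, 0]], dtype=np.int32)
        fv = glszm_features(glszm(patch, 4, n_levels=2)).as_dict()
        assert fv["sze"] == 1.0 and fv["lze"] == 1.0


# ----------------------------------------------- oracle equivalence


@pytest.mark.parametrize("builder", ["glcm", "glrlm", "glszm"])
def test_matrix_builders_match_brute_force(builder):
    """Each matrix builder equals exhaustive enumeration on random 6x6
    masked patches over the full (d, θ, connectivity) sets."""
    g = 4
    seeds = {"glcm": 101, "glrlm": 202, "glszm": 303}
    for levels in random_masked_patches(40, seed=seeds[builder]):
        if builder == "glcm":
            for d in (1, 2, 3):
                for theta in (0, 45, 90, 135):
                    got = glcm(levels, d, theta, n_levels=g).counts
                    assert np.array_equal(got, brute_glcm(levels, d, theta, g))
        elif builder == "glrlm":
            for theta in (0, 45, 90, 135):
                got = glrlm(levels, theta, n_levels=g).counts
                assert np.array_equal(got, brute_glrlm(levels, theta, g))
        else:
            for conn in (4, 8):
                got = glszm(levels, conn, n_levels=g).counts
                exp = brute_glszm(levels, conn, g)
                assert np.array_equal(got, exp[:, : got.shape[1]])
                assert exp[:, got.shape[1]:].sum() == 0


def test_conservation_invariants():
    for levels in random_masked_patches(30, seed=99):
        n_mask = (levels != BACKGROUND).sum()
        for theta in (0, 45, 90, 135):
            r = glrlm(levels, theta, n_levels=4)
            lens = np.arange(1, r.counts.shape[1] + 1)
            assert (r.counts.sum(axis=0) * lens).sum() == n_mask
        for conn in (4, 8):
            z = glszm(levels, conn, n_levels=4)
            sizes = np.arange(1, z.counts.shape[1] + 1)
            assert (z.counts.sum(axis=0) * sizes).sum() == n_mask
        m = glcm(levels, 1, 0, n_levels=4)
        if not m.degenerate:
            assert m.normalize().counts.sum() == pytest.approx(1.0)


def test_feature_ranges():
    for levels in random_masked_patches(25, seed=123):
        m = glcm(levels, 1, 45, n_levels=4)
        if not m.degenerate:
            fv = glcm_features(m).as_dict()
            assert 0 < fv["energy"] <= 1 and fv["contrast"] >= 0
        fr = glrlm_features(glrlm(levels, 0, n_levels=4)).as_dict()
        assert 0 < fr["sre"] <= 1 and fr["lre"] >= 1
        fz = glszm_features(glszm(levels, 8, n_levels=4)).as_dict()
        assert 0 < fz["sze"] <= 1 and fz["lze"] >= 1


# ------------------------------------------------ nucleus vector


class TestNucleusVector:
    def test_arity_and_unique_names(self, region_patch):
        fv = nucleus_feature_vector(region_patch)
        assert len(fv) == 86
        assert len(set(fv.names)) == 86

    def test_constant_patch_contrast_zero_energy_one(self):
        patch = RegionPatch(gray=np.full((5, 5), 0.4),
                            mask=np.ones((5, 5), bool), region_id=1,
                            area=25, bbox=(0, 0, 5, 5))
        fv = nucleus_feature_vector(patch).as_dict()
        contrasts = [v for k, v in fv.items() if k.endswith("contrast")]
        energies = [v for k, v in fv.items()
                    if "glcm" in k and k.endswith("energy")]
        assert all(c == 0 for c in contrasts)
        assert all(e == 1 for e in energies)

    def test_composition_matches_suboperations(self, region_patch):
        cfg = TextureConfig()
        fv = nucleus_feature_vector(region_patch, cfg).as_dict()
        q = quantize(region_patch, cfg.n_levels)
        sub = glcm_features(glcm(q, 2, 135, n_levels=cfg.n_levels)).as_dict()
        for name, val in sub.items():
            assert fv[f"glcm_d2_a135_{name}"] == val
        subz = glszm_features(glszm(q, 8, n_levels=cfg.n_levels)).as_dict()
        assert fv["glszm_c8_sze"] == subz["sze"]
        assert fv["shape_area"] == region_patch.area

    def test_all_values_finite(self, region_patch):
        fv = nucleus_feature_vector(region_patch)
        assert np.all(np.isfinite(fv.values))


class TestAggregate:
    def _vectors(self, rng, n):
        names = [f"f{i}" for i in range(5)]
        return [FeatureVector(values=rng.uniform(size=5), names=list(names))
                for _ in range(n)]

    def test_single_nucleus(self, rng):
        vecs = self._vectors(rng, 1)
        agg = aggregate_features(vecs)
        assert np.allclose(agg.values[:5], vecs[0].values)
        assert np.allclose(agg.values[5:10], 0.0)
        assert agg.values[-1] == 1

    def test_two_point_moments(self):
        a = FeatureVector(values=[1.0], names=["x"])
        b = FeatureVector(values=[3.0], names=["x"])
        agg = aggregate_features([a, b]).as_dict()
        assert agg["x_mean"] == 2.0 and agg["x_std"] == 1.0

    def test_permutation_invariance(self, rng):
        vecs = self._vectors(rng, 6)
        fwd = aggregate_features(vecs)
        rev = aggregate_features(vecs[::-1])
        assert np.allclose(fwd.values, rev.values)

    def test_empty_input_flagged(self):
        agg = aggregate_features([])
        assert "no-nuclei" in agg.flags
        assert agg.values[-1] == 0 and len(agg) == 173

    def test_aggregate_length_matches_contract(self, region_patch):
        agg = aggregate_features([nucleus_feature_vector(region_patch)])
        assert len(agg) == 173
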