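"""Rotation grids, masked normalized cross-correlation, peak extraction and
the greedy overlap-exclusion filter."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ciliacoat.errors import ParameterError
from ciliacoat.geometry import angular_distance, euler_to_matrix, rotate_volume
from ciliacoat.matching import (
    Candidate,
    RotationGrid,
    ScoreMap,
    SENTINEL,
    coat_statistics,
    extract_peaks,
    make_rotation_grid,
    match_template,
    overlap_filter,
    template_footprint,
)
from ciliacoat.synthetic import default_template
from ciliacoat.volume import Volume3D


class TestRotationGrid:
    def test_step_360_is_identity_only(self):
        grid = make_rotation_grid(360)
        assert len(grid) == 1
        np.testing.assert_allclose(grid.matrices()[0], np.eye(3), atol=1e-12)

    def test_step_90_matches_lattice_dedup_oracle(self):
        """The 90° grid equals the brute-force 90° Euler lattice after
        duplicate-rotation removal (quaternion distance < 1e-6)."""
        lattice = [
            (a, b, c)
            for a in (0, 90, 180, 270)
            for b in (0, 90, 180)
            for c in (0, 90, 180, 270)
        ]
        quats = Rotation.from_euler("ZYZ", lattice, degrees=True).as_quat()
        unique = []
        for q in quats:
            if not any(
                min(np.linalg.norm(q - u), np.linalg.norm(q + u)) < 1e-6
                for u in unique
            ):
                unique.append(q)
        assert len(make_rotation_grid(90)) == len(unique)

    def test_halving_step_never_decreases_count(self):
        counts = [len(make_rotation_grid(s)) for s in (120, 60, 30)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_contains_identity(self):
        for step in (90, 45, 20):
            grid = make_rotation_grid(step)
            assert np.allclose(grid.matrices()[0], np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("step", [90, 45, 30])
    def test_pairwise_distance_at_least_half_step(self, step):
        mats = make_rotation_grid(step).matrices()
        quats = Rotation.from_matrix(mats).as_quat()
        dots = np.abs(quats @ quats.T)
        np.fill_diagonal(dots, 0)
        min_angle = np.degrees(2 * np.arccos(np.clip(dots.max(), -1, 1)))
        assert min_angle >= step / 2

    def test_bad_step_rejected(self):
        with pytest.raises(ParameterError):
            make_rotation_grid(0)


def _embed(template, pos, angles=(0.0, 0.0, 0.0), shape=(48, 48, 48)):
    vol = np.zeros(shape, dtype=np.float32)
    t = rotate_volume(template, angles)
    box = np.array(t.shape)
    lo = np.array(pos) - box // 2
    vol[lo[0]: lo[0] + box[0], lo[1]: lo[1] + box[1], lo[2]: lo[2] + box[2]] += t
    return Volume3D(vol, 10.0)


class TestMatchTemplate:
    def test_identity_copy_scores_near_one_at_position(self):
        tpl = default_template()
        pos = (24, 20, 26)
        vol = _embed(tpl.data, pos)
        mask = np.ones(vol.data.shape, dtype=bool)
        grid = make_rotation_grid(360)
        scores = match_template(vol, tpl, mask, grid)
        argmax = np.unravel_index(np.argmax(scores.scores), scores.scores.shape)
        assert argmax == pos
        assert scores.scores[pos] >= 0.999

    def test_rotated_copy_recovers_grid_orientation(self):
        tpl = default_template()
        grid = make_rotation_grid(90)
        idx = 7  # an arbitrary non-identity grid orientation
        angles = tuple(grid.angles[idx])
        pos = (24, 24, 24)
        vol = _embed(tpl.data, pos, angles)
        mask = np.ones(vol.data.shape, dtype=bool)
        scores = match_template(vol, tpl, mask, grid)
        best = int(scores.best_orientation[pos])
        got = euler_to_matrix(*grid.angles[best])
        want = euler_to_matrix(*angles)
        assert angular_distance(got, want) < 1e-6

    def test_scores_bounded_by_one(self, small_phantom):
        spec, vol, _ = small_phantom
        mask = np.zeros(vol.data.shape, dtype=bool)
        mask[20:44, 10:54, 10:54] = True
        scores = match_template(vol, spec.template, mask, make_rotation_grid(120))
        inside = scores.scores[mask]
        assert inside.max() <= 1.0 + 1e-6
        assert np.all(scores.scores[~mask] == SENTINEL)

    def test_voxel_size_mismatch_rejected(self):
        tpl = default_template(voxel_size=10.0)
        vol = Volume3D(np.zeros((32, 32, 32)), 3.78)
        with pytest.raises(ParameterError, match="voxel size"):
            match_template(vol, tpl, np.ones((32, 32, 32), bool), make_rotation_grid(360))

    def test_masked_equals_unmasked_restricted(self):
        """Scoring inside a mask equals full scoring restricted to the mask."""
        tpl = default_template()
        vol = _embed(tpl.data, (20, 24, 28), shape=(40, 48, 56))
        rng = np.random.default_rng(5)
        vol = Volume3D(
            vol.data + rng.normal(0, 0.1, vol.data.shape).astype(np.float32), 10.0
        )
        grid = make_rotation_grid(120)
        full = match_template(vol, tpl, np.ones(vol.data.shape, bool), grid)
        sub = np.zeros(vol.data.shape, bool)
        sub[12:30, 14:36, 16:42] = True
        masked = match_template(vol, tpl, sub, grid)
        np.testing.assert_allclose(
            masked.scores[sub], full.scores[sub], atol=1e-5
        )


def _score_map(arr, mask=None):
    arr = np.asarray(arr, dtype=np.float32)
    if mask is None:
        mask = np.ones(arr.shape, bool)
    grid = make_rotation_grid(360)
    return ScoreMap(arr, np.zeros(arr.shape, np.int32), grid, mask, 1.0)


class TestExtractPeaks:
    def test_close_maxima_keep_only_higher(self):
        arr = np.zeros((16, 16, 16))
        arr[8, 8, 8] = 0.9
        arr[8, 8, 11] = 0.8
        peaks = extract_peaks(_score_map(arr), min_distance=5, threshold=0.5)
        assert [p.position for p in peaks] == [(8, 8, 8)]

    def test_threshold_above_max_gives_empty(self):
        arr = np.zeros((8, 8, 8))
        arr[4, 4, 4] = 0.7
        assert extract_peaks(_score_map(arr), 2, threshold=0.9) == []

    def test_matches_brute_force_greedy_nms_oracle(self, rng):
        """Random score maps: identical to an exhaustive greedy oracle that
        re-scans all remaining maxima at every step."""
        for _ in range(5):
            arr = rng.random((16, 16, 16)).astype(np.float32)
            got = extract_peaks(_score_map(arr), min_distance=4, threshold=0.8)
            # oracle: all local maxima (3³ neighborhood) above threshold
            cand = []
            for z in range(16):
                for y in range(16):
                    for x in range(16):
                        v = arr[z, y, x]
                        if v < 0.8:
                            continue
                        neigh = arr[
                            max(z - 1, 0): z + 2,
                            max(y - 1, 0): y + 2,
                            max(x - 1, 0): x + 2,
                        ]
                        if v == neigh.max():
                            cand.append((-v, z, y, x))
            cand.sort()
            kept = []
            for nv, z, y, x in cand:
                p = np.array([z, y, x], float)
                if all(np.linalg.norm(p - np.array(k, float)) >= 4 for k in kept):
                    kept.append((z, y, x))
            assert [p.position for p in got] == kept


def _random_candidates(rng, n, shape, grid):
    out = []
    for _ in range(n):
        pos = tuple(int(v) for v in rng.integers(8, np.array(shape) - 8))
        oi = int(rng.integers(len(grid)))
        out.append(
            Candidate(
                position=pos,
                angles=tuple(grid.angles[oi]),
                orientation_index=oi,
                score=float(np.round(rng.random(), 3)),
            )
        )
    return out


class TestOverlapFilter:
    def test_duplicate_position_keeps_higher_score(self):
        tpl = default_template()
        grid = make_rotation_grid(360)
        a = Candidate(position=(20, 20, 20), angles=(0, 0, 0), orientation_index=0, score=0.9)
        b = Candidate(position=(20, 20, 20), angles=(0, 0, 0), orientation_index=0, score=0.8)
        out = overlap_filter([b, a], tpl, 0.2, (40, 40, 40))
        assert [c.score for c in out] == [0.9]

    def test_disjoint_footprints_all_accepted(self):
        tpl = default_template()
        cands = [
            Candidate(position=p, angles=(0, 0, 0), orientation_index=0, score=s)
            for p, s in [((12, 12, 12), 0.5), ((12, 12, 40), 0.3), ((40, 40, 40), 0.1)]
        ]
        out = overlap_filter(cands, tpl, 0.0, (56, 56, 56))
        assert len(out) == 3

    def test_matches_sequential_resimulation_oracle(self, rng):
        """Accept set identical to a literal oracle that rebuilds the
        occupancy volume from scratch at every step."""
        tpl = default_template()
        grid = make_rotation_grid(90)
        shape = (40, 40, 40)
        for _ in range(10):
            cands = _random_candidates(rng, 30, shape, grid)
            got = overlap_filter(cands, tpl, 0.2, shape)
            accepted = []
            for cand in sorted(cands):
                occ = np.zeros(shape, bool)  # rebuild from scratch
                for prev in accepted:
                    occ |= _paint(prev, tpl.data, shape)
                foot = _paint(cand, tpl.data, shape)
                nfoot = foot.sum()
                if nfoot and (occ & foot).sum() / nfoot <= 0.2:
                    accepted.append(cand)
            assert [c.position for c in got] == [c.position for c in accepted]

    def test_order_invariance_up_to_tie_rule(self, rng):
        tpl = default_template()
        grid = make_rotation_grid(90)
        shape = (48, 48, 48)
        cands = _random_candidates(rng, 40, shape, grid)
        ref = overlap_filter(cands, tpl, 0.2, shape)
        for _ in range(3):
            shuffled = [cands[i] for i in rng.permutation(len(cands))]
            out = overlap_filter(shuffled, tpl, 0.2, shape)
            assert [c.position for c in out] == [c.position for c in ref]

    def test_accepted_pairwise_overlap_within_threshold(self, rng):
        tpl = default_template()
        grid = make_rotation_grid(90)
        shape = (40, 40, 40)
        out = overlap_filter(_random_candidates(rng, 30, shape, grid), tpl, 0.2, shape)
        # direct check: each accepted footprint vs the union of higher-scored
        occ = np.zeros(shape, bool)
        for cand in out:
            foot = _paint(cand, tpl.data, shape)
            assert (occ & foot).sum() / foot.sum() <= 0.2
            occ |= foot

    def test_bad_threshold_rejected(self):
        with pytest.raises(ParameterError):
            overlap_filter([], default_template(), 1.0, (8, 8, 8))


def _paint(cand, template, shape):
    foot = template_footprint(rotate_volume(template, cand.angles))
    box = np.array(foot.shape)
    lo = np.array(cand.position) - box // 2
    out = np.zeros(shape, bool)
    zz, yy, xx = np.nonzero(foot)
    z, y, x = zz + lo[0], yy + lo[1], xx + lo[2]
    ok = (z >= 0) & (z < shape[0]) & (y >= 0) & (y < shape[1]) & (x >= 0) & (x < shape[2])
    out[z[ok], y[ok], x[ok]] = True
    return out


class TestCoatStatistics:
    def _tube(self, spec):
        from collections import defaultdict

        from ciliacoat.membrane import build_tube, fit_closed_contour
        from ciliacoat.synthetic import membrane_points

        groups = defaultdict(list)
        for s, y, x in membrane_points(spec, slices=range(0, 64, 8)):
            groups[s].append((y, x))
        return build_tube(
            [fit_closed_contour(np.array(v), slice_index=s) for s, v in sorted(groups.items())]
        )

    def test_empty_set_gives_zeroed_summary(self, small_phantom):
        from ciliacoat.particles import ParticleTable

        spec, _, _ = small_phantom
        stats = coat_statistics(ParticleTable.empty(), self._tube(spec), spec.voxel_size)
        assert stats["count"] == 0
        assert stats["surface_density_per_um2"] == 0.0

    def test_truth_particles_reproduce_planted_density(self, small_phantom):
        """Feeding the generator's own truth list reproduces the planted
        surface density within 10%."""
        import pandas as pd

        from ciliacoat.particles import ParticleTable

        spec, _, truth = small_phantom
        table = ParticleTable(
            pd.DataFrame(
                {
                    "x": [t.position[2] for t in truth],
                    "y": [t.position[1] for t in truth],
                    "z": [t.position[0] for t in truth],
                    "rot": [t.angles[0] for t in truth],
                    "tilt": [t.angles[1] for t in truth],
                    "psi": [t.angles[2] for t in truth],
                    "score": [1.0] * len(truth),
                }
            )
        )
        tube = self._tube(spec)
        stats = coat_statistics(table, tube, spec.voxel_size)
        assert stats["count"] == len(truth)
        # planted density: count over the cylinder at the mean placement radius
        r_mid = (spec.tube_radius + (spec.d_in + spec.d_out) / 2) * 1e-4  # µm
        z0, z1 = tube.slice_range
        height = (z1 - z0) * spec.voxel_size * 1e-4
        planted = len(truth) / (2 * np.pi * r_mid * height)
        assert stats["surface_density_per_um2"] == pytest.approx(planted, rel=0.10)
        assert np.all(stats["nn_distances_angstrom"] > 0)

    def test_orientations_point_along_outward_normals(self, small_phantom):
        import pandas as pd

        from ciliacoat.particles import ParticleTable

        spec, _, truth = small_phantom
        table = ParticleTable(
            pd.DataFrame(
                {
                    "x": [t.position[2] for t in truth],
                    "y": [t.position[1] for t in truth],
                    "z": [t.position[0] for t in truth],
                    "rot": [t.angles[0] for t in truth],
                    "tilt": [t.angles[1] for t in truth],
                    "psi": [t.angles[2] for t in truth],
                    "score": [1.0] * len(truth),
                }
            )
        )
        stats = coat_statistics(table, self._tube(spec), spec.voxel_size)
        assert np.nanmax(stats["normal_angles_deg"]) < 5.0
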