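import numpy as np
import pytest

from phyloconv.shapes import (
    LandmarkConfiguration,
    ShapeError,
    TPSFormatError,
    TraitMatrix,
    centroid_size,
    gpa,
    pca,
    procrustes_distance,
    read_tps,
    species_mean_scores,
    write_tps,
)
from phyloconv.synthetic_data import synthesize_landmarks

BASE_SHAPE = np.array([
    [0.0, 0.0], [2.0, 0.3], [4.0, 0.0], [3.5, 1.0], [2.0, 1.6],
    [0.5, 1.0], [1.0, 0.5], [3.0, 0.5], [1.5, 1.2], [2.5, 1.2],
])


def rand_config(rng, spec_id="s", species="sp"):
    return LandmarkConfiguration(spec_id, species,
                                 rng.standard_normal((10, 2)))


def similarity_transform(coords, angle, scale, shift):
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    return coords @ rot.T * scale + np.asarray(shift)


class TestCentroidSize:
    def test_known_value(self):
        coords = np.zeros((10, 2))
        coords[:4] = [[1, 1], [1, -1], [-1, 1], [-1, -1]]
        cfg = LandmarkConfiguration("x", "sp", coords)
        assert centroid_size(cfg) == pytest.approx(np.sqrt(8.0))

    def test_scales_linearly(self, rng):
        cfg = rand_config(rng)
        scaled = LandmarkConfiguration("y", "sp", cfg.coords * 3.7)
        assert centroid_size(scaled) == pytest.approx(
            3.7 * centroid_size(cfg))

    def test_direct_formula(self, rng):
        cfg = rand_config(rng)
        centred = cfg.coords - cfg.coords.mean(axis=0)
        expected = np.sqrt(sum(x * x + y * y for x, y in centred))
        assert centroid_size(cfg) == pytest.approx(expected)

    def test_degenerate_raises(self):
        cfg = LandmarkConfiguration("x", "sp", np.ones((10, 2)))
        with pytest.raises(ShapeError):
            centroid_size(cfg)


class TestTPS:
    def test_round_trip(self, rng, tmp_path):
        configs = [rand_config(rng, f"id_{i}", f"sp{i % 2}")
                   for i in range(5)]
        path = tmp_path / "shapes.tps"
        write_tps(configs, path)
        back = read_tps(path)
        assert len(back) == 5
        for a, b in zip(configs, back):
            assert a.specimen_id == b.specimen_id
            assert a.species == b.species
            np.testing.assert_allclose(a.coords, b.coords, rtol=1e-9)

    def test_scale_honored(self, tmp_path):
        lines = ["LM=10"] + [f"{i} {i + 1}" for i in range(10)] + \
            ["ID=sp_a_01", "SCALE=0.5", ""]
        path = tmp_path / "s.tps"
        path.write_text("\n".join(lines))
        cfg = read_tps(path)[0]
        assert cfg.coords[3, 0] == pytest.approx(1.5)

    def test_wrong_landmark_count(self, tmp_path):
        lines = ["LM=12"] + [f"{i} 0" for i in range(12)] + ["ID=x", ""]
        path = tmp_path / "bad.tps"
        path.write_text("\n".join(lines))
        with pytest.raises(TPSFormatError, match="record 0"):
            read_tps(path)

    def test_truncated_record(self, tmp_path):
        path = tmp_path / "bad.tps"
        path.write_text("LM=10\n1 2\n3 4\n")
        with pytest.raises(TPSFormatError, match="truncated"):
            read_tps(path)

    def test_non_numeric(self, tmp_path):
        lines = ["LM=10"] + ["1 2"] * 9 + ["x y", "ID=a", ""]
        path = tmp_path / "bad.tps"
        path.write_text("\n".join(lines))
        with pytest.raises(TPSFormatError, match="non-numeric"):
            read_tps(path)


class TestGPA:
    def test_rotated_copy_aligns_exactly(self):
        a = LandmarkConfiguration("a", "sp", BASE_SHAPE)
        b = LandmarkConfiguration(
            "b", "sp", similarity_transform(BASE_SHAPE, np.pi / 2, 1.0,
                                            (5.0, -3.0)))
        res = gpa([a, b])
        assert np.abs(res.aligned[0] - res.aligned[1]).max() < 1e-10
        assert procrustes_distance(a, b) < 1e-10

    def test_duplicates_give_centered_scaled_consensus(self):
        cfgs = [LandmarkConfiguration(f"c{i}", "sp", BASE_SHAPE.copy())
                for i in range(4)]
        res = gpa(cfgs)
        centred = BASE_SHAPE - BASE_SHAPE.mean(axis=0)
        expected = centred / np.sqrt((centred ** 2).sum())
        # consensus may differ by a rotation; distance must be ~0
        d = procrustes_distance(
            LandmarkConfiguration("e", "sp", expected),
            LandmarkConfiguration("f", "sp", res.consensus))
        assert d < 1e-10

    def test_unit_centroid_sizes(self, rng):
        cfgs = [rand_config(rng, str(i)) for i in range(6)]
        res = gpa(cfgs)
        for shape in res.aligned:
            assert np.sqrt((shape ** 2).sum()) == pytest.approx(1.0,
                                                                abs=1e-8)
        assert np.abs(res.consensus.mean(axis=0)).max() < 1e-12

    def test_invariance_under_similarity_transform(self, rng):
        cfgs = [rand_config(rng, str(i)) for i in range(5)]
        res1 = gpa(cfgs)
        jittered = list(cfgs)
        jittered[2] = LandmarkConfiguration(
            "2", "sp", similarity_transform(cfgs[2].coords, 1.1, 2.5,
                                            (7.0, 7.0)))
        res2 = gpa(jittered)
        # align the two consensuses before comparing per-specimen shapes
        for i in range(5):
            d = procrustes_distance(
                LandmarkConfiguration("x", "s", res1.aligned[i]),
                LandmarkConfiguration("y", "s", res2.aligned[i]))
            assert d < 1e-8

    def test_matches_alternating_procrustes_oracle(self, rng):
        """Independent oracle: closed-form 2-D rotation angle iteration."""
        cfgs = [rand_config(rng, str(i)) for i in range(3)]

        def unit(x):
            c = x - x.mean(axis=0)
            return c / np.sqrt((c ** 2).sum())

        shapes = [unit(c.coords) for c in cfgs]
        consensus = shapes[0]
        for _ in range(2000):
            rotated = []
            for s in shapes:
                # optimal rotation angle: atan2(sum cross, sum dot)
                dot = float(np.sum(s * consensus))
                cross = float(np.sum(s[:, 0] * consensus[:, 1]
                                     - s[:, 1] * consensus[:, 0]))
                ang = np.arctan2(cross, dot)
                rot = np.array([[np.cos(ang), -np.sin(ang)],
                                [np.sin(ang), np.cos(ang)]])
                rotated.append(s @ rot.T)
            shapes = rotated
            new_consensus = unit(np.mean(shapes, axis=0))
            if np.abs(new_consensus - consensus).max() < 1e-13:
                break
            consensus = new_consensus
        oracle_ss = sum(((s - consensus) ** 2).sum() for s in shapes)

        res = gpa(cfgs, tol=1e-12)
        ours_ss = ((res.aligned - res.consensus) ** 2).sum()
        assert ours_ss == pytest.approx(oracle_ss, abs=1e-8)

    def test_needs_two_configs(self, rng):
        with pytest.raises(ShapeError):
            gpa([rand_config(rng)])


class TestProcrustesDistance:
    def test_zero_for_similarity_copy(self, rng):
        a = rand_config(rng)
        b = LandmarkConfiguration(
            "b", "sp", similarity_transform(a.coords, 0.7, 3.0, (1.0, 2.0)))
        assert procrustes_distance(a, b) < 1e-10

    def test_symmetric(self, rng):
        a, b = rand_config(rng, "a"), rand_config(rng, "b")
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-12)

    def test_rotation_grid_oracle(self, rng):
        a, b = rand_config(rng, "a"), rand_config(rng, "b")

        def unit(x):
            c = x - x.mean(axis=0)
            return c / np.sqrt((c ** 2).sum())

        x, y = unit(a.coords), unit(b.coords)
        best = np.inf
        for ang in np.arange(0.0, 2 * np.pi, 1e-4):
            rot = np.array([[np.cos(ang), -np.sin(ang)],
                            [np.sin(ang), np.cos(ang)]])
            yr = y @ rot.T
            # optimal scale for this rotation
            s = float(np.sum(yr * x))
            best = min(best, float(((s * yr - x) ** 2).sum()))
        assert procrustes_distance(a, b) == pytest.approx(
            np.sqrt(best), abs=1e-6)


class TestPCA:
    @pytest.fixture
    def aligned(self, rng):
        cfgs = [rand_config(rng, str(i)) for i in range(12)]
        return gpa(cfgs)

    def test_proportions_sum_to_one(self, aligned):
        res = pca(aligned)
        assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_at_most_16_components(self, aligned):
        res = pca(aligned)
        assert len(res.eigenvalues) <= 16
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_svd_oracle(self, aligned):
        res = pca(aligned)
        dev = (aligned.aligned - aligned.consensus).reshape(12, -1)
        dev = dev - dev.mean(axis=0)
        cov = dev.T @ dev / (len(dev) - 1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.eigenvalues,
                                   evals[:len(res.eigenvalues)], atol=1e-12)
        # reconstruct data from scores/loadings
        np.testing.assert_allclose(res.scores @ res.loadings, dev,
                                   atol=1e-10)

    def test_total_variance_identity(self, aligned):
        res = pca(aligned)
        dev = (aligned.aligned - aligned.consensus).reshape(12, -1)
        dev = dev - dev.mean(axis=0)
        total = (dev ** 2).sum() / (len(dev) - 1)
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-9)

    def test_needs_three_specimens(self, rng):
        cfgs = [rand_config(rng, str(i)) for i in range(2)]
        with pytest.raises(ShapeError):
            pca(gpa(cfgs))

    def test_sign_convention_deterministic(self, aligned):
        res = pca(aligned)
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0


class TestSpeciesMeans:
    def test_duplicate_specimens_mean_equals_scores(self, rng):
        shape = rng.standard_normal((10, 2))
        cfgs = synthesize_landmarks(shape, 6, shape_noise_sd=0.05, seed=2)
        species = ["a", "a", "b", "b", "c", "c"]
        res = pca(gpa(cfgs))
        tm = species_mean_scores(res, species, n_components=2)
        assert tm.species == ["a", "b", "c"]
        np.testing.assert_allclose(
            tm.row("a"), res.scores[:2, :2].mean(axis=0), atol=1e-12)

    def test_one_specimen_per_species_identity(self, rng):
        cfgs = [rand_config(rng, str(i)) for i in range(4)]
        res = pca(gpa(cfgs))
        tm = species_mean_scores(res, ["w", "x", "y", "z"], 2)
        np.testing.assert_allclose(tm.traits, res.scores[:, :2], atol=1e-12)

    def test_group_mean_oracle(self, rng):
        cfgs = [rand_config(rng, str(i)) for i in range(10)]
        species = [f"sp{i % 3}" for i in range(10)]
        res = pca(gpa(cfgs))
        tm = species_mean_scores(res, species, 3)
        for sp in set(species):
            idx = [i for i, s in enumerate(species) if s == sp]
            np.testing.assert_allclose(
                tm.row(sp), res.scores[idx, :3].mean(axis=0), atol=1e-12)

    def test_grand_mean_preserved(self, rng):
        cfgs = [rand_config(rng, str(i)) for i in range(9)]
        species = ["a"] * 4 + ["b"] * 3 + ["c"] * 2
        res = pca(gpa(cfgs))
        tm = species_mean_scores(res, species, 2)
        counts = np.array([4, 3, 2])
        weighted = (tm.traits * counts[:, None]).sum(axis=0) / 9
        np.testing.assert_allclose(weighted, res.scores[:, :2].mean(axis=0),
                                   atol=1e-12)

    def test_too_many_components_raises(self, rng):
        cfgs = [rand_config(rng, str(i)) for i in range(4)]
        res = pca(gpa(cfgs))
        with pytest.raises(ValueError):
            species_mean_scores(res, ["a"] * 4, n_components=50)


class TestTraitMatrix:
    def test_reorder_and_row(self):
        tm = TraitMatrix(["a", "b"], [[1.0, 2.0], [3.0, 4.0]])
        r = tm.reorder(["b", "a"])
        np.testing.assert_allclose(r.traits[0], [3.0, 4.0])

    def test_csv_round_trip(self, tmp_path):
        tm = TraitMatrix(["a", "b"], [[1.5, 2.5], [3.5, 4.5]],
                         ["PC1", "PC2"])
        path = tmp_path / "traits.csv"
        tm.write_csv(path)
        back = TraitMatrix.read_csv(path)
        assert back.species == tm.species
        assert back.trait_names == tm.trait_names
        np.testing.assert_allclose(back.traits, tm.traits)

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            TraitMatrix(["a"], [[np.nan]])

    def test_rejects_duplicates(self):
        with pytest.raises(ValueError):
            TraitMatrix(["a", "a"], [[1.0], [2.0]])
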