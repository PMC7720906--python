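import numpy as np
import pytest

from ramanmc.geometry import LayeredGeometry, VoxelGeometry, load_label_volume


@pytest.fixture
def two_layer():
    # 0.913 mm layer 1 over 10 mm layer 2, 6 mm wide
    return LayeredGeometry([0.0, 0.913, 10.913], [1, 2], half_x=3.0, half_y=3.0)


class TestLayered:
    def test_material_lookup(self, two_layer):
        assert two_layer.material_at(0.0, 0.0, -0.1) == 0      # void above
        assert two_layer.material_at(0.0, 0.0, 0.5) == 1       # top layer
        assert two_layer.material_at(0.0, 0.0, 1.5) == 2       # substrate
        assert two_layer.material_at(0.0, 0.0, 11.0) == 0      # below
        assert two_layer.material_at(4.0, 0.0, 0.5) == 0       # outside laterally

    def test_segment_inside_one_layer(self, two_layer):
        assert two_layer.first_interface((0, 0, 0.2), (1, 0, 0), 0.5) is None

    def test_entry_from_void(self, two_layer):
        hit = two_layer.first_interface((0, 0, -0.1), (0, 0, 1.0), 0.2)
        assert hit is not None
        assert hit.distance == pytest.approx(0.1, abs=1e-12)
        np.testing.assert_allclose(hit.normal, [0, 0, -1])  # faces the ray
        assert (hit.material_before, hit.material_after) == (0, 1)

    def test_layer_to_layer_crossing(self, two_layer):
        hit = two_layer.first_interface((0, 0, 0.5), (0, 0, 1.0), 5.0)
        assert hit.distance == pytest.approx(0.413, abs=1e-12)
        assert (hit.material_before, hit.material_after) == (1, 2)

    def test_lateral_exit(self, two_layer):
        hit = two_layer.first_interface((2.5, 0, 0.5), (1.0, 0, 0), 5.0)
        assert hit.distance == pytest.approx(0.5, abs=1e-12)
        assert hit.material_after == 0


class TestVoxel:
    def test_rejects_bad_volumes(self):
        with pytest.raises(ValueError):
            VoxelGeometry(np.ones((2, 2), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError):
            VoxelGeometry(np.ones((2, 2, 2)), 1.0)  # float labels
        with pytest.raises(ValueError):
            VoxelGeometry(np.ones((2, 2, 2), dtype=np.uint8), 0.0)

    def test_dda_matches_brute_force_supersampling(self):
        rng = np.random.default_rng(42)
        labels = rng.integers(0, 3, size=(10, 10, 10)).astype(np.uint8)
        geom = VoxelGeometry(labels, 0.5, origin=(-2.5, -2.5, 0.0))
        n_checked = 0
        for _ in range(300):
            p = rng.uniform(-3.5, 3.5, 3)
            p[2] = rng.uniform(-1.0, 6.0)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            step = rng.uniform(0.1, 6.0)
            hit = geom.first_interface(p, d, step)
            # brute force: walk the segment at fine resolution
            ts = np.linspace(1e-6, step, 1200)
            mats = np.array([geom.material_at(*(p + t * d)) for t in ts])
            change = np.nonzero(mats != mats[0])[0]
            if hit is None:
                assert change.size == 0
            else:
                assert change.size > 0
                t_brute = ts[change[0]]
                spacing = ts[1] - ts[0]
                assert abs(hit.distance - t_brute) < spacing + 1e-9
                assert hit.material_before == mats[0]
                # point lookup (grazing corner slivers are below the
                # supersampling resolution)
                q = p + (hit.distance + 1e-9) * d
                assert hit.material_after == geom.material_at(*q)
                n_checked += 1
        assert n_checked > 50  # the medium is busy enough to be a real oracle

    def test_layered_and_rasterized_voxel_agree(self, two_layer):
        pitch = 0.0913
        vox = two_layer.to_voxel(pitch)
        rng = np.random.default_rng(7)
        for _ in range(300):
            p = np.array([rng.uniform(-2, 2), rng.uniform(-2, 2), -0.5])
            d = rng.normal(size=3)
            d[2] = abs(d[2]) + 0.3  # downward rays
            d /= np.linalg.norm(d)
            h1 = two_layer.first_interface(p, d, 8.0)
            h2 = vox.first_interface(p, d, 8.0)
            assert (h1 is None) == (h2 is None)
            if h1 is not None:
                assert abs(h1.distance - h2.distance) <= pitch + 1e-9
                assert h1.material_after == h2.material_after

    def test_first_interface_is_reversible(self):
        rng = np.random.default_rng(3)
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[:4] = 1
        labels[4:] = 2
        geom = VoxelGeometry(labels, 0.25, origin=(-1, -1, 0))
        for _ in range(100):
            p = np.array([rng.uniform(-0.9, 0.9), rng.uniform(-0.9, 0.9),
                          rng.uniform(0.01, 1.9)])
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            hit = geom.first_interface(p, d, 3.0)
            if hit is not None:
                q = p + (hit.distance + 1e-9) * d
                assert geom.material_at(*q) == hit.material_after

    def test_uniform_fast_path_consistent_with_dda(self):
        labels = np.ones((6, 6, 6), dtype=np.uint8)
        geom = VoxelGeometry(labels, 1.0, origin=(0, 0, 0))
        assert geom.uniform
        # interior segment: no interface
        assert geom.first_interface((3, 3, 3), (1, 0, 0), 2.0) is None
        # segment reaching outside: exits to void
        hit = geom.first_interface((3, 3, 3), (1, 0, 0), 10.0)
        assert hit.distance == pytest.approx(3.0)
        assert hit.material_after == 0


class TestLoadLabelVolume:
    def test_uniform_stack(self):
        arr = np.ones((4, 5, 6), dtype=np.uint8)
        geom = load_label_volume(arr, 0.1)
        assert geom.shape == (4, 5, 6)
        assert geom.material_at(0.05, 0.05, 0.05) == 1

    def test_two_layer_stack_matches_layered_construction(self):
        arr = np.zeros((10, 4, 4), dtype=np.uint8)
        arr[:3] = 1
        arr[3:] = 2
        geom = load_label_volume(arr, 0.1, origin=(-0.2, -0.2, 0.0))
        layered = LayeredGeometry([0.0, 0.3, 1.0], [1, 2], half_x=0.2, half_y=0.2)
        rng = np.random.default_rng(0)
        for _ in range(200):
            x, y = rng.uniform(-0.19, 0.19, 2)
            z = rng.uniform(-0.1, 1.1)
            assert geom.material_at(x, y, z) == layered.material_at(x, y, z)

    def test_image_stack_round_trip(self, tmp_path):
        import imageio.v3 as iio

        arr = np.zeros((3, 8, 8), dtype=np.uint8)
        arr[1] = 1
        arr[2] = 2
        for i, sl in enumerate(arr):
            iio.imwrite(tmp_path / f"slice_{i:03d}.png", sl)
        geom = load_label_volume(tmp_path, 0.5)
        np.testing.assert_array_equal(geom.labels, arr)

    def test_ragged_stack_rejected(self, tmp_path):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "a.png", np.zeros((4, 4), dtype=np.uint8))
        iio.imwrite(tmp_path / "b.png", np.zeros((5, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="ragged"):
            load_label_volume(tmp_path, 0.5)

    def test_non_integer_pixels_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            load_label_volume(np.full((2, 2, 2), 0.5), 0.5)

    def test_thin_layer_resolved_within_one_voxel(self):
        # 200 slices at 4.56 um pitch ~ a 913 um top layer
        arr = np.full((203, 4, 4), 2, dtype=np.uint8)
        arr[:200] = 1
        geom = load_label_volume(arr, 0.00456)
        boundary = 200 * 0.00456
        assert abs(boundary - 0.913) <= 0.00456
        assert geom.material_at(0.001, 0.001, boundary - 0.001) == 1
        assert geom.material_at(0.001, 0.001, boundary + 0.001) == 2
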