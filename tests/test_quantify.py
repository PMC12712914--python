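import numpy as np
import pytest

from srshisto import quantify as q
from srshisto.preproc import MolecularMaps
from tests.conftest import cellular_patches


def maps_of(lipid, protein=None, collagen=None):
    lipid = np.asarray(lipid, dtype=float)
    return MolecularMaps(
        lipid=lipid,
        protein=np.zeros_like(lipid) if protein is None else np.asarray(protein, float),
        collagen=np.zeros_like(lipid) if collagen is None else np.asarray(collagen, float))


class TestMaskClass:
    def test_uniform_class_is_identity(self):
        maps = maps_of(np.full((4, 4), 9.0))
        out = q.mask_class(maps, np.full((4, 4), 3, dtype=int), 3)
        np.testing.assert_array_equal(out.lipid, maps.lipid)

    def test_class_partition_reconstructs_tissue(self, rng):
        lipid = rng.uniform(1, 9, (16, 16))
        labels = rng.integers(0, 8, (16, 16))
        maps = maps_of(lipid)
        total = sum(q.mask_class(maps, labels, k).lipid for k in range(1, 8))
        np.testing.assert_allclose(total, np.where(labels > 0, lipid, 0.0))

    def test_absent_class_yields_all_zero(self):
        out = q.mask_class(maps_of(np.ones((4, 4))), np.zeros((4, 4), int), 5)
        assert not out.lipid.any()


class TestChemStats:
    def test_uniform_tile_mean(self):
        cfg = q.QuantConfig(tile_size=8)
        stats = q.tile_chem_stats(maps_of(np.full((8, 8), 100.0)), cfg)
        assert len(stats) == 1 and stats[0].lipid_mean == 100.0

    def test_black_pixels_excluded_from_denominator(self):
        lipid = np.zeros((8, 8))
        lipid[:4] = 100.0
        stats = q.tile_chem_stats(maps_of(lipid), q.QuantConfig(tile_size=8))
        assert stats[0].lipid_mean == 100.0
        assert stats[0].nonblack_px == 32

    def test_adding_black_pixels_leaves_mean_unchanged(self):
        lipid = np.full((4, 4), 80.0)
        small = q.tile_chem_stats(maps_of(lipid), q.QuantConfig(tile_size=4))
        grown = np.zeros((8, 8))
        grown[:4, :4] = lipid
        big = q.tile_chem_stats(maps_of(grown), q.QuantConfig(tile_size=8))
        assert small[0].lipid_mean == big[0].lipid_mean

    def test_lp_ratio(self):
        stats = q.tile_chem_stats(
            maps_of(np.full((4, 4), 120.0), np.full((4, 4), 60.0)),
            q.QuantConfig(tile_size=4))
        assert stats[0].lp_ratio == pytest.approx(2.0)

    def test_fully_black_tile_skipped(self):
        stats = q.tile_chem_stats(maps_of(np.zeros((8, 8))), q.QuantConfig(tile_size=4))
        assert stats == []


def flood_fill_count(mask, min_px, visited_connectivity=8):
    """Independent stack-based flood-fill oracle with the 0.5 edge rule."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    total = 0.0
    for y0 in range(h):
        for x0 in range(w):
            if not mask[y0, x0] or seen[y0, x0]:
                continue
            stack, comp = [(y0, x0)], []
            seen[y0, x0] = True
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] \
                                and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
            if len(comp) < min_px:
                continue
            edge = any(y in (0, h - 1) or x in (0, w - 1) for y, x in comp)
            total += 0.5 if edge else 1.0
    return total


class TestCountNuclei:
    def test_interior_blob_counts_one(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:9, 3:8] = True
        assert q.count_nuclei(mask, q.QuantConfig(min_component_px=10)) == 1.0

    def test_border_blob_counts_half(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0:6, 3:8] = True  # touches top border
        assert q.count_nuclei(mask, q.QuantConfig(min_component_px=10)) == 0.5

    def test_small_component_ignored(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[5, 5:8] = True  # 3 px < threshold 10
        assert q.count_nuclei(mask, q.QuantConfig(min_component_px=10)) == 0.0

    def test_matches_flood_fill_oracle(self, rng):
        cfg = q.QuantConfig(min_component_px=5)
        for _ in range(25):
            h, w = rng.integers(8, 40, 2)
            mask = rng.random((h, w)) < 0.35
            assert q.count_nuclei(mask, cfg) == flood_fill_count(mask, 5)


class TestCytologyStats:
    def test_direct_arithmetic_oracle(self):
        # 84,040 tissue px, 10 interior nuclei of 100 px each
        tissue = np.zeros((300, 300), dtype=bool)
        tissue.ravel()[:84040] = True
        nuclei = np.zeros_like(tissue)
        for i in range(10):
            nuclei[30 + 20 * i:30 + 20 * i + 10, 30:40] = True  # 100 px blobs
        nuclei &= tissue
        assert nuclei.sum() == 1000
        cfg = q.QuantConfig(min_component_px=20)
        st = q.cytology_stats(nuclei, tissue, cfg)
        assert st.weighted_nuclei == 10.0
        assert st.mean_cell_area == pytest.approx(8404 / 2.8986 ** 2, rel=1e-4)
        assert st.nc_ratio == pytest.approx(1000 / 83040, rel=1e-6)

    def test_density_area_count_identity(self, rng):
        tissue = rng.random((64, 64)) < 0.9
        nuclei = tissue & (rng.random((64, 64)) < 0.1)
        cfg = q.QuantConfig(min_component_px=1)
        st = q.cytology_stats(nuclei, tissue, cfg)
        area_um2 = tissue.sum() / cfg.px_per_um ** 2
        assert st.density * area_um2 == pytest.approx(st.weighted_nuclei)

    def test_zero_tissue_rejected(self):
        with pytest.raises(ValueError):
            q.cytology_stats(np.zeros((4, 4), bool), np.zeros((4, 4), bool),
                             q.QuantConfig())

    def test_zero_nuclei_reported_missing(self):
        st = q.cytology_stats(np.zeros((4, 4), bool), np.ones((4, 4), bool),
                              q.QuantConfig())
        assert np.isnan(st.mean_cell_area) and np.isnan(st.nc_ratio)
        assert st.density == 0.0


class TestAggregate:
    def _tiles(self, k, n):
        return [q.ClassTileStats(k, i, 100.0 + i, 50.0, 2.0, 64) for i in range(n)]

    def test_under_quota_all_retained(self):
        cfg = q.QuantConfig(n_tiles_per_class=10)
        out = q.aggregate({3: self._tiles(3, 5)}, cfg)
        assert (out[out.metric == "lipid_mean"].n == 5).all()

    def test_seeded_subsample_reproducible(self):
        cfg = q.QuantConfig(n_tiles_per_class=4, seed=9)
        a = q.aggregate({3: self._tiles(3, 50)}, cfg)
        b = q.aggregate({3: self._tiles(3, 50)}, cfg)
        assert a.equals(b)
        assert (a[a.metric == "lipid_mean"].n == 4).all()


@pytest.fixture(scope="module")
def trained():
    patches = cellular_patches(24, size=64, seed0=100)
    cfg = q.QuantConfig(train_epochs=8, lr=3e-3, batch=4, seed=0)
    return patches, q.train_nuclei_model(patches, cfg)


class TestNucleiUNet:
    def test_validation_dice_on_held_out_patches(self, trained):
        _, state = trained
        assert state.val_dice >= 0.85

    def test_loss_decreases_over_training(self, trained):
        _, state = trained
        assert state.loss_curve[-1] < state.loss_curve[0]

    def test_mask_is_binary_and_deterministic(self, trained):
        patches, state = trained
        m1 = q.segment_nuclei(state, patches[0][0])
        m2 = q.segment_nuclei(state, patches[0][0])
        assert m1.dtype == bool
        np.testing.assert_array_equal(m1, m2)

    def test_acellular_input_yields_near_empty_mask(self, trained):
        _, state = trained
        rng = np.random.default_rng(0)
        empty = np.abs(rng.standard_normal((64, 64, 3))) * 4.0
        assert q.segment_nuclei(state, empty).mean() < 0.01

    def test_too_few_patches_rejected(self):
        with pytest.raises(ValueError):
            q.train_nuclei_model([(np.zeros((8, 8, 3)), np.zeros((8, 8)))],
                                 q.QuantConfig())

    def test_fixed_seed_reproducible(self):
        patches = cellular_patches(4, size=32, seed0=7)
        cfg = q.QuantConfig(train_epochs=2, lr=3e-3, batch=2, seed=3)
        a = q.train_nuclei_model(patches, cfg)
        b = q.train_nuclei_model(patches, cfg)
        assert a.loss_curve == b.loss_curve
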