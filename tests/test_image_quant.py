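"""Cell counting, shell geometry, donut densities, aggregation semantics."""

import numpy as np
import pytest

from fearframe.errors import QuantificationError
from fearframe.image_quant import (
    CellCountParams,
    CellCountResult,
    CellStack,
    DensityResult,
    SectionImage,
    aggregate_cell_density,
    aggregate_perisomatic,
    count_labeled_cells,
    densitometry_ratio,
    extract_perisomatic_shell,
    normalize_density,
    paired_background_density,
    perisomatic_density,
    quantify_cell,
)

from _oracles import brute_force_shell


def _disk_image(centers, radius_px=6, shape=(200, 200), level=200.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for r, c in centers:
        img[(yy - r) ** 2 + (xx - c) ** 2 <= radius_px**2] = level
    return img


def _section(img, pixel_size=1.0, margin=5):
    h, w = img.shape
    roi = np.array(
        [[margin, margin], [margin, w - margin],
         [h - margin, w - margin], [h - margin, margin]], dtype=float
    )
    return SectionImage(intensity=img, pixel_size=pixel_size, roi=roi)


class TestCountLabeledCells:
    def test_blank_image_counts_zero(self):
        res = count_labeled_cells(_section(np.zeros((100, 100))))
        assert res.count == 0 and res.density == 0.0

    def test_twelve_planted_disks_counted(self):
        rng = np.random.default_rng(0)
        centers = [(20 + 50 * i, 20 + 45 * j) for i in range(4) for j in range(3)]
        img = _disk_image(centers, shape=(220, 180)) + rng.normal(5, 1, (220, 180))
        res = count_labeled_cells(_section(np.clip(img, 0, None)))
        assert res.count == 12

    def test_overlapping_disks_split_by_watershed(self):
        # two disks overlapping by ~30% of a radius
        r = 8
        centers = [(50, 50), (50, 50 + int(1.7 * r))]
        img = _disk_image(centers, radius_px=r, shape=(100, 120))
        res = count_labeled_cells(
            _section(img), CellCountParams(peak_min_distance=6.0)
        )
        assert res.count == 2
        merged = count_labeled_cells(
            _section(img),
            CellCountParams(use_watershed=False, max_area=2000.0),
        )
        assert merged.count == 1  # without watershed they fuse

    def test_translation_invariance(self):
        img = _disk_image([(40, 40), (80, 90)], shape=(160, 160))
        roi = np.array([[20, 20], [20, 120], [120, 120], [120, 20]], dtype=float)
        sec1 = SectionImage(intensity=img, pixel_size=1.0, roi=roi)
        shifted = np.roll(np.roll(img, 13, axis=0), 7, axis=1)
        sec2 = SectionImage(intensity=shifted, pixel_size=1.0, roi=roi + [13, 7])
        r1, r2 = count_labeled_cells(sec1), count_labeled_cells(sec2)
        assert r1.count == r2.count == 2

    def test_size_filter_excludes_debris_and_blobs(self):
        img = _disk_image([(50, 50)], radius_px=8, shape=(120, 120))  # ~201 um^2
        img[(np.mgrid[:120, :120][0] - 20) ** 2
            + (np.mgrid[:120, :120][1] - 100) ** 2 <= 2**2] = 200.0  # ~12 um^2
        res = count_labeled_cells(_section(img))
        assert res.count == 1

    def test_roi_outside_bounds_rejected(self):
        img = np.zeros((50, 50))
        roi = np.array([[0, 0], [0, 80], [40, 80], [40, 0]], dtype=float)
        with pytest.raises(QuantificationError):
            count_labeled_cells(
                SectionImage(intensity=img, pixel_size=1.0, roi=roi)
            )

    def test_density_is_count_over_roi_area(self):
        img = _disk_image([(60, 60), (60, 120), (120, 60), (120, 120)],
                          shape=(180, 180))
        sec = _section(img, pixel_size=2.0, margin=10)  # 320x320 um roi
        res = count_labeled_cells(sec)
        assert res.count == 4
        assert res.roi_area_mm2 == pytest.approx(0.1024)
        assert res.density == pytest.approx(4 / 0.1024)


class TestAggregateCellDensity:
    def _r(self, animal, density, area=1.0):
        return CellCountResult(
            count=int(density * area), roi_area_mm2=area,
            density=density, animal_id=animal,
        )

    def test_mean_of_two_sections(self):
        out = aggregate_cell_density([self._r("a", 10.0), self._r("a", 20.0)])
        assert out["a"] == pytest.approx(15.0)

    def test_single_section_identity(self):
        out = aggregate_cell_density([self._r("a", 12.5)])
        assert out["a"] == pytest.approx(12.5)

    def test_unequal_areas_use_mean_of_means(self):
        # density 10 over 1 mm^2 and 20 over 3 mm^2: mean of means = 15,
        # pooled count/area would be (10+60)/4 = 17.5
        out = aggregate_cell_density(
            [self._r("a", 10.0, area=1.0), self._r("a", 20.0, area=3.0)]
        )
        assert out["a"] == pytest.approx(15.0)


def _spherical_stack(r_um=5.0, voxel=(0.33, 0.111, 0.111), margin_um=6.0):
    vz, vy, vx = voxel
    nz = int(2 * (r_um + 1.0) / vz) + 3
    nxy = int(2 * (r_um + margin_um) / vx) + 3
    cz, cy, cx = (nz - 1) / 2, (nxy - 1) / 2, (nxy - 1) / 2
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(nxy), np.arange(nxy), indexing="ij", sparse=True
    )
    soma = ((zz - cz) * vz) ** 2 + ((yy - cy) * vy) ** 2 + ((xx - cx) * vx) ** 2 <= r_um**2
    return CellStack(
        signal=np.zeros((nz, nxy, nxy)), soma_mask=soma, voxel_size=voxel
    )


class TestShellGeometry:
    def test_dilation_radius_is_45_px_at_confocal_voxels(self):
        stack = _spherical_stack(r_um=2.0, margin_um=5.5)
        shell = extract_perisomatic_shell(stack, 5.0)
        # 5 um / 0.111 um = 45.045 -> 45 px under round-half-even
        assert shell.radius_px == 45

    def test_shell_disjoint_from_soma_and_within_dilation(self):
        stack = _spherical_stack(r_um=2.0, margin_um=4.0)
        shell = extract_perisomatic_shell(stack, 3.0)
        assert not np.any(shell.mask & stack.soma_mask)

    def test_shell_only_on_soma_slices(self):
        stack = _spherical_stack(r_um=2.0, margin_um=4.0)
        shell = extract_perisomatic_shell(stack, 3.0)
        soma_slices = stack.soma_mask.any(axis=(1, 2))
        shell_slices = shell.mask.any(axis=(1, 2))
        assert not np.any(shell_slices & ~soma_slices)

    def test_matches_brute_force_distance_oracle(self):
        # small stack, exhaustive per-voxel min-distance comparison
        voxel = (0.33, 0.111, 0.111)
        nz, nxy = 12, 64
        rng = np.random.default_rng(1)
        soma = np.zeros((nz, nxy, nxy), bool)
        zz, yy, xx = np.meshgrid(
            np.arange(nz), np.arange(nxy), np.arange(nxy), indexing="ij",
            sparse=True,
        )
        soma[((zz - 6) * 3) ** 2 + (yy - 30) ** 2 + (xx - 34) ** 2 <= 13**2] = True
        stack = CellStack(
            signal=np.zeros((nz, nxy, nxy)), soma_mask=soma, voxel_size=voxel
        )
        shell = extract_perisomatic_shell(stack, 1.5)
        oracle = brute_force_shell(soma, shell.radius_px)
        assert np.array_equal(shell.mask, oracle)

    def test_shell_thickness_within_one_pixel(self):
        stack = _spherical_stack(r_um=3.0, margin_um=6.0)
        shell = extract_perisomatic_shell(stack, 5.0)
        vz, vy, vx = stack.voxel_size
        # max in-plane distance from shell voxel to soma, central slice
        z = stack.soma_mask.shape[0] // 2
        from scipy import ndimage as ndi

        dt = ndi.distance_transform_edt(~stack.soma_mask[z]) * vx
        dmax = dt[shell.mask[z]].max()
        assert abs(dmax - 5.0) <= vx * (1 + 1e-9) + (5.0 - 45 * vx)

    def test_excessive_clipping_rejected(self):
        # soma hugging the image edge: most of the shell falls outside
        soma = np.zeros((3, 40, 40), bool)
        soma[1, 18:22, 0:4] = True
        stack = CellStack(
            signal=np.zeros((3, 40, 40)), soma_mask=soma,
            voxel_size=(0.33, 0.111, 0.111),
        )
        with pytest.raises(QuantificationError):
            extract_perisomatic_shell(stack, 5.0)


class TestPerisomaticDensity:
    def _shell_stack(self):
        stack = _spherical_stack(r_um=2.0, margin_um=4.0)
        shell = extract_perisomatic_shell(stack, 3.0)
        return stack, shell

    def test_zero_channel_gives_zero(self):
        stack, shell = self._shell_stack()
        d, _ = perisomatic_density(np.zeros_like(stack.signal), shell, 10.0)
        assert d == 0.0

    def test_saturated_channel_gives_one(self):
        stack, shell = self._shell_stack()
        d, _ = perisomatic_density(np.full_like(stack.signal, 100.0), shell, 50.0)
        assert d == 1.0

    def test_planted_fraction_recovered_with_fixed_threshold(self):
        stack, shell = self._shell_stack()
        rng = np.random.default_rng(2)
        idx = np.argwhere(shell.mask)
        chosen = idx[rng.choice(len(idx), size=int(0.12 * len(idx)), replace=False)]
        chan = np.zeros_like(stack.signal)
        chan[tuple(chosen.T)] = 100.0
        d, _ = perisomatic_density(chan, shell, 50.0)
        assert d == pytest.approx(0.12, abs=0.005)

    def test_monotone_in_threshold(self):
        stack, shell = self._shell_stack()
        rng = np.random.default_rng(3)
        chan = rng.uniform(0, 100, stack.signal.shape)
        ds = [perisomatic_density(chan, shell, thr)[0] for thr in (10, 30, 50, 80)]
        assert ds == sorted(ds, reverse=True)

    def test_empty_shell_rejected(self):
        stack, shell = self._shell_stack()
        from dataclasses import replace

        empty = replace(shell, mask=np.zeros_like(shell.mask))
        with pytest.raises(QuantificationError):
            perisomatic_density(stack.signal, empty, 10.0)


class TestNormalize:
    def test_stated_subtraction(self):
        assert normalize_density(0.30, 0.05) == pytest.approx(0.25)

    def test_equal_gives_zero(self):
        assert normalize_density(0.2, 0.2) == 0.0

    def test_negative_retained(self):
        assert normalize_density(0.10, 0.15) == pytest.approx(-0.05)

    def test_missing_background_errors(self):
        stack = _spherical_stack(r_um=2.0, margin_um=4.0)
        with pytest.raises(QuantificationError):
            paired_background_density(None, stack, 3.0, 10.0)

    def test_background_shell_same_size_at_center(self):
        stack = _spherical_stack(r_um=2.0, margin_um=4.0)
        shell = extract_perisomatic_shell(stack, 3.0)
        bg = np.zeros_like(stack.signal)
        d, _ = paired_background_density(bg, stack, 3.0, 10.0)
        assert d == 0.0


class TestAggregatePerisomatic:
    def _cell(self, animal, section, label, nd):
        return DensityResult(
            raw_density=nd, background_density=0.0, normalized_density=nd,
            animal_id=animal, section_id=section, cell_label=label,
        )

    def test_single_section_mean(self):
        out = aggregate_perisomatic(
            [self._cell("a", "s1", "retro-labeled", 0.2),
             self._cell("a", "s1", "retro-labeled", 0.4)]
        )
        assert out[("a", "retro-labeled")] == pytest.approx(0.3)

    def test_hierarchical_mean_not_pooled(self):
        cells = [self._cell("a", "sA", "retro-labeled", 0.2)] * 4
        cells += [self._cell("a", "sB", "retro-labeled", 0.4)]
        out = aggregate_perisomatic(cells)
        # mean of section means (0.2, 0.4) = 0.3; pooled mean would be 0.24
        assert out[("a", "retro-labeled")] == pytest.approx(0.3)

    def test_labels_aggregate_independently(self):
        cells = [
            self._cell("a", "s1", "retro-labeled", 0.5),
            self._cell("a", "s1", "unlabeled", 0.1),
        ]
        out = aggregate_perisomatic(cells)
        assert out[("a", "unlabeled")] == pytest.approx(0.1)
        assert out[("a", "retro-labeled")] == pytest.approx(0.5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        cells = [
            self._cell("a", f"s{s}", "unlabeled", float(rng.uniform()))
            for s in range(3)
            for _ in range(4)
        ]
        out1 = aggregate_perisomatic(cells)
        out2 = aggregate_perisomatic(list(reversed(cells)))
        assert out1[("a", "unlabeled")] == pytest.approx(out2[("a", "unlabeled")])


class TestTiffIO:
    def test_section_round_trip_through_tiff_and_json_roi(self, tmp_path):
        import json

        import tifffile

        from fearframe.image_quant import read_section_image

        img = _disk_image([(60, 60), (120, 120)], shape=(180, 180))
        tifffile.imwrite(tmp_path / "sec.tif", img.astype(np.float32))
        roi = [[10, 10], [10, 170], [170, 170], [170, 10]]
        (tmp_path / "roi.json").write_text(json.dumps(roi))
        sec = read_section_image(
            tmp_path / "sec.tif", tmp_path / "roi.json", pixel_size=1.0
        )
        np.testing.assert_allclose(sec.intensity, img)
        assert count_labeled_cells(sec).count == 2

    def test_stack_round_trip_through_tiff(self, tmp_path):
        import tifffile

        from fearframe.image_quant import read_cell_stack

        stack = _spherical_stack(r_um=2.0, margin_um=4.0)
        tifffile.imwrite(tmp_path / "sig.tif", stack.signal.astype(np.float32))
        tifffile.imwrite(
            tmp_path / "soma.tif", stack.soma_mask.astype(np.uint8)
        )
        back = read_cell_stack(
            tmp_path / "sig.tif", tmp_path / "soma.tif",
            cell_label="retro-labeled",
        )
        assert np.array_equal(back.soma_mask, stack.soma_mask)
        assert back.cell_label == "retro-labeled"


class TestDensitometry:
    def test_unit_ratio(self):
        assert densitometry_ratio(1.2, 1.2) == pytest.approx(1.0)

    def test_duplicates_averaged_before_ratio(self):
        assert densitometry_ratio([1.0, 1.2], 1.1) == pytest.approx(1.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            densitometry_ratio(1.0, 0.0)
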