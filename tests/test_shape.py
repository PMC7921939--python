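"""Half-spheroid standardization and voxel enrichment ratios."""

import numpy as np
import pytest

from synquant import (
    StandardizedMap,
    SynthCoupleSpec,
    build_enrichment_region,
    central_core_ratio,
    enrichment_ratio,
    render_pattern_template,
    reorient_interface_up,
    standardize_couple,
)
from synquant.shape import template_support
from synquant.synth import _tcell_mask, _truth_interface
from synquant.tracking import InterfaceGeometry

from conftest import rot90_interface


def _iso_cell(radius=4.0, rc=3.0, s=0.5, n=45):
    """Truncated sphere on an isotropic grid with its exact interface.

    n is odd so the cell axis falls on a voxel column; resampling paths
    then compare against the upright original without sub-voxel offsets.
    """
    ax = np.arange(n) * s
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    c = np.array([8.0, (n - 1) * s / 2, (n - 1) * s / 2])
    d0 = np.sqrt(radius**2 - rc**2)
    cc = c + np.array([d0, 0.0, 0.0])
    mask = ((z - cc[0]) ** 2 + (y - cc[1]) ** 2 + (x - cc[2]) ** 2
            <= radius**2) & (z >= c[0] - 1e-9)
    r = np.hypot(y - c[1], x - c[2])
    vox = np.argwhere(mask & (np.abs(z - c[0]) < s / 2) & (r <= rc))
    iface = InterfaceGeometry(
        voxels=vox, center=c, normal=np.array([1.0, 0.0, 0.0]),
        diameter=2 * rc,
    )
    return mask, iface, (s, s, s)


class TestStandardization:
    def test_uniform_cell_maps_to_uniform_template(self, coupled_cell):
        mask, iface, spacing = coupled_cell
        vol = np.where(mask, 100.0, 0.0)
        m = standardize_couple(vol, mask, iface, spacing)
        vals = m.values[m.support]
        assert vals.sum() == pytest.approx(1.0, abs=1e-9)
        assert vals.std() / vals.mean() <= 0.05

    def test_scale_invariance_across_cell_sizes(self):
        # the same relative-coordinate accumulation (relative depth < 0.3,
        # relative radius < 0.5) in cells of two radii gives equal maps.
        # The two cells are voxelized at scale-matched resolution so the
        # relative accumulation boundary is quantized identically; only
        # then is the comparison about the standardization, not about
        # voxelization of the inputs.
        from synquant.config import ShapeParams

        maps = []
        for radius, rc, s, n, z_if in (
            (4.0, 3.0, 0.5, 45, 8.0),
            (2.0, 1.5, 0.25, 53, 5.0),
        ):
            ax = np.arange(n) * s
            z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
            c = np.array([z_if, (n - 1) * s / 2, (n - 1) * s / 2])
            d0 = np.sqrt(radius**2 - rc**2)
            mask = (
                (z - c[0] - d0) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2
                <= radius**2
            ) & (z >= c[0] - 1e-9)
            r = np.hypot(y - c[1], x - c[2])
            vox = np.argwhere(mask & (np.abs(z - c[0]) < s / 2) & (r <= rc))
            iface = InterfaceGeometry(
                voxels=vox, center=c, normal=np.array([1.0, 0.0, 0.0]),
                diameter=2 * rc,
            )
            depth = z - c[0]
            depth_max = depth[mask].max()
            vol = np.where(mask, 100.0, 0.0)
            vol[mask & (depth / depth_max < 0.3) & (r / rc < 0.5)] += 200.0
            params = ShapeParams(iso_spacing_um=s)
            maps.append(
                standardize_couple(vol, mask, iface, (s, s, s), params)
            )
        l1 = np.abs(maps[0].values - maps[1].values).sum()
        assert l1 <= 0.02

    def test_map_normalization_enforced(self):
        support = template_support((32, 64, 64))
        bad = np.where(support, 2.0, 0.0)
        with pytest.raises(ValueError, match="sum to 1"):
            StandardizedMap(values=bad, support=support)

    def test_empty_mask_rejected(self, coupled_cell):
        _, iface, spacing = coupled_cell
        empty = np.zeros((21, 64, 64), bool)
        with pytest.raises(ValueError):
            standardize_couple(np.zeros(empty.shape), empty, iface, spacing)


class TestReorientation:
    def test_already_upright_is_identity(self):
        mask, iface, spacing = _iso_cell()
        vol = np.where(mask, 50.0, 0.0)
        cell = reorient_interface_up(mask, vol, iface, spacing)
        assert np.array_equal(cell.volume, vol)
        assert np.array_equal(cell.mask, mask)

    def test_rotated_cell_realigns(self):
        # couple axis along +y: standardized map equals the upright one
        mask, iface, spacing = _iso_cell()
        vol = render_pattern_template("central", mask, iface, 2.0, spacing)
        m0 = standardize_couple(vol, mask, iface, spacing)
        mask2 = np.transpose(mask, (1, 0, 2)).copy()
        vol2 = np.transpose(vol, (1, 0, 2)).copy()
        iface2 = InterfaceGeometry(
            voxels=iface.voxels[:, [1, 0, 2]],
            center=iface.center[[1, 0, 2]],
            normal=np.array([0.0, 1.0, 0.0]),
            diameter=iface.diameter,
        )
        m1 = standardize_couple(vol2, mask2, iface2, spacing)
        v0, v1 = m0.values[m0.support], m1.values[m1.support]
        corr = np.corrcoef(v0, v1)[0, 1]
        assert corr >= 0.99

    def test_antiparallel_normal_flips(self):
        mask, iface, spacing = _iso_cell()
        vol = render_pattern_template("central", mask, iface, 2.0, spacing)
        m0 = standardize_couple(vol, mask, iface, spacing)
        n = mask.shape[0]
        mask3, vol3 = mask[::-1].copy(), vol[::-1].copy()
        s = spacing[0]
        iface3 = InterfaceGeometry(
            voxels=np.column_stack(
                [n - 1 - iface.voxels[:, 0], iface.voxels[:, 1],
                 iface.voxels[:, 2]]
            ),
            center=np.array(
                [(n - 1) * s - iface.center[0], iface.center[1],
                 iface.center[2]]
            ),
            normal=np.array([-1.0, 0.0, 0.0]),
            diameter=iface.diameter,
        )
        m3 = standardize_couple(vol3, mask3, iface3, spacing)
        assert central_core_ratio(m3) == pytest.approx(
            central_core_ratio(m0), rel=0.02
        )

    def test_intensity_conserved_within_one_percent(self):
        mask, iface, spacing = _iso_cell()
        vol = np.where(mask, 80.0, 0.0)
        iface2 = InterfaceGeometry(
            voxels=iface.voxels[:, [1, 0, 2]],
            center=iface.center[[1, 0, 2]],
            normal=np.array([0.0, 1.0, 0.0]),
            diameter=iface.diameter,
        )
        cell = reorient_interface_up(
            np.transpose(mask, (1, 0, 2)).copy(),
            np.transpose(vol, (1, 0, 2)).copy(),
            iface2, spacing,
        )
        assert cell.volume.sum() == pytest.approx(vol.sum(), rel=0.01)

    def test_degenerate_normal_rejected(self):
        mask, iface, spacing = _iso_cell()
        iface.normal = np.zeros(3)
        with pytest.raises(ValueError, match="degenerate"):
            reorient_interface_up(mask, np.ones(mask.shape), iface, spacing)


class TestEnrichmentRegionAndRatios:
    def _uniform_map(self):
        support = template_support((32, 64, 64))
        values = np.where(support, 1.0 / support.sum(), 0.0)
        return StandardizedMap(values=values, support=support)

    def test_region_size_is_exact_decile(self):
        m = self._uniform_map()
        region = build_enrichment_region([m])
        assert region.mask.sum() == round(0.10 * m.support.sum())

    def test_uniform_map_ratios_are_one(self):
        m = self._uniform_map()
        region = build_enrichment_region([m, m, m])
        assert enrichment_ratio(m, region) == pytest.approx(1.0, abs=1e-6)
        assert central_core_ratio(m) == pytest.approx(1.0, abs=1e-6)

    def test_all_mass_in_region_gives_count_quotient(self):
        m = self._uniform_map()
        region = build_enrichment_region([m])
        values = np.zeros_like(m.values)
        values[region.mask] = 1.0 / region.mask.sum()
        point = StandardizedMap(values=values, support=m.support)
        expected = m.support.sum() / region.mask.sum()
        assert enrichment_ratio(point, region) == pytest.approx(
            expected, abs=1e-6
        )

    def test_zero_mass_in_region_gives_zero(self):
        m = self._uniform_map()
        region = build_enrichment_region([m])
        values = np.where(m.support & ~region.mask, 1.0, 0.0)
        values /= values.sum()
        hollow = StandardizedMap(values=values, support=m.support)
        assert enrichment_ratio(hollow, region) == 0.0

    def test_central_cohort_region_is_under_interface_center(self):
        # constructed central-concentrated maps: a graded focus under the
        # interface center; the top-decile region must sit inside the
        # central cylinder (voxel-count oracle)
        support = template_support((32, 64, 64))
        d, h, w = support.shape
        radius = (min(h, w) - 1) / 2.0
        k = np.arange(d)[:, None, None]
        jj = np.arange(h)[None, :, None]
        ii = np.arange(w)[None, None, :]
        rr = np.hypot(jj - (h - 1) / 2, ii - (w - 1) / 2)
        focus = np.exp(-((rr / (0.4 * radius)) ** 2) - ((k + 0.5) / (0.3 * d)) ** 2)
        rng = np.random.default_rng(0)
        maps = []
        for _ in range(3):
            vals = np.where(
                support, 1.0 + 30.0 * focus * rng.uniform(0.9, 1.1), 0.0
            )
            vals /= vals.sum()
            maps.append(StandardizedMap(values=vals, support=support))
        region = build_enrichment_region(maps)
        kk, jj2, ii2 = np.nonzero(region.mask)
        rr2 = np.hypot(jj2 - (h - 1) / 2, ii2 - (w - 1) / 2)
        inside = (rr2 <= 0.5 * radius) & ((kk + 0.5) / d <= 0.5)
        assert inside.mean() >= 0.8

    def test_central_scores_higher_core_ratio_than_peripheral(self):
        # paired comparison on generated maps, several seeds
        spec0 = SynthCoupleSpec()
        spacing = spec0.acquisition.spacing
        rng = np.random.default_rng(1)
        for _ in range(10):
            rc = float(rng.uniform(2.5, 3.3))
            spec = SynthCoupleSpec(interface_radius=rc)
            mask = _tcell_mask(spec, rc, 0)
            iface = _truth_interface(spec, rc)
            ratios = {}
            for pat in ("central", "peripheral"):
                vol = render_pattern_template(pat, mask, iface, 2.0, spacing)
                vol += rng.normal(0, 2.0, vol.shape)
                smap = standardize_couple(vol, mask, iface, spacing)
                ratios[pat] = central_core_ratio(smap)
            assert ratios["central"] > ratios["peripheral"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            build_enrichment_region([])

    def test_monotone_in_region_mass(self):
        # moving mass into the region strictly increases the ratio
        m = self._uniform_map()
        region = build_enrichment_region([m])
        prev = None
        for frac in (0.1, 0.3, 0.6, 0.9):
            values = np.where(m.support, 1.0, 0.0)
            values[region.mask] = 0.0
            values *= (1 - frac) / values.sum()
            values[region.mask] = frac / region.mask.sum()
            ratio = enrichment_ratio(
                StandardizedMap(values=values, support=m.support), region
            )
            if prev is not None:
                assert ratio > prev
            prev = ratio

    def test_rigid_motion_changes_ratios_by_at_most_two_percent(
        self, coupled_cell
    ):
        mask, iface, spacing = coupled_cell
        vol = render_pattern_template("central", mask, iface, 2.0, spacing)
        m0 = standardize_couple(vol, mask, iface, spacing)
        e0 = enrichment_ratio(m0, build_enrichment_region([m0]))
        c0 = central_core_ratio(m0)
        mask_r = np.rot90(mask, 1, axes=(1, 2)).copy()
        vol_r = np.rot90(vol, 1, axes=(1, 2)).copy()
        iface_r = rot90_interface(iface, mask.shape[1], spacing[1])
        m1 = standardize_couple(vol_r, mask_r, iface_r, spacing)
        e1 = enrichment_ratio(m1, build_enrichment_region([m1]))
        c1 = central_core_ratio(m1)
        assert abs(e1 - e0) / e0 <= 0.02
        assert abs(c1 - c0) / c0 <= 0.02
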