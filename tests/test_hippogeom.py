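import numpy as np
import pytest
from scipy import ndimage

from hippodev.hippogeom import (CoordinateField, cosine_similarity,
                                gradient_field, macrostructure,
                                midthickness_surface, orientation_maps,
                                parcel_average, sample_to_surface,
                                solve_laplace, surface_at_io)
from hippodev.mesh import build_template_mesh


def offrim_mask(mask, n=2):
    return mask & ndimage.binary_erosion(mask, iterations=n)


class TestSolveLaplace:
    def test_1d_slab_linear(self):
        """Field on a straight slab is linear in position."""
        mask = np.zeros((12, 5, 5), bool)
        mask[1:11] = True
        source = np.zeros_like(mask)
        source[0] = True
        sink = np.zeros_like(mask)
        sink[11] = True
        tol = 1e-7
        psi = solve_laplace(mask, source, sink, tol=tol)
        x = np.arange(1, 11)
        expect = (x - 0.5) / 10.0  # face-Dirichlet: 0 at x=0.5, 1 at x=10.5
        got = psi[1:11, 2, 2]
        assert np.max(np.abs(got - expect)) < tol * 10

    def test_annulus_matches_log_radial_solution(self):
        """2-D concentric-ring domain reproduces the closed-form
        log-radial harmonic within 1% away from the rim."""
        n = 128
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        cx = cy = (n - 1) / 2 + 0.21  # off-grid centre
        r = np.hypot(xx - cx, yy - cy)
        r0, r1 = 20.0, 50.0
        ring = (r > r0) & (r < r1)
        mask = np.zeros((n, n, 3), bool)
        mask[:, :, 1] = ring
        grown = ndimage.binary_dilation(ring)
        source = np.zeros_like(mask)
        source[:, :, 1] = (r <= r0) & grown
        sink = np.zeros_like(mask)
        sink[:, :, 1] = (r >= r1) & grown
        psi = solve_laplace(mask, source, sink, tol=1e-7)
        analytic = np.log(r / r0) / np.log(r1 / r0)
        core = ring & ndimage.binary_erosion(ring, iterations=3)
        err = np.abs(psi[:, :, 1][core] - analytic[core])
        assert err.max() < 0.01

    def test_maximum_principle(self, curved_coords, curved_phantom):
        for ax in ("AP", "PD", "IO"):
            vals = curved_coords.psi[ax][curved_phantom.mask]
            assert np.all((vals > 0) & (vals < 1))

    def test_disconnected_component_error(self):
        mask = np.zeros((10, 3, 3), bool)
        mask[1:4] = True
        mask[6:9] = True  # island touching nothing
        source = np.zeros_like(mask)
        source[0] = True
        sink = np.zeros_like(mask)
        sink[4] = True
        with pytest.raises(ValueError, match="component"):
            solve_laplace(mask, source, sink)

    def test_phantom_fields_match_analytic(self, curved_phantom, curved_coords):
        core = offrim_mask(curved_phantom.mask)
        for ax in ("AP", "PD", "IO"):
            err = np.abs(curved_coords.psi[ax][core]
                         - curved_phantom.coords[ax][core])
            assert err.max() < 0.02, ax


class TestGradientField:
    def test_affine_field_constant_gradient(self):
        mask = np.ones((8, 8, 8), bool)
        x = np.arange(8)[:, None, None] * 1.0
        psi = np.broadcast_to(x / 7.0, (8, 8, 8)).copy()
        grad, degen = gradient_field(psi, mask, voxel_mm=2.0)
        inner = grad[1:-1, 1:-1, 1:-1]
        assert np.allclose(inner[..., 0], 1 / 14.0, atol=1e-12)
        assert np.allclose(inner[..., 1:], 0.0)
        assert not degen.any()

    def test_phantom_gradients_within_2_degrees_of_analytic(
            self, curved_phantom):
        """Numerical gradients of the analytic coordinate volumes match the
        closed-form direction fields away from the mask edges."""
        ph = curved_phantom
        grad, _ = gradient_field(ph.coords["AP"], ph.mask, ph.voxel_mm)
        cx, cy = ph.geometry["center_xy"]
        core = offrim_mask(ph.mask)
        idx = np.argwhere(core)
        g = grad[core]
        g = g / np.linalg.norm(g, axis=1, keepdims=True)
        x = idx[:, 0] * ph.voxel_mm - cx
        y = idx[:, 1] * ph.voxel_mm - cy
        phi_hat = np.stack([-y, x, np.zeros(len(x))], axis=1)
        phi_hat /= np.linalg.norm(phi_hat, axis=1, keepdims=True)
        angles = np.degrees(np.arccos(np.clip(np.abs(np.sum(g * phi_hat, 1)),
                                              -1, 1)))
        assert np.percentile(angles, 99) < 2.0

    def test_constant_field_degenerate(self):
        mask = np.ones((5, 5, 5), bool)
        grad, degen = gradient_field(np.full((5, 5, 5), 0.3), mask, 1.0)
        assert degen.all()
        assert np.all(grad[mask] == 0)


class TestCosineSimilarity:
    def test_parallel_orthogonal_antiparallel(self):
        a = np.zeros((3, 1, 1, 3))
        a[..., 0] = 2.0  # x, arbitrary magnitude
        b = np.zeros((3, 1, 1, 3))
        b[0, ..., 0] = 1.0    # parallel
        b[1, ..., 1] = 3.0    # orthogonal
        b[2, ..., 0] = -0.5   # antiparallel
        sim = cosine_similarity(a, b)
        assert sim[0, 0, 0] == pytest.approx(1.0)
        assert sim[1, 0, 0] == pytest.approx(0.0)
        assert sim[2, 0, 0] == pytest.approx(1.0)

    def test_degenerate_vector_nan(self):
        a = np.zeros((1, 1, 1, 3))
        b = np.ones((1, 1, 1, 3))
        assert np.isnan(cosine_similarity(a, b)[0, 0, 0])

    def test_orientation_maps_on_phantom(self, curved_phantom, curved_coords):
        """Peaks aligned with the long axis give long-axis similarity near 1
        and radial similarity near 0."""
        grad, _ = curved_coords.gradient("AP")
        with np.errstate(invalid="ignore"):
            peaks = grad / np.linalg.norm(grad, axis=-1, keepdims=True)
        omaps = orientation_maps(curved_coords, peaks)
        core = offrim_mask(curved_phantom.mask)
        assert np.nanmedian(omaps.long_axis[core]) >= 0.98
        assert np.nanmedian(omaps.radial[core]) <= 0.1
        for channel in (omaps.long_axis, omaps.tangential, omaps.radial):
            vals = channel[np.isfinite(channel)]
            assert np.all((vals >= 0) & (vals <= 1))


class TestSurfaces:
    def test_straight_slab_midthickness_is_midplane(self, straight_phantom,
                                                    straight_coords):
        tmpl = build_template_mesh(n_ap=24, n_pd=12, n_apex=0)
        mid = midthickness_surface(straight_coords, tmpl)
        ok = np.all(np.isfinite(mid.vertices), axis=1)
        assert ok.sum() > 0.5 * tmpl.n_vertices
        y0, thick = 1.5, straight_phantom.geometry["thickness_mm"]
        y_mid = y0 + thick / 2.0
        assert np.nanmax(np.abs(mid.vertices[ok, 1] - y_mid)) \
            < 0.5 * straight_phantom.voxel_mm

    def test_curved_vertices_near_half_io(self, curved_coords, small_mesh):
        mid = midthickness_surface(curved_coords, small_mesh)
        io = sample_to_surface(curved_coords.psi["IO"], mid,
                               curved_coords.voxel_mm, method="trilinear")
        io = io[np.isfinite(io)]
        assert io.size > 0
        assert np.all((io > 0.45) & (io < 0.55))

    def test_standard_template_vertex_count_preserved(self, curved_coords):
        tmpl = build_template_mesh()
        assert tmpl.n_vertices == 7262
        mid = midthickness_surface(curved_coords, tmpl)
        assert mid.n_vertices == 7262


class TestSampleToSurface:
    def test_constant_volume(self, small_mesh):
        surf = small_mesh.with_vertices(
            np.column_stack([small_mesh.unfolded * 5.0,
                             np.ones(small_mesh.n_vertices)]))
        vol = np.full((10, 10, 10), 3.14)
        vals = sample_to_surface(vol, surf, voxel_mm=1.0)
        assert np.allclose(vals[np.isfinite(vals)], 3.14)

    def test_linear_ramp_enclosing_matches_voxel_lookup(self):
        rng = np.random.default_rng(0)
        vol = np.arange(1000.0).reshape(10, 10, 10)
        pts = rng.uniform(0.6, 8.4, size=(50, 3))
        mesh = build_template_mesh(n_ap=10, n_pd=5, n_apex=0)
        surf = mesh.with_vertices(np.vstack([pts,
                                             np.zeros((mesh.n_vertices - 50, 3))]))
        vals = sample_to_surface(vol, surf, voxel_mm=1.0)[:50]
        expect = vol[tuple(np.round(pts).astype(int).T)]
        assert np.array_equal(vals, expect)

    def test_face_tie_goes_to_lower_voxel(self):
        vol = np.arange(27.0).reshape(3, 3, 3)
        mesh = build_template_mesh(n_ap=2, n_pd=2, n_apex=0)
        verts = np.zeros((4, 3))
        verts[0] = [0.5, 1.0, 1.0]  # exactly on the face between voxels 0 and 1
        surf = mesh.with_vertices(verts)
        vals = sample_to_surface(vol, surf, voxel_mm=1.0)
        assert vals[0] == vol[0, 1, 1]

    def test_outside_volume_missing(self):
        vol = np.zeros((3, 3, 3))
        mesh = build_template_mesh(n_ap=2, n_pd=2, n_apex=0)
        surf = mesh.with_vertices(np.full((4, 3), 99.0))
        assert np.all(np.isnan(sample_to_surface(vol, surf, 1.0)))


class TestParcelAverage:
    def test_constant_surface(self):
        labels = np.array([0, 0, 1, 1, 2])
        out = parcel_average(np.full(5, 2.5), labels)
        assert np.allclose(out, 2.5)

    def test_indicator(self):
        labels = np.array([0, 0, 1, 1, 2])
        out = parcel_average((labels == 1).astype(float), labels)
        assert np.allclose(out, [0, 1, 0])

    def test_hand_computed_means_on_toy_mesh(self):
        values = np.arange(10.0)
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2])
        out = parcel_average(values, labels)
        assert np.allclose(out, [1.0, 4.5, 8.0])

    def test_vertex_order_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=20)
        labels = rng.integers(0, 3, 20)
        perm = rng.permutation(20)
        a = parcel_average(values, labels, 3)
        b = parcel_average(values[perm], labels[perm], 3)
        assert np.allclose(a, b)

    def test_empty_parcel_warns_nan(self):
        with pytest.warns(UserWarning, match="parcel"):
            out = parcel_average(np.ones(4), np.zeros(4, int), n_parcels=2)
        assert np.isnan(out[1])

    def test_nan_values_excluded(self):
        values = np.array([1.0, np.nan, 3.0])
        out = parcel_average(values, np.zeros(3, int), 1)
        assert out[0] == pytest.approx(2.0)


class TestMacrostructure:
    def test_straight_slab_thickness(self, straight_phantom, straight_coords):
        tmpl = build_template_mesh(n_ap=24, n_pd=12, n_apex=0)
        mac = macrostructure(straight_coords, tmpl)
        thick = mac["thickness_mm"]
        want = straight_phantom.geometry["thickness_mm"]
        assert abs(np.nanmedian(thick) - want) < 0.5 * straight_phantom.voxel_mm

    def test_subfield_volume_is_voxel_count_arithmetic(self, curved_phantom,
                                                       curved_coords):
        from hippodev.mesh import SUBFIELD_PD_EDGES, SUBFIELD_NAMES

        tmpl = build_template_mesh(n_ap=24, n_pd=12, n_apex=0)
        mac = macrostructure(curved_coords, tmpl)
        pd_vals = curved_coords.psi["PD"][curved_phantom.mask]
        for i, name in enumerate(SUBFIELD_NAMES):
            lo, hi = SUBFIELD_PD_EDGES[i], SUBFIELD_PD_EDGES[i + 1]
            count = int(np.sum((pd_vals >= lo) & (pd_vals < hi)))
            assert mac["volume_mm3"][name] == pytest.approx(
                count * curved_phantom.voxel_mm**3)

    def test_scaling_law(self, curved_coords):
        """Scaling the geometry by s scales volume by s^3, thickness by s
        and gyrification by s^2."""
        tmpl = build_template_mesh(n_ap=24, n_pd=12, n_apex=0)
        mac1 = macrostructure(curved_coords, tmpl)
        s = 1.5
        scaled = CoordinateField(psi=curved_coords.psi, mask=curved_coords.mask,
                                 voxel_mm=curved_coords.voxel_mm * s)
        mac2 = macrostructure(scaled, tmpl)
        for name in mac1["volume_mm3"]:
            assert mac2["volume_mm3"][name] == pytest.approx(
                mac1["volume_mm3"][name] * s**3)
        assert np.nanmedian(mac2["thickness_mm"]) == pytest.approx(
            np.nanmedian(mac1["thickness_mm"]) * s, rel=1e-6)
        assert np.nanmedian(mac2["gyrification"]) == pytest.approx(
            np.nanmedian(mac1["gyrification"]) * s**2, rel=1e-6)
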