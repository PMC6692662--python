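"""Finite-volume current-flow solver: analytic oracles and physics laws."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import eval_legendre

from peristim import reference
from peristim.dosimetry import SafetyLimit
from peristim.phantom import (CurrentSourceSpec, SurfacePatch,
                              TissueLabelVolume, boundary_faces)
from peristim.volume_conductor import (ConvergenceError, SingularSystemError,
                                       assemble_system, field_maps,
                                       margin_report, plane_current,
                                       solve_potential, summarize_fields)
from conftest import face_patch, uniform_box

CURRENT = 1e-3  # A
TABLE1 = {"air": 1e-7, "tissue": 1.0}


def solve_box(volume, table, source, rtol=1e-10):
    system = assemble_system(volume, table, source)
    solution = solve_potential(system, rtol=rtol)
    return system, solution


class TestAssembly:
    def test_interior_operator_conserves_current(self):
        """Without the Dirichlet gauge the operator annihilates constants:
        every row of the pure-Neumann system sums to zero."""
        volume = uniform_box((8, 6, 6))
        source = CurrentSourceSpec((face_patch(volume, 0, -1),),
                                   face_patch(volume, 0, +1), CURRENT)
        system = assemble_system(volume, TABLE1, source, apply_dirichlet=False)
        row_sums = np.asarray(system.matrix.sum(axis=1)).ravel()
        assert np.abs(row_sums).max() < 1e-12

    def test_disconnected_domain_raises(self):
        labels = np.zeros((11, 4, 4), dtype=np.int16)
        labels[:4] = 1   # blob with the active patch
        labels[7:] = 1   # blob with the return patch, separated by air
        volume = TissueLabelVolume(labels, (2.0,) * 3, (0.0,) * 3,
                                   {0: "air", 1: "tissue"})
        faces = boundary_faces(volume)
        active = faces[(faces[:, 3] == 0) & (faces[:, 4] == -1)
                       & (faces[:, 0] == 0)]
        ret = faces[(faces[:, 3] == 0) & (faces[:, 4] == +1)
                    & (faces[:, 0] == 10)]
        source = CurrentSourceSpec((SurfacePatch(active, 1.0),),
                                   SurfacePatch(ret, 1.0), CURRENT)
        with pytest.raises(SingularSystemError):
            assemble_system(volume, TABLE1, source)


@pytest.fixture(scope="module")
def ramp():
    volume = uniform_box((20, 10, 10), spacing=2.0)
    source = CurrentSourceSpec((face_patch(volume, 0, -1),),
                               face_patch(volume, 0, +1), CURRENT)
    system, solution = solve_box(volume, TABLE1, source)
    return volume, source, system, solution


class TestUniformConductor:
    def test_potential_is_linear_ramp(self, ramp):
        volume, _, _, solution = ramp
        V = solution.potential
        # constant over each cross-section, linear along the axis
        assert np.nanmax(np.abs(V - V[:, :1, :1])) < 1e-9 * np.nanmax(np.abs(V))
        profile = V[:, 0, 0]
        steps = np.diff(profile)
        assert np.allclose(steps, steps[0], rtol=1e-6)

    def test_current_density_is_injected_current_over_area(self, ramp):
        volume, source, _, solution = ramp
        fields = field_maps(solution, volume, TABLE1)
        area = 10 * 10 * (2e-3) ** 2
        expected = source.total_current / area
        j = fields.j_magnitude[volume.tissue_mask]
        assert np.abs(j / expected - 1).max() < 0.01

    def test_midplane_flux_equals_injected_current(self, ramp):
        _, source, system, solution = ramp
        flux = plane_current(system, solution.potential, axis=0, index=10)
        assert flux == pytest.approx(source.total_current, rel=1e-6)

    def test_conductivity_scaling_law(self, ramp):
        """σ → 10σ leaves J unchanged and divides V and E by 10."""
        volume, source, _, solution = ramp
        scaled_table = {"air": 1e-7, "tissue": 10.0}
        _, sol10 = solve_box(volume, scaled_table, source)
        mask = volume.tissue_mask
        assert np.allclose(sol10.potential[mask] * 10,
                           solution.potential[mask], rtol=1e-6, atol=1e-12)
        f1 = field_maps(solution, volume, TABLE1)
        f10 = field_maps(sol10, volume, scaled_table)
        assert np.allclose(f10.j_magnitude[mask], f1.j_magnitude[mask],
                           rtol=1e-6)
        assert np.allclose(f10.e_magnitude[mask] * 10, f1.e_magnitude[mask],
                           rtol=1e-6)

    def test_linearity_in_injected_current(self, ramp):
        volume, source, _, solution = ramp
        _, sol2 = solve_box(volume, TABLE1, source.scaled(2 * CURRENT))
        mask = volume.tissue_mask
        assert np.allclose(sol2.potential[mask],
                           2 * solution.potential[mask], rtol=1e-6,
                           atol=1e-12)

    def test_reciprocity_under_electrode_swap(self):
        """Swapping source and return reverses the current flow: for this
        mirror-symmetric montage the swapped potential is exactly the mirror
        image of the original, i.e. the negated potential expressed in the
        frame of the new source (up to the Dirichlet reference)."""
        volume = uniform_box((16, 9, 9), spacing=2.0)
        faces = boundary_faces(volume)

        def centered_patch(side):
            sel = (faces[:, 3] == 0) & (faces[:, 4] == side)
            sub = faces[sel]
            keep = (np.abs(sub[:, 1] - 4) <= 1) & (np.abs(sub[:, 2] - 4) <= 1)
            return SurfacePatch(sub[keep], 1.0)

        source = CurrentSourceSpec((centered_patch(-1),), centered_patch(+1),
                                   CURRENT)
        _, sol_fwd = solve_box(volume, TABLE1, source)
        _, sol_rev = solve_box(volume, TABLE1, source.swapped())
        mask = volume.tissue_mask
        mirrored = sol_rev.potential[::-1, :, :]
        scale = np.abs(sol_fwd.potential[mask]).max()
        assert np.abs(sol_fwd.potential[mask] - mirrored[mask]).max() \
            < 1e-6 * scale
        # in the shared frame the swap negates the gauge-aligned potential
        fwd = sol_fwd.potential[mask] - sol_fwd.potential[mask].mean()
        rev = sol_rev.potential[mask] - sol_rev.potential[mask].mean()
        assert np.corrcoef(fwd, rev)[0, 1] < -0.97


def sphere_setup(radius_mm=50.0, voxel_mm=2.5):
    half = radius_mm + 2 * voxel_mm
    n = int(np.ceil(2 * half / voxel_mm))
    origin = (-half + voxel_mm / 2,) * 3
    ax = [origin[i] + voxel_mm * np.arange(n) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij", sparse=True)
    labels = ((X ** 2 + Y ** 2 + Z ** 2) <= radius_mm ** 2).astype(np.int16)
    volume = TissueLabelVolume(labels, (voxel_mm,) * 3, origin,
                               {0: "air", 1: "tissue"})
    faces = boundary_faces(volume)
    spacing = np.array(volume.spacing)
    centers = np.asarray(origin) + faces[:, :3] * spacing
    for axis in range(3):
        sel = faces[:, 3] == axis
        centers[sel, axis] += faces[sel, 4] * spacing[axis] / 2

    def pole_patch(sign):
        target = np.array([0.0, 0.0, sign * radius_mm])
        dist = np.linalg.norm(centers - target, axis=1)
        return SurfacePatch(faces[np.argsort(dist)[:5]], 1.0)

    source = CurrentSourceSpec((pole_patch(+1),), pole_patch(-1), CURRENT)
    return volume, source


def legendre_potential(points, radius_m, sigma, current, n_terms=200):
    """Analytic potential of two antipodal point electrodes on the surface of
    a homogeneous conducting sphere (Legendre series, insulated surface)."""
    r = np.linalg.norm(points, axis=1)
    cos_t = np.divide(points[:, 2], r, out=np.zeros_like(r), where=r > 0)
    x = r / radius_m
    V = np.zeros(len(points))
    for n in range(1, n_terms + 1):
        pn = eval_legendre(n, cos_t) - eval_legendre(n, -cos_t)
        V += (2 * n + 1) / n * x ** n * pn
    return current / (2 * np.pi * sigma * radius_m) * V / 2.0


@pytest.fixture(scope="module")
def solved_sphere():
    volume, source = sphere_setup(50.0, 1.25)
    system, solution = solve_box(volume, TABLE1, source, rtol=1e-8)
    return volume, source, system, solution


def sphere_oracle_error(volume, source, solution):
    """Gauge-aligned deviation from the analytic series in the interior
    away from the electrodes (r ≤ 0.8 R, > 15 mm from either pole)."""
    X, Y, Z = volume.voxel_centers()
    pts_mm = np.stack(np.broadcast_arrays(X, Y, Z), axis=-1)
    r = np.linalg.norm(pts_mm, axis=-1)
    d_src = np.linalg.norm(pts_mm - np.array([0.0, 0.0, 50.0]), axis=-1)
    d_ret = np.linalg.norm(pts_mm - np.array([0.0, 0.0, -50.0]), axis=-1)
    mask = volume.tissue_mask & (r <= 40.0) & (d_src > 15) & (d_ret > 15)
    pts = pts_mm[mask] * 1e-3
    num = solution.potential[mask]
    ana = legendre_potential(pts, 50e-3, 1.0, source.total_current)
    num = num - num.mean()
    ana = ana - ana.mean()
    rel_l2 = np.linalg.norm(num - ana) / np.linalg.norm(ana)
    rel_max = np.abs(num - ana).max() / np.abs(ana).max()
    return rel_l2, rel_max


class TestSphereOracle:
    def test_matches_legendre_series(self, solved_sphere):
        """Numeric potential within 2% (relative L2) of the analytic series
        away from the electrodes; pointwise deviation bounded by the O(h)
        staircase-boundary error."""
        volume, source, _, solution = solved_sphere
        rel_l2, rel_max = sphere_oracle_error(volume, source, solution)
        assert rel_l2 < 0.02
        assert rel_max < 0.05

    def test_oracle_error_shrinks_with_resolution(self, solved_sphere):
        """The deviation from the analytic series is discretization error:
        it decreases when the sphere is voxelized more finely."""
        volume, source, _, solution = solved_sphere
        fine_l2, _ = sphere_oracle_error(volume, source, solution)
        coarse_vol, coarse_src = sphere_setup(50.0, 2.5)
        _, coarse_sol = solve_box(coarse_vol, TABLE1, coarse_src, rtol=1e-8)
        coarse_l2, _ = sphere_oracle_error(coarse_vol, coarse_src, coarse_sol)
        assert fine_l2 < coarse_l2

    def test_tolerance_refinement_consistency(self, solved_sphere):
        volume, source, _, tight = solved_sphere
        _, loose = solve_box(volume, TABLE1, source, rtol=1e-3)
        mask = volume.tissue_mask
        scale = np.abs(tight.potential[mask]).max()
        diff = np.abs(loose.potential[mask] - tight.potential[mask]).max()
        assert diff / scale < 1e-2

    def test_convergence_error_reports_residual(self, solved_sphere):
        volume, source, _, _ = solved_sphere
        system = assemble_system(volume, TABLE1, source)
        with pytest.raises(ConvergenceError, match="residual"):
            solve_potential(system, rtol=1e-12, maxiter=3)


def layered_slab_oracle(neumann_system, source):
    """Series-resistance closed form: walking from the grounded end, each
    cell-to-cell potential step is I divided by the face conductance (read
    off the pure-Neumann operator, where no entry has been eliminated)."""
    A = neumann_system.matrix
    n = A.shape[0]
    V = np.zeros(n)
    for k in range(n - 2, -1, -1):
        g = -A[k, k + 1]
        assert g > 0
        V[k] = V[k + 1] + source.total_current / g
    return V


class TestLayeredSlab:
    def test_interface_matches_resistive_divider(self):
        """A two-conductivity column reproduces the series-resistance
        (resistive divider) potential profile to 0.1%."""
        labels = np.ones((40, 1, 1), dtype=np.int16)
        labels[20:] = 2
        volume = TissueLabelVolume(labels, (2.0,) * 3, (0.0,) * 3,
                                   {0: "air", 1: "layer1", 2: "layer2"})
        table = {"air": 1e-7, "layer1": 1.0, "layer2": 0.2}
        source = CurrentSourceSpec((face_patch(volume, 0, -1),),
                                   face_patch(volume, 0, +1), CURRENT)
        system = assemble_system(volume, table, source)
        solution = solve_potential(system, rtol=1e-12)
        neumann = assemble_system(volume, table, source, apply_dirichlet=False)
        expected = layered_slab_oracle(neumann, source)
        got = solution.potential[volume.tissue_mask]
        assert np.abs(got - expected).max() <= 1e-3 * np.abs(expected).max()
        # the drop across the resistive layer is 5x the drop across the
        # conductive one (σ ratio), measured between matching cell spans
        drop1 = got[0] - got[10]
        drop2 = got[25] - got[35]
        assert drop2 / drop1 == pytest.approx(5.0, rel=1e-6)


class TestDefaultPhantomSolution:
    def test_global_current_conservation(self, head_2mm):
        """Injected and returned current agree within 0.1% across any plane
        between the electrodes."""
        for index in (20, head_2mm.volume.labels.shape[1] // 2, 60):
            flux = plane_current(head_2mm.system, head_2mm.solution.potential,
                                 axis=1, index=index)
            assert abs(abs(flux) - head_2mm.source.total_current) \
                <= 1e-3 * head_2mm.source.total_current

    def test_linearity_doubling_current(self, head_2mm):
        system = assemble_system(head_2mm.volume, head_2mm.table,
                                 head_2mm.source.scaled(700e-6))
        sol2 = solve_potential(system, rtol=1e-8)
        mask = head_2mm.volume.tissue_mask
        scale = np.abs(head_2mm.solution.potential[mask]).max()
        assert np.abs(sol2.potential[mask]
                      - 2 * head_2mm.solution.potential[mask]).max() \
            < 1e-4 * scale

    def test_anterior_visual_pathway_ordering(self, head_2mm):
        """Peak current density: retina > optic nerve > cortex, the published
        qualitative ordering for this montage."""
        j = head_2mm.summary.table.query("quantity == 'current_density'")
        jmax = dict(zip(j["region"], j["max"]))
        assert jmax["retina"] > jmax["optic nerve"] > jmax["cortex"]

    def test_summary_ordering_invariants(self, head_2mm):
        t = head_2mm.summary.table
        assert (t["max"] >= t["mean"]).all()
        assert (t["max"] >= t["median"]).all()
        assert (t["max"] >= t["p99_9"]).all()
        assert (t[["max", "mean", "median"]] >= 0).all().all()

    def test_grid_convergence_on_resolved_geometry(self):
        """Halving the voxel size moves the mean |J| of a well-resolved
        region by < 5% (mid-radius band of the homogeneous sphere; thin
        phantom structures such as the 2 mm eye shell are not in the
        asymptotic regime at these resolutions)."""
        from peristim.volume_conductor import field_maps as fmaps

        means = {}
        for h in (2.5, 1.25):
            vol, src = sphere_setup(50.0, h)
            _, sol = solve_box(vol, TABLE1, src, rtol=1e-8)
            fm = fmaps(sol, vol, TABLE1)
            X, Y, Z = vol.voxel_centers()
            r = np.sqrt(np.broadcast_to(X ** 2 + Y ** 2 + Z ** 2,
                                        vol.labels.shape))
            band = vol.tissue_mask & (r > 15) & (r < 35)
            means[h] = fm.j_magnitude[band].mean()
        assert abs(means[1.25] - means[2.5]) / means[1.25] < 0.05

    def test_sigma_scaling_on_phantom(self, head_4mm):
        scaled = {k: 10 * v for k, v in head_4mm.table.items()}
        system = assemble_system(head_4mm.volume, scaled, head_4mm.source)
        sol = solve_potential(system, rtol=1e-8)
        fields = field_maps(sol, head_4mm.volume, scaled)
        mask = head_4mm.volume.tissue_mask
        assert np.allclose(fields.j_magnitude[mask],
                           head_4mm.fields.j_magnitude[mask],
                           rtol=1e-3, atol=1e-9)


class TestSummaries:
    def test_constant_field_region_collapses_statistics(self):
        volume = uniform_box((12, 8, 8))
        source = CurrentSourceSpec((face_patch(volume, 0, -1),),
                                   face_patch(volume, 0, +1), CURRENT)
        _, solution = solve_box(volume, TABLE1, source)
        fields = field_maps(solution, volume, TABLE1)
        summary = summarize_fields(fields, volume,
                                   regions={"block": ("tissue",)})
        row = summary.table.iloc[0]
        assert row["max"] == pytest.approx(row["mean"], rel=1e-6)
        assert row["max"] == pytest.approx(row["median"], rel=1e-6)

    def test_absent_region_is_flagged(self, head_4mm):
        summary = summarize_fields(head_4mm.fields, head_4mm.volume,
                                   regions={"muscle": ("muscle",)})
        assert summary.missing == ("muscle",)
        assert summary.table.empty


class TestMarginReport:
    def test_published_benchmark_margins(self):
        """Published per-region maxima against the lesion thresholds give the
        published order-of-magnitude margins."""
        limits = [SafetyLimit("lesion threshold", "current_density", 14.29,
                              "mA/cm^2"),
                  SafetyLimit("lesion threshold", "electric_field", 42.0,
                              "V/m")]
        report = margin_report(reference.published_field_summary(), limits)
        oom = {(r.region, r.metric): r.orders_of_magnitude
               for r in report.itertuples()}
        assert oom[("retina", "current_density")] == 2
        assert oom[("optic nerve", "current_density")] == 2
        assert oom[("cortex", "current_density")] == 3
        assert oom[("retina", "electric_field")] == 1
        assert report["within_limit"].all()

    def test_value_above_limit_flagged(self):
        table = pd.DataFrame([{"region": "hot spot",
                               "quantity": "electric_field", "unit": "V/m",
                               "max": 100.0, "mean": 50.0, "median": 50.0,
                               "p99_9": 99.0, "n_voxels": 10}])
        limit = SafetyLimit("lesion threshold", "electric_field", 42.0, "V/m")
        report = margin_report(table, [limit])
        assert not report.loc[0, "within_limit"]
        assert report.loc[0, "orders_of_magnitude"] == 0
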