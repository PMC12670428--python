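import numpy as np
import pytest

from cglamella import metrics as M
from cglamella import topology as topo
from cglamella.frames import CGFrame
from cglamella.synth import BilayerRecipe, gen_bilayer

from conftest import make_rod_frame


def headgroup_frame(z_planes, per_plane=10, box=(6.0, 6.0, 12.0)):
    """Lipids reduced to a single HEAD bead per molecule, at given z planes."""
    positions, types, mids, specs = [], [], [], []
    m = 0
    for z in z_planes:
        for i in range(per_plane):
            positions.append([0.5 + 0.05 * i, 0.5, z])
            types.append("HEAD")
            mids.append(m)
            specs.append("FFA_C24")
            m += 1
    return CGFrame(
        positions=np.array(positions),
        bead_types=np.array(types),
        mol_ids=np.array(mids),
        mol_species=np.array(specs),
        box=np.array(box, dtype=float),
    )


class TestAssignLeaflets:
    def test_symmetric_bilayer(self):
        frame = headgroup_frame([2.5, 7.7])
        lf = M.assign_leaflets(frame, 2)
        assert lf.n_leaflets == 2
        assert list(lf.counts()) == [10, 10]
        assert lf.leaflet_z == pytest.approx([2.5, 7.7], abs=0.01)

    def test_six_leaflet_stack_inner_subset(self):
        planes = [1.0, 4.0, 5.5, 8.5, 10.0, 13.0]
        frame = headgroup_frame(planes, box=(6, 6, 15))
        lf = M.assign_leaflets(frame, 6)
        assert lf.n_leaflets == 6
        assert lf.inner_leaflets == [1, 2, 3, 4]
        assert lf.central_pair == (2, 3)

    def test_degenerate_single_plane_errors_with_found_count(self):
        frame = headgroup_frame([5.0])
        with pytest.raises(M.LeafletError) as exc:
            M.assign_leaflets(frame, 2)
        assert exc.value.found == 1


class TestAPL:
    def test_simple_arithmetic(self):
        frame = headgroup_frame([2.0, 8.0], per_plane=250, box=(10, 10, 10))
        lf = M.assign_leaflets(frame, 2)
        per, mean = M.apl(frame, lf)
        assert per == pytest.approx([0.4, 0.4])
        assert mean == pytest.approx(0.4)

    def test_unequal_leaflets(self):
        frame = headgroup_frame([2.0], per_plane=240, box=(10, 10, 10))
        top = headgroup_frame([8.0], per_plane=260, box=(10, 10, 10))
        top.mol_ids += 240
        merged = CGFrame(
            positions=np.vstack([frame.positions, top.positions]),
            bead_types=np.concatenate([frame.bead_types, top.bead_types]),
            mol_ids=np.concatenate([frame.mol_ids, top.mol_ids]),
            mol_species=np.concatenate([frame.mol_species, top.mol_species]),
            box=frame.box,
        )
        lf = M.assign_leaflets(merged, 2)
        per, mean = M.apl(merged, lf)
        assert per == pytest.approx([100 / 240, 100 / 260])
        assert mean == pytest.approx((100 / 240 + 100 / 260) / 2)

    def test_invariant_under_doubling(self):
        f1 = headgroup_frame([2.0, 8.0], per_plane=100, box=(10, 10, 10))
        f2 = headgroup_frame([2.0, 8.0], per_plane=200, box=(20, 10, 10))
        m1 = M.apl(f1, M.assign_leaflets(f1, 2))[1]
        m2 = M.apl(f2, M.assign_leaflets(f2, 2))[1]
        assert m1 == pytest.approx(m2)


class TestNLA:
    def test_pure_cer_halves_apl(self):
        spec = topo.CompositionSpec({"CER_NP": 1}, 128, 2)
        assert round(M.nla(0.405, spec), 3) == 0.203

    def test_mixture_uses_mean_tail_factor(self, mixture_spec):
        assert round(M.nla(0.304, mixture_spec), 3) == 0.192

    def test_pure_ffa_is_identity(self):
        spec = topo.CompositionSpec({"FFA_C24": 1}, 100, 2)
        assert M.nla(0.37, spec) == pytest.approx(0.37)


class TestDensityProfileAndThickness:
    def delta_layers_frame(self, z1=2.32, z2=7.68, n=200, box=(8.0, 8.0, 10.0)):
        return headgroup_frame([z1, z2], per_plane=n, box=box)

    def test_mass_closure(self):
        frame = self.delta_layers_frame()
        prof = M.density_profile(frame, bin_width=0.1)
        assert prof.total_mass == pytest.approx(frame.bead_masses().sum(), rel=1e-3)

    def test_two_delta_layers_give_two_peaks(self):
        frame = self.delta_layers_frame()
        prof = M.density_profile(frame, bin_width=0.1)
        assert M.thickness(prof) == pytest.approx(7.68 - 2.32, abs=0.1)

    def test_thickness_invariant_under_reflection(self):
        frame = self.delta_layers_frame()
        prof = M.density_profile(frame, bin_width=0.1)
        reflected = CGFrame(
            positions=frame.positions * [1, 1, -1] + [0, 0, frame.box[2]],
            bead_types=frame.bead_types,
            mol_ids=frame.mol_ids,
            mol_species=frame.mol_species,
            box=frame.box,
        )
        prof_r = M.density_profile(reflected, bin_width=0.1)
        assert M.thickness(prof_r) == pytest.approx(M.thickness(prof), abs=1e-6)

    def test_single_peak_errors(self):
        frame = headgroup_frame([5.0], per_plane=100)
        prof = M.density_profile(frame, bin_width=0.1)
        with pytest.raises(M.MetricsError):
            M.thickness(prof)

    def test_empty_selection_errors(self):
        frame = self.delta_layers_frame()
        with pytest.raises(M.MetricsError):
            M.density_profile(frame, mask=np.zeros(frame.n_beads, dtype=bool))


class TestTilt:
    def test_z_aligned_chain_has_zero_tilt(self):
        frame = make_rod_frame([[0, 0, 1]] * 5)
        _, ang = M.tilt_angles(frame)
        assert ang == pytest.approx([0.0] * 5, abs=1e-6)

    @pytest.mark.parametrize("theta", [5.0, 15.0, 30.0])
    def test_rotated_chain_recovers_angle(self, theta):
        d = [np.sin(np.radians(theta)), 0.0, np.cos(np.radians(theta))]
        frame = make_rod_frame([d] * 4)
        _, ang = M.tilt_angles(frame)
        assert ang == pytest.approx([theta] * 4, abs=1e-6)

    def test_isotropic_rods_average_one_radian(self):
        """⟨θ⟩ = ∫θ sinθ dθ / ∫sinθ dθ over [0, π/2] = 1 rad = 57.30°."""
        rng = np.random.default_rng(5)
        v = rng.normal(size=(4000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        frame = make_rod_frame(v)
        _, ang = M.tilt_angles(frame)
        assert ang.mean() == pytest.approx(np.degrees(1.0), abs=1.0)


class TestNematicOrder:
    def test_parallel_directors(self):
        assert M.nematic_order(np.tile([0, 0, 1.0], (50, 1))) == pytest.approx(1.0)

    def test_planar_isotropic_is_quarter(self):
        """Directors uniform in x-y: Q = diag(1/4, 1/4, -1/2), S2 = 0.25."""
        phi = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        u = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
        assert M.nematic_order(u) == pytest.approx(0.25, abs=1e-6)

    def test_random_directors_near_zero(self):
        rng = np.random.default_rng(6)
        u = rng.normal(size=(10**4, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        assert M.nematic_order(u) <= 0.05

    def test_bounds_and_noise_monotonicity(self):
        rng = np.random.default_rng(7)
        base = np.tile([0, 0, 1.0], (2000, 1))
        prev = 1.1
        for noise in [0.0, 0.1, 0.3, 0.6, 1.0]:
            u = base + rng.normal(0, noise, base.shape)
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            s2 = M.nematic_order(u)
            assert -0.5 <= s2 <= 1.0
            assert s2 <= prev + 1e-9
            prev = s2

    def test_too_few_directors_error(self):
        with pytest.raises(M.MetricsError):
            M.nematic_order(np.array([[0, 0, 1.0]]))


class TestInterdigitation:
    def rect(self, z, lo, hi, level=1.0):
        d = np.where((z >= lo) & (z <= hi), level, 0.0)
        return M.DensityProfile(z, d, float(z[1] - z[0]), area=100.0)

    def test_disjoint_supports_zero(self):
        z = np.linspace(0, 10, 501)
        assert M.interdigitation(self.rect(z, 1, 3), self.rect(z, 6, 8)) == 0.0

    @pytest.mark.parametrize("w", [0.5, 1.0, 2.0])
    def test_identical_rectangles_give_width(self, w):
        z = np.linspace(0, 10, 2001)
        a = self.rect(z, 5 - w / 2, 5 + w / 2)
        lam = M.interdigitation(a, a)
        assert lam == pytest.approx(w, abs=0.01)

    def test_symmetric_in_arguments(self):
        z = np.linspace(0, 10, 1001)
        a = self.rect(z, 2, 6, level=1.0)
        b = self.rect(z, 4, 8, level=2.5)
        assert M.interdigitation(a, b) == pytest.approx(M.interdigitation(b, a))

    def test_bounded_by_overlap_support(self):
        z = np.linspace(0, 10, 1001)
        a = self.rect(z, 2, 6, level=1.0)
        b = self.rect(z, 4, 8, level=3.0)
        lam = M.interdigitation(a, b)
        assert 0.0 <= lam <= 2.0 + 0.02  # overlap support [4, 6]

    def test_grid_mismatch_errors(self):
        z1 = np.linspace(0, 10, 101)
        z2 = np.linspace(0, 10, 201)
        with pytest.raises(M.MetricsError):
            M.interdigitation(self.rect(z1, 2, 4), self.rect(z2, 2, 4))


class TestExtendedFraction:
    def gen(self, pct, seed=0):
        spec = topo.CompositionSpec({"CER_NS": 1.0}, 100, 2)
        recipe = BilayerRecipe(
            spec, apl=0.40, tilt=0.0, extended_pct=pct, noise_sigma=0.01, seed=seed
        )
        return gen_bilayer(recipe)

    @pytest.mark.parametrize("pct", [0.0, 30.0, 100.0])
    def test_constructed_fraction_recovered_exactly(self, registry, pct):
        frame, _ = self.gen(pct)
        assert M.extended_fraction(frame, registry) == pytest.approx(pct)

    def test_non_cer_selection_errors(self, registry):
        frame = make_rod_frame([[0, 0, 1]] * 3)  # FFA molecules
        with pytest.raises(M.MetricsError, match="not a ceramide"):
            M.extended_fraction(frame, registry, subset_ids=np.array([0]))


class TestWaterPerLipid:
    def frame_with_water(self, z_values):
        positions = [[1, 1, z] for z in z_values]
        n = len(z_values)
        return CGFrame(
            positions=np.array(positions, dtype=float).reshape(n, 3),
            bead_types=np.array(["W"] * n),
            mol_ids=np.arange(n),
            mol_species=np.array(["WATER"] * n),
            box=np.array([5.0, 5.0, 10.0]),
        )

    def test_ninety_beads_over_720_lipids(self):
        frame = self.frame_with_water(np.linspace(4.0, 6.0, 90))
        assert M.water_per_lipid(frame, 3.0, 7.0, 720) == pytest.approx(0.5)

    def test_no_water_inside_region(self):
        frame = self.frame_with_water([1.0, 9.0])
        assert M.water_per_lipid(frame, 3.0, 7.0, 100) == 0.0

    def test_undefined_region_errors(self):
        frame = self.frame_with_water([5.0])
        with pytest.raises(M.MetricsError):
            M.water_per_lipid(frame, 7.0, 3.0, 100)


class TestAggregate:
    def rec(self, **kw):
        base = {k: np.nan for k in M._SCALAR_METRICS}
        base.update(kw)
        return base

    def test_identical_frames_zero_spread(self):
        records = [self.rec(apl=0.40, thickness=5.3)] * 4
        rep = M.aggregate(records, replicates=[0, 0, 1, 1])
        assert rep.mean["apl"] == pytest.approx(0.40)
        assert rep.sd["apl"] == pytest.approx(0.0)

    def test_two_replicates_two_point_sd(self):
        records = [self.rec(apl=0.42), self.rec(apl=0.44)]
        rep = M.aggregate(records, replicates=[0, 1])
        assert rep.mean["apl"] == pytest.approx(0.43)
        assert rep.sd["apl"] == pytest.approx(0.014142, abs=1e-5)

    def test_single_replicate_reports_absent_sd(self):
        rep = M.aggregate([self.rec(apl=0.42), self.rec(apl=0.44)])
        assert rep.mean["apl"] == pytest.approx(0.43)
        assert rep.sd["apl"] is None

    def test_frame_order_irrelevant(self):
        a = [self.rec(apl=0.41), self.rec(apl=0.43), self.rec(apl=0.45)]
        r1 = M.aggregate(a, replicates=[0, 1, 1])
        r2 = M.aggregate([a[2], a[0], a[1]], replicates=[1, 0, 1])
        assert r1.mean["apl"] == pytest.approx(r2.mean["apl"])
        assert r1.sd["apl"] == pytest.approx(r2.sd["apl"])

    def test_tilt_sd_is_pooled_per_molecule_variance(self):
        records = [
            self.rec(tilt_mean=10.0, tilt_groups=[(5, 10.0, 4.0), (5, 10.0, 4.0)]),
            self.rec(tilt_mean=12.0, tilt_groups=[(5, 12.0, 9.0)]),
        ]
        rep = M.aggregate(records, replicates=[0, 1])
        pooled = np.sqrt((4 * 4.0 + 4 * 4.0 + 4 * 9.0) / 12.0)
        assert rep.tilt_sd_pooled == pytest.approx(pooled)
        assert rep.sd["tilt_mean"] == pytest.approx(pooled)
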