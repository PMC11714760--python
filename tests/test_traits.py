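"""Morphometric traits: analytic limits, dimensional traits, derived ratios."""

from dataclasses import replace

import numpy as np
import pytest

from grainmri.errors import StateError, ValidationError
from grainmri.alignment import align_instance
from grainmri.instances import SeedInstance, separate_instances
from grainmri.phantom import NoiseSpec, PhantomSpec, generate_phantom, render_intensity
from grainmri.traits import (build_trait_table, compute_aligned_traits, compute_derived_traits,
                             compute_static_traits, compute_traits)

R = 0.04


def _inst_from_labels(data, aligned=False):
    inst = SeedInstance(instance_id=1, source_id="t", labels=np.asarray(data, np.uint8),
                        intensity=np.zeros(np.asarray(data).shape, np.float32),
                        offset=(0, 0, 0), voxel_size=R)
    return replace(inst, aligned=aligned)


@pytest.fixture(scope="module")
def cube_inst():
    data = np.zeros((16, 16, 16), dtype=np.uint8)
    data[3:13, 3:13, 3:13] = 2
    return _inst_from_labels(data, aligned=True)


@pytest.fixture(scope="module")
def sphere_inst(request):
    spec = PhantomSpec(semi_axes=(20, 20, 20), exponent=2, pericarp_thickness=0,
                       aleurone_thickness=0, embryo_fraction=0, crease_depth=0)
    labels, _ = generate_phantom(spec, (48, 48, 48))
    return _inst_from_labels(labels.data, aligned=True)


class TestStaticTraits:
    def test_cube_volume_is_exact_voxel_count_times_r3(self, cube_inst):
        rec = compute_static_traits(cube_inst)
        assert rec["Vm"] == pytest.approx(1000 * R ** 3)
        assert rec["Ven"] == pytest.approx(1000 * R ** 3)

    def test_cube_is_its_own_convex_hull(self, cube_inst):
        rec = compute_static_traits(cube_inst)
        assert rec["Tm"] == pytest.approx(1.0)

    def test_cube_sphericity_bounded_by_closed_form_and_sphere_limit(self, cube_inst):
        # anti-staircase smoothing rounds the cube's sharp edges, so the
        # measured area is below 6a^2 and Sm lies above the closed form
        # (pi/6)^(1/3) ~ 0.806 but below the sphere limit 1
        rec = compute_static_traits(cube_inst)
        assert (np.pi / 6) ** (1 / 3) < rec["Sm"] < 1.0

    def test_sphere_sphericity_and_solidity_near_one(self, sphere_inst):
        rec = compute_static_traits(sphere_inst)
        assert rec["Sm"] == pytest.approx(1.0, rel=0.02)
        assert rec["Tm"] == pytest.approx(1.0, rel=0.03)

    def test_sphere_mesh_area_matches_analytic_within_3pct(self, sphere_inst):
        rec = compute_static_traits(sphere_inst)
        assert rec["Am"] == pytest.approx(4 * np.pi * (20 * R) ** 2, rel=0.03)

    def test_sphericity_scale_invariant_within_2pct(self):
        recs = []
        for radius in (10, 20):
            spec = PhantomSpec(semi_axes=(radius,) * 3, exponent=2, pericarp_thickness=0,
                               aleurone_thickness=0, embryo_fraction=0, crease_depth=0)
            labels, _ = generate_phantom(spec, (2 * radius + 8,) * 3)
            recs.append(compute_static_traits(_inst_from_labels(labels.data)))
        assert recs[0]["Sm"] == pytest.approx(recs[1]["Sm"], rel=0.02)
        assert recs[1]["Vm"] == pytest.approx(8 * recs[0]["Vm"], rel=0.05)
        assert recs[1]["Am"] == pytest.approx(4 * recs[0]["Am"], rel=0.05)

    def test_groove_decreases_solidity(self):
        flat, _ = generate_phantom(PhantomSpec(crease_depth=0))
        carved, _ = generate_phantom(PhantomSpec(crease_depth=8))
        t_flat = compute_static_traits(_inst_from_labels(flat.data))["Tm"]
        t_carved = compute_static_traits(_inst_from_labels(carved.data))["Tm"]
        assert t_carved < t_flat

    def test_empty_embryo_yields_nan_embryo_traits(self, sphere_inst):
        rec = compute_static_traits(sphere_inst)
        assert np.isnan(rec["Se"]) and np.isnan(rec["Te"]) and np.isnan(rec["Ae"])

    def test_empty_monolith_raises(self):
        with pytest.raises(ValidationError):
            compute_static_traits(_inst_from_labels(np.zeros((4, 4, 4))))


class TestAlignedTraits:
    def test_ellipsoid_dimensions_within_one_voxel(self):
        spec = PhantomSpec(semi_axes=(50, 20, 10), exponent=2, pericarp_thickness=0,
                           aleurone_thickness=0, embryo_fraction=0.2, crease_depth=0)
        labels, truth = generate_phantom(spec, (112, 72, 72))
        rec = compute_aligned_traits(_inst_from_labels(labels.data, aligned=True))
        for name, dim in zip(("Lm", "Wm", "Dm"), truth.dimensions):
            assert rec[name] == pytest.approx(dim * R, abs=R)
        assert rec["Lm"] == pytest.approx(4.0, abs=2 * R)

    def test_convex_phantom_has_zero_crease(self):
        spec = PhantomSpec(crease_depth=0)
        labels, _ = generate_phantom(spec)
        rec = compute_aligned_traits(_inst_from_labels(labels.data, aligned=True))
        assert rec["Dc"] == 0.0

    def test_groove_depth_recovered_within_one_voxel(self):
        spec = PhantomSpec(crease_depth=8)
        labels, truth = generate_phantom(spec)
        rec = compute_aligned_traits(_inst_from_labels(labels.data, aligned=True))
        assert rec["Dc"] == pytest.approx(truth.crease_depth * R, abs=R)
        assert rec["Dc"] > 0.15  # a deep groove, on the order of 8 voxels * 0.04 mm

    def test_unaligned_instance_raises_state_error(self, default_phantom):
        labels, _ = default_phantom
        with pytest.raises(StateError):
            compute_aligned_traits(_inst_from_labels(labels.data, aligned=False))


class TestDerivedTraits:
    BASE = {"Vm": 10.0, "Ve": 1.5, "Ven": 10.0, "Va": 0.8, "Lm": 4.0, "Wm": 2.0}

    def test_sef_from_starch_and_endosperm(self):
        rec = compute_derived_traits({**self.BASE, "Ven": 10.0}, {"Gs": 60.0, "Gl": 3.0})
        assert rec["SEF"] == pytest.approx(600.0)

    def test_lef_from_lipid_and_embryo_plus_aleurone(self):
        rec = compute_derived_traits(self.BASE, {"Gs": 60.0, "Gl": 3.0})
        assert rec["LEF"] == pytest.approx(3.0 * (1.5 + 0.8))

    def test_fractions_partition_to_unity_with_pericarp(self, default_phantom):
        labels, truth = default_phantom
        inst = _inst_from_labels(labels.data, aligned=True)
        rec = compute_traits(inst)
        v_pericarp = truth.class_counts[4] * R ** 3
        assert rec["Ra"] + rec["Re"] + rec["Ren"] + v_pericarp / rec["Vm"] == pytest.approx(1.0)

    def test_missing_composition_leaves_sef_lef_nan(self):
        rec = compute_derived_traits(self.BASE, None)
        assert np.isnan(rec["SEF"]) and np.isnan(rec["LEF"])


class TestTraitTable:
    def test_one_row_per_instance_with_composition_join(self, default_phantom, clean_image):
        import pandas as pd
        labels, _ = default_phantom
        inst = separate_instances(labels, clean_image, instance_shape=(96, 64, 64))[0]
        aligned = align_instance(inst)
        comp = pd.DataFrame([{"sample_id": "phantom", "Gs": 60.0, "Gm": 10.0,
                              "Gp": 12.0, "Gl": 3.0, "Area": 15.0,
                              "Length": 6.0, "Width": 3.0}])
        table = build_trait_table([aligned], comp)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["SEF"] == pytest.approx(60.0 * row["Ven"])
        assert row["Gs"] == 60.0

    def test_without_composition_sef_lef_empty(self, default_phantom, clean_image):
        labels, _ = default_phantom
        inst = separate_instances(labels, clean_image, instance_shape=(96, 64, 64))[0]
        table = build_trait_table([align_instance(inst)])
        assert table["SEF"].isna().all() and table["LEF"].isna().all()

    def test_duplicate_instance_ids_rejected(self, default_phantom, clean_image):
        labels, _ = default_phantom
        inst = separate_instances(labels, clean_image, instance_shape=(96, 64, 64))[0]
        aligned = align_instance(inst)
        with pytest.raises(ValidationError, match="duplicate"):
            build_trait_table([aligned, aligned])
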