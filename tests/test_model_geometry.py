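import json

import numpy as np
import pytest

from clemquant.errors import FormatError, GeometryError, ValidationError
from clemquant.model_geometry import (
    CompartmentClass,
    ContourModel,
    ContourObject,
    compute_domain_measure,
    project_outlines,
    read_contour_model,
    write_contour_model,
)

from conftest import circle_contour, sphere_model

IDENTITY = np.eye(3)


class TestReader:
    def test_json_round_trip(self, tmp_path, simple_three_class_model):
        path = tmp_path / "model.json"
        write_contour_model(simple_three_class_model, path)
        restored = read_contour_model(path, dialect="json")
        assert restored.endosome_id == simple_three_class_model.endosome_id
        assert restored.z_step == simple_three_class_model.z_step
        assert len(restored.objects) == len(simple_three_class_model.objects)
        for a, b in zip(restored.objects, simple_three_class_model.objects):
            assert a.label is b.label
            assert a.capped == b.capped
            for ca, cb in zip(a.contours, b.contours):
                np.testing.assert_allclose(ca, cb)

    def test_class_census(self, tmp_path, simple_three_class_model):
        path = tmp_path / "model.json"
        write_contour_model(simple_three_class_model, path)
        model = read_contour_model(path)
        census = {c: len(model.objects_of(c)) for c in CompartmentClass}
        assert census == {
            CompartmentClass.BM: 1, CompartmentClass.ILV: 1, CompartmentClass.RT: 1,
        }

    def test_cross_dialect_equality(self, tmp_path, simple_three_class_model):
        json_path = tmp_path / "model.json"
        write_contour_model(simple_three_class_model, json_path)
        txt_path = tmp_path / "model.txt"
        class_map = {}
        with open(txt_path, "w") as fh:
            for i_obj, obj in enumerate(simple_three_class_model.objects, start=1):
                class_map[i_obj] = obj.label.value
                for i_ct, contour in enumerate(obj.contours, start=1):
                    for x, y, z in contour:
                        fh.write(f"{i_obj} {i_ct} {x:.6f} {y:.6f} {z:.6f}\n")
        from_json = read_contour_model(json_path)
        from_txt = read_contour_model(
            txt_path, dialect="imod_points", class_map=class_map,
            z_step=simple_three_class_model.z_step,
        )
        assert [o.label for o in from_txt.objects] == [o.label for o in from_json.objects]
        for a, b in zip(from_txt.objects, from_json.objects):
            for ca, cb in zip(a.contours, b.contours):
                np.testing.assert_allclose(ca, cb, atol=1e-5)

    def test_two_point_contour_rejected(self, tmp_path):
        payload = {
            "endosome_id": "bad", "z_step_nm": 10.0,
            "objects": [{"class": "BM", "contours": [[[0, 0, 0], [1, 1, 0]]]}],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValidationError, match="need >= 3"):
            read_contour_model(path)

    def test_unknown_class_rejected(self, tmp_path):
        payload = {
            "endosome_id": "bad", "z_step_nm": 10.0,
            "objects": [{"class": "XX", "contours": [[[0, 0, 0], [1, 0, 0], [0, 1, 0]]]}],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValidationError, match="unknown compartment class"):
            read_contour_model(path)

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "broken.txt"
        path.write_text("1 1 0 0 0\n1 1 not-a-number 0\n")
        with pytest.raises(FormatError, match=":2"):
            read_contour_model(path, dialect="imod_points", class_map={1: "BM"})

    def test_missing_file(self):
        with pytest.raises(FormatError, match="no such file"):
            read_contour_model("does-not-exist.json")

    def test_imod_points_requires_class_map(self, tmp_path):
        path = tmp_path / "pts.txt"
        path.write_text("1 1 0 0 0\n")
        with pytest.raises(ValidationError, match="class_map"):
            read_contour_model(path, dialect="imod_points")

    def test_analysable_requires_all_classes(self):
        model = ContourModel(
            endosome_id="only-bm", z_step=10.0,
            objects=[ContourObject(CompartmentClass.BM, [circle_contour(50, 0)])],
        )
        with pytest.raises(ValidationError, match="missing classes"):
            model.validate(require_all_classes=True)


class TestMeasure:
    def test_circle_perimeter_2d(self):
        model = ContourModel(
            endosome_id="circle", z_step=1.0,
            objects=[ContourObject(CompartmentClass.BM, [circle_contour(100.0, 0.0, n=360)])],
        )
        measure = compute_domain_measure(model, mode="length2d")
        assert measure[CompartmentClass.BM] == pytest.approx(2 * np.pi * 100, rel=1e-3)

    def test_cylinder_area(self):
        z_step = 20.0
        contours = [circle_contour(50.0, z, n=90) for z in np.arange(0.0, 201.0, z_step)]
        model = ContourModel(
            endosome_id="cyl", z_step=z_step,
            objects=[ContourObject(CompartmentClass.RT, contours, capped=True)],
        )
        measure = compute_domain_measure(model, mode="area3d")
        analytic = 2 * np.pi * 50 * 200 + 2 * np.pi * 50**2
        assert measure[CompartmentClass.RT] == pytest.approx(analytic, rel=0.05)

    def test_sphere_area_41_slices(self):
        model = sphere_model(radius=200.0, n_slices=41)
        measure = compute_domain_measure(model, mode="area3d")
        assert measure.total == pytest.approx(4 * np.pi * 200**2, rel=0.05)

    def test_sphere_convergence_monotone(self):
        analytic = 4 * np.pi * 200**2
        errors = []
        for n_slices in (11, 21, 41):
            measure = compute_domain_measure(sphere_model(200.0, n_slices), mode="area3d")
            errors.append(abs(measure.total - analytic) / analytic)
        assert errors[0] >= errors[1] >= errors[2]

    def test_additivity_exact(self, simple_three_class_model):
        measure = compute_domain_measure(simple_three_class_model, mode="area3d")
        assert measure.total == sum(measure.per_class.values())

    def test_length2d_rejects_multi_plane(self, simple_three_class_model):
        with pytest.raises(GeometryError, match="single-plane"):
            compute_domain_measure(simple_three_class_model, mode="length2d")

    def test_degenerate_contour_errors(self):
        contour = np.tile([[10.0, 10.0, 0.0]], (4, 1))
        model = ContourModel(
            endosome_id="deg", z_step=1.0,
            objects=[ContourObject(CompartmentClass.BM, [contour])],
        )
        with pytest.raises(GeometryError):
            compute_domain_measure(model, mode="length2d")
        with pytest.raises(GeometryError):
            compute_domain_measure(model, mode="area3d")

    def test_single_slice_flat_disc_warns(self):
        model = ContourModel(
            endosome_id="disc", z_step=1.0,
            objects=[ContourObject(CompartmentClass.ILV, [circle_contour(50.0, 0.0, n=180)])],
        )
        with pytest.warns(UserWarning, match="single slice"):
            measure = compute_domain_measure(model, mode="area3d")
        assert measure[CompartmentClass.ILV] == pytest.approx(2 * np.pi * 50**2, rel=0.01)

    def test_bm_cap_flag(self):
        model = sphere_model(radius=200.0, n_slices=21, label=CompartmentClass.BM)
        model.objects[0].capped = True
        capped = compute_domain_measure(model, mode="area3d", cap_bm=True)
        open_ = compute_domain_measure(model, mode="area3d", cap_bm=False)
        assert capped.total > open_.total


class TestProjection:
    def _circle_model(self):
        return ContourModel(
            endosome_id="circle", z_step=1.0,
            objects=[ContourObject(
                CompartmentClass.BM, [circle_contour(20.0, 0.0, n=180, center=(32.0, 32.0))]
            )],
        )

    def test_identity_projection_is_outline(self):
        rasters = project_outlines(self._circle_model(), IDENTITY, (64, 64))
        raster = rasters[CompartmentClass.BM]
        rr, cc = np.nonzero(raster)
        radii = np.hypot(rr - 32, cc - 32)
        assert raster.sum() > 0
        assert np.all(np.abs(radii - 20.0) < 1.0)  # 1-px-wide ring

    def test_translation_equivariance(self):
        base = project_outlines(self._circle_model(), IDENTITY, (80, 80))
        shift = np.array([[1, 0, 5.0], [0, 1, 3.0], [0, 0, 1]])  # +5 px in x, +3 in y
        moved = project_outlines(self._circle_model(), shift, (80, 80))
        np.testing.assert_array_equal(
            moved[CompartmentClass.BM][3:, 5:], base[CompartmentClass.BM][:-3, :-5]
        )

    def test_point_pixels_subset_of_raster(self):
        """Brute-force oracle: every directly transformed contour point
        lands on a raster pixel of its class."""
        model = sphere_model(radius=200.0, n_slices=41, center=(300.0, 300.0, 300.0))
        scale = np.diag([0.1, 0.1, 1.0])  # nm -> px
        rasters = project_outlines(model, scale, (64, 64))
        raster = rasters[CompartmentClass.ILV]
        for contour in model.objects[0].contours:
            cols = np.round(contour[:, 0] * 0.1).astype(int)
            rows = np.round(contour[:, 1] * 0.1).astype(int)
            assert raster[rows, cols].all()

    def test_slice_count_grows_support(self):
        few = project_outlines(
            sphere_model(200.0, 11, center=(300.0, 300.0, 300.0)), np.diag([0.1, 0.1, 1.0]), (64, 64)
        )[CompartmentClass.ILV]
        many = project_outlines(
            sphere_model(200.0, 41, center=(300.0, 300.0, 300.0)), np.diag([0.1, 0.1, 1.0]), (64, 64)
        )[CompartmentClass.ILV]
        assert many.sum() >= few.sum()

    def test_singular_transform_errors(self):
        singular = np.zeros((3, 3))
        with pytest.raises(GeometryError, match="singular"):
            project_outlines(self._circle_model(), singular, (64, 64))

    def test_all_clipped_errors(self):
        shift = np.array([[1, 0, 1000.0], [0, 1, 1000.0], [0, 0, 1]])
        with pytest.raises(GeometryError, match="outside field of view"):
            project_outlines(self._circle_model(), shift, (64, 64))

    def test_partial_clipping_logged(self, caplog):
        shift = np.array([[1, 0, 20.0], [0, 1, 0.0], [0, 0, 1]])
        import logging

        with caplog.at_level(logging.WARNING, logger="clemquant.model_geometry"):
            rasters = project_outlines(self._circle_model(), shift, (64, 64))
        assert rasters[CompartmentClass.BM].sum() > 0
        assert any("clipped" in r.message for r in caplog.records)
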