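"""Morphometry: axes, neck/lamella scoring, off-interface protrusions."""

import numpy as np
import pandas as pd
import pytest

from synquant import (
    AcquisitionSpec,
    ShapeEvent,
    SynthCoupleSpec,
    detect_off_interface_lamella,
    measure_axes,
    measure_morph_frame,
    score_lamella,
    shape_factor,
    simulate_couple,
)
from synquant.morphometrics import (
    midline_profile,
    morph_from_annotations,
    morph_table,
    read_annotations,
)
from synquant.phantoms import bent_tube, hourglass, sphere_with_disc

ISO = (0.25, 0.25, 0.25)


class TestAxes:
    def test_sphere_with_disc_closed_form(self):
        mask, iface = sphere_with_disc(radius=5.0, disc_radius=3.0)
        d, w, length, _ = measure_axes(mask, iface, ISO)
        assert d == pytest.approx(6.0, abs=0.5)
        assert w == pytest.approx(10.0, abs=0.5)
        # straight cell: length equals the interface-to-pole distance
        assert length == pytest.approx(5.0 + 4.0, abs=0.25)

    def test_bent_midline_arc_length(self):
        mask, iface, truth = bent_tube()
        _, _, length, _ = measure_axes(mask, iface, ISO)
        assert length == pytest.approx(truth, rel=0.05)


class TestLamellaScoring:
    def test_convex_cell_has_no_neck(self):
        mask, iface = sphere_with_disc()
        profile = midline_profile(mask, iface, ISO)
        scorable, neck, lam = score_lamella(profile, iface.diameter)
        assert not scorable and neck is None and lam is None

    def test_hourglass_neck_position_recovered(self):
        mask, iface = hourglass(neck_position=2.0)
        profile = midline_profile(mask, iface, ISO)
        scorable, neck, lam = score_lamella(profile, iface.diameter)
        assert scorable
        assert lam == pytest.approx(2.0, abs=0.25)

    @pytest.mark.parametrize(
        "position,expected", [(1.1, False), (1.5, True)]
    )
    def test_thirteen_hundred_nm_rule_is_sharp(self, position, expected):
        mask, iface = hourglass(neck_position=position)
        profile = midline_profile(mask, iface, ISO)
        scorable, _, _ = score_lamella(profile, iface.diameter)
        assert scorable is expected

    def test_generator_early_lamella_recovered(self):
        acq = AcquisitionSpec(n_z=42, z_step=0.5, n_frames=2)
        spec = SynthCoupleSpec(
            seed=5, contact_frame=0, acquisition=acq,
            shape_events=[ShapeEvent(kind="early_lamella", length=2.5)],
        )
        _, truth, _ = simulate_couple(spec)
        frame = measure_morph_frame(
            truth.tcell_masks[1], truth.interfaces[1], acq.spacing
        )
        assert frame.has_scorable_lamella
        assert frame.lamellal_length == pytest.approx(2.5, abs=0.3)
        # invariant: scorable implies neck beyond 1.3 µm
        assert frame.neck_distance > 1.3

    def test_scale_equivariance_of_shape_factor(self):
        mask, iface = hourglass(neck_position=2.0)
        f1 = measure_morph_frame(mask, iface, ISO)
        iface2 = type(iface)(
            voxels=iface.voxels, center=iface.center * 2,
            normal=iface.normal, diameter=iface.diameter * 2,
        )
        f2 = measure_morph_frame(mask, iface2, tuple(2 * s for s in ISO))
        assert f2.shape_factor == pytest.approx(f1.shape_factor, rel=0.05)


class TestShapeFactor:
    def test_direct_quotient(self):
        assert shape_factor(3.0, 6.0) == 0.5

    def test_zero_length(self):
        assert shape_factor(0.0, 6.0) == 0.0

    def test_identity_case(self):
        assert shape_factor(4.2, 4.2) == 1.0

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            shape_factor(3.0, 0.0)


class TestOffInterfaceLamella:
    def test_smooth_spheroid_is_negative(self):
        mask, iface = sphere_with_disc()
        assert not detect_off_interface_lamella(mask, iface, ISO)

    def test_programmed_protrusion_flags_only_after_onset(self):
        spec = SynthCoupleSpec(
            seed=3, contact_frame=0,
            acquisition=AcquisitionSpec(n_frames=3),
            shape_events=[
                ShapeEvent(kind="off_interface_protrusion", frame=1,
                           length=2.0)
            ],
        )
        _, truth, _ = simulate_couple(spec)
        sp = spec.acquisition.spacing
        flags = [
            detect_off_interface_lamella(
                truth.tcell_masks[t], truth.interfaces[t], sp
            )
            for t in range(3)
        ]
        assert flags == [False, True, True]

    def test_interface_lamella_is_not_off_interface(self):
        # a stalk at the synapse itself must not be counted
        acq = AcquisitionSpec(n_z=42, z_step=0.5, n_frames=2)
        spec = SynthCoupleSpec(
            seed=5, contact_frame=0, acquisition=acq,
            shape_events=[ShapeEvent(kind="early_lamella", length=2.5)],
        )
        _, truth, _ = simulate_couple(spec)
        assert not detect_off_interface_lamella(
            truth.tcell_masks[1], truth.interfaces[1], acq.spacing
        )


class TestAnnotations:
    def _annotation_df(self, frame, cid=0, t=20.0):
        rows = []
        lines = {
            "interface_diameter": frame.interface_diameter,
            "cell_width": frame.cell_width,
            "cell_length": frame.cell_length,
        }
        if frame.has_scorable_lamella:
            lines["lamellal_length"] = frame.lamellal_length
        for lt, ln in lines.items():
            rows.append(
                {"couple_id": cid, "time_rel_s": t, "line_type": lt,
                 "x1": 0.0, "y1": 0.0, "x2": ln, "y2": 0.0}
            )
        return pd.DataFrame(rows)

    def test_manual_path_agrees_with_automatic(self, tmp_path):
        mask, iface = hourglass(neck_position=2.0)
        auto = measure_morph_frame(mask, iface, ISO)
        csv = tmp_path / "ann.csv"
        self._annotation_df(auto).to_csv(csv, index=False)
        manual = morph_from_annotations(read_annotations(csv))[(0, 20.0)]
        for attr in ("interface_diameter", "cell_width", "cell_length",
                     "lamellal_length"):
            a, m = getattr(auto, attr), getattr(manual, attr)
            assert m == pytest.approx(a, rel=0.10)
        assert manual.has_scorable_lamella == auto.has_scorable_lamella
        assert manual.shape_factor == pytest.approx(
            auto.shape_factor, rel=0.10
        )

    def test_bad_line_type_rejected(self, tmp_path):
        df = pd.DataFrame(
            [{"couple_id": 0, "time_rel_s": 0.0, "line_type": "banana",
              "x1": 0, "y1": 0, "x2": 1, "y2": 0}]
        )
        csv = tmp_path / "bad.csv"
        df.to_csv(csv, index=False)
        with pytest.raises(ValueError, match="line types"):
            read_annotations(csv)

    def test_morph_table_columns(self):
        mask, iface = sphere_with_disc()
        frame = measure_morph_frame(mask, iface, ISO)
        table = morph_table({(0, 0.0): frame})
        assert {
            "couple_id", "time_rel_s", "interface_diameter_um",
            "cell_width_um", "shape_factor", "has_scorable_lamella",
            "has_off_interface_lamella",
        } <= set(table.columns)
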