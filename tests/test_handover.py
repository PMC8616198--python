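"""DVH-to-template conversion, NTO and the surrogate re-optimizer."""

import numpy as np
import pytest

import lexiplan as lp
from lexiplan.handover import (
    NTOParams,
    build_objective_template,
    dvh_to_line_objectives,
    line_objective_residuals,
    nto_threshold,
    surrogate_reoptimize,
    template_from_plan,
    template_from_xml,
    template_to_xml,
)
from lexiplan.metrics import DVHCurve, compute_dvh

import oracles


def step_dvh(max_dose, structure="lungs"):
    axis = np.arange(0.0, max_dose + 1.0, 0.1)
    vol = np.where(axis <= max_dose, 100.0, 0.0)
    return DVHCurve(axis, vol, structure)


class TestLineObjectives:
    def test_point_count_for_42gy_curve(self):
        line = dvh_to_line_objectives(step_dvh(42.0), spacing_Gy=0.7)
        assert len(line.doses_Gy) == 61
        assert line.doses_Gy[0] == 0.0
        assert line.doses_Gy[-1] == pytest.approx(42.0)

    def test_first_multiple_at_or_above_max_dose_is_included(self):
        line = dvh_to_line_objectives(step_dvh(42.3), spacing_Gy=0.7)
        assert len(line.doses_Gy) == 62
        assert line.doses_Gy[-1] == pytest.approx(42.7)

    def test_step_function_dvh_hugged_within_one_spacing(self):
        line = dvh_to_line_objectives(step_dvh(30.0))
        assert (line.volumes_pct[line.doses_Gy <= 29.9] == 100.0).all()
        assert line.volumes_pct[-1] <= 100.0

    def test_sampled_volumes_match_counting_oracle_within_a_bin(self):
        rng = np.random.default_rng(9)
        dose = rng.random(400) * 55.0
        dvh = compute_dvh(dose, bin_width_Gy=0.02, structure="heart")
        line = dvh_to_line_objectives(dvh)
        brute = oracles.brute_dvh(dose, line.doses_Gy)
        bin_tol = 100.0 / 400 + 1e-9  # one voxel of volume per 0.02 Gy bin
        assert np.abs(line.volumes_pct - brute).max() <= 2.5


class TestTemplate:
    def dvhs(self):
        return {
            name: step_dvh(30.0, name)
            for name in ("lungs", "heart", "esophagus", "spinal_canal")
        }

    def test_ptv_point_objectives_bracket_prescription(self):
        t = build_objective_template(self.dvhs(), D_p=66.0)
        ptv = [p for p in t.point_objectives if p.structure == "PTV"]
        assert {(p.kind, p.dose_Gy, p.priority) for p in ptv} == {
            ("Min", 65.5, 130),
            ("Max", 66.5, 130),
        }

    def test_serial_oars_get_max_point_plus_line(self):
        t = build_objective_template(self.dvhs(), D_p=66.0)
        canal_max = next(
            p for p in t.point_objectives if p.structure == "spinal_canal"
        )
        assert (canal_max.dose_Gy, canal_max.priority) == (48.0, 100)
        canal_line = next(
            l for l in t.line_objectives if l.structure == "spinal_canal"
        )
        assert canal_line.priority == 40

    def test_line_priorities_per_structure(self):
        t = build_objective_template(self.dvhs(), D_p=66.0)
        prio = {l.structure: l.priority for l in t.line_objectives}
        assert prio == {"lungs": 80, "heart": 80, "esophagus": 60, "spinal_canal": 40}

    def test_missing_oar_dvh_rejected(self):
        d = self.dvhs()
        del d["heart"]
        with pytest.raises(ValueError, match="heart"):
            build_objective_template(d, D_p=66.0)


class TestNTO:
    def test_start_dose_at_border_distance(self):
        assert nto_threshold(5.0, 66.0) == pytest.approx(1.05 * 66.0)

    def test_far_field_tends_to_end_dose(self):
        assert nto_threshold(1e4, 66.0) == pytest.approx(0.60 * 66.0)

    def test_monotone_non_increasing_and_matches_closed_form(self):
        d = np.linspace(0.0, 120.0, 200)
        vals = nto_threshold(d, 66.0)
        assert (np.diff(vals) <= 1e-12).all()
        p = NTOParams()
        mid = 37.0
        expected = 66.0 * (
            p.end_frac + (p.start_frac - p.end_frac) * np.exp(-p.falloff * (mid - 5.0))
        )
        assert nto_threshold(mid, 66.0) == pytest.approx(expected, rel=1e-12)


class TestSurrogate:
    def test_ptv_only_template_hits_the_band(self, small_phantom, influence_template):
        from lexiplan.handover import ObjectiveTemplate, PointObjective

        template = ObjectiveTemplate(
            D_p=66.0,
            point_objectives=[
                PointObjective("PTV", "Min", 65.5, 130),
                PointObjective("PTV", "Max", 66.5, 130),
            ],
        )
        structures = {
            "PTV": influence_template.rows_for_mask(small_phantom.masks["PTV"])
        }
        plan = surrogate_reoptimize(
            influence_template, template, structures, normalize=False
        )
        ptv = plan.structure_dose("PTV")
        assert ptv.min() >= 65.5 - 0.3
        assert ptv.max() <= 66.5 + 0.3

    def test_priority_rescaling_leaves_optimum_unchanged(
        self, small_phantom, influence_template
    ):
        import copy

        t1 = template_from_plan_fixture(influence_template, small_phantom)
        t2 = copy.deepcopy(t1)
        for p in t2.point_objectives:
            p.priority *= 2
        for l in t2.line_objectives:
            l.priority *= 2
        t2.nto = NTOParams(priority=t2.nto.priority * 2)
        structures = {
            name: influence_template.rows_for_mask(mask)
            for name, mask in small_phantom.masks.items()
        }
        p1 = surrogate_reoptimize(influence_template, t1, structures, normalize=False)
        p2 = surrogate_reoptimize(influence_template, t2, structures, normalize=False)
        np.testing.assert_allclose(p1.dose, p2.dose, rtol=1e-5, atol=1e-7)

    def test_reproduces_fmo_dvhs_within_two_points(self, fmo_plan, influence_template):
        src = lp.normalize_plan(fmo_plan)
        template = template_from_plan(src)
        plan = surrogate_reoptimize(
            influence_template, template, src.structures, x0=src.fluence
        )
        for lo in template.line_objectives:
            d = plan.structure_dose(lo.structure)
            achieved = 100.0 * (d[None, :] >= lo.doses_Gy[:, None]).mean(axis=1)
            assert np.abs(achieved - lo.volumes_pct).max() <= 2.0, lo.structure

    def test_residuals_zero_when_line_dominates(self, fmo_plan):
        template = template_from_plan(fmo_plan)
        res = line_objective_residuals(fmo_plan, template)
        for structure, r in res.items():
            assert r.max() <= 1e-9, structure


def template_from_plan_fixture(influence, phantom):
    dvhs = {
        name: compute_dvh(
            (influence.matrix @ np.ones(influence.n_beamlets))[
                influence.rows_for_mask(phantom.masks[name])
            ]
            * 0.5,
            structure=name,
        )
        for name in ("lungs", "heart", "esophagus", "spinal_canal")
    }
    return build_objective_template(dvhs, D_p=66.0)


def test_xml_round_trip(fmo_plan, tmp_path):
    template = template_from_plan(fmo_plan)
    path = tmp_path / "template.xml"
    template_to_xml(template, path)
    back = template_from_xml(path)
    assert back.D_p == template.D_p
    assert len(back.point_objectives) == len(template.point_objectives)
    for a, b in zip(back.line_objectives, template.line_objectives):
        assert a.structure == b.structure and a.priority == b.priority
        np.testing.assert_allclose(a.doses_Gy, b.doses_Gy)
        np.testing.assert_allclose(a.volumes_pct, b.volumes_pct)
    assert back.nto == template.nto
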