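"""End-to-end pipeline driver and run configuration.

A run takes a seeded phantom through influence computation, beam-angle
optimization (or fixed angles), two-round lexicographic FMO, DVH-template
handover with surrogate re-optimization, and plan evaluation, writing
every artifact plus a manifest of content hashes.  All randomness is
funneled through the single configured seed, so reruns with the same
configuration produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bao, dose, fmo, handover, metrics, phantom as phantom_mod, wishlist as wl_mod

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one planning run.

    Defaults reproduce the 6-beam plan with beam-angle optimization — the
    configuration matching clinical beam numbers.
    """

    phantom: phantom_mod.PhantomConfig = field(default_factory=phantom_mod.PhantomConfig)
    D_p: float = 66.0
    seed: int = 0
    candidate_spacing_deg: float = 5.0
    n_beams: tuple[int, ...] = (6,)
    use_bao: bool = True
    fixed_angles: tuple[float, ...] = bao.DEFAULT_TEMPLATE_ANGLES
    relaxation_factor: float = wl_mod.DEFAULT_RELAXATION_FACTOR
    beam_geometry: dose.BeamGeometry = field(default_factory=dose.BeamGeometry)
    output_dir: str = "runs/latest"

    def validate(self) -> None:
        self.phantom.validate()
        if self.D_p not in wl_mod.SUPPORTED_PRESCRIPTIONS:
            raise ValueError(f"unsupported prescription {self.D_p}")
        if not self.n_beams or any(n < 1 for n in self.n_beams):
            raise ValueError(f"invalid beam counts {self.n_beams}")
        if self.relaxation_factor <= 1.0:
            raise ValueError("relaxation factor must exceed 1")
        if self.candidate_spacing_deg <= 0:
            raise ValueError("candidate spacing must be positive")
        if not self.use_bao and len(self.n_beams) > 1:
            raise ValueError("fixed-angle mode plans a single beam count")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = phantom_mod.config_to_dict(self.phantom)
        d["beam_geometry"] = dataclasses.asdict(self.beam_geometry)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d:
            ph = d["phantom"]
            d["phantom"] = (
                ph if isinstance(ph, phantom_mod.PhantomConfig)
                else phantom_mod.config_from_dict(ph)
            )
        if "beam_geometry" in d and isinstance(d["beam_geometry"], dict):
            d["beam_geometry"] = dose.BeamGeometry(**d["beam_geometry"])
        for key in ("n_beams", "fixed_angles"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config_yaml(path) -> RunConfig:
    import yaml

    with open(path) as f:
        return RunConfig.from_dict(yaml.safe_load(f))


def save_config_yaml(path, config: RunConfig) -> None:
    import yaml

    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)


def _hash_array(arr: np.ndarray) -> str:
    a = np.ascontiguousarray(arr)
    return hashlib.sha256(a.tobytes() + str(a.shape).encode()).hexdigest()


def run_pipeline(config: RunConfig, output_dir=None) -> Path:
    """Execute the configured planning run; returns the run directory.

    Writes phantom and influence HDF5, per-beam-count FMO and final
    (handed-over) plans, DVH CSVs, the objective-template XML, the
    constraint report, stage logs, and a manifest of deterministic
    content hashes.
    """
    config.validate()
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "hashes": {}}
    t0 = time.time()

    cfg_ph = dataclasses.replace(config.phantom, prescription_Gy=config.D_p)
    ph = phantom_mod.generate_phantom(cfg_ph, seed=config.seed)
    derived = phantom_mod.derive_structures(ph)
    phantom_mod.save_phantom(out / "phantom.h5", ph)
    for name, mask in ph.masks.items():
        manifest["hashes"][f"mask:{name}"] = _hash_array(mask)
    manifest["stages"]["phantom"] = {"seconds": time.time() - t0}

    wishlist = wl_mod.build_wishlist(config.D_p, config.relaxation_factor)
    wl_mod.save_wishlist_yaml(out / "wishlist.yaml", wishlist)

    t1 = time.time()
    plans: dict[int, fmo.FluencePlan] = {}
    if config.use_bao:
        candidates = dose.candidate_angles(ph.laterality, config.candidate_spacing_deg)
        result = bao.beam_count_study(
            ph, wishlist, config.n_beams,
            candidates=candidates, geometry=config.beam_geometry, derived=derived,
        )
        plans.update(result)
        manifest["stages"]["bao"] = {
            "seconds": time.time() - t1,
            "n_candidates": len(candidates),
        }
    else:
        plan = bao.plan_without_bao(
            ph, wishlist, config.fixed_angles,
            geometry=config.beam_geometry, derived=derived,
        )
        plans[len(config.fixed_angles)] = plan
        manifest["stages"]["fmo_fixed"] = {"seconds": time.time() - t1}

    influence_cache: dict[tuple, dose.InfluenceMatrix] = {}
    for n, plan in sorted(plans.items()):
        tag = f"{n}beam"
        t2 = time.time()
        plan = metrics.normalize_plan(plan, config.D_p)
        plans[n] = plan
        plan.stage_log_json(out / f"fmo_stage_log_{tag}.json")
        save_plan(out / f"fmo_plan_{tag}.h5", plan)
        manifest["hashes"][f"fmo_dose:{tag}"] = _hash_array(plan.dose)
        manifest["hashes"][f"angles:{tag}"] = _hash_array(np.sort(plan.angles_deg))

        key = tuple(np.sort(plan.angles_deg))
        if key not in influence_cache:
            influence_cache[key] = dose.compute_influence(
                ph, np.asarray(key), config.beam_geometry
            )
        influence = influence_cache[key]
        dose.save_influence(out / f"influence_{tag}.h5", influence)

        for name in plan.structures:
            dvh = metrics.compute_dvh(plan.structure_dose(name), structure=name)
            metrics.save_dvh_csv(out / f"dvh_{tag}_{name}.csv", dvh)

        template = handover.template_from_plan(plan)
        handover.template_to_xml(template, out / f"objective_template_{tag}.xml")
        ptv_mask = ph.masks["PTV"]
        nt_mask = ph.masks["body"] & ~ptv_mask
        rows = influence.rows_for_mask(nt_mask)
        dist = phantom_mod.distance_to_structure_mm(ph, ptv_mask).ravel()[
            influence.voxel_indices
        ]
        nt_rows_mm = (rows, dist[rows])
        final = handover.surrogate_reoptimize(
            influence, template, plan.structures,
            x0=plan.fluence, ptv_distance_rows_mm=nt_rows_mm,
        )
        save_plan(out / f"final_plan_{tag}.h5", final)
        manifest["hashes"][f"final_dose:{tag}"] = _hash_array(final.dose)

        report = metrics.check_clinical_constraints(final, ph)
        report.to_json(out / f"constraint_report_{tag}.json")
        manifest["stages"][f"plan_{tag}"] = {
            "seconds": time.time() - t2,
            "constraints_pass": report.passed,
        }

    manifest["total_seconds"] = time.time() - t0
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return out


# ---------------------------------------------------------------------------
# Plan HDF5 round-trip

def save_plan(path, plan: fmo.FluencePlan) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name, data in (
            ("angles_deg", plan.angles_deg),
            ("fluence", plan.fluence),
            ("dose", plan.dose),
            ("achieved", np.asarray(plan.achieved, dtype=float)),
        ):
            f.create_dataset(name, data=np.asarray(data, dtype=float), track_times=False)
        g = f.create_group("structures")
        for name, rows in plan.structures.items():
            g.create_dataset(name, data=rows, track_times=False)
        f.attrs["normalized"] = plan.normalized
        if plan.prescription_Gy is not None:
            f.attrs["prescription_Gy"] = plan.prescription_Gy


def load_plan(path) -> fmo.FluencePlan:
    import h5py

    with h5py.File(path, "r") as f:
        return fmo.FluencePlan(
            angles_deg=f["angles_deg"][...],
            fluence=f["fluence"][...],
            dose=f["dose"][...],
            structures={k: f["structures"][k][...] for k in f["structures"]},
            achieved=list(f["achieved"][...]),
            stage_log=[],
            normalized=bool(f.attrs["normalized"]),
            prescription_Gy=float(f.attrs["prescription_Gy"])
            if "prescription_Gy" in f.attrs
            else None,
        )
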