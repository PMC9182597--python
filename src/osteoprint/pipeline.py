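"""Run the full reconstruction procedure from one YAML configuration.

Stages: input (DICOM series or phantom recipe) -> enhancement -> segmentation
(with implant/cement separation when configured) -> isosurface extraction ->
repair -> optional plane splitting -> artifact export (STL, NIfTI masks,
JSON reports, resolved config).  All randomness flows from the single config
seed, so reruns with the same config are bit-identical.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import enhancement, mesh_repair, metrology, phantoms, segmentation, splitting
from .errors import ParameterError
from .mesh import save_stl
from .surface import extract_isosurface
from .volume_io import read_dicom_series, write_nifti

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "input": {"kind": "phantom", "phantom": "femur_implant", "noise_sd": 50.0, "streak_amplitude": 300.0},
    "enhance": {"enabled": True},
    "segment": {
        "structures": {
            "bone": {"low": 150.0, "high": 2500.0},
            "bone_cement": {"low": 800.0, "high": 1200.0},
        },
        "metal_low": 3000.0,
        "margin_mm": 0.5,
    },
    "surface": {"iso": 0.5},
    "repair": {},
    "split": [],  # list of {structure, point, normal}
    "metrology": None,  # {points_xyz: path, structure: name} | None
}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    return merge_config(cfg or {})


def merge_config(cfg: dict) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in cfg.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


def _load_input(cfg: dict, seed: int):
    kind = cfg["input"]["kind"]
    if kind == "dicom":
        path = Path(cfg["input"]["path"])
        if not path.exists():
            raise ParameterError(f"input DICOM directory does not exist: {path}")
        return read_dicom_series(path), None
    if kind == "phantom":
        kwargs = {}
        if "shape" in cfg["input"]:
            kwargs["shape"] = tuple(cfg["input"]["shape"])
        if "spacing" in cfg["input"]:
            kwargs["spacing"] = tuple(cfg["input"]["spacing"])
        spec = phantoms.femur_implant_phantom(
            noise_sd=float(cfg["input"].get("noise_sd", 0.0)),
            streak_amplitude=float(cfg["input"].get("streak_amplitude", 0.0)),
            seed=seed,
            **kwargs,
        )
        return phantoms.generate_phantom(spec)
    raise ParameterError(f"unknown input kind {kind!r}")


def run_procedure(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured procedure; returns the output manifest."""
    cfg = merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    vol, truth = _load_input(cfg, int(cfg["seed"]))
    log.info("input volume %s at spacing %s", vol.shape, vol.spacing)

    if cfg["enhance"].get("enabled", True):
        work = enhancement.enhance(vol, cfg["enhance"])
    else:
        work = vol

    seg = cfg["segment"]
    bone_iv = seg["structures"]["bone"]
    bone_mask, implant_mask = segmentation.separate_implant(
        work,
        (float(bone_iv["low"]), float(bone_iv["high"])),
        float(seg["metal_low"]),
        margin=float(seg.get("margin_mm", 0.5)),
    )
    masks = {"bone": bone_mask, "implant": implant_mask}
    if "bone_cement" in seg["structures"]:
        civ = seg["structures"]["bone_cement"]
        cement = segmentation.threshold_mask(work, float(civ["low"]), float(civ["high"]))
        cement_arr = cement.astype_bool() & ~implant_mask.astype_bool()
        masks["bone_cement"] = type(cement)(
            cement_arr.astype(np.uint8), cement.spacing, cement.origin
        )
        # cement takes priority over the bone interval where both claim a voxel
        bone_arr = bone_mask.astype_bool() & ~cement_arr
        masks["bone"] = type(bone_mask)(
            bone_arr.astype(np.uint8), bone_mask.spacing, bone_mask.origin
        )

    manifest = {"seed": int(cfg["seed"]), "structures": {}}
    for name, mask in masks.items():
        write_nifti(mask, out_dir / f"{name}.nii")
        entry = {"voxels": mask.count(), "nifti": f"{name}.nii"}
        if mask.count() == 0:
            manifest["structures"][name] = entry
            continue
        mesh = extract_isosurface(mask, float(cfg["surface"].get("iso", 0.5)))
        repaired, before, after = mesh_repair.repair(mesh, **cfg.get("repair", {}))
        save_stl(repaired, out_dir / f"{name}.stl")
        entry.update(
            {
                "stl": f"{name}.stl",
                "triangles": repaired.n_triangles,
                "volume_mm3": repaired.volume(),
                "diagnostics_before": before.as_dict(),
                "diagnostics_after": after.as_dict(),
            }
        )
        for cut in cfg.get("split", []) or []:
            if cut.get("structure") != name:
                continue
            plane = splitting.CutPlane(tuple(cut["point"]), tuple(cut["normal"]))
            pos, neg = splitting.split_by_plane(repaired, plane, cap=True)
            splitting.export_parts(
                [pos, neg], [f"{name}_pos", f"{name}_neg"], out_dir / f"{name}_parts"
            )
            entry["split_parts"] = f"{name}_parts/manifest.json"
        manifest["structures"][name] = entry

    met = cfg.get("metrology")
    if met:
        from .mesh import load_stl

        points = metrology.read_xyz(met["points_xyz"])
        target = met.get("structure", "bone")
        nominal = load_stl(out_dir / f"{target}.stl")
        transform = metrology.best_fit(points, nominal)
        report = metrology.deviation_report(points, nominal, transform)
        (out_dir / "deviation.json").write_text(
            json.dumps(report.as_dict(), indent=1, sort_keys=True)
        )
        manifest["deviation"] = report.as_dict()

    (out_dir / "config.resolved.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
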