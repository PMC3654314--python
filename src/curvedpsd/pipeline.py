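"""End-to-end pipeline orchestration with a run manifest.

A run executes the reduction chain

    simulate -> findpeaks -> merge -> index -> predict -> reduce

(or any contiguous suffix, resuming from files a previous run left in the
working directory).  Every stage reads and writes the documented text
formats, so each is independently re-runnable, and a JSON manifest records
the configuration snapshot, seeds, per-stage record counts, timings and
SHA-256 digests of every output file.  Identical configuration and seeds
reproduce identical outputs bit for bit in the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .frame_io import (FrameStack, read_stack, read_table, write_stack,
                       write_table)
from .geometry import Cell, ScanConfig
from .indexing import (UBMatrix, index_points, observations_to_q,
                       predict_observations, refine_ub_lsq,
                       ub_montecarlo, vector_minimum)
from .peaksearch import Peak3D, find_peaks_stack, merge_frames
from .profiles import builtin_profile, load_profile
from .reduce import build_reflection_list, classify, export_reflections
from .simulate import SpotShape, simulate_full_rotation

STAGES = ("simulate", "findpeaks", "merge", "index", "predict", "reduce")


class StageError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _digest(path: Path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest_tree(path: Path):
    path = Path(path)
    if path.is_file():
        return _digest(path)
    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(bytes.fromhex(_digest(f)))
    return h.hexdigest()


def load_config(path):
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _resolve_profile(cfg):
    if "profile" in cfg:
        prof = cfg["profile"]
        if isinstance(prof, str) and Path(prof).exists():
            geom, scan = load_profile(prof)
        else:
            geom, scan = builtin_profile(prof)
    else:
        from .profiles import geometry_from_dict, scan_from_dict
        geom = geometry_from_dict(cfg["geometry"])
        scan = scan_from_dict(cfg["scan"]) if "scan" in cfg else None
    overrides = cfg.get("scan_overrides", {})
    if overrides and scan is not None:
        scan = ScanConfig(**{**dataclasses.asdict(scan), **overrides})
    return geom, scan


def run_pipeline(config, stages=None, workdir="."):
    """Execute the configured stages; returns the manifest dict.

    ``config`` is a mapping (or a path to a YAML file).  Stage outputs and
    the manifest land in ``workdir``.  On a stage failure the partial
    manifest is written before the stage's error propagates as
    :class:`StageError`.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages.sort(key=STAGES.index)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    geom, scan = _resolve_profile(config)
    manifest = {
        "tool": "curvedpsd",
        "version": __version__,
        "config": config,
        "seeds": {},
        "stages": {},
    }
    paths = {
        "stack": workdir / "stack",
        "peaks": workdir / "peaks.dat",
        "peaks3d": workdir / "peaks3d.dat",
        "qlist": workdir / "ang-q.dat",
        "ub": workdir / "ub.dat",
        "predictions": workdir / "predictions.dat",
        "hkl": workdir / "hkl.dat",
        "rejects": workdir / "rejects.dat",
    }

    def record(stage, outputs, count, t0):
        manifest["stages"][stage] = {
            "outputs": {k: {"path": str(p), "sha256": _digest_tree(p)}
                        for k, p in outputs.items()},
            "records": count,
            "seconds": round(time.monotonic() - t0, 3),
        }
        _write_manifest(manifest, workdir)

    def fail(stage, exc):
        manifest["stages"][stage] = {"error": str(exc)}
        _write_manifest(manifest, workdir)
        raise StageError(stage, str(exc)) from exc

    state = {}

    if "simulate" in stages:
        t0 = time.monotonic()
        sim = dict(config.get("simulate", {}))
        try:
            cell = Cell(*sim.pop("cell"))
            seed = sim.pop("seed", None)
            manifest["seeds"]["simulate"] = seed
            orientation = None
            if seed is not None:
                from scipy.spatial.transform import Rotation
                orientation = Rotation.random(
                    random_state=np.random.default_rng(seed)).as_matrix()
            shape = None
            if "spot" in sim:
                shape = SpotShape(**sim.pop("spot"))
            stack, truth = simulate_full_rotation(
                geom, cell, scan.wavelength if scan else sim.pop("wavelength"),
                orientation=orientation,
                delta_phi=scan.delta_phi if scan else 0.2,
                shape=shape, seed=seed, **sim)
            write_stack(stack, config.get("stack_mode", "full"),
                        paths["stack"])
            truth.to_csv(workdir / "truth.dat", sep=" ", index=False)
            state["stack"] = stack
            state["scan"] = stack.scan
        except StageError:
            raise
        except Exception as exc:
            fail("simulate", exc)
        record("simulate", {"stack": paths["stack"],
                            "truth": workdir / "truth.dat"},
               len(stack.frames), t0)

    if "findpeaks" in stages:
        t0 = time.monotonic()
        try:
            stack = state.get("stack")
            if stack is None:
                if not paths["stack"].exists():
                    raise FileNotFoundError("no frame stack; run simulate "
                                            "first or point workdir at one")
                stack = read_stack(paths["stack"])
                state["stack"] = stack
            state["scan"] = stack.scan
            fp = config.get("findpeaks", {})
            peaks = find_peaks_stack(stack, fp.get("threshold", 10.0),
                                     fp.get("box", 11))
            recs = [{"peak_number": i, "file_number": p.frame_index,
                     "x": p.x, "y": p.y, "intensity": p.net_intensity}
                    for i, p in enumerate(peaks)]
            write_table("peaks", recs, paths["peaks"])
            state["peaks2d"] = peaks
        except StageError:
            raise
        except Exception as exc:
            fail("findpeaks", exc)
        record("findpeaks", {"peaks": paths["peaks"]}, len(peaks), t0)

    if "merge" in stages:
        t0 = time.monotonic()
        try:
            peaks = state.get("peaks2d")
            scan_eff = state.get("scan") or scan
            if peaks is None:
                raise FileNotFoundError("no 2D peaks in memory; run "
                                        "findpeaks in the same invocation")
            mg = config.get("merge", {})
            peaks3d = merge_frames(peaks, scan_eff,
                                   xy_tol=mg.get("xy_tol", 1.5),
                                   gap_tol=mg.get("gap_tol", 0))
            recs = [{"peak_number": i, "file_number": p.first_frame,
                     "x": p.x, "y": p.y, "intensity": p.intensity}
                    for i, p in enumerate(peaks3d)]
            write_table("peaks", recs, paths["peaks3d"])
            state["peaks3d"] = peaks3d
            qs = observations_to_q(peaks3d, geom, scan_eff)
            qrecs = [{"peak_number": i, "qx": q[0], "qy": q[1], "qz": q[2],
                      "intensity": p.intensity}
                     for i, (q, p) in enumerate(zip(qs, peaks3d))]
            write_table("qlist", qrecs, paths["qlist"])
            state["qs"] = qs
        except StageError:
            raise
        except Exception as exc:
            fail("merge", exc)
        record("merge", {"peaks3d": paths["peaks3d"],
                         "qlist": paths["qlist"]}, len(peaks3d), t0)

    if "index" in stages:
        t0 = time.monotonic()
        try:
            qs = state.get("qs")
            if qs is None:
                if not paths["qlist"].exists():
                    raise FileNotFoundError(
                        "no q list: run merge first or provide ang-q.dat")
                qdf = read_table("qlist", paths["qlist"])
                qs = qdf[["qx", "qy", "qz"]].to_numpy()
                state["qs"] = qs
            ix = config.get("index", {})
            method = ix.get("method", "vm")
            tol = ix.get("tol", 0.1)
            if method == "vm":
                ub = vector_minimum(qs, index_tol=tol)
            elif method == "mc":
                seed = ix.get("seed", 0)
                manifest["seeds"]["index"] = seed
                ub = ub_montecarlo(qs, Cell(*ix["cell"]), seed=seed,
                                   n_trials=ix.get("n_trials", 20000),
                                   index_tol=tol)
            else:
                raise ValueError(f"pipeline indexing supports vm|mc, "
                                 f"not {method!r}")
            obs = [o for o in index_points(ub, qs, tol) if o.indexed]
            ub = refine_ub_lsq(ub, [o.hkl for o in obs], [o.q for o in obs])
            write_table("ub", (ub.matrix, ub.cell), paths["ub"])
            state["ub"] = ub
        except StageError:
            raise
        except Exception as exc:
            fail("index", exc)
        record("index", {"ub": paths["ub"]}, len(obs), t0)

    if "predict" in stages:
        t0 = time.monotonic()
        try:
            ub = state.get("ub")
            if ub is None:
                if not paths["ub"].exists():
                    raise FileNotFoundError("no ub.dat: run index first")
                mat, _ = read_table("ub", paths["ub"])
                ub = UBMatrix(mat)
                state["ub"] = ub
            scan_eff = state.get("scan") or scan
            preds = predict_observations(ub, geom, scan_eff)
            preds.to_csv(paths["predictions"], sep=" ", index=False)
            state["predictions"] = preds
        except StageError:
            raise
        except Exception as exc:
            fail("predict", exc)
        record("predict", {"predictions": paths["predictions"]},
               len(preds), t0)

    if "reduce" in stages:
        t0 = time.monotonic()
        try:
            preds = state.get("predictions")
            peaks3d = state.get("peaks3d")
            ub = state.get("ub")
            scan_eff = state.get("scan") or scan
            if preds is None or peaks3d is None or ub is None:
                raise FileNotFoundError(
                    "reduce needs predictions, 3D peaks and a UB in the "
                    "same invocation")
            rd = config.get("reduce", {})
            classified = classify(preds, peaks3d, ub, geom, scan_eff,
                                  tol_recip=rd.get("tol", 0.1),
                                  qs=state.get("qs"))
            table, rejects = build_reflection_list(
                classified, scale=rd.get("scale", 1.0))
            export_reflections(table, paths["hkl"], fmt="plain")
            rejects.to_csv(paths["rejects"], sep=" ", index=False)
            counts = pd.Series([r.quality for r in classified]) \
                .value_counts().to_dict()
            state["classified"] = classified
            state["hkl_table"] = table
        except StageError:
            raise
        except Exception as exc:
            fail("reduce", exc)
        manifest["quality_counts"] = {k: int(v) for k, v in counts.items()}
        record("reduce", {"hkl": paths["hkl"], "rejects": paths["rejects"]},
               len(table), t0)

    _write_manifest(manifest, workdir)
    return manifest


def _write_manifest(manifest, workdir):
    with open(Path(workdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
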