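"""File formats: OpenSim storage tables, model config, trial bundles.

Time-series tables use the OpenSim STO/MOT storage dialect: a free-form
header terminated by ``endheader``, optional ``nRows=``/``nColumns=`` keys,
then a tab-delimited body whose first column is ``time`` (strictly
increasing).  The model config is TOML; weight chains and band matrices are
plain CSV.  Every pipeline stage writes a JSON run manifest listing its
outputs with SHA-256 checksums so reruns can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, StoParseError
from .model import (FrameGeometry, LinkageModel, MuscleSpec, TrialData)
from .synthetic import GroundTruth


# ---------------------------------------------------------------------------
# STO / MOT storage tables
# ---------------------------------------------------------------------------

def read_sto(path) -> pd.DataFrame:
    """Read an OpenSim STO/MOT table into a DataFrame indexed by row.

    The first column must be ``time`` and strictly increasing.  When the
    header declares ``nRows``/``nColumns`` they are checked against the body.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    n_rows = n_cols = None
    body_start = None
    for k, line in enumerate(lines):
        stripped = line.strip()
        low = stripped.lower()
        if low.startswith("nrows"):
            n_rows = int(stripped.split("=")[1])
        elif low.startswith("ncolumns"):
            n_cols = int(stripped.split("=")[1])
        if low == "endheader":
            body_start = k + 1
            break
    if body_start is None:
        raise StoParseError(f"{path.name}: no 'endheader' line found")
    if body_start >= len(lines):
        raise StoParseError(f"{path.name}: empty body", line=body_start + 1)
    columns = lines[body_start].rstrip("\n").split("\t")
    if not columns or columns[0] != "time":
        raise StoParseError(f"{path.name}: first column must be 'time', got "
                            f"{columns[:1]}", line=body_start + 1)
    try:
        df = pd.read_csv(path, sep="\t", skiprows=body_start, dtype=float,
                         float_precision="round_trip")
    except ValueError as err:
        raise StoParseError(f"{path.name}: unparseable body ({err})") from err
    if n_cols is not None and df.shape[1] != n_cols:
        raise StoParseError(
            f"{path.name}: header declares nColumns={n_cols}, body has "
            f"{df.shape[1]}")
    if n_rows is not None and df.shape[0] != n_rows:
        raise StoParseError(
            f"{path.name}: header declares nRows={n_rows}, body has "
            f"{df.shape[0]}")
    t = df["time"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path.name}: time column not strictly increasing")
    return df


def write_sto(table: pd.DataFrame, path, name: str | None = None) -> None:
    """Write a DataFrame (first column ``time``) as an STO table.

    Values are written with 17 significant digits so a write -> read round
    trip preserves doubles exactly.
    """
    path = Path(path)
    if table.columns[0] != "time":
        raise DataError("first column must be 'time'")
    header = [name or path.stem,
              "version=1",
              f"nRows={len(table)}",
              f"nColumns={table.shape[1]}",
              "inDegrees=no",
              "endheader"]
    body = table.to_csv(sep="\t", index=False, float_format="%.17g",
                        lineterminator="\n")
    path.write_text("\n".join(header) + "\n" + body)


# ---------------------------------------------------------------------------
# Model config (TOML)
# ---------------------------------------------------------------------------

def read_model_config(path) -> LinkageModel:
    """Load a LinkageModel from a TOML config file."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    mc = cfg["model"]
    muscles = tuple(
        MuscleSpec(m["name"], float(m["f_max"]),
                   frozenset(m["spanned_dofs"]),
                   bool(m.get("emg_measured", False)))
        for m in mc["muscles"])
    joints = tuple((j["name"], tuple(j["dofs"])) for j in mc["joints"])
    return LinkageModel(
        muscles, joints,
        subject_mass=float(mc["subject_mass"]),
        template_mass=float(mc["template_mass"]),
        gravity=float(mc.get("gravity", 9.81)),
        weight_levels=tuple(mc.get("weight_levels", (1.0, 10.0, 100.0))))


def _toml_str(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(float(v)) if isinstance(v, float) else str(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_str(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def write_model_config(model: LinkageModel, path) -> None:
    """Write a LinkageModel as a TOML config file.

    Sign conventions documented in the emitted comments: positive moment arm
    = positive torque about the DOF; lines of action point so positive force
    compresses the joint.
    """
    out = ["# solband model config",
           "# sign conventions: positive moment arm generates positive DOF",
           "# torque; line-of-action vectors add compressive joint load",
           "[model]",
           f"subject_mass = {_toml_str(model.subject_mass)}",
           f"template_mass = {_toml_str(model.template_mass)}",
           f"gravity = {_toml_str(model.gravity)}",
           f"weight_levels = {_toml_str(model.weight_levels)}",
           ""]
    for name, dofs in model.joints:
        out += ["[[model.joints]]",
                f"name = {_toml_str(name)}",
                f"dofs = {_toml_str(list(dofs))}",
                ""]
    for mus in model.muscles:
        out += ["[[model.muscles]]",
                f"name = {_toml_str(mus.name)}",
                f"f_max = {_toml_str(mus.f_max)}",
                f"spanned_dofs = {_toml_str(sorted(mus.spanned_dofs))}",
                f"emg_measured = {_toml_str(mus.emg_measured)}",
                ""]
    Path(path).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# Trial bundles (directory of STO/MOT + JSON metadata)
# ---------------------------------------------------------------------------

def write_trial(trial: TrialData, model: LinkageModel, out_dir,
                truth: GroundTruth | None = None) -> list[Path]:
    """Write a trial as a directory of storage files the CLI can reload.

    Layout: ``torques.sto``, ``grf.mot``, ``emg.mot`` (if present),
    ``moment_arms.sto`` (columns dof|muscle), ``lines_of_action.sto``
    (columns joint|muscle|axis), ``intersegmental.sto`` (joint|axis),
    ``trial.json`` (stance window, bodyweight), and optionally
    ``ground_truth.sto``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t = trial.time

    def emit(name, cols, data):
        df = pd.DataFrame({"time": t} | dict(zip(cols, np.asarray(data).T)))
        p = out_dir / name
        write_sto(df, p)
        written.append(p)

    emit("torques.sto", [f"torque_{d}" for d in model.dof_names], trial.torques)
    emit("grf.mot", ["grf_vertical"], trial.grf_vertical[:, None])
    if trial.emg is not None:
        names = [model.muscle_names[i] for i in model.emg_measured_indices]
        emit("emg.mot", [f"emg_{n}" for n in names], trial.emg)

    arm_cols, arm_data = [], []
    for d, dof in enumerate(model.dof_names):
        for i, mus in enumerate(model.muscle_names):
            arm_cols.append(f"arm|{dof}|{mus}")
            arm_data.append([g.moment_arms[d, i] for g in trial.geometry])
    emit("moment_arms.sto", arm_cols, np.asarray(arm_data).T)

    loa_cols, loa_data = [], []
    for joint in model.joint_names:
        for i, mus in enumerate(model.muscle_names):
            for ax, axis in enumerate("xyz"):
                loa_cols.append(f"loa|{joint}|{mus}|{axis}")
                loa_data.append([g.lines_of_action[joint][i, ax]
                                 for g in trial.geometry])
    emit("lines_of_action.sto", loa_cols, np.asarray(loa_data).T)

    int_cols, int_data = [], []
    for joint in model.joint_names:
        for ax, axis in enumerate("xyz"):
            int_cols.append(f"inter|{joint}|{axis}")
            int_data.append([g.intersegmental_force[joint][ax]
                             for g in trial.geometry])
    emit("intersegmental.sto", int_cols, np.asarray(int_data).T)

    if truth is not None:
        emit("ground_truth.sto",
             [f"act_{n}" for n in model.muscle_names], truth.activations)

    meta = {"stance_window": list(trial.stance_window),
            "bodyweight": trial.bodyweight,
            "n_frames": trial.n_frames}
    p = out_dir / "trial.json"
    p.write_text(json.dumps(meta, indent=2) + "\n")
    written.append(p)
    return written


def read_trial(trial_dir, model: LinkageModel) -> TrialData:
    """Reload a trial bundle written by :func:`write_trial`."""
    trial_dir = Path(trial_dir)
    meta = json.loads((trial_dir / "trial.json").read_text())
    torques_df = read_sto(trial_dir / "torques.sto")
    t = torques_df["time"].to_numpy()
    n = len(t)
    torques = torques_df[[f"torque_{d}" for d in model.dof_names]].to_numpy()
    grf = read_sto(trial_dir / "grf.mot")["grf_vertical"].to_numpy()

    arms_df = read_sto(trial_dir / "moment_arms.sto")
    loa_df = read_sto(trial_dir / "lines_of_action.sto")
    int_df = read_sto(trial_dir / "intersegmental.sto")
    nd, m = model.n_dof, model.m
    arms = np.zeros((n, nd, m))
    for d, dof in enumerate(model.dof_names):
        for i, mus in enumerate(model.muscle_names):
            arms[:, d, i] = arms_df[f"arm|{dof}|{mus}"].to_numpy()
    geometry = []
    loa_all = {}
    inter_all = {}
    for joint in model.joint_names:
        loa = np.zeros((n, m, 3))
        for i, mus in enumerate(model.muscle_names):
            for ax, axis in enumerate("xyz"):
                loa[:, i, ax] = loa_df[f"loa|{joint}|{mus}|{axis}"].to_numpy()
        loa_all[joint] = loa
        inter = np.zeros((n, 3))
        for ax, axis in enumerate("xyz"):
            inter[:, ax] = int_df[f"inter|{joint}|{axis}"].to_numpy()
        inter_all[joint] = inter
    for k in range(n):
        geometry.append(FrameGeometry(
            arms[k],
            {j: loa_all[j][k] for j in model.joint_names},
            {j: inter_all[j][k] for j in model.joint_names}))

    emg = None
    emg_path = trial_dir / "emg.mot"
    if emg_path.exists():
        names = [model.muscle_names[i] for i in model.emg_measured_indices]
        emg = read_sto(emg_path)[[f"emg_{n}" for n in names]].to_numpy()

    return TrialData(
        time=t, stance_window=tuple(meta["stance_window"]),
        torques=torques, geometry=geometry, grf_vertical=grf,
        bodyweight=float(meta["bodyweight"]), emg=emg)


# ---------------------------------------------------------------------------
# Chains, bands, manifests
# ---------------------------------------------------------------------------

def write_chain_csv(chain_matrix: np.ndarray, muscle_names, path) -> None:
    """One row per sample, one column per muscle."""
    pd.DataFrame(chain_matrix, columns=list(muscle_names)).to_csv(
        path, index=False, float_format="%.17g")


def read_chain_csv(path) -> np.ndarray:
    return pd.read_csv(path, float_precision="round_trip").to_numpy(dtype=float)


def write_band_csv(curves: np.ndarray, path) -> None:
    """Wide CSV: one row per sample, 101 %stance columns."""
    cols = [f"pct{p:03d}" for p in range(curves.shape[1])]
    pd.DataFrame(curves, columns=cols).to_csv(path, index=False,
                                              float_format="%.17g")


def read_band_csv(path) -> np.ndarray:
    return pd.read_csv(path, float_precision="round_trip").to_numpy(dtype=float)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, stage: str, seeds: dict | None = None,
                   options: dict | None = None, failures: int = 0,
                   extra: dict | None = None) -> Path:
    """Write ``manifest.json`` inventorying every file in *out_dir*.

    Checksums make end-to-end determinism checkable: identical seeds must
    yield identical manifests (timestamps are deliberately omitted).
    """
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "stage": stage,
        "seeds": seeds or {},
        "options": options or {},
        "failures": failures,
        "files": {str(p.relative_to(out_dir)): sha256_file(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return p
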