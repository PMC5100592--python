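"""Readers and writers for the package's text formats.

All tabular output is tab-separated UTF-8 with ``#``-prefixed header
lines naming columns and units; the NaN sentinel of joint maps is
written as ``NA``.  Config files are YAML mappings validated against the
typed config dataclasses; unknown keys are rejected by name.  Every CLI
run drops a provenance JSON (config echo, package version, seed) next to
its outputs so results can be regenerated byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .elasticity import PARAM_NAMES, StepStiffness
from .sequences import CircularSequence
from .sidd_model import DenaturationProfile, EnergyParams, JointProfile
from .synthetic_data import GeneratorConfig
from .trajectory_analysis import (
    KIND_BOOL,
    KIND_DISTANCE,
    KIND_ENERGY,
    BasePairTrajectory,
    DefectCall,
    OpenCallConfig,
)

_SENTINEL = "NA"


# ---------------------------------------------------------------------------
# typed config files
# ---------------------------------------------------------------------------

_CONFIG_TYPES = {
    "energy": EnergyParams,
    "open_call": OpenCallConfig,
    "generator": GeneratorConfig,
}


def read_params(path, kind: str = "energy"):
    """Read a YAML mapping into a validated config object.

    ``kind`` is one of ``energy`` (:class:`EnergyParams`), ``open_call``
    (:class:`OpenCallConfig`) or ``generator``
    (:class:`GeneratorConfig`).  An empty file yields all defaults;
    unknown keys and range violations raise errors naming the field.
    """
    if kind not in _CONFIG_TYPES:
        raise ValueError(
            f"unknown config kind {kind!r}; expected one of {sorted(_CONFIG_TYPES)}"
        )
    cls = _CONFIG_TYPES[kind]
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a YAML mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown keys for {kind} config: {unknown}")
    if kind == "generator" and "energy_params" in raw:
        raw = dict(raw)
        raw["energy_params"] = EnergyParams(**raw["energy_params"])
    return cls(**raw)


def write_provenance(out_path, config: dict, seed: int | None = None) -> Path:
    """Write a provenance JSON record next to an output file."""
    out_path = Path(out_path)
    record = {
        "package": "minicircle",
        "version": __version__,
        "seed": seed,
        "config": config,
    }
    prov = out_path.with_suffix(out_path.suffix + ".provenance.json")
    prov.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return prov


# ---------------------------------------------------------------------------
# profiles and joint maps
# ---------------------------------------------------------------------------


def write_profile(path, seq: CircularSequence, profile: DenaturationProfile) -> None:
    """Write a per-bp opening-probability profile as TSV."""
    with open(path, "w") as fh:
        fh.write("# per-base-pair equilibrium opening probabilities\n")
        fh.write("# columns: position (1-based)\tbase\tp_raw\tp_norm\n")
        fh.write("position\tbase\tp_raw\tp_norm\n")
        for i in range(profile.n_bp):
            fh.write(
                f"{i + 1}\t{seq.base(i + 1)}\t{profile.p_raw[i]:.10e}"
                f"\t{profile.p_norm[i]:.10e}\n"
            )


def read_profile(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_joint(path, joint: JointProfile) -> None:
    """Write a joint map as TSV triples i, j, log_p (NaN as 'NA')."""
    with open(path, "w") as fh:
        fh.write("# log joint opening probability; unsampled pairs = NA\n")
        fh.write("i\tj\tlog_p\n")
        n = joint.n_bp
        for i in range(n):
            for j in range(n):
                v = joint.log_p[i, j]
                txt = _SENTINEL if not np.isfinite(v) else f"{v:.10e}"
                fh.write(f"{i + 1}\t{j + 1}\t{txt}\n")


def read_joint(path) -> JointProfile:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[_SENTINEL])
    n = int(df["i"].max())
    log_p = np.full((n, n), np.nan)
    log_p[df["i"].to_numpy() - 1, df["j"].to_numpy() - 1] = df["log_p"].to_numpy()
    return JointProfile(log_p=log_p)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_AUX_COLUMNS = {"stacking": "stacking_broken", "twist_deg": "step_twist_deg",
                "registry": "registry_shift"}


def write_trajectory(path, traj: BasePairTrajectory) -> None:
    """Write a trajectory in long form: frame_ns, bp, value [+ aux columns]."""
    cols = {"frame_ns": np.repeat(np.arange(traj.n_frames) * traj.dt_ns, traj.n_bp),
            "bp": np.tile(np.arange(1, traj.n_bp + 1), traj.n_frames),
            "value": traj.values.astype(float).ravel()}
    for col, attr in _AUX_COLUMNS.items():
        aux = getattr(traj, attr)
        if aux is not None:
            cols[col] = np.asarray(aux).astype(float).ravel()
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(
            f"# trajectory: n_bp={traj.n_bp} n_frames={traj.n_frames} "
            f"dt_ns={traj.dt_ns!r} kind={traj.kind}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_trajectory(path) -> BasePairTrajectory:
    """Read a long-form trajectory TSV written by :func:`write_trajectory`."""
    header = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# trajectory:"):
        for token in first.split(":", 1)[1].split():
            key, _, val = token.partition("=")
            header[key] = val
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("frame_ns", "bp", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    n_bp = int(header.get("n_bp", df["bp"].max()))
    frames = np.unique(df["frame_ns"].to_numpy())
    n_frames = int(header.get("n_frames", frames.size))
    if "dt_ns" in header:
        dt = float(header["dt_ns"])
    elif frames.size > 1:
        dt = float(frames[1] - frames[0])
    else:
        dt = 1.0
    kind = header.get("kind", KIND_DISTANCE)
    if kind not in (KIND_DISTANCE, KIND_ENERGY, KIND_BOOL):
        raise ValueError(f"{path}: unknown trajectory kind {kind!r}")
    order = np.lexsort((df["bp"].to_numpy(), df["frame_ns"].to_numpy()))
    values = df["value"].to_numpy()[order].reshape(n_frames, n_bp)
    if kind == KIND_BOOL:
        values = values.astype(bool)
    aux = {}
    for col, attr in _AUX_COLUMNS.items():
        if col in df.columns:
            arr = df[col].to_numpy()[order].reshape(n_frames, n_bp)
            if attr == "stacking_broken":
                arr = arr.astype(bool)
            elif attr == "registry_shift":
                arr = arr.astype(int)
            aux[attr] = arr
    return BasePairTrajectory(values=values, dt_ns=dt, kind=kind, **aux)


def write_defect_calls(path, calls: list[DefectCall]) -> None:
    with open(path, "w") as fh:
        fh.write("# classified structural episodes\n")
        fh.write("kind\tstart_bp\tlength_bp\tfirst_frame\tlast_frame\tpersistent\n")
        for c in calls:
            fh.write(
                f"{c.kind}\t{c.span[0]}\t{c.span[1]}\t{c.first_frame}"
                f"\t{c.last_frame}\t{int(c.persistent)}\n"
            )


# ---------------------------------------------------------------------------
# stiffness libraries and structures
# ---------------------------------------------------------------------------

_TRIU = [(i, j) for i in range(6) for j in range(i, 6)]


def write_stiffness_library(path, library: dict[str, StepStiffness]) -> None:
    """One row per step type: means, upper-triangle covariance, temperature.

    Units: translations Angstrom, rotations degrees; covariance in the
    corresponding squared/mixed units; stiffness is recomputed on read as
    kB T C^-1.
    """
    mean_cols = [f"mean_{p}" for p in PARAM_NAMES]
    cov_cols = [f"cov_{PARAM_NAMES[i]}_{PARAM_NAMES[j]}" for i, j in _TRIU]
    with open(path, "w") as fh:
        fh.write("# base-pair-step stiffness library\n")
        fh.write("# units: shift/slide/rise in Angstrom, tilt/roll/twist in degrees\n")
        fh.write("step_type\t" + "\t".join(mean_cols + cov_cols) + "\ttemperature_K\n")
        for step_type in sorted(library):
            entry = library[step_type]
            vals = [f"{m:.8e}" for m in entry.mean]
            vals += [f"{entry.covariance[i, j]:.8e}" for i, j in _TRIU]
            fh.write(f"{step_type}\t" + "\t".join(vals) + f"\t{entry.temperature_K}\n")


def read_stiffness_library(path) -> dict[str, StepStiffness]:
    df = pd.read_csv(path, sep="\t", comment="#")
    library = {}
    for _, row in df.iterrows():
        mean = np.array([row[f"mean_{p}"] for p in PARAM_NAMES])
        cov = np.zeros((6, 6))
        for i, j in _TRIU:
            cov[i, j] = cov[j, i] = row[f"cov_{PARAM_NAMES[i]}_{PARAM_NAMES[j]}"]
        library[row["step_type"]] = StepStiffness(
            step_type=row["step_type"],
            mean=mean,
            covariance=cov,
            temperature_K=float(row["temperature_K"]),
        )
    return library


def write_structure(path, structure: np.ndarray, step_types: list[str]) -> None:
    """Per-step six helical parameters of one circle structure."""
    structure = np.asarray(structure, dtype=float)
    with open(path, "w") as fh:
        fh.write("# per-step helical parameters (Angstrom / degrees)\n")
        fh.write("step\tstep_type\t" + "\t".join(PARAM_NAMES) + "\n")
        for i, (row, t) in enumerate(zip(structure, step_types), start=1):
            fh.write(f"{i}\t{t}\t" + "\t".join(f"{v:.8e}" for v in row) + "\n")


def read_structure(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    structure = df[list(PARAM_NAMES)].to_numpy(dtype=float)
    return structure, df["step_type"].astype(str).tolist()
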