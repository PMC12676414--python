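"""File formats and configuration.

Body models live in a small documented YAML schema (the package's only
model-input path); trajectories, keypoints and rollouts use HDF5 with fixed
group layouts; run configuration is a strict (unknown-key-rejecting) YAML
document. One root seed fans out to per-component seeds through
``numpy.random.SeedSequence`` so no stochastic entry point shares hidden
global state.

Body-model YAML schema (version 1)::

    schema_version: 1
    name: quadruped
    bodies:              # parent-first; parent -1 marks the root
      - {name: torso, parent: -1, offset: [0, 0, 0]}
    joints:              # kind: free | hinge | slide
      - {name: root, kind: free, body: 0}
      - {name: hip, kind: hinge, body: 1, axis: [0, 1, 0], range: [-1.2, 1.2]}
    sites:
      - {keypoint: head, body: 0, offset: [0.13, 0, 0.04]}
    end_effectors: [2, 4]
    actuators:
      - {label: hip_act, joint: hip, tau_max: 1.0, v_max: 6.0}

Trajectory HDF5 layout: ``/qpos`` (T, 7+n), ``/qvel`` (T, 6+n), ``/sites``
(T, K, 3), ``/offsets`` (K, 3) with keypoint names and body ids, and
``/objective`` (T,); attributes carry the frame rate, schema version and
the source model hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from kinemimic.bodies import (
    Actuator,
    Body,
    JointSpec,
    KeypointSeries,
    KinematicTree,
    MarkerBinding,
    Pose,
)
from kinemimic.stac import StacOutput, finite_difference_velocities

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    pass


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return mapping[key]


# ----------------------------------------------------------------------
# body models


def model_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_body_model(tree: KinematicTree, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": tree.name,
        "bodies": [
            {"name": b.name, "parent": b.parent, "offset": [float(x) for x in b.offset]}
            for b in tree.bodies
        ],
        "joints": [
            {
                "name": j.name,
                "kind": j.kind,
                "body": j.body,
                **(
                    {"axis": [float(x) for x in j.axis], "range": [j.range[0], j.range[1]]}
                    if j.kind != "free"
                    else {}
                ),
            }
            for j in tree.joints
        ],
        "sites": [
            {"keypoint": s.keypoint_name, "body": s.body, "offset": [float(x) for x in s.offset]}
            for s in tree.sites
        ],
        "end_effectors": list(tree.end_effectors),
        "actuators": [
            {"label": a.label, "joint": a.joint, "tau_max": a.tau_max, "v_max": a.v_max}
            for a in tree.actuators
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_body_model(path: str | Path) -> KinematicTree:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise SchemaError(f"unparsable model file: {e}") from e
    if not isinstance(doc, dict):
        raise SchemaError("model file is not a mapping")
    version = _require(doc, "schema_version", "model")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version}")
    bodies = [
        Body(_require(b, "name", "body"), int(_require(b, "parent", "body")),
             np.asarray(_require(b, "offset", "body"), dtype=float))
        for b in _require(doc, "bodies", "model")
    ]
    joints = []
    for j in _require(doc, "joints", "model"):
        kind = _require(j, "kind", "joint")
        if kind == "free":
            joints.append(JointSpec(_require(j, "name", "joint"), "free", np.zeros(3),
                                    (0.0, 0.0), int(_require(j, "body", "joint"))))
        else:
            joints.append(
                JointSpec(
                    _require(j, "name", "joint"), kind,
                    np.asarray(_require(j, "axis", f"joint {j.get('name')}"), dtype=float),
                    tuple(_require(j, "range", f"joint {j.get('name')}")),
                    int(_require(j, "body", "joint")),
                )
            )
    sites = [
        MarkerBinding(_require(s, "keypoint", "site"), int(_require(s, "body", "site")),
                      np.asarray(_require(s, "offset", "site"), dtype=float))
        for s in doc.get("sites", [])
    ]
    actuators = [
        Actuator(_require(a, "label", "actuator"), _require(a, "joint", "actuator"),
                 float(a.get("tau_max", 1.0)), float(a.get("v_max", 4.0)))
        for a in doc.get("actuators", [])
    ]
    try:
        return KinematicTree(bodies, joints, sites, list(doc.get("end_effectors", [])),
                             actuators, name=doc.get("name", "tree"))
    except ValueError as e:
        raise SchemaError(str(e)) from e


# ----------------------------------------------------------------------
# trajectories


def write_trajectory(out: StacOutput, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("qpos", data=out.qpos)
        f.create_dataset("qvel", data=out.qvel)
        f.create_dataset("sites", data=out.sites)
        f.create_dataset("offsets", data=np.stack([o.offset for o in out.offsets])
                         if out.offsets else np.zeros((0, 3)))
        f.create_dataset("offset_bodies", data=np.array([o.body for o in out.offsets], dtype=int))
        names = [o.keypoint_name for o in out.offsets]
        f.create_dataset("offset_names", data=np.array(names, dtype=h5py.string_dtype()))
        f.create_dataset("objective", data=out.objective)
        f.attrs["rate"] = out.rate
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["model_hash"] = out.model_hash


def read_trajectory(path: str | Path) -> StacOutput:
    with h5py.File(path, "r") as f:
        for group in ("qpos", "qvel", "sites", "offsets", "objective"):
            if group not in f:
                raise SchemaError(f"trajectory file missing required group {group!r}")
        qpos = f["qpos"][:]
        qvel = f["qvel"][:]
        sites = f["sites"][:]
        off = f["offsets"][:]
        bodies = f["offset_bodies"][:] if "offset_bodies" in f else np.zeros(len(off), dtype=int)
        names = (
            [n.decode() if isinstance(n, bytes) else str(n) for n in f["offset_names"][:]]
            if "offset_names" in f
            else [f"kp{i}" for i in range(len(off))]
        )
        objective = f["objective"][:]
        rate = float(f.attrs["rate"])
        mhash = str(f.attrs.get("model_hash", ""))
    poses = [Pose.from_qpos(qpos[t]) for t in range(qpos.shape[0])]
    offsets = [MarkerBinding(n, int(b), o) for n, b, o in zip(names, bodies, off)]
    return StacOutput(poses, qpos, qvel, sites, offsets, objective, rate, mhash)


# ----------------------------------------------------------------------
# keypoints


def write_keypoints(series: KeypointSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("keypoints", data=series.values)
        f.create_dataset("names", data=np.array(series.names, dtype=h5py.string_dtype()))
        f.create_dataset("valid_mask", data=series.valid_mask)
        f.create_dataset("rate", data=series.rate)


def read_keypoints(path: str | Path) -> KeypointSeries:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_keypoints_csv(path)
    with h5py.File(path, "r") as f:
        for group in ("keypoints", "names", "rate"):
            if group not in f:
                raise SchemaError(f"keypoint file missing required group {group!r}")
        values = f["keypoints"][:]
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["names"][:]]
        rate = float(f["rate"][()])
        mask = f["valid_mask"][:] if "valid_mask" in f else None
    return KeypointSeries(values, rate, names, mask)


def read_keypoints_csv(path: str | Path, rate: float | None = None) -> KeypointSeries:
    """CSV import: header ``frame,<name>_x,<name>_y,<name>_z,...`` with one
    row per frame; a ``# rate: <Hz>`` comment line may carry the frame rate."""
    lines = Path(path).read_text().strip().splitlines()
    if rate is None:
        rate = 50.0
        for ln in lines:
            if ln.startswith("#") and "rate:" in ln:
                rate = float(ln.split("rate:")[1])
    rows = [ln for ln in lines if not ln.startswith("#")]
    header = rows[0].split(",")
    cols = header[1:]
    if len(cols) % 3:
        raise SchemaError("keypoint CSV needs _x,_y,_z column triplets")
    names = [c[:-2] for c in cols[::3]]
    data = np.array([[float(v) for v in r.split(",")[1:]] for r in rows[1:]])
    return KeypointSeries(data.reshape(len(rows) - 1, len(names), 3), rate, names)


def stac_output_from_arrays(qpos: np.ndarray, rate: float) -> StacOutput:
    """Wrap a bare qpos trajectory (e.g. scripted clips) as a StacOutput."""
    qpos = np.asarray(qpos, dtype=float)
    poses = [Pose.from_qpos(qpos[t]) for t in range(qpos.shape[0])]
    qvel = finite_difference_velocities(qpos, rate)
    T = qpos.shape[0]
    return StacOutput(poses, qpos, qvel, np.zeros((T, 0, 3)), [], np.zeros(T), rate)


# ----------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Composed run configuration; unknown keys are rejected on load."""

    model_path: str = ""
    seed: int = 0
    out_dir: str = "runs"
    stac: dict = field(default_factory=dict)
    env: dict = field(default_factory=dict)
    reward: dict = field(default_factory=dict)
    termination: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    bowl: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise SchemaError("run config is not a mapping")
        known = set(RunConfig.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**doc)


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Fan a root seed out to n component seeds (documented splitting rule:
    SeedSequence.spawn, truncated below 2**31)."""
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(root_seed).spawn(n)]
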