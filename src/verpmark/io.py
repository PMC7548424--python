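"""Cohort container I/O (HDF5) plus manifest and report serialization."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .data import EpochSet, OcularComponents, ParticipantMeta
from .montage import standard_montage

__all__ = [
    "save_cohort",
    "load_cohort",
    "write_manifest",
    "save_json",
    "load_json",
    "artifact_hash",
]


def save_cohort(path, cohort) -> None:
    """Write a simulated cohort (epochs, events, ocular sources) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for meta, epochs, ocular in cohort:
            g = f.create_group(meta.pid)
            g.attrs["group"] = meta.group
            g.attrs["age_years"] = meta.age_years
            g.attrs["responds_manually"] = meta.responds_manually
            if meta.age_at_surgery_months is not None:
                g.attrs["age_at_surgery_months"] = meta.age_at_surgery_months
                g.attrs["time_since_surgery_months"] = (
                    meta.time_since_surgery_months
                )
            g.create_dataset("data", data=epochs.data, compression="gzip")
            g.create_dataset("times", data=epochs.times)
            g.attrs["sfreq"] = epochs.sfreq
            ev = g.create_group("events")
            ev.create_dataset(
                "field", data=epochs.events["field"].astype("S8").to_numpy()
            )
            ev.create_dataset(
                "side", data=epochs.events["side"].astype("S8").to_numpy()
            )
            ev.create_dataset(
                "target", data=epochs.events["target"].to_numpy(dtype=bool)
            )
            ev.create_dataset(
                "response_ms",
                data=epochs.events["response_ms"].to_numpy(dtype=float),
            )
            g.create_dataset("keep", data=epochs.keep)
            oc = g.create_group("ocular")
            for name in ("blink", "saccade"):
                src = getattr(ocular, name)
                topo = getattr(ocular, f"{name}_topo")
                if src is not None:
                    oc.create_dataset(name, data=src, compression="gzip")
                    oc.create_dataset(f"{name}_topo", data=topo)


def load_cohort(path):
    """Inverse of :func:`save_cohort`; montage is rebuilt from the standard."""
    montage = standard_montage()
    cohort = []
    with h5py.File(path, "r") as f:
        for pid in sorted(f.keys()):
            g = f[pid]
            meta = ParticipantMeta(
                pid=pid,
                group=g.attrs["group"],
                age_years=float(g.attrs["age_years"]),
                age_at_surgery_months=(
                    float(g.attrs["age_at_surgery_months"])
                    if "age_at_surgery_months" in g.attrs else None
                ),
                time_since_surgery_months=(
                    float(g.attrs["time_since_surgery_months"])
                    if "time_since_surgery_months" in g.attrs else None
                ),
                responds_manually=bool(g.attrs["responds_manually"]),
            )
            events = pd.DataFrame(
                {
                    "field": [s.decode() for s in g["events/field"][()]],
                    "side": [s.decode() for s in g["events/side"][()]],
                    "target": g["events/target"][()],
                    "response_ms": g["events/response_ms"][()],
                }
            )
            epochs = EpochSet(
                data=g["data"][()], times=g["times"][()],
                sfreq=float(g.attrs["sfreq"]), montage=montage,
                events=events, keep=g["keep"][()], pid=pid,
            )
            oc = g["ocular"]
            ocular = OcularComponents(
                blink=oc["blink"][()] if "blink" in oc else None,
                blink_topo=oc["blink_topo"][()] if "blink_topo" in oc else None,
                saccade=oc["saccade"][()] if "saccade" in oc else None,
                saccade_topo=(
                    oc["saccade_topo"][()] if "saccade_topo" in oc else None
                ),
                times=epochs.times,
            )
            cohort.append((meta, epochs, ocular))
    return cohort


def write_manifest(path, design, seed: int, cohort) -> None:
    """YAML manifest listing participants, groups and the master seed."""
    manifest = {
        "label": design.label,
        "seed": int(seed),
        "sfreq": float(design.sfreq),
        "trials_per_condition": int(design.trials_per_condition),
        "participants": [
            {"pid": meta.pid, "group": meta.group,
             "age_years": round(float(meta.age_years), 2)}
            for meta, _, _ in cohort
        ],
    }
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonify))


def load_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def artifact_hash(obj) -> str:
    """Stable content hash for frozen model/threshold artifacts."""
    payload = json.dumps(obj, sort_keys=True, default=_jsonify).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
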