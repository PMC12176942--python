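"""Bit-stable on-disk container for event datasets.

Two interchangeable backends share the same field names:

* **HDF5** (default, any suffix other than ``.npz``): one group per event
  under ``events/``, one dataset per modality, string attributes for the
  label and scalar fields, JSON-encoded provenance on the root.
* **NPZ** (suffix ``.npz``): flat archive with ``e<index>/<field>`` keys.

Both carry the schema tag ``sporoclass-events-v1`` and round-trip datasets
bit-exactly (array dtypes and values, label strings, event order, absence
flags for missing holography images, provenance metadata).
"""

from __future__ import annotations

import json
import os
from typing import Union

import h5py
import numpy as np

from .events import EventDataset, PolenoEvent, RapidEEvent, SchemaError

__all__ = ["SCHEMA_VERSION", "write_events", "read_events"]

SCHEMA_VERSION = "sporoclass-events-v1"

_POLENO_ARRAYS = ("image_a", "image_b", "fluorescence")
_RAPIDE_ARRAYS = ("scattering", "spectrum", "lifetime", "infrared")


def write_events(dataset: EventDataset, path: Union[str, os.PathLike]) -> str:
    """Serialize ``dataset`` to ``path``; returns the path written.

    The dataset is validated first; the backend is chosen by suffix
    (``.npz`` -> NPZ, anything else -> HDF5).
    """
    dataset.validate()
    path = os.fspath(path)
    if path.endswith(".npz"):
        _write_npz(dataset, path)
    else:
        _write_hdf5(dataset, path)
    return path


def read_events(path: Union[str, os.PathLike]) -> EventDataset:
    """Load an event dataset written by :func:`write_events`.

    Raises :class:`SchemaError` naming the first violation if the container
    is malformed (wrong schema tag, bad shapes, unknown labels...).
    """
    path = os.fspath(path)
    ds = _read_npz(path) if path.endswith(".npz") else _read_hdf5(path)
    ds.validate()
    return ds


# ---------------------------------------------------------------- HDF5

def _write_hdf5(dataset: EventDataset, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["instrument"] = dataset.instrument
        f.attrs["provenance"] = json.dumps(dataset.provenance)
        grp = f.create_group("events")
        for i, ev in enumerate(dataset.events):
            g = grp.create_group(f"{i:06d}")
            if isinstance(ev, PolenoEvent):
                for name in _POLENO_ARRAYS:
                    arr = getattr(ev, name)
                    if arr is not None:
                        g.create_dataset(name, data=np.asarray(arr))
                g.attrs["channel_position_um"] = float(ev.channel_position_um)
            else:
                for name in _RAPIDE_ARRAYS:
                    g.create_dataset(name, data=np.asarray(getattr(ev, name)))
            if ev.label is not None:
                g.attrs["label"] = ev.label


def _read_hdf5(path: str) -> EventDataset:
    with h5py.File(path, "r") as f:
        schema = f.attrs.get("schema")
        if schema != SCHEMA_VERSION:
            raise SchemaError(f"unknown schema tag {schema!r} in {path}")
        instrument = str(f.attrs["instrument"])
        provenance = json.loads(f.attrs.get("provenance", "{}"))
        events: list = []
        grp = f.get("events")
        keys = sorted(grp.keys()) if grp is not None else []
        for key in keys:
            g = grp[key]
            label = str(g.attrs["label"]) if "label" in g.attrs else None
            if instrument == "poleno":
                events.append(
                    PolenoEvent(
                        image_a=g["image_a"][()] if "image_a" in g else None,
                        image_b=g["image_b"][()] if "image_b" in g else None,
                        channel_position_um=float(g.attrs["channel_position_um"]),
                        fluorescence=g["fluorescence"][()],
                        label=label,
                    )
                )
            else:
                events.append(
                    RapidEEvent(
                        scattering=g["scattering"][()],
                        spectrum=g["spectrum"][()],
                        lifetime=g["lifetime"][()],
                        infrared=g["infrared"][()],
                        label=label,
                    )
                )
    return EventDataset(events, instrument, provenance)  # type: ignore[arg-type]


# ----------------------------------------------------------------- NPZ

def _write_npz(dataset: EventDataset, path: str) -> None:
    payload: dict[str, np.ndarray] = {
        "__schema__": np.array(SCHEMA_VERSION),
        "__instrument__": np.array(dataset.instrument),
        "__provenance__": np.array(json.dumps(dataset.provenance)),
        "__n_events__": np.array(len(dataset.events)),
    }
    for i, ev in enumerate(dataset.events):
        pre = f"e{i:06d}/"
        names = _POLENO_ARRAYS if isinstance(ev, PolenoEvent) else _RAPIDE_ARRAYS
        for name in names:
            arr = getattr(ev, name)
            if arr is not None:
                payload[pre + name] = np.asarray(arr)
        if isinstance(ev, PolenoEvent):
            payload[pre + "channel_position_um"] = np.array(
                float(ev.channel_position_um)
            )
        if ev.label is not None:
            payload[pre + "label"] = np.array(ev.label)
    np.savez(path, **payload)


def _read_npz(path: str) -> EventDataset:
    with np.load(path, allow_pickle=False) as z:
        if "__schema__" not in z or str(z["__schema__"]) != SCHEMA_VERSION:
            raise SchemaError(f"unknown schema tag in {path}")
        instrument = str(z["__instrument__"])
        provenance = json.loads(str(z["__provenance__"]))
        n = int(z["__n_events__"])
        events: list = []
        for i in range(n):
            pre = f"e{i:06d}/"
            label = str(z[pre + "label"]) if pre + "label" in z else None
            if instrument == "poleno":
                events.append(
                    PolenoEvent(
                        image_a=z[pre + "image_a"] if pre + "image_a" in z else None,
                        image_b=z[pre + "image_b"] if pre + "image_b" in z else None,
                        channel_position_um=float(z[pre + "channel_position_um"]),
                        fluorescence=z[pre + "fluorescence"],
                        label=label,
                    )
                )
            else:
                events.append(
                    RapidEEvent(
                        scattering=z[pre + "scattering"],
                        spectrum=z[pre + "spectrum"],
                        lifetime=z[pre + "lifetime"],
                        infrared=z[pre + "infrared"],
                        label=label,
                    )
                )
    return EventDataset(events, instrument, provenance)  # type: ignore[arg-type]
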