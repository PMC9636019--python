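"""File formats and provenance for pipeline artifacts.

Tabular data travels as CSV (human-readable); large numeric arrays as
HDF5.  Every HDF5 artifact written by the pipeline embeds provenance
attributes: a hash of the generating configuration, the seed, and the
package version.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np

from . import __version__


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(h5: h5py.File, config: dict | None, seed: int | None):
    h5.attrs["package_version"] = __version__
    if config is not None:
        h5.attrs["config_hash"] = config_hash(config)
        h5.attrs["config_json"] = json.dumps(config, sort_keys=True, default=str)
    if seed is not None:
        h5.attrs["seed"] = int(seed)


def write_arrays(path, arrays: dict[str, np.ndarray],
                 config: dict | None = None, seed: int | None = None):
    """Write a dict of arrays to HDF5 with provenance attributes."""
    with h5py.File(path, "w") as h5:
        for name, arr in arrays.items():
            h5.create_dataset(name, data=np.asarray(arr))
        _write_provenance(h5, config, seed)


def read_arrays(path) -> tuple[dict[str, np.ndarray], dict]:
    """Read all datasets and attributes from an HDF5 artifact."""
    out, attrs = {}, {}
    with h5py.File(path, "r") as h5:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                out[name] = obj[()]
        h5.visititems(visit)
        attrs = dict(h5.attrs)
    return out, attrs


def write_skeleton_params(path, graph, layout, params, objective_trace=None,
                          poses=None, config=None, seed=None):
    arrays = {
        "bone_lengths": params.bone_lengths,
        "marker_offsets": params.marker_offsets,
    }
    if poses is not None:
        arrays["poses"] = poses
    if objective_trace is not None:
        arrays["objective_trace"] = np.asarray(objective_trace)
    with h5py.File(path, "w") as h5:
        for name, arr in arrays.items():
            h5.create_dataset(name, data=np.asarray(arr))
        h5.create_dataset(
            "bone_names",
            data=np.array([b.name for b in graph.bones], dtype="S"),
        )
        h5.create_dataset(
            "marker_names", data=np.array(layout.names, dtype="S")
        )
        _write_provenance(h5, config, seed)


def read_skeleton_params(path, graph, layout):
    """Load learned skeleton parameters, checking name alignment."""
    from .skeleton import SkeletonParams

    data, attrs = read_arrays(path)
    names = [n.decode() for n in data["bone_names"]]
    if names != [b.name for b in graph.bones]:
        raise ValueError("bone names in file do not match the skeleton graph")
    mnames = [n.decode() for n in data["marker_names"]]
    if mnames != layout.names:
        raise ValueError("marker names in file do not match the layout")
    return SkeletonParams(data["bone_lengths"], data["marker_offsets"]), attrs
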