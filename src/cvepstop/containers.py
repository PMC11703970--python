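"""Single-file dataset container: a compressed named-array archive (.npz)
with a JSON metadata block, round-tripping every array bit-exactly."""

from __future__ import annotations

import json

import numpy as np

FORMAT_VERSION = "1"
_META_KEY = "_meta_json"

#: arrays a dataset archive must provide
DATASET_REQUIRED = ("trials", "labels", "codes")
#: arrays a calibrated-model archive must provide
MODEL_REQUIRED = ("w", "r", "templates")


class SchemaError(ValueError):
    """A mandatory array or metadata field is missing from an archive."""


def write_container(path: str, arrays: dict, meta: dict | None = None) -> None:
    """Write named arrays plus JSON metadata to a single compressed archive.

    A sidecar ``<path>.json`` with the metadata is written as well, for
    humans and external tools.
    """
    meta = dict(meta or {})
    meta.setdefault("format_version", FORMAT_VERSION)
    payload = {k: np.asarray(v) for k, v in arrays.items()}
    payload[_META_KEY] = np.array(json.dumps(meta, sort_keys=True))
    np.savez_compressed(path, **payload)
    sidecar = str(path)
    if not sidecar.endswith(".json"):
        sidecar = sidecar + ".json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_container(path: str, required: tuple[str, ...] = ()) -> tuple[dict, dict]:
    """Read back (arrays, meta); missing required arrays raise SchemaError
    naming the field."""
    with np.load(path, allow_pickle=False) as npz:
        arrays = {k: npz[k] for k in npz.files if k != _META_KEY}
        if _META_KEY in npz.files:
            meta = json.loads(str(npz[_META_KEY]))
        else:
            meta = {}
    for name in required:
        if name not in arrays:
            raise SchemaError(f"archive {path!r} is missing required array {name!r}")
    return arrays, meta


def dataset_to_arrays(ds) -> tuple[dict, dict]:
    """Flatten a SyntheticDataset into archive arrays + metadata."""
    arrays = {
        "trials": ds.trials,
        "labels": ds.labels,
        "codes": ds.codes.codes,
        "structures": np.stack([s.entries for s in ds.structures]),
        "gt_spatial_pattern": ds.ground_truth["spatial_pattern"],
        "gt_temporal_response": ds.ground_truth["temporal_response"],
        "gt_templates": ds.ground_truth["templates"],
    }
    meta = {
        "sample_rate": ds.config.sample_rate,
        "frame_rate": ds.codes.frame_rate,
        "n_classes": ds.config.n_classes,
        "modulated": bool(ds.codes.modulated),
        "response_len": ds.config.response_len,
        "gt_alpha": ds.ground_truth["alpha"],
        "gt_sigma": ds.ground_truth["sigma"],
        "gt_sigma_bg": ds.ground_truth["sigma_bg"],
        "config": ds.config.to_dict(),
    }
    return arrays, meta


def arrays_to_dataset(arrays: dict, meta: dict):
    """Rebuild a SyntheticDataset from archive contents."""
    from .codes import StimulusCodeSet, StructureMatrix
    from .simulate import SimConfig, SyntheticDataset

    config = SimConfig.from_dict(meta["config"])
    codes = StimulusCodeSet(
        arrays["codes"], float(meta["frame_rate"]), bool(meta["modulated"])
    )
    structures = [
        StructureMatrix(
            entries=e,
            response_len=int(meta["response_len"]),
            sample_rate=float(meta["sample_rate"]),
        )
        for e in arrays["structures"]
    ]
    ground_truth = {
        "spatial_pattern": arrays["gt_spatial_pattern"],
        "temporal_response": arrays["gt_temporal_response"],
        "templates": arrays["gt_templates"],
        "alpha": meta["gt_alpha"],
        "sigma": meta["gt_sigma"],
        "sigma_bg": meta["gt_sigma_bg"],
    }
    return SyntheticDataset(
        trials=arrays["trials"],
        labels=arrays["labels"].astype(int),
        codes=codes,
        structures=structures,
        ground_truth=ground_truth,
        config=config,
    )
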