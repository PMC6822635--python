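"""Trial-archive reading and writing.

The on-disk standard of this package is a directory holding a JSON
``manifest.json`` (format version, sampling rate, channel names, labels,
trial count, trial shape, payload format) plus the trial payload: either
one delimited-text matrix per trial (``trial_00000.csv`` ...,
locale-independent ``.`` decimals) or a single ``trials.npz`` container.
Text payloads round-trip to 1e-12; the binary container is bit-exact.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .exceptions import ArchiveFormatError, InvalidParameterError
from .preprocessing import TrialSet

__all__ = ["read_archive", "write_archive", "FORMAT_VERSION"]

FORMAT_VERSION = "1.0"
_PAYLOADS = ("csv", "npz")


def write_archive(ts: TrialSet, path, payload_format: str = "csv") -> None:
    """Write a :class:`TrialSet` as a manifest + payload directory."""
    if payload_format not in _PAYLOADS:
        raise InvalidParameterError(
            f"payload_format must be one of {_PAYLOADS}, got {payload_format!r}"
        )
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "fs": float(ts.fs),
        "channel_names": list(ts.channel_names),
        "labels": [lab.item() if hasattr(lab, "item") else lab
                   for lab in ts.labels],
        "n_trials": int(ts.n_trials),
        "shape": [int(ts.n_channels), int(ts.n_samples)],
        "payload_format": payload_format,
    }
    with open(path / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if payload_format == "csv":
        for i, X in enumerate(ts.trials):
            np.savetxt(path / f"trial_{i:05d}.csv", X, delimiter=",",
                       fmt="%.17g")
    else:
        np.savez(path / "trials.npz",
                 **{f"trial_{i:05d}": X for i, X in enumerate(ts.trials)})


def read_archive(path) -> TrialSet:
    """Read a trial archive back into a :class:`TrialSet`.

    Validation problems (missing trials, shape mismatches) are collected
    and reported together, naming the offending trial indices.
    """
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise ArchiveFormatError(f"missing manifest: {mpath}")
    try:
        with open(mpath, encoding="utf-8") as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ArchiveFormatError(f"manifest does not parse: {exc}") from exc
    for key in ("format_version", "fs", "labels", "n_trials", "shape",
                "payload_format"):
        if key not in manifest:
            raise ArchiveFormatError(f"manifest missing key {key!r}")
    n = int(manifest["n_trials"])
    shape = tuple(int(s) for s in manifest["shape"])
    fmt = manifest["payload_format"]
    if fmt not in _PAYLOADS:
        raise ArchiveFormatError(f"unknown payload format {fmt!r}")
    errors = []
    trials = []
    if fmt == "npz":
        zpath = path / "trials.npz"
        if not zpath.exists():
            raise ArchiveFormatError(f"missing payload container: {zpath}")
        with np.load(zpath) as z:
            for i in range(n):
                key = f"trial_{i:05d}"
                if key not in z:
                    errors.append(f"trial {i}: missing from container")
                    continue
                X = z[key]
                if X.shape != shape:
                    errors.append(f"trial {i}: shape {X.shape} != declared {shape}")
                    continue
                trials.append(X)
    else:
        for i in range(n):
            fpath = path / f"trial_{i:05d}.csv"
            if not fpath.exists():
                errors.append(f"trial {i}: missing file {fpath.name}")
                continue
            X = np.loadtxt(fpath, delimiter=",", ndmin=2)
            if X.shape != shape:
                errors.append(f"trial {i}: shape {X.shape} != declared {shape}")
                continue
            trials.append(X)
    if errors:
        raise ArchiveFormatError("archive validation failed:\n  "
                                 + "\n  ".join(errors))
    labels = np.asarray(manifest["labels"])
    if len(labels) != n:
        raise ArchiveFormatError(
            f"manifest declares {n} trials but lists {len(labels)} labels"
        )
    if n == 0:
        trials_arr = np.zeros((0,) + shape)
    else:
        trials_arr = np.stack(trials)
    return TrialSet(trials_arr, labels, float(manifest["fs"]),
                    list(manifest.get("channel_names") or []) or None)
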