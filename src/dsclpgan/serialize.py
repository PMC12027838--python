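"""Checkpoint archive helpers shared by the generator and discriminators.

A checkpoint is a single ``.npz`` archive holding every parameter array under
``param/<name>``, a JSON config snapshot, and a format-version string.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

CHECKPOINT_FORMAT = "dsclpgan-checkpoint-1"

__all__ = ["save_module", "load_arrays", "CHECKPOINT_FORMAT"]


def save_module(path, module, config) -> None:
    arrays = {f"param/{k}": v for k, v in module.state_dict().items()}
    arrays["__format__"] = np.array(CHECKPOINT_FORMAT)
    arrays["__config__"] = np.array(json.dumps(asdict(config)))
    np.savez(path, **arrays)


def load_arrays(path) -> tuple[dict, dict[str, np.ndarray]]:
    """Return (config dict, parameter dict) from a checkpoint archive."""
    with np.load(path, allow_pickle=False) as archive:
        fmt = str(archive["__format__"])
        if fmt != CHECKPOINT_FORMAT:
            raise ValueError(f"unsupported checkpoint format {fmt!r}")
        config = json.loads(str(archive["__config__"]))
        params = {
            k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")
        }
    return config, params
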