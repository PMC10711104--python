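"""Run artifacts: checkpoints (npz + JSON sidecar) and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .config import RunConfig, load_config
from .segnet import NetworkConfig, SegmentationModel, build_acunet

__all__ = [
    "content_hash",
    "load_checkpoint",
    "save_checkpoint",
    "write_manifest",
]


def content_hash(paths) -> str:
    """Deterministic sha256 over sorted file names and contents."""
    digest = hashlib.sha256()
    for path in sorted(Path(p) for p in paths):
        digest.update(path.name.encode())
        digest.update(path.read_bytes())
    return digest.hexdigest()


def save_checkpoint(model: SegmentationModel, path, run_config: RunConfig | None = None, **extra) -> None:
    """Write weights to ``path`` (.npz) and a JSON manifest alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {
        "network": model.config.as_dict(),
        "run": run_config.as_dict() if run_config is not None else None,
        **extra,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_checkpoint(path) -> SegmentationModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    net = dict(sidecar["network"])
    for key in ("decoder_widths", "aspp_rates"):
        net[key] = tuple(net[key])
    model = build_acunet(NetworkConfig(**net))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def write_manifest(out_dir, command: str, config: dict, seed: int, inputs=None, **outputs) -> Path:
    """One JSON manifest per run: config echo, seed, input hash, outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "input_hash": content_hash(inputs) if inputs else None,
        "outputs": outputs,
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
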