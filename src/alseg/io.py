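"""File formats for scenes, models, probability maps, and metrics.

A scene suite on disk is one directory per split (``train``, ``validation``,
``test``) holding ``scene_####.tif`` (multi-band float32 TIFF) and
``scene_####_mask.png`` (0/255) pairs, plus a top-level ``manifest.json``
recording generator parameters and per-scene seeds.  ``format="npz"``
stores each scene as a single compressed NPZ instead.  Mask and model
round trips are lossless; image round trips are exact at float32 precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .simulate import Scene, SceneSet

__all__ = [
    "write_scene_set",
    "read_scene_set",
    "write_probability_map",
    "read_probability_map",
    "write_mask",
    "read_mask",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config, for provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_probability_map(p: np.ndarray, path: str | Path) -> None:
    """Single-band float map, as .npy or float32 TIFF by extension."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(p, dtype=float))
    else:
        import tifffile

        tifffile.imwrite(path, np.asarray(p, dtype=np.float32))


def read_probability_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def _scene_stem(scene: Scene) -> str:
    return f"scene_{scene.scene_id:04d}"


def write_scene_set(scenes: SceneSet, root: str | Path, fmt: str = "tiff") -> Path:
    """Write a suite to disk; returns the root directory."""
    if fmt not in ("tiff", "npz"):
        raise ValueError(f"unknown format {fmt!r}")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for scene in scenes.scenes:
        sdir = root / scene.split
        sdir.mkdir(exist_ok=True)
        stem = _scene_stem(scene)
        if fmt == "tiff":
            import tifffile

            img_file = f"{scene.split}/{stem}.tif"
            photometric = "rgb" if scene.stack.shape[-1] == 3 else "minisblack"
            tifffile.imwrite(
                root / img_file, scene.stack.astype(np.float32), photometric=photometric
            )
            mask_file = f"{scene.split}/{stem}_mask.png"
            write_mask(scene.mask, root / mask_file)
        else:
            img_file = f"{scene.split}/{stem}.npz"
            np.savez_compressed(
                root / img_file, stack=scene.stack.astype(np.float32), mask=scene.mask
            )
            mask_file = None
        entries.append(
            {
                "id": scene.scene_id,
                "split": scene.split,
                "image": img_file,
                "mask": mask_file,
                "seed": scene.seed,
                "shape": list(scene.shape),
            }
        )
    manifest = {
        "format": fmt,
        "master_seed": scenes.master_seed,
        "params": scenes.params,
        "scenes": entries,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root


def read_scene_set(root: str | Path) -> SceneSet:
    root = Path(root)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {root}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed manifest at {manifest_path}: {exc}") from exc
    fmt = manifest.get("format", "tiff")
    scenes = []
    for entry in manifest["scenes"]:
        if fmt == "tiff":
            import tifffile

            stack = np.asarray(tifffile.imread(root / entry["image"]), dtype=float)
            mask = read_mask(root / entry["mask"])
        else:
            with np.load(root / entry["image"]) as npz:
                stack = np.asarray(npz["stack"], dtype=float)
                mask = np.asarray(npz["mask"], dtype=bool)
        scenes.append(
            Scene(
                stack=stack,
                mask=mask,
                split=entry["split"],
                scene_id=entry["id"],
                seed=entry.get("seed"),
            )
        )
    return SceneSet(
        scenes=scenes,
        params=manifest.get("params", {}),
        master_seed=manifest.get("master_seed"),
    )
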