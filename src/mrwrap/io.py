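"""Image readers/writers, dataset manifests, and the 80/20 split.

The interchange default is 16-bit grayscale PNG, which keeps quantization
error (1/65535) well below the tolerances used elsewhere; single-slice
NIfTI is supported for medical-imaging interoperability. All images are
returned as float64 in [0, 1] with the exact-zero background preserved —
no epsilon is ever injected, because the simulator's support pattern
relies on strict positivity.

A dataset manifest is a JSON document:

    {"schema_version": 1,
     "entries": [{"source": int, "clean_path": ..., "artifacted_path": ...,
                  "mask_path": ..., "d": int, "r": float, "side": str,
                  "level": int|null, "seed": int|null}, ...],
     "splits": {"<source>": "train"|"test"}}

Splits are assigned per SOURCE clean image, so all distortion levels of
one image land on the same side of the 80/20 split (no leakage).
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image as PILImage

from .phantom import PhantomSpec, derive_seeds, generate_phantom
from .simulator import SimulationSample, simulate_level

__all__ = [
    "read_image",
    "write_image",
    "write_sample",
    "save_manifest",
    "load_manifest",
    "split_dataset",
    "simulate_corpus",
]

SCHEMA_VERSION = 1


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".png"):
        return "png"
    raise ValueError(f"cannot infer image format from {path.name!r}")


def read_image(path, format: str | None = None) -> np.ndarray:
    """Read a 2-D grayscale image as float64 in [0, 1].

    8-bit PNG is divided by 255, 16-bit by 65535. NIfTI slices stored as
    integers are divided by the dtype maximum; float slices outside [0, 1]
    are min-max rescaled (zeros stay zero when the minimum is zero).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt == "png":
        with PILImage.open(path) as im:
            if im.mode == "L":
                return np.asarray(im, dtype=np.float64) / 255.0
            if im.mode in ("I", "I;16"):
                arr = np.asarray(im, dtype=np.float64)
                return arr / 65535.0
            raise ValueError(
                f"expected single-channel grayscale PNG, got mode {im.mode!r}"
            )
    if fmt == "nifti":
        img = nib.load(str(path))
        arr = np.squeeze(np.asanyarray(img.dataobj)).astype(np.float64)
        if arr.ndim != 2:
            raise ValueError(
                f"expected a single 2-D NIfTI slice, got shape {arr.shape}"
            )
        if np.issubdtype(img.get_data_dtype(), np.integer):
            return arr / np.iinfo(img.get_data_dtype()).max
        lo, hi = arr.min(), arr.max()
        if lo < 0.0 or hi > 1.0:
            if hi == lo:
                raise ValueError("constant out-of-range NIfTI slice cannot be rescaled")
            arr = (arr - lo) / (hi - lo)
        return arr
    raise ValueError(f"unknown format {fmt!r}")


def write_image(img: np.ndarray, path, format: str | None = None, bitdepth: int = 16):
    """Write a [0, 1] float image as 16/8-bit PNG or float32 NIfTI."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image must be normalized to [0, 1] before writing")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format or _detect_format(path)
    if fmt == "png":
        if bitdepth == 16:
            arr = np.round(img * 65535.0).astype(np.uint16)
            PILImage.fromarray(arr).save(path)
        elif bitdepth == 8:
            arr = np.round(img * 255.0).astype(np.uint8)
            PILImage.fromarray(arr, mode="L").save(path)
        else:
            raise ValueError(f"bitdepth must be 8 or 16, got {bitdepth}")
    elif fmt == "nifti":
        nib.save(nib.Nifti1Image(img.astype(np.float32), affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_sample(
    sample: SimulationSample, out_dir, stem: str, format: str = "png",
    source: int | None = None, seed: int | None = None,
) -> dict:
    """Write clean/artifacted/mask images of one sample; return a manifest entry."""
    out_dir = Path(out_dir)
    ext = ".png" if format == "png" else ".nii.gz"
    paths = {
        "clean_path": out_dir / f"{stem}_clean{ext}",
        "artifacted_path": out_dir / f"{stem}_artifacted{ext}",
        "mask_path": out_dir / f"{stem}_mask{ext}",
    }
    write_image(sample.clean, paths["clean_path"], format)
    write_image(sample.artifacted, paths["artifacted_path"], format)
    write_image(sample.artifact_mask.astype(np.float64), paths["mask_path"], format)
    return {
        **{k: str(v) for k, v in paths.items()},
        "d": sample.d,
        "r": sample.r,
        "side": sample.side,
        "level": sample.level,
        "seed": seed,
        "source": source,
    }


def save_manifest(entries: list[dict], path, splits: dict | None = None) -> None:
    doc = {"schema_version": SCHEMA_VERSION, "entries": entries}
    if splits is not None:
        doc["splits"] = {str(k): v for k, v in splits.items()}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_manifest(path, check_files: bool = True) -> dict:
    """Load and validate a manifest; missing referenced files are an error."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported manifest schema: {doc.get('schema_version')}")
    if check_files:
        for e in doc["entries"]:
            for key in ("clean_path", "artifacted_path", "mask_path"):
                if not Path(e[key]).exists():
                    raise FileNotFoundError(f"manifest references missing file {e[key]}")
    return doc


def split_dataset(manifest: dict, train_fraction: float = 0.8, seed: int = 0) -> dict:
    """Assign train/test per source clean image at the given fraction.

    All entries sharing a ``source`` id receive the same assignment, so no
    clean image contributes to both splits. Deterministic under ``seed``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    entries = manifest["entries"]
    if not entries:
        raise ValueError("manifest has no entries")
    sources = sorted({e["source"] for e in entries}, key=str)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sources))
    n_train = int(round(train_fraction * len(sources)))
    splits = {}
    for rank, idx in enumerate(order):
        splits[str(sources[idx])] = "train" if rank < n_train else "test"
    return {**manifest, "splits": splits}


def simulate_corpus(
    n_sources: int,
    levels: tuple[int, ...] = (1, 2, 3, 4, 5),
    phantom_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> tuple[list[SimulationSample], list[int]]:
    """Generate an in-memory corpus: each phantom simulated at every level.

    Returns the samples and a parallel list of source indices (one source
    per phantom; n_sources × len(levels) samples in total).
    """
    spec = PhantomSpec() if phantom_spec is None else phantom_spec
    phantom_seeds = derive_seeds(seed, n_sources)
    level_seeds = derive_seeds(seed + 1, n_sources * len(levels))
    samples: list[SimulationSample] = []
    sources: list[int] = []
    k = 0
    for i, ps in enumerate(phantom_seeds):
        img = generate_phantom(replace(spec, seed=ps))
        for level in levels:
            samples.append(simulate_level(img, level, seed=level_seeds[k]))
            sources.append(i)
            k += 1
    return samples, sources
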