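"""Readers and writers for stacks, calibration bundles, masks, graphs and
feature tables.

Stacks are stored as multi-page TIFF (one page per band) or as a directory
of per-band 16-bit PNGs, in both cases next to a ``manifest.json`` naming
band order, wavelengths and roles.  Calibration bundles are a directory
with a ``bundle.json`` (intrinsics row-major, distortion k1,k2,p1,p2,k3,
mm/px) plus white/dark reference stacks.  Feature records go to CSV with a
JSON sidecar of run metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .calibrate import CalibrationBundle, ValidationError
from .features import FEATURE_COLUMNS
from .stack import BandInfo, FormatError, MultispectralStack

MANIFEST_NAME = "manifest.json"


def _manifest_dict(stack: MultispectralStack, extra: dict | None = None) -> dict:
    d = {
        "bands": [
            {"index": i, "wavelength_nm": b.wavelength_nm, "role": b.role}
            for i, b in enumerate(stack.manifest)
        ],
        "dtype": str(stack.data.dtype),
    }
    if extra:
        d.update(extra)
    return d


def _manifest_from_dict(d: dict) -> list[BandInfo]:
    bands = sorted(d["bands"], key=lambda x: x["index"])
    return [BandInfo(b["wavelength_nm"], b["role"]) for b in bands]


def write_stack(stack: MultispectralStack, path: str | Path, *, extra_meta: dict | None = None) -> Path:
    """Write a stack as multi-page TIFF (``*.tif``) or a PNG16 directory.

    A ``manifest.json`` is written next to the TIFF (same stem) or inside
    the directory.  Integer stacks round-trip bit-exactly; float stacks are
    stored as float32 TIFF pages (PNG directories require integer data).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = stack.data
        if data.dtype.kind == "f":
            data = data.astype(np.float32)
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data, photometric="minisblack")
        manifest_path = path.with_suffix(".manifest.json")
        manifest_path.write_text(json.dumps(_manifest_dict(stack, extra_meta), indent=2))
        return path
    # PNG16 directory
    if stack.data.dtype.kind == "f":
        raise FormatError("PNG16 directories store integer counts; write float stacks as TIFF")
    path.mkdir(parents=True, exist_ok=True)
    for i, band in enumerate(stack.manifest):
        img = Image.fromarray(stack.data[i].astype(np.uint16))
        img.save(path / f"band_{i}_{int(band.wavelength_nm)}nm.png")
    (path / MANIFEST_NAME).write_text(json.dumps(_manifest_dict(stack, extra_meta), indent=2))
    return path


def read_stack(path: str | Path) -> MultispectralStack:
    """Read a stack written by :func:`write_stack` (TIFF or PNG16 directory)."""
    path = Path(path)
    if path.is_dir():
        manifest_file = path / MANIFEST_NAME
        if not manifest_file.exists():
            raise FormatError(f"no {MANIFEST_NAME} in {path}")
        meta = json.loads(manifest_file.read_text())
        manifest = _manifest_from_dict(meta)
        pages = []
        for i, band in enumerate(manifest):
            f = path / f"band_{i}_{int(band.wavelength_nm)}nm.png"
            if not f.exists():
                raise FormatError(f"manifest lists band {i} but {f.name} is missing")
            pages.append(np.asarray(Image.open(f), dtype=np.uint16))
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise FormatError(f"mixed band shapes in {path}: {sorted(shapes)}")
        return MultispectralStack(np.stack(pages), manifest)

    manifest_file = path.with_suffix(".manifest.json")
    if not manifest_file.exists():
        raise FormatError(f"no manifest {manifest_file.name} next to {path.name}")
    meta = json.loads(manifest_file.read_text())
    manifest = _manifest_from_dict(meta)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(manifest):
        raise FormatError(
            f"TIFF has {data.shape[0]} pages but manifest lists {len(manifest)} bands"
        )
    return MultispectralStack(data, manifest)


# ---------------------------------------------------------------------------
# calibration bundles


def write_calibration(bundle: CalibrationBundle, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_stack(bundle.white_ref, path / "white_ref.tif")
    write_stack(bundle.dark_ref, path / "dark_ref.tif")
    meta = {
        "intrinsic_matrix": np.asarray(bundle.intrinsic_matrix).tolist(),
        "distortion_coeffs": np.asarray(bundle.distortion_coeffs).tolist(),
        "mm_per_px": bundle.mm_per_px,
        "platform_distance_mm": bundle.platform_distance_mm,
    }
    (path / "bundle.json").write_text(json.dumps(meta, indent=2))
    return path


def read_calibration(path: str | Path) -> CalibrationBundle:
    """Read a calibration bundle directory; validates white > dark per band."""
    path = Path(path)
    meta_file = path / "bundle.json"
    if not meta_file.exists():
        raise FormatError(f"no bundle.json in {path}")
    meta = json.loads(meta_file.read_text())
    white = read_stack(path / "white_ref.tif")
    dark = read_stack(path / "dark_ref.tif")
    try:
        return CalibrationBundle(
            white_ref=white,
            dark_ref=dark,
            intrinsic_matrix=np.asarray(meta["intrinsic_matrix"], dtype=float),
            distortion_coeffs=np.asarray(meta["distortion_coeffs"], dtype=float),
            mm_per_px=float(meta["mm_per_px"]),
            platform_distance_mm=float(meta.get("platform_distance_mm", 0.0)),
        )
    except ValidationError:
        raise


# ---------------------------------------------------------------------------
# masks, graphs, feature tables


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Binary mask as an 8-bit PNG (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127


def write_label_map(labels: np.ndarray, path: str | Path) -> Path:
    """Integer section labels as a 16-bit PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(labels, dtype=np.uint16)).save(path)
    return path


def write_graph(graph_json: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(graph_json, indent=2))
    return path


def write_features(records: list[dict], path: str | Path, *, metadata: dict | None = None) -> Path:
    """Feature records to CSV (fixed leading column order) + JSON sidecar.

    An empty record list yields a header-only CSV with the canonical
    columns.  Extra keys (section means, venation features) are appended
    after the canonical block, sorted for stability.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if records:
        extra = sorted({k for r in records for k in r} - set(FEATURE_COLUMNS))
        cols = [c for c in FEATURE_COLUMNS] + extra
        df = pd.DataFrame(records).reindex(columns=cols)
    else:
        df = pd.DataFrame(columns=list(FEATURE_COLUMNS))
    df.to_csv(path, index=False, encoding="utf-8")
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(metadata or {}, indent=2, default=str))
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
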