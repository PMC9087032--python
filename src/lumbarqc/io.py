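"""File formats: grayscale images (PNG/TIFF), indexed label-mask PNGs,
threshold YAML and JSON reports, plus the provenance block every command
output carries."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .qc import CriterionResult, QCReport, QCThresholds
from .schema import GrayImage, LabelMask, Position, schema_for

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_report",
    "read_report",
    "load_thresholds",
    "save_thresholds",
    "provenance",
    "schema_manifest",
    "MASK_PALETTE",
]

# Fixed, versioned palette for indexed mask PNGs: index == schema label.
# Colors are for visual inspection only; the palette index is the data.
MASK_PALETTE: list[tuple[int, int, int]] = [
    (0, 0, 0),        # 0 background
    (230, 80, 80),    # 1
    (80, 180, 80),    # 2
    (80, 100, 230),   # 3
    (230, 200, 60),   # 4
    (200, 80, 200),   # 5
    (70, 200, 220),   # 6
    (240, 140, 50),   # 7
]


def read_image(path: str | Path,
               position: Position | str | None = None) -> GrayImage:
    """Read an 8/16-bit grayscale PNG or TIFF; intensities are preserved.

    RGB input is converted to luminance with a warning.  Row-major,
    origin top-left.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                im.load()
                if im.mode in ("RGB", "RGBA"):
                    warnings.warn(
                        f"{path.name}: RGB input converted to grayscale")
                    im = im.convert("L")
                elif im.mode == "P":
                    im = im.convert("L")
                arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        warnings.warn(f"{path.name}: multi-channel input averaged to grayscale")
        arr = arr.mean(axis=-1)
    return GrayImage(arr, position=position)


def write_image(image: GrayImage | np.ndarray, path: str | Path) -> None:
    """Write a grayscale image; float arrays in [0,1] are scaled to 16-bit."""
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    path = Path(path)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.round(np.clip(arr, 0.0, 1.0) * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
        return
    if arr.dtype == np.uint16:
        Image.fromarray(arr).save(path)  # 16-bit grayscale ("I;16")
    else:
        Image.fromarray(arr.astype(np.uint8)).save(path)


def read_mask(path: str | Path, position: Position | str) -> LabelMask:
    """Read an indexed PNG whose palette indices are schema labels.

    Labels outside the position's schema raise a validation error naming
    the offending values.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode != "P":
                if im.mode in ("L", "I", "I;16"):
                    arr = np.asarray(im)
                else:
                    raise ValueError(
                        f"mask must be an indexed or grayscale PNG, got mode "
                        f"{im.mode}")
            else:
                arr = np.asarray(im)
    except OSError as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    return LabelMask(arr.astype(np.int64), position=Position.parse(position))


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as an indexed PNG (palette index == label)."""
    arr = mask.labels
    if arr.max() > 255:
        raise ValueError("label values exceed 8-bit palette indices")
    im = Image.fromarray(arr.astype(np.uint8), mode="P")
    palette: list[int] = []
    for i in range(256):
        rgb = MASK_PALETTE[i] if i < len(MASK_PALETTE) else (i, i, i)
        palette.extend(rgb)
    im.putpalette(palette)
    im.save(Path(path))


# ---------------------------------------------------------------------------
# reports and thresholds

def write_report(report: QCReport, path: str | Path,
                 provenance_block: dict | None = None) -> None:
    """Serialize a QC report to JSON with stable key order."""
    d = report.to_dict()
    if provenance_block:
        d["provenance"] = provenance_block
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=False))


def read_report(path: str | Path) -> QCReport:
    d = json.loads(Path(path).read_text())
    criteria = [
        CriterionResult(name=c["name"], value=c["value"],
                        required=c["required"], passed=c["pass"],
                        detail=c.get("detail", {}))
        for c in d["criteria"]
    ]
    return QCReport(position=Position.parse(d["position"]), criteria=criteria,
                    qualified=d["qualified"],
                    failure_reasons=list(d["reasons"]))


def load_thresholds(path: str | Path) -> QCThresholds:
    d = yaml.safe_load(Path(path).read_text())
    return QCThresholds.from_dict(d or {})


def save_thresholds(th: QCThresholds, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(th.to_dict(), sort_keys=False))


def provenance(command: str, config: dict, seed: int | None) -> dict:
    """Machine-readable provenance: command, config hash, seed, version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "command": command,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }


def schema_manifest(position: Position | str) -> dict:
    """Label schema + palette, embedded in dataset/model manifests."""
    pos = Position.parse(position)
    return {
        "position": pos.value,
        "labels": {str(k): v for k, v in schema_for(pos).items()},
        "palette": [list(MASK_PALETTE[i]) for i in range(len(schema_for(pos)))],
    }
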