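"""Seeded synthetic lumbar-radiograph phantoms with ground-truth masks.

Real lumbar radiograph datasets with QC annotations are rarely shareable, so
this module renders geometric phantoms that reproduce exactly the properties
the quality criteria consume: a stack of vertebral bodies (with L3 carrying
its own label), spinous processes at a controllable horizontal offset within
the column, an L3 bilateral-shadow band of controllable relative area,
inferior articular processes at a controllable position (oblique), pelvis /
sacrum / foraminal structures that can be toggled off, plus additive noise
and contrast jitter.  Geometry is deterministic given the spec; only the
intensity noise uses the seed's random stream.

Every continuous control is expressed in the same normalized units the QC
engine measures, so each criterion can be driven in or out of range
independently and the generator's truth labels are threshold-consistent with
the engine by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .qc import QCThresholds
from .schema import GrayImage, LabelMask, Position, schema_for

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "truth_from_spec",
    "DEFECTS_BY_POSITION",
]

# Rendering intensities (arbitrary units in [0,1]); bone bright, lucencies dark.
_INTENSITY = {
    "background": 0.08,
    "vertebral_body": 0.72,
    "l3": 0.72,
    "spinous_process": 0.90,
    "pelvis": 0.58,
    "bilateral_shadow": 0.45,
    "outer_contour": 0.85,
    "intervertebral_foramen": 0.22,
    "sacral_vertebrae": 0.60,
    "inferior_articular": 0.88,
}

# How close (normalized units) a continuous control may sit to a threshold
# endpoint before the sample is flagged borderline; rasterization can move a
# measurement by about half a pixel, so near-boundary samples are excluded
# from round-trip statistics.
BORDERLINE_MARGIN = 0.01


@dataclass(frozen=True)
class PhantomSpec:
    """Controls for one synthetic radiograph.

    ``centre_offset`` and ``iap_offset`` are positions within the vertebral
    column bounding box (0 = left edge, 1 = right edge); ``shadow_ratio`` is
    the target bilateral-shadow area divided by the L3 area.
    """

    position: Position = Position.AP
    n_vertebrae: int = 7
    centre_offset: float = 0.5
    shadow_ratio: float = 0.08
    iap_offset: float = 0.315
    n_iap: int = 4
    show_pelvis: bool = True
    show_sacrum: bool = True
    show_foramen: bool = True
    show_spinous: bool = True
    curvature: float = 0.0
    image_size: tuple[int, int] = (256, 256)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", Position.parse(self.position))
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        if self.n_iap < 0:
            raise ValueError("n_iap must be >= 0")
        for name in ("centre_offset", "shadow_ratio", "iap_offset",
                     "noise_sd", "curvature"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or (name != "curvature" and v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (0.0 <= self.centre_offset <= 1.0):
            raise ValueError("centre_offset must lie in [0, 1]")
        if not (0.0 <= self.iap_offset <= 1.0):
            raise ValueError("iap_offset must lie in [0, 1]")
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image_size must be at least 64x64")


@dataclass
class PhantomSample:
    """A rendered phantom: image, ground-truth mask and criterion truth."""

    spec: PhantomSpec
    image: GrayImage
    mask: LabelMask
    truth: dict[str, bool]
    borderline: bool
    defects: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# truth labels, derived from the spec against the engine's thresholds

def truth_from_spec(
    spec: PhantomSpec, thresholds: QCThresholds | None = None
) -> tuple[dict[str, bool], bool]:
    """Per-criterion truth and a borderline flag, as pure functions of the spec."""
    th = thresholds or QCThresholds()
    truth: dict[str, bool] = {
        "number_of_spines": spec.n_vertebrae == th.n_spines_required,
    }
    near: list[bool] = []

    def _range_check(value: float, rng: tuple[float, float]) -> bool:
        near.append(min(abs(value - rng[0]), abs(value - rng[1])) < BORDERLINE_MARGIN)
        return th.in_range(value, rng)

    if spec.position in (Position.AP, Position.LATERAL):
        truth["bilateral_shadow_ratio"] = _range_check(
            spec.shadow_ratio, th.shadow_ratio_range)
    if spec.position is Position.AP:
        truth["spinous_process_position"] = spec.show_spinous and _range_check(
            spec.centre_offset, th.spinous_position_range)
        truth["pelvis_visible"] = spec.show_pelvis
    if spec.position is Position.LATERAL:
        truth["spinous_process_visible"] = spec.show_spinous
        truth["intervertebral_foramen_visible"] = spec.show_foramen
        truth["sacral_vertebrae_visible"] = spec.show_sacrum
    if spec.position is Position.OBLIQUE:
        truth["pelvis_visible"] = spec.show_pelvis
        count_ok = (spec.n_iap > th.min_iap_count if th.iap_count_strict
                    else spec.n_iap >= th.min_iap_count)
        pos_ok = spec.n_iap > 0 and _range_check(
            spec.iap_offset, th.iap_position_range)
        truth["dog_sign"] = count_ok and pos_ok

    truth["qualified"] = all(truth.values())
    return truth, any(near)


# ---------------------------------------------------------------------------
# rasterization helpers

def _fill_rect(mask: np.ndarray, r0: int, r1: int, c0: int, c1: int,
               label: int) -> None:
    h, w = mask.shape
    mask[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)] = label


def _fill_ellipse(mask: np.ndarray, rc: float, cc: float, rr: float,
                  cr: float, label: int) -> None:
    h, w = mask.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    inside = ((rows - rc) / rr) ** 2 + ((cols - cc) / cr) ** 2 <= 1.0
    mask[inside] = label


def _grow_shadow(mask: np.ndarray, l3_pix: np.ndarray, bg_label: int,
                 shadow_label: int, target: int) -> None:
    """Dilate outward from L3 through background until exactly ``target``
    pixels are painted with the shadow label; partial rings are filled in
    raster order for determinism."""
    from scipy import ndimage

    region = l3_pix.copy()
    painted = 0
    while painted < target:
        grown = ndimage.binary_dilation(region, structure=np.ones((3, 3), bool))
        ring = grown & ~region & (mask == bg_label)
        if not ring.any():
            break  # no background left to grow into
        coords = np.argwhere(ring)
        take = min(target - painted, len(coords))
        rr, cc = coords[:take, 0], coords[:take, 1]
        mask[rr, cc] = shadow_label
        painted += take
        region = grown


# ---------------------------------------------------------------------------
# the generator

def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom; bit-identical for identical specs."""
    h, w = spec.image_size
    pos = spec.position
    schema = schema_for(pos)
    name_to_label = {v: k for k, v in schema.items()}
    mask = np.zeros((h, w), dtype=np.uint8)

    # outer contour: thin body-outline frame (AP and lateral schemas only)
    if "outer_contour" in name_to_label:
        lbl = name_to_label["outer_contour"]
        inset = max(2, int(0.02 * min(h, w)))
        t = 2
        _fill_rect(mask, inset, inset + t, inset, w - inset, lbl)
        _fill_rect(mask, h - inset - t, h - inset, inset, w - inset, lbl)
        _fill_rect(mask, inset, h - inset, inset, inset + t, lbl)
        _fill_rect(mask, inset, h - inset, w - inset - t, w - inset, lbl)

    # vertebral column: n stacked pixel-aligned rectangles
    n = spec.n_vertebrae
    top, bottom = 0.06 * h, 0.78 * h
    pitch = (bottom - top) / n
    body_h = 0.82 * pitch
    body_w = {"anteroposterior": 0.30, "lateral": 0.26, "oblique": 0.28}[pos.value] * w
    l3_index = n - 3 if n >= 3 else None
    v_label = name_to_label["vertebral_body"]
    l3_label = name_to_label.get("l3")
    body_boxes: list[tuple[int, int, int, int]] = []
    for i in range(n):
        cy = top + (i + 0.5) * pitch
        cx = 0.5 * w
        if spec.curvature != 0.0 and n > 1:
            cx += spec.curvature * w * np.sin(np.pi * i / (n - 1))
        r0 = int(round(cy - body_h / 2))
        r1 = int(round(cy + body_h / 2))
        c0 = int(round(cx - body_w / 2))
        c1 = int(round(cx + body_w / 2))
        lbl = l3_label if (l3_label is not None and i == l3_index) else v_label
        _fill_rect(mask, r0, r1, c0, c1, lbl)
        body_boxes.append((r0, r1, c0, c1))

    # anatomy-relative reference frame: the column's tight bounding box
    col0 = min(b[2] for b in body_boxes)
    col1 = max(b[3] for b in body_boxes) - 1  # inclusive right edge
    col_w = col1 - col0

    # spinous processes: one ellipse per vertebra on the target centreline
    if spec.show_spinous and "spinous_process" in name_to_label:
        sp_label = name_to_label["spinous_process"]
        if pos is Position.LATERAL:
            # posterior (rightward) projections, clear of the bodies
            sp_w = 0.06 * w
            for r0, r1, c0, c1 in body_boxes:
                rc = (r0 + r1 - 1) / 2
                _fill_ellipse(mask, rc, c1 + 2 + sp_w / 2,
                              0.28 * body_h, sp_w / 2, sp_label)
        else:
            sp_c = col0 + spec.centre_offset * col_w
            for r0, r1, c0, c1 in body_boxes:
                rc = (r0 + r1 - 1) / 2
                _fill_ellipse(mask, rc, sp_c,
                              0.275 * body_h, 0.045 * w, sp_label)

    # inferior articular processes (oblique): a vertical run of round facets
    if pos is Position.OBLIQUE and spec.n_iap > 0:
        iap_label = name_to_label["inferior_articular"]
        iap_c = col0 + spec.iap_offset * col_w
        radius = min(0.030 * w, 0.33 * body_h)
        first = max(0, (n - spec.n_iap) // 2)
        for k in range(min(spec.n_iap, n)):
            r0, r1, _, _ = body_boxes[first + k]
            _fill_ellipse(mask, (r0 + r1 - 1) / 2, iap_c, radius, radius,
                          iap_label)

    # pelvis: trapezoid spanning the lower image
    if spec.show_pelvis and "pelvis" in name_to_label:
        p_label = name_to_label["pelvis"]
        pr0, pr1 = int(0.83 * h), int(0.95 * h)
        for r in range(pr0, pr1):
            f = (r - pr0) / max(1, pr1 - pr0)  # widen toward the bottom
            half = (0.22 + 0.18 * f) * w
            _fill_rect(mask, r, r + 1, int(0.5 * w - half), int(0.5 * w + half),
                       p_label)

    # sacrum (lateral): tapering block under the column
    if pos is Position.LATERAL and spec.show_sacrum:
        s_label = name_to_label["sacral_vertebrae"]
        sr0, sr1 = int(0.80 * h), int(0.93 * h)
        for r in range(sr0, sr1):
            f = (r - sr0) / max(1, sr1 - sr0)
            half = (0.13 - 0.06 * f) * w
            cx = 0.5 * w + 0.05 * w * f  # sacrum curves posteriorly
            _fill_rect(mask, r, r + 1, int(cx - half), int(cx + half), s_label)

    # intervertebral foramina (lateral): lucent ellipses between bodies
    if pos is Position.LATERAL and spec.show_foramen:
        f_label = name_to_label["intervertebral_foramen"]
        for i in range(n - 1):
            _, r1, c0, c1 = body_boxes[i]
            nr0 = body_boxes[i + 1][0]
            rc = (r1 + nr0 - 1) / 2
            _fill_ellipse(mask, rc, c1 + 2 + 0.025 * w,
                          max(2.0, 0.35 * (nr0 - r1) + 2), 0.022 * w, f_label)

    # bilateral shadow: exact pixel budget grown around L3
    if (l3_label is not None and l3_index is not None
            and spec.shadow_ratio > 0):
        l3_pix = mask == l3_label
        l3_area = int(l3_pix.sum())
        if l3_area > 0:
            target = int(round(spec.shadow_ratio * l3_area))
            _grow_shadow(mask, l3_pix, 0, name_to_label["bilateral_shadow"],
                         target)

    # intensity rendering: per-structure brightness, contrast jitter, noise
    rng = np.random.default_rng(spec.seed)
    img = np.full((h, w), _INTENSITY["background"], dtype=np.float64)
    for lbl, name in schema.items():
        if lbl == 0:
            continue
        img[mask == lbl] = _INTENSITY[name]
    gain = rng.uniform(0.9, 1.1)
    img = np.clip(img * gain + rng.normal(0.0, spec.noise_sd, size=(h, w)),
                  0.0, 1.0)

    truth, borderline = truth_from_spec(spec)
    return PhantomSample(
        spec=spec,
        image=GrayImage(img, position=pos),
        mask=LabelMask(mask, position=pos),
        truth=truth,
        borderline=borderline,
    )


# ---------------------------------------------------------------------------
# dataset generation

# Defect types applicable per projection; each flips exactly one criterion
# out of range (well clear of threshold boundaries).
DEFECTS_BY_POSITION: dict[Position, tuple[str, ...]] = {
    Position.AP: ("extra_vertebrae", "off_centre", "shadow", "missing_pelvis"),
    Position.LATERAL: ("extra_vertebrae", "shadow", "missing_spinous",
                       "missing_foramen", "missing_sacrum"),
    Position.OBLIQUE: ("extra_vertebrae", "missing_pelvis",
                       "bad_iap_position", "too_few_iaps"),
}


def _qualified_spec(position: Position, rng: np.random.Generator,
                    image_size: tuple[int, int],
                    noise_sd: float) -> PhantomSpec:
    return PhantomSpec(
        position=position,
        n_vertebrae=7,
        centre_offset=rng.uniform(0.44, 0.56),
        shadow_ratio=rng.uniform(0.03, 0.18),
        iap_offset=rng.uniform(0.285, 0.345),
        n_iap=int(rng.integers(3, 5)),
        image_size=image_size,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _apply_defect(spec: PhantomSpec, defect: str,
                  rng: np.random.Generator) -> PhantomSpec:
    if defect == "extra_vertebrae":
        return replace(spec, n_vertebrae=int(rng.integers(8, 10)))
    if defect == "off_centre":
        lo, hi = ((0.63, 0.75) if rng.random() < 0.5 else (0.25, 0.37))
        return replace(spec, centre_offset=rng.uniform(lo, hi))
    if defect == "shadow":
        return replace(spec, shadow_ratio=rng.uniform(0.24, 0.45))
    if defect == "missing_pelvis":
        return replace(spec, show_pelvis=False)
    if defect == "missing_spinous":
        return replace(spec, show_spinous=False)
    if defect == "missing_foramen":
        return replace(spec, show_foramen=False)
    if defect == "missing_sacrum":
        return replace(spec, show_sacrum=False)
    if defect == "bad_iap_position":
        lo, hi = ((0.40, 0.50) if rng.random() < 0.5 else (0.15, 0.24))
        return replace(spec, iap_offset=rng.uniform(lo, hi))
    if defect == "too_few_iaps":
        return replace(spec, n_iap=int(rng.integers(1, 3)))
    raise ValueError(f"unknown defect {defect!r}")


def generate_dataset(
    n: int,
    position: Position | str,
    qualified_fraction: float,
    seed: int,
    image_size: tuple[int, int] = (256, 256),
    noise_sd: float = 0.03,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with about ``n * qualified_fraction`` qualified.

    Unqualified samples carry one or (30% of the time) two defect types drawn
    uniformly from the projection's applicable set.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0.0 <= qualified_fraction <= 1.0):
        raise ValueError("qualified_fraction must lie in [0, 1]")
    position = Position.parse(position)
    rng = np.random.default_rng(seed)
    n_qualified = int(round(n * qualified_fraction))
    flags = np.zeros(n, dtype=bool)
    flags[:n_qualified] = True
    rng.shuffle(flags)

    samples: list[PhantomSample] = []
    defect_pool = DEFECTS_BY_POSITION[position]
    for is_qualified in flags:
        spec = _qualified_spec(position, rng, image_size, noise_sd)
        defects: list[str] = []
        if not is_qualified:
            k = 2 if rng.random() < 0.3 else 1
            defects = [str(d) for d in
                       rng.choice(defect_pool, size=min(k, len(defect_pool)),
                                  replace=False)]
            for d in defects:
                spec = _apply_defect(spec, d, rng)
        sample = generate_phantom(spec)
        sample.defects = defects
        samples.append(sample)
    return samples
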