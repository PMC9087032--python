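"""Rule-based quality assessment of lumbar radiograph segmentation masks.

Each projection has a fixed set of objective criteria; an image is qualified
only when every criterion for its projection passes:

* anteroposterior — exactly 7 vertebrae (T11–L5) in frame; bilateral-shadow
  area over L3 area within (0, 0.21); spinous-process centreline within
  (0.4, 0.6) of the column width (patient not rotated); pelvis visible.
* lateral — 7 vertebrae; shadow ratio in range; spinous processes,
  intervertebral foramina and sacral vertebrae visible.
* oblique — 7 vertebrae; pelvis visible; the "dog" sign: at least 3 inferior
  articular processes whose mean position along the vertebral column width
  falls within (0.265, 0.365).

Positions are measured in an anatomy-relative frame (the tight bounding box
of the vertebral-column labels) so that verdicts are invariant to collimation
and cropping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .schema import LabelMask, Position, column_labels_for

__all__ = [
    "QCThresholds",
    "CriterionResult",
    "QCReport",
    "count_vertebrae",
    "spinous_centreline_position",
    "bilateral_shadow_ratio",
    "structure_visible",
    "inferior_articular_position",
    "column_bounding_box",
    "assess",
]

# 8-connectivity for component labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class QCThresholds:
    """Objective criterion thresholds.

    ``min_component_area`` is the visibility floor in pixels; ``None`` means
    0.05% of the image area, resolved per mask.  All interval bounds are
    inclusive by default (``inclusive_bounds=False`` makes them strict).
    ``iap_count_strict`` switches the inferior-articular count rule from
    "at least 3" to "strictly more than 3".
    """

    n_spines_required: int = 7
    shadow_ratio_range: tuple[float, float] = (0.0, 0.21)
    spinous_position_range: tuple[float, float] = (0.4, 0.6)
    iap_position_range: tuple[float, float] = (0.265, 0.365)
    min_iap_count: int = 3
    min_component_area: int | None = None
    inclusive_bounds: bool = True
    iap_count_strict: bool = False

    def __post_init__(self) -> None:
        for name in ("shadow_ratio_range", "spinous_position_range",
                     "iap_position_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must be a finite interval with lo < hi")
        if self.n_spines_required < 1 or self.min_iap_count < 1:
            raise ValueError("counts must be positive")

    def resolve_min_area(self, mask_shape: tuple[int, int]) -> int:
        if self.min_component_area is not None:
            return int(self.min_component_area)
        return max(1, int(round(0.0005 * mask_shape[0] * mask_shape[1])))

    def in_range(self, value: float, rng: tuple[float, float]) -> bool:
        lo, hi = rng
        if self.inclusive_bounds:
            return lo <= value <= hi
        return lo < value < hi

    def to_dict(self) -> dict:
        return {
            "n_spines_required": self.n_spines_required,
            "shadow_ratio_range": list(self.shadow_ratio_range),
            "spinous_position_range": list(self.spinous_position_range),
            "iap_position_range": list(self.iap_position_range),
            "min_iap_count": self.min_iap_count,
            "min_component_area": self.min_component_area,
            "inclusive_bounds": self.inclusive_bounds,
            "iap_count_strict": self.iap_count_strict,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QCThresholds":
        kwargs = dict(d)
        for name in ("shadow_ratio_range", "spinous_position_range",
                     "iap_position_range"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)


@dataclass
class CriterionResult:
    """One measured criterion: name, value, what was required, verdict."""

    name: str
    value: float | int | None
    required: str
    passed: bool
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "value": self.value,
            "required": self.required,
            "pass": self.passed,
            **({"detail": self.detail} if self.detail else {}),
        }


@dataclass
class QCReport:
    """Per-criterion measurements and the overall qualified/unqualified verdict."""

    position: Position
    criteria: list[CriterionResult]
    qualified: bool
    failure_reasons: list[str]

    def criterion(self, name: str) -> CriterionResult:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "position": self.position.value,
            "criteria": [c.to_dict() for c in self.criteria],
            "qualified": self.qualified,
            "reasons": list(self.failure_reasons),
        }


def _components(pixels: np.ndarray, min_area: int) -> list[tuple[float, float, int]]:
    """8-connected components with area >= min_area as (row, col, area) centroids."""
    lab, n = ndimage.label(pixels, structure=_STRUCT8)
    out = []
    if n == 0:
        return out
    areas = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    centroids = ndimage.center_of_mass(pixels, lab, index=range(1, n + 1))
    for (r, c), a in zip(centroids, areas):
        if a >= min_area:
            out.append((float(r), float(c), int(a)))
    return out


def column_bounding_box(
    mask: LabelMask,
) -> tuple[int, int, int, int] | None:
    """Tight bounding box (r0, r1, c0, c1), inclusive, of the vertebral column.

    This is the anatomy-relative reference frame for normalized positions;
    None when no column pixels exist.
    """
    pix = mask.union_pixels(column_labels_for(mask.position))
    if not pix.any():
        return None
    rows = np.flatnonzero(pix.any(axis=1))
    cols = np.flatnonzero(pix.any(axis=0))
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def _norm_horizontal(col: float, bbox: tuple[int, int, int, int]) -> float:
    """Map a column coordinate to [0,1] across the reference-frame width."""
    _, _, c0, c1 = bbox
    if c1 == c0:
        return 0.5
    return (col - c0) / (c1 - c0)


def count_vertebrae(
    mask: LabelMask, thresholds: QCThresholds | None = None
) -> int:
    """Number of distinct vertebral bodies (T11–L5 should give 7).

    Counts 8-connected components of the vertebral-column labels with area at
    least the visibility floor; L3 carries its own label but is a vertebra
    and is included.
    """
    thresholds = thresholds or QCThresholds()
    pix = mask.union_pixels(column_labels_for(mask.position))
    min_area = thresholds.resolve_min_area(mask.shape)
    return len(_components(pix, min_area))


def spinous_centreline_position(
    mask: LabelMask, thresholds: QCThresholds | None = None
) -> float | None:
    """Normalized horizontal position of the spinous-process centreline.

    The centreline connects the centroids of all spinous-process components;
    its mean horizontal coordinate is normalized by the vertebral-column
    bounding-box width (0 = left edge, 1 = right edge).  A centred, unrotated
    patient gives ~0.5.  None when not measurable.
    """
    thresholds = thresholds or QCThresholds()
    try:
        pix = mask.structure_pixels("spinous_process")
    except ValueError:
        return None
    comps = _components(pix, thresholds.resolve_min_area(mask.shape))
    bbox = column_bounding_box(mask)
    if not comps or bbox is None:
        return None
    mean_col = float(np.mean([c for _, c, _ in comps]))
    return _norm_horizontal(mean_col, bbox)


def bilateral_shadow_ratio(
    mask: LabelMask, thresholds: QCThresholds | None = None
) -> float | None:
    """Bilateral-shadow area over L3 area (A/B); None when L3 is absent.

    A double contour at L3's endplates indicates patient rotation; its area
    relative to L3 quantifies how pronounced the artifact is.
    """
    try:
        shadow = int(mask.structure_pixels("bilateral_shadow").sum())
        l3 = int(mask.structure_pixels("l3").sum())
    except ValueError:
        return None
    if l3 == 0:
        return None
    return shadow / l3


def structure_visible(
    mask: LabelMask, structure: str, thresholds: QCThresholds | None = None
) -> bool:
    """True iff the structure's total area reaches the visibility floor."""
    thresholds = thresholds or QCThresholds()
    area = int(mask.structure_pixels(structure).sum())  # raises on unknown name
    return area >= thresholds.resolve_min_area(mask.shape)


def inferior_articular_position(
    mask: LabelMask, thresholds: QCThresholds | None = None
) -> tuple[float | None, int]:
    """(normalized position, count) of the inferior articular processes.

    Oblique view only.  The processes form the "front leg" of the Scottie
    dog; their mean horizontal centroid, normalized by the vertebral-column
    bounding-box width, locates the dog sign.  Position is None when no
    process is visible.
    """
    if mask.position is not Position.OBLIQUE:
        raise ValueError("inferior articular processes are measured on oblique views")
    thresholds = thresholds or QCThresholds()
    pix = mask.structure_pixels("inferior_articular")
    comps = _components(pix, thresholds.resolve_min_area(mask.shape))
    count = len(comps)
    bbox = column_bounding_box(mask)
    if count == 0 or bbox is None:
        return None, count
    mean_col = float(np.mean([c for _, c, _ in comps]))
    return _norm_horizontal(mean_col, bbox), count


def _fmt_range(rng: tuple[float, float]) -> str:
    return f"({rng[0]:g}, {rng[1]:g})"


def assess(mask: LabelMask, thresholds: QCThresholds | None = None) -> QCReport:
    """Evaluate every objective criterion for the mask's projection.

    Deterministic pure function of (mask, thresholds).  The overall verdict
    is the conjunction of all per-criterion verdicts.
    """
    th = thresholds or QCThresholds()
    pos = mask.position
    criteria: list[CriterionResult] = []

    n = count_vertebrae(mask, th)
    criteria.append(CriterionResult(
        name="number_of_spines",
        value=n,
        required=f"= {th.n_spines_required}",
        passed=n == th.n_spines_required,
    ))

    if pos in (Position.AP, Position.LATERAL):
        ratio = bilateral_shadow_ratio(mask, th)
        criteria.append(CriterionResult(
            name="bilateral_shadow_ratio",
            value=ratio,
            required=_fmt_range(th.shadow_ratio_range),
            passed=ratio is not None and th.in_range(ratio, th.shadow_ratio_range),
            detail={} if ratio is not None else {"reason": "L3 not measurable"},
        ))

    if pos is Position.AP:
        sp = spinous_centreline_position(mask, th)
        criteria.append(CriterionResult(
            name="spinous_process_position",
            value=sp,
            required=_fmt_range(th.spinous_position_range),
            passed=sp is not None and th.in_range(sp, th.spinous_position_range),
            detail={} if sp is not None else {"reason": "no spinous process found"},
        ))
        criteria.append(_visibility(mask, th, "pelvis"))

    if pos is Position.LATERAL:
        criteria.append(_visibility(mask, th, "spinous_process"))
        criteria.append(_visibility(mask, th, "intervertebral_foramen"))
        criteria.append(_visibility(mask, th, "sacral_vertebrae"))

    if pos is Position.OBLIQUE:
        criteria.append(_visibility(mask, th, "pelvis"))
        iap_pos, iap_count = inferior_articular_position(mask, th)
        count_ok = (iap_count > th.min_iap_count if th.iap_count_strict
                    else iap_count >= th.min_iap_count)
        pos_ok = iap_pos is not None and th.in_range(iap_pos, th.iap_position_range)
        cmp_sym = ">" if th.iap_count_strict else ">="
        criteria.append(CriterionResult(
            name="dog_sign",
            value=iap_pos,
            required=(f"count {cmp_sym} {th.min_iap_count} and position in "
                      f"{_fmt_range(th.iap_position_range)}"),
            passed=count_ok and pos_ok,
            detail={"iap_count": iap_count},
        ))

    failures = [
        f"{c.name}: measured {c.value if c.value is not None else 'not measurable'}, "
        f"required {c.required}"
        for c in criteria if not c.passed
    ]
    return QCReport(
        position=pos,
        criteria=criteria,
        qualified=all(c.passed for c in criteria),
        failure_reasons=failures,
    )


def _visibility(mask: LabelMask, th: QCThresholds, structure: str) -> CriterionResult:
    area = int(mask.structure_pixels(structure).sum())
    floor = th.resolve_min_area(mask.shape)
    return CriterionResult(
        name=f"{structure}_visible",
        value=area,
        required=f"area >= {floor} px",
        passed=area >= floor,
    )
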