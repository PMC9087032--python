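"""Label schemas and core containers for lumbar-spine radiograph QC.

A radiograph is taken in one of three standard projections (anteroposterior,
lateral, oblique), each with its own set of annotated anatomical structures.
Masks are 2-D integer grids whose nonzero values index structures in the
projection's schema.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Position",
    "LABEL_SCHEMAS",
    "COLUMN_LABELS",
    "GrayImage",
    "LabelMask",
    "schema_for",
    "column_labels_for",
]


class Position(str, enum.Enum):
    """The three standard lumbar radiograph projections."""

    AP = "anteroposterior"
    LATERAL = "lateral"
    OBLIQUE = "oblique"

    @classmethod
    def parse(cls, value: "Position | str") -> "Position":
        if isinstance(value, cls):
            return value
        v = str(value).strip().lower()
        aliases = {
            "ap": cls.AP,
            "anteroposterior": cls.AP,
            "frontal": cls.AP,
            "lat": cls.LATERAL,
            "lateral": cls.LATERAL,
            "oblique": cls.OBLIQUE,
            "obl": cls.OBLIQUE,
        }
        if v not in aliases:
            raise ValueError(
                f"unknown position {value!r}; expected one of "
                f"{sorted(set(aliases))}"
            )
        return aliases[v]


# Integer label -> structure name, per projection.  Index 0 is always
# background.  The anteroposterior view annotates the vertebral column,
# spinous processes, pelvis, L3 (kept separate because the bilateral-shadow
# criterion needs its area) and the L3 bilateral shadow, plus the patient's
# outer contour.  The lateral view swaps the pelvis for the intervertebral
# foramina and sacrum.  The oblique view annotates vertebrae, the inferior
# articular processes (the "Scottie dog" front leg) and the pelvis.
LABEL_SCHEMAS: dict[Position, dict[int, str]] = {
    Position.AP: {
        0: "background",
        1: "vertebral_body",
        2: "spinous_process",
        3: "pelvis",
        4: "l3",
        5: "bilateral_shadow",
        6: "outer_contour",
    },
    Position.LATERAL: {
        0: "background",
        1: "vertebral_body",
        2: "spinous_process",
        3: "l3",
        4: "bilateral_shadow",
        5: "outer_contour",
        6: "intervertebral_foramen",
        7: "sacral_vertebrae",
    },
    Position.OBLIQUE: {
        0: "background",
        1: "vertebral_body",
        2: "inferior_articular",
        3: "pelvis",
    },
}

# Labels that make up the vertebral column proper.  L3 carries its own label
# so its area can be measured, but it is still a vertebra: spine counting and
# the anatomy-relative reference frame use the union of these labels.
COLUMN_LABELS: dict[Position, tuple[str, ...]] = {
    Position.AP: ("vertebral_body", "l3"),
    Position.LATERAL: ("vertebral_body", "l3"),
    Position.OBLIQUE: ("vertebral_body",),
}


def schema_for(position: Position | str) -> dict[int, str]:
    return LABEL_SCHEMAS[Position.parse(position)]


def column_labels_for(position: Position | str) -> tuple[str, ...]:
    return COLUMN_LABELS[Position.parse(position)]


@dataclass
class GrayImage:
    """A 2-D grayscale intensity grid with its projection tag.

    ``pixels`` keeps the intensities as read (8/16-bit or float); network
    input normalization is a separate, explicit step.
    """

    pixels: np.ndarray
    position: Position | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if self.position is not None:
            self.position = Position.parse(self.position)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LabelMask:
    """Per-pixel integer anatomical labels under a projection's schema."""

    labels: np.ndarray
    position: Position
    schema: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = Position.parse(self.position)
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise ValueError("mask labels must be integers")
            self.labels = self.labels.astype(np.int64)
        if not self.schema:
            self.schema = dict(LABEL_SCHEMAS[self.position])
        self.validate()

    def validate(self) -> None:
        present = np.unique(self.labels)
        unknown = [int(v) for v in present if int(v) not in self.schema]
        if unknown:
            raise ValueError(
                f"mask contains labels {unknown} not in the "
                f"{self.position.value} schema {sorted(self.schema)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_of(self, structure: str) -> int:
        """Integer label for a structure name; KeyError-free explicit error."""
        for lbl, name in self.schema.items():
            if name == structure:
                return lbl
        raise ValueError(
            f"structure {structure!r} is not in the {self.position.value} "
            f"schema ({sorted(self.schema.values())})"
        )

    def structure_pixels(self, structure: str) -> np.ndarray:
        """Boolean mask of the structure's pixels."""
        return self.labels == self.label_of(structure)

    def union_pixels(self, structures: tuple[str, ...]) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=bool)
        for s in structures:
            try:
                out |= self.structure_pixels(s)
            except ValueError:
                continue
        return out
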