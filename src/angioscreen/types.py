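"""Core data containers shared across the pipeline.

Coordinates are (row, col), 0-based, y-down. Areas and lengths are in pixel
units unless a pixel size is attached, in which case conversion to µm happens
only at output time.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.draw import polygon2mask

# VesselMask label values
BACKGROUND = 0
THIN = 1
THICK = 2


class ParameterError(ValueError):
    """A configuration or call parameter is invalid."""


class EmptyNetworkError(ParameterError):
    """Growth parameters cannot produce any vessel (zero seeds / zero steps)."""


@dataclass(frozen=True)
class ChipGeometry:
    """Geometry of one chip: frame, tumor-compartment region and the central
    circular region ("glass hole") used as the density denominator.

    Parameters
    ----------
    shape
        Image size (rows, cols).
    center
        Center of the central circle, (row, col).
    radius
        Radius of the central circle in pixels.
    compartment
        Optional polygon vertices ((N, 2) array of (row, col)) delimiting the
        tumor compartment; ``None`` means the full frame.
    """

    shape: tuple[int, int] = (1024, 1024)
    center: tuple[float, float] = (512.0, 512.0)
    radius: float = 300.0
    compartment: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("center-circle radius must be > 0")
        r, c = self.center
        nr, nc = self.shape
        if not (0 <= r < nr and 0 <= c < nc):
            raise ParameterError("circle center must lie inside the frame")
        inside = self.compartment_mask()
        # circle center must belong to the compartment
        if not inside[int(round(r)), int(round(c))]:
            raise ParameterError("center circle must lie inside the compartment")

    def center_mask(self) -> np.ndarray:
        """Boolean mask of the central circle."""
        rr, cc = np.ogrid[: self.shape[0], : self.shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2

    def compartment_mask(self) -> np.ndarray:
        """Boolean mask of the tumor compartment (full frame if no polygon)."""
        if self.compartment is None:
            return np.ones(self.shape, dtype=bool)
        return polygon2mask(self.shape, np.asarray(self.compartment, dtype=float))


@dataclass
class ChipImage:
    """Single-channel intensity image with chip metadata."""

    data: np.ndarray
    bit_depth: int = 16
    pixel_size_um: Optional[float] = None
    geometry: Optional[ChipGeometry] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ParameterError("image must be a non-empty 2-D grid")
        if np.any(self.data < 0) or np.any(self.data > 2**self.bit_depth - 1):
            raise ParameterError("intensities must lie within the bit depth")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "ChipImage":
        return ChipImage(
            data=data,
            bit_depth=self.bit_depth,
            pixel_size_um=self.pixel_size_um,
            geometry=self.geometry,
        )


@dataclass
class VesselMask:
    """3-class label grid: 0 background, 1 thin vessel, 2 thick vessel."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ParameterError("mask must be 2-D")
        bad = ~np.isin(self.labels, (BACKGROUND, THIN, THICK))
        if bad.any():
            raise ParameterError("mask labels must be in {0, 1, 2}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def vessel(self) -> np.ndarray:
        return self.labels != BACKGROUND

    @property
    def thin(self) -> np.ndarray:
        return self.labels == THIN

    @property
    def thick(self) -> np.ndarray:
        return self.labels == THICK


@dataclass
class SkeletonNode:
    id: int
    kind: str  # "junction" | "endpoint" | "isolated"
    coordinate: tuple[float, float]  # centroid (row, col)
    pixels: np.ndarray  # (k, 2) int pixel coordinates


@dataclass
class SkeletonEdge:
    u: int
    v: int
    path: np.ndarray  # (k, 2) int path pixels (may be empty for direct contacts)
    length: float  # geometric length: axial steps 1, diagonal steps sqrt(2)


@dataclass
class SkeletonGraph:
    """Branch/junction graph of a 1-px skeleton."""

    nodes: list[SkeletonNode]
    edges: list[SkeletonEdge]
    shape: tuple[int, int]

    @property
    def n_junctions(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "junction")

    @property
    def n_endpoints(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "endpoint")

    @property
    def total_length(self) -> float:
        return float(sum(e.length for e in self.edges))

    def to_edge_table(self):
        import pandas as pd

        rows = []
        kinds = {n.id: n.kind for n in self.nodes}
        for i, e in enumerate(self.edges):
            rows.append(
                {
                    "edge": i,
                    "node_u": e.u,
                    "node_v": e.v,
                    "kind_u": kinds[e.u],
                    "kind_v": kinds[e.v],
                    "length_px": e.length,
                    "n_path_px": len(e.path),
                }
            )
        return pd.DataFrame(rows)


DESCRIPTOR_NAMES = (
    "explant_area",
    "thick_area",
    "thin_area",
    "total_area",
    "thick_density",
    "thin_density",
    "total_density",
    "n_junctions",
    "branching_index",
    "total_length",
    "avg_branch_length",
    "avg_width",
    "thick_total_area_ratio",
    "inout_total_ratio",
    "inout_thick_ratio",
)


@dataclass
class VesselDescriptors:
    """The 15 per-chip vascular organization descriptors.

    Areas are px², lengths px, densities are dimensionless (area divided by
    the center-circle area). Degenerate ratios (zero denominator on a
    non-empty mask) are NaN and listed in ``flags``; an empty mask yields all
    zeros with the ``"empty_mask"`` flag.
    """

    explant_area: float = 0.0
    thick_area: float = 0.0
    thin_area: float = 0.0
    total_area: float = 0.0
    thick_density: float = 0.0
    thin_density: float = 0.0
    total_density: float = 0.0
    n_junctions: float = 0.0
    branching_index: float = 0.0
    total_length: float = 0.0
    avg_branch_length: float = 0.0
    avg_width: float = 0.0
    thick_total_area_ratio: float = 0.0
    inout_total_ratio: float = 0.0
    inout_thick_ratio: float = 0.0
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        d.pop("flags")
        return d

    def to_um(self, pixel_size_um: float) -> dict[str, float]:
        """Convert to physical units (µm / µm²); counts and ratios unchanged."""
        s = pixel_size_um
        conv = {
            "explant_area": s**2, "thick_area": s**2, "thin_area": s**2,
            "total_area": s**2, "total_length": s, "avg_branch_length": s,
            "avg_width": s, "branching_index": 1 / s**2,
        }
        return {k: v * conv.get(k, 1.0) for k, v in self.as_dict().items()}
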