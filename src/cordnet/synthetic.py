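"""Synthetic cord-network images with exact planar-graph ground truth.

Endothelial cells plated on basement-membrane matrix self-organize into a
reticular mesh of bright cords.  No public raw time-lapse data exists for
this assay, so this module generates stand-in images whose topology is known
exactly: cords are the ridges of a Voronoi tessellation of random,
well-separated seed points, clipped to an interior margin of the frame.
Because a Voronoi diagram is planar by construction, the bounded faces of
the drawn graph (the "loops of connectivity" the downstream metric measures)
can be enumerated in closed form and their areas computed analytically.

Degradation of network complexity — the phenotype seen with serial cell
passage — is modelled as nested random edge dropout: each edge receives one
uniform mark, and dropout level ``d`` removes every edge whose mark falls
below ``d``.  An edge removed at a low level therefore stays removed at all
higher levels, which makes ground-truth face counts provably non-increasing
along a dropout series.

Corruption (multiplicative illumination gradient, additive Gaussian noise)
is applied after the geometry is fixed; the ground truth always describes
the retained, pre-noise geometry.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import networkx as nx
from scipy import ndimage as ndi
from scipy.spatial import Voronoi
from shapely.geometry import LineString
from shapely.ops import polygonize

__all__ = [
    "SyntheticNetworkSpec",
    "GroundTruth",
    "Face",
    "generate_network",
    "degrade_series",
    "timelapse_assembly",
]

_COORD_DECIMALS = 6  # vertex-merge tolerance for clipped geometry


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of one synthetic cord-network image.

    Attributes
    ----------
    image_height, image_width : int
        Frame size in pixels (>= 64).
    n_seeds : int
        Number of Voronoi generator points (>= 4).  More seeds give a finer
        mesh with more, smaller loops.
    cord_width : int
        Stroke thickness of drawn edges, pixels (>= 1).
    edge_dropout : float
        Fraction of edges removed, in [0, 1].  This is the degradation axis
        standing in for culture passage.
    noise_sd : float
        Standard deviation of additive Gaussian noise, 8-bit intensity units.
    illumination_amplitude : float
        Peak intensity drop of a smooth multiplicative shading ramp, 8-bit
        intensity units (0 disables shading).
    foreground_level, background_level : int
        Cord and background intensities before corruption (8-bit range).
    rng_seed : int
        Seed for all randomness; identical specs are bit-reproducible.
    margin : int
        Cords are clipped to the frame inset by this many pixels, so the
        mesh never touches the frame border and boundary cells stay open.
    """

    image_height: int = 384
    image_width: int = 384
    n_seeds: int = 25
    cord_width: int = 3
    edge_dropout: float = 0.0
    noise_sd: float = 6.0
    illumination_amplitude: float = 12.0
    foreground_level: int = 200
    background_level: int = 40
    rng_seed: int = 0
    margin: int = 8

    def validate(self) -> None:
        if self.n_seeds < 4:
            raise ValueError(f"n_seeds must be >= 4, got {self.n_seeds}")
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError(
                f"image dims must be >= 64, got "
                f"{self.image_height}x{self.image_width}"
            )
        if not 0.0 <= self.edge_dropout <= 1.0:
            raise ValueError(f"edge_dropout must be in [0,1], got {self.edge_dropout}")
        if self.cord_width < 1:
            raise ValueError(f"cord_width must be >= 1, got {self.cord_width}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.illumination_amplitude < 0:
            raise ValueError("illumination_amplitude must be >= 0")
        if not 0 <= self.background_level < self.foreground_level <= 255:
            raise ValueError(
                "need 0 <= background_level < foreground_level <= 255"
            )
        if self.margin < 1 or 2 * self.margin >= min(
            self.image_height, self.image_width
        ):
            raise ValueError("margin must be >= 1 and leave a nonempty interior")

    def replace(self, **kw) -> "SyntheticNetworkSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class Face:
    """One bounded face of the drawn planar graph."""

    area: float  # px^2, analytic (shoelace on the centerline polygon)
    cycle: list[int]  # vertex indices around the face, closed implicitly
    centroid: tuple[float, float]  # (row, col)


@dataclass
class GroundTruth:
    """Exact planar graph underlying a generated image.

    ``vertices`` are (row, col) sub-pixel positions; ``edges`` index into
    them; ``faces`` are the bounded faces of the retained edge set.  For
    every connected component drawn without crossings, the number of bounded
    faces it contributes equals ``E_c - V_c + 1``.
    """

    vertices: list[tuple[float, float]]
    edges: list[tuple[int, int]]
    faces: list[Face]
    n_components: int

    @property
    def face_count(self) -> int:
        return len(self.faces)

    @property
    def face_areas(self) -> list[float]:
        return [f.area for f in self.faces]

    @property
    def total_face_area(self) -> float:
        return float(sum(f.area for f in self.faces))

    @property
    def mean_face_area(self) -> float:
        return self.total_face_area / len(self.faces) if self.faces else 0.0

    def to_json(self) -> str:
        payload = {
            "vertices": [list(v) for v in self.vertices],
            "edges": [list(e) for e in self.edges],
            "faces": [
                {"area": f.area, "cycle": f.cycle, "centroid": list(f.centroid)}
                for f in self.faces
            ],
            "n_components": self.n_components,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            vertices=[tuple(v) for v in d["vertices"]],
            edges=[tuple(e) for e in d["edges"]],
            faces=[
                Face(area=f["area"], cycle=f["cycle"], centroid=tuple(f["centroid"]))
                for f in d["faces"]
            ],
            n_components=d["n_components"],
        )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent streams so point layout, dropout marks and noise never
    interact (dropout marks must not depend on the dropout level)."""
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(4)
    names = ("points", "dropout", "noise", "illumination")
    return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


def _sample_seed_points(spec: SyntheticNetworkSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform seeds with a minimum pairwise separation.

    The separation (0.7 of the mean nearest-neighbour spacing at this
    density) keeps every interior Voronoi cell wide enough that a cord of
    default width, after blurring, cannot fill a loop — matching the look of
    real cord meshes, whose loops are much wider than the cords.
    """
    lo_r, hi_r = spec.margin, spec.image_height - spec.margin
    lo_c, hi_c = spec.margin, spec.image_width - spec.margin
    area = (hi_r - lo_r) * (hi_c - lo_c)
    dmin = 0.7 * math.sqrt(area / spec.n_seeds)
    pts: list[np.ndarray] = []
    misses = 0
    while len(pts) < spec.n_seeds:
        cand = np.array(
            [rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)]
        )
        if all(np.hypot(*(cand - p)) >= dmin for p in pts):
            pts.append(cand)
            misses = 0
        else:
            misses += 1
            if misses > 200:  # relax packing if the draw got unlucky
                dmin *= 0.9
                misses = 0
    return np.array(pts)


def _clipped_voronoi_segments(
    spec: SyntheticNetworkSpec, points: np.ndarray
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Voronoi ridge segments lying entirely inside the margin box.

    Ridges that cross the box (and all infinite ridges) are dropped whole
    rather than clipped.  Clipping would place free cord tips on the box
    boundary at arbitrary mutual distances, and two tips closer than the
    cord width would fuse when rasterized, sealing a loop the vector
    ground truth considers open.  Keeping only whole interior ridges makes
    every free tip a true Voronoi vertex, which any nearby retained ridge
    shares, so the drawn raster realizes exactly the ground-truth topology.
    """
    vor = Voronoi(points)
    lo_r, lo_c = spec.margin, spec.margin
    hi_r = spec.image_height - spec.margin
    hi_c = spec.image_width - spec.margin

    def inside(v: np.ndarray) -> bool:
        return lo_r <= v[0] <= hi_r and lo_c <= v[1] <= hi_c

    segments = []
    for v1, v2 in vor.ridge_vertices:
        if v1 < 0 or v2 < 0:
            continue
        a, b = vor.vertices[v1], vor.vertices[v2]
        if not (inside(a) and inside(b)):
            continue
        if np.hypot(*(a - b)) < 1e-9:
            continue
        segments.append((tuple(a), tuple(b)))
    return segments


def _build_truth(
    segments: Sequence[tuple[tuple[float, float], tuple[float, float]]],
) -> GroundTruth:
    """Planar graph and bounded faces of a set of non-crossing segments."""
    key_to_idx: dict[tuple[float, float], int] = {}
    vertices: list[tuple[float, float]] = []

    def vid(pt: tuple[float, float]) -> int:
        key = (round(pt[0], _COORD_DECIMALS), round(pt[1], _COORD_DECIMALS))
        if key not in key_to_idx:
            key_to_idx[key] = len(vertices)
            vertices.append(key)
        return key_to_idx[key]

    edges = []
    for a, b in segments:
        i, j = vid(a), vid(b)
        if i != j:
            edges.append((i, j))

    faces: list[Face] = []
    if edges:
        lines = [LineString([vertices[i], vertices[j]]) for i, j in edges]
        for poly in polygonize(lines):
            cyc = [vid((c[0], c[1])) for c in poly.exterior.coords[:-1]]
            cen = poly.centroid
            faces.append(Face(area=float(poly.area), cycle=cyc,
                              centroid=(float(cen.x), float(cen.y))))
    faces.sort(key=lambda f: f.centroid)

    g = nx.Graph()
    g.add_edges_from(edges)
    n_comp = nx.number_connected_components(g)
    return GroundTruth(vertices=vertices, edges=edges, faces=faces,
                       n_components=n_comp)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _draw_edges(
    spec: SyntheticNetworkSpec,
    vertices: Sequence[tuple[float, float]],
    edges: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Boolean cord mask: centerlines rasterized then thickened to
    cord_width via an exact Euclidean distance threshold."""
    from skimage.draw import line as sk_line

    h, w = spec.image_height, spec.image_width
    center = np.zeros((h, w), dtype=bool)
    for i, j in edges:
        r0, c0 = (int(round(x)) for x in vertices[i])
        r1, c1 = (int(round(x)) for x in vertices[j])
        rr, cc = sk_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        center[rr[keep], cc[keep]] = True
    if spec.cord_width <= 1 or not center.any():
        return center
    radius = (spec.cord_width - 1) / 2.0
    dist = ndi.distance_transform_edt(~center)
    return dist <= radius


def _corrupt(
    spec: SyntheticNetworkSpec,
    cord_mask: np.ndarray,
    rngs: dict[str, np.random.Generator],
) -> np.ndarray:
    """Apply illumination shading and noise; return uint8 image."""
    img = np.where(cord_mask, float(spec.foreground_level),
                   float(spec.background_level))
    if spec.illumination_amplitude > 0:
        theta = rngs["illumination"].uniform(0, 2 * np.pi)
        rr, cc = np.mgrid[0 : spec.image_height, 0 : spec.image_width]
        proj = rr * math.cos(theta) + cc * math.sin(theta)
        proj = (proj - proj.min()) / max(np.ptp(proj), 1e-12)
        gain = 1.0 - (spec.illumination_amplitude / spec.foreground_level) * proj
        img = img * gain
    if spec.noise_sd > 0:
        img = img + rngs["noise"].normal(
            0.0, spec.noise_sd, size=img.shape
        )
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _layout(spec: SyntheticNetworkSpec):
    """Deterministic full edge layout plus per-edge dropout marks."""
    rngs = _child_rngs(spec.rng_seed)
    points = _sample_seed_points(spec, rngs["points"])
    segments = _clipped_voronoi_segments(spec, points)
    marks = rngs["dropout"].uniform(size=len(segments))
    return segments, marks, rngs


def generate_network(
    spec: SyntheticNetworkSpec,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one cord-network image and its exact ground truth.

    Edges whose dropout mark falls below ``spec.edge_dropout`` are removed
    before drawing; the ground truth describes the retained, pre-noise
    geometry (vertices, edges, bounded faces with analytic areas).
    """
    spec.validate()
    segments, marks, rngs = _layout(spec)
    retained = [s for s, m in zip(segments, marks) if m >= spec.edge_dropout]
    truth = _build_truth(retained)
    mask = _draw_edges(spec, truth.vertices, truth.edges)
    img = _corrupt(spec, mask, rngs)
    return img, truth


def degrade_series(
    spec: SyntheticNetworkSpec, dropout_levels: Sequence[float]
) -> list[tuple[np.ndarray, GroundTruth]]:
    """One image + truth per dropout level, with nested edge removal.

    Levels must be strictly increasing in [0, 1].  All levels share the
    spec's per-edge dropout marks, so the removed edge sets are nested and
    the ground-truth bounded-face count is non-increasing along the series.
    """
    levels = list(dropout_levels)
    if not levels:
        raise ValueError("dropout_levels must be non-empty")
    if any(not 0.0 <= d <= 1.0 for d in levels):
        raise ValueError("dropout levels must lie in [0,1]")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("dropout_levels must be strictly increasing")
    return [generate_network(spec.replace(edge_dropout=d)) for d in levels]


def timelapse_assembly(
    spec: SyntheticNetworkSpec,
    n_frames: int,
    return_truth: bool = False,
) -> list[np.ndarray] | list[tuple[np.ndarray, GroundTruth]]:
    """Frames of a growing network: frame k draws the first
    ``ceil(k / n_frames * |E|)`` retained edges, so cords appear
    progressively and the last frame equals ``generate_network``'s image.
    """
    spec.validate()
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    segments, marks, rngs = _layout(spec)
    retained = [s for s, m in zip(segments, marks) if m >= spec.edge_dropout]
    full_truth = _build_truth(retained)
    n_edges = len(full_truth.edges)

    # one shared corruption field: re-derive identical rng streams per frame
    frames = []
    for k in range(1, n_frames + 1):
        n_draw = math.ceil(k / n_frames * n_edges)
        prefix_truth = _build_truth(retained[:n_draw])
        mask = _draw_edges(spec, prefix_truth.vertices, prefix_truth.edges)
        frame_rngs = _child_rngs(spec.rng_seed)
        img = _corrupt(spec, mask, frame_rngs)
        frames.append((img, prefix_truth) if return_truth else img)
    return frames
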