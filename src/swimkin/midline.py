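"""Midlines from binary silhouettes: skeleton paths, arc length, curvature.

The fish's midline is recovered per frame by medial-axis skeletonization of
the silhouette, followed by a shortest-path walk through the skeleton pixel
graph between the skeleton endpoints nearest the nose and tail landmarks
(which automatically drops fin-induced side spurs), extension to the
landmark points themselves, resampling to a uniform arc-length grid, and a
light smoothing of x(s), y(s) — curvature is a second derivative, and raw
skeletons are pixel-quantized.

Signed curvature is computed as the derivative of the tangent angle with
respect to arc length; positive curvature is fish-left bending under the
raster image convention (origin top-left, y down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import map_coordinates
from scipy.signal import savgol_filter
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .exceptions import AmbiguousSilhouette, MidlineError

__all__ = [
    "Midline",
    "MidlineSequence",
    "CurvatureField",
    "extract_midline",
    "estimate_body_length",
    "curvature",
    "curvature_field",
]


@dataclass
class Midline:
    """Ordered head→tail midline points with arc-length parameterization."""

    points: np.ndarray  # (N, 2) pixel coordinates (x, y), nose first

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("midline points must be an (N, 2) array")
        if len(self.points) < 2:
            raise MidlineError("midline must have at least 2 points")

    @property
    def arclen(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclen[-1])

    @property
    def s_frac(self) -> np.ndarray:
        al = self.arclen
        return al / al[-1]

    def resample(self, n: int) -> "Midline":
        """Resample to ``n`` points equally spaced in arc length."""
        al = self.arclen
        target = np.linspace(0.0, al[-1], n)
        pts = np.column_stack(
            [np.interp(target, al, self.points[:, d]) for d in range(2)]
        )
        return Midline(pts)

    def point_at(self, s: float) -> np.ndarray:
        """Interpolated point at arc-length fraction ``s`` in [0, 1]."""
        sf = self.s_frac
        return np.array(
            [np.interp(s, sf, self.points[:, 0]), np.interp(s, sf, self.points[:, 1])]
        )


@dataclass
class MidlineSequence:
    """One midline per frame, at a common frame rate."""

    midlines: list
    fps: float
    body_length_px: float | None = field(default=None)

    def __post_init__(self):
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.body_length_px is None and len(self.midlines) >= 5:
            self.body_length_px = estimate_body_length(self)

    def __len__(self) -> int:
        return len(self.midlines)

    def __iter__(self):
        return iter(self.midlines)

    def __getitem__(self, i):
        return self.midlines[i]


@dataclass
class CurvatureField:
    """Signed curvature κ(s, t) on a body-fraction × frame grid.

    ``kappa`` is (n_frames, N) in px⁻¹; ``xy`` holds the matching midline
    coordinates so spatial distances between curvature features can be
    measured; ``s_frac`` is the common arc-length-fraction grid.
    """

    kappa: np.ndarray
    s_frac: np.ndarray
    xy: np.ndarray  # (n_frames, N, 2)
    fps: float

    def kappa_bl(self, body_length_px: float) -> np.ndarray:
        """Curvature in BL⁻¹."""
        return self.kappa * body_length_px


# 8-connected neighbour offsets and their step lengths
_OFFS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_STEP = {o: np.hypot(*o) for o in _OFFS}


def _skeleton_path(skel: np.ndarray, nose: np.ndarray, tail: np.ndarray) -> np.ndarray:
    """Ordered (x, y) pixel path through the skeleton from near-nose to near-tail.

    Dijkstra over the 8-connected skeleton pixel graph between the skeleton
    endpoints closest to each landmark; side branches fall off the shortest
    path.
    """
    import heapq

    rows, cols = np.nonzero(skel)
    if len(rows) == 0:
        raise MidlineError("skeleton is empty")
    pix = set(zip(rows.tolist(), cols.tolist()))
    degree = {
        p: sum((p[0] + dr, p[1] + dc) in pix for dr, dc in _OFFS) for p in pix
    }
    endpoints = [p for p, d in degree.items() if d <= 1]
    candidates = endpoints if endpoints else list(pix)

    def nearest(landmark):
        lx, ly = landmark
        return min(candidates, key=lambda p: (p[1] - lx) ** 2 + (p[0] - ly) ** 2)

    start = nearest(nose)
    goal = nearest(tail)
    if start == goal and len(candidates) > 1:
        others = [p for p in candidates if p != start]
        goal = min(others, key=lambda p: (p[1] - tail[0]) ** 2 + (p[0] - tail[1]) ** 2)
    if start == goal:
        raise MidlineError("skeleton degenerate: single endpoint")

    dist = {start: 0.0}
    prev: dict = {}
    heap = [(0.0, start)]
    while heap:
        d, node = heapq.heappop(heap)
        if node == goal:
            break
        if d > dist.get(node, np.inf):
            continue
        for dr, dc in _OFFS:
            nb = (node[0] + dr, node[1] + dc)
            if nb not in pix:
                continue
            nd = d + _STEP[(dr, dc)]
            if nd < dist.get(nb, np.inf):
                dist[nb] = nd
                prev[nb] = node
                heapq.heappush(heap, (nd, nb))
    if goal not in dist:
        raise MidlineError("no skeleton path between head and tail endpoints")
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()
    return np.array([(c, r) for r, c in path], dtype=float)  # (x, y)


def _refine_to_centroid(
    frame: np.ndarray, pts: np.ndarray, width: float, iters: int = 2, step: float = 0.5
) -> np.ndarray:
    """Slide midline points to the sub-pixel cross-sectional centroid.

    At each point the silhouette is sampled (bilinear) along the local
    normal over ±``width`` px and the point moves to the mass centroid of
    the foreground chord.  This recovers sub-pixel accuracy that the
    pixel-quantized skeleton cannot provide; without it, curvature — a
    second derivative — is dominated by skeleton wobble.
    """
    img = frame.astype(float)
    offs = np.arange(-width, width + step, step)
    for _ in range(iters):
        d = np.gradient(pts, axis=0)
        tang = d / np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-9)
        nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
        ys = pts[:, 1][:, None] + nrm[:, 1][:, None] * offs[None, :]
        xs = pts[:, 0][:, None] + nrm[:, 0][:, None] * offs[None, :]
        m = map_coordinates(img, [ys.ravel(), xs.ravel()], order=1).reshape(ys.shape)
        tot = m.sum(axis=1)
        shift = np.where(
            tot > 0, (m * offs[None, :]).sum(axis=1) / np.maximum(tot, 1e-9), 0.0
        )
        pts = pts + shift[:, None] * nrm
    return pts


def extract_midline(
    frame: np.ndarray,
    nose,
    tail,
    n_points: int = 100,
    anchor_tol: float = 10.0,
    smooth: bool = True,
    refine: bool = True,
) -> Midline:
    """Extract the nose→tail midline of a binary silhouette.

    Parameters
    ----------
    frame : boolean image
        Foreground = fish silhouette; must be a single large 8-connected
        component with both landmarks on or within ``anchor_tol`` px of it.
    nose, tail : (x, y) points
        Head and tail landmarks anchoring the path orientation; the path is
        extended to them so blunt-head skeleton shortening does not bias the
        body-length estimate.
    n_points : int
        Arc-length resampling density (all %BL positions refer to this grid).
    """
    frame = np.asarray(frame).astype(bool)
    nose = np.asarray(nose, dtype=float)
    tail = np.asarray(tail, dtype=float)
    if not frame.any():
        raise MidlineError("empty frame: no foreground pixels")

    labels, n_comp = ndimage.label(frame, structure=np.ones((3, 3), int))
    sizes = ndimage.sum_labels(frame, labels, index=np.arange(1, n_comp + 1))
    order = np.argsort(sizes)[::-1]
    if n_comp > 1 and sizes[order[1]] >= 0.25 * sizes[order[0]]:
        raise AmbiguousSilhouette(
            f"ambiguous silhouette: {n_comp} components, two largest have "
            f"{int(sizes[order[0]])} and {int(sizes[order[1]])} px"
        )
    comp = labels == (order[0] + 1)

    fg = np.column_stack(np.nonzero(comp))  # (row, col)
    tree = cKDTree(fg[:, ::-1])  # query in (x, y)
    for name, lm in (("nose", nose), ("tail", tail)):
        d, _ = tree.query(lm)
        if d > anchor_tol:
            raise MidlineError(
                f"{name} landmark is {d:.1f} px from the silhouette "
                f"(tolerance {anchor_tol} px)"
            )

    skel = skeletonize(comp)
    pts = _skeleton_path(skel, nose, tail)

    # extend to the landmark points so midline spans the full body
    if np.linalg.norm(pts[0] - nose) > 1.0:
        pts = np.vstack([nose, pts])
    if np.linalg.norm(pts[-1] - tail) > 1.0:
        pts = np.vstack([pts, tail])

    ml = Midline(pts).resample(n_points)
    if smooth:
        window = 2 * max(2, n_points // 20) + 1  # ~N/10, odd
        sm = np.column_stack(
            [
                savgol_filter(ml.points[:, d], window, polyorder=3, mode="interp")
                for d in range(2)
            ]
        )
        ml = Midline(sm).resample(n_points)
    if refine:
        # half the body width from the distance transform, with slack
        width = 1.5 * float(ndimage.distance_transform_edt(comp).max()) + 3.0
        refined = _refine_to_centroid(frame, ml.points, width)
        # the refinement pulls interior points; keep landmark-anchored ends
        refined[0], refined[-1] = ml.points[0], ml.points[-1]
        ml = Midline(refined).resample(n_points)
    return ml


def estimate_body_length(midlines: MidlineSequence) -> float:
    """Median per-frame midline arc length (px); the BL unit denominator."""
    if len(midlines) < 5:
        raise ValueError(
            f"body-length estimation needs ≥5 frames, got {len(midlines)}"
        )
    return float(np.median([m.length for m in midlines]))


def curvature(midline: Midline) -> np.ndarray:
    """Signed curvature κ(s) in px⁻¹ along the midline.

    Central differences of the unwrapped tangent angle with respect to arc
    length; endpoint values copy their interior neighbours.  Positive sign is
    fish-left bending under the raster convention.
    """
    pts = midline.points
    d = np.diff(pts, axis=0)
    seg = np.linalg.norm(d, axis=1)
    if np.any(seg == 0):
        keep = np.concatenate([[True], seg > 0])
        pts = pts[keep]
        d = np.diff(pts, axis=0)
        seg = np.linalg.norm(d, axis=1)
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    # tangent angles live at segment midpoints; κ at interior vertices
    ds = 0.5 * (seg[:-1] + seg[1:])
    kappa_int = np.diff(theta) / ds
    kappa = np.empty(len(pts))
    kappa[1:-1] = kappa_int
    kappa[0] = kappa_int[0]
    kappa[-1] = kappa_int[-1]
    if len(kappa) != len(midline.points):  # degenerate duplicate points removed
        sf_full = midline.s_frac
        sf = Midline(pts).s_frac
        kappa = np.interp(sf_full, sf, kappa)
    return kappa


def curvature_field(midlines: MidlineSequence, n_points: int | None = None) -> CurvatureField:
    """Stack per-frame curvature into a κ(s, t) field on a common s grid."""
    if len(midlines) == 0:
        raise ValueError("empty midline sequence")
    n = n_points or len(midlines[0].points)
    kappas = []
    coords = []
    for ml in midlines:
        if len(ml.points) != n:
            ml = ml.resample(n)
        kappas.append(curvature(ml))
        coords.append(ml.points)
    return CurvatureField(
        kappa=np.array(kappas),
        s_frac=np.linspace(0.0, 1.0, n),
        xy=np.array(coords),
        fps=midlines.fps,
    )
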