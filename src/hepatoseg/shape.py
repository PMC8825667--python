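"""Seed-sphere shape descriptor and planar-convex surface parameterization.

The local shape function S(p, r) of a surface point p is the fraction of a
small ball ("seed sphere") of radius r centred at p that lies inside the
object: 0.5 on a locally flat boundary, > 0.5 in concavities, < 0.5 on
convex bumps.  Evaluating S at corresponded parameterization points of two
shapes gives a point-to-point local discrepancy map; thresholding the
normalized map at 0.5 flags uncertain surface regions whose centroids seed
the contour-correction stage.

Correspondence relies on planar convexity: a family of parallel planes each
of which cuts the object in a single closed curve.  Candidate plane normals
are the canonical axes plus a 32-vertex pentakis-dodecahedron sampling
(icosahedron + dodecahedron vertices); the winning normal minimizes the
mean number of cross-section components per slice.  Each slice curve is
then resampled at a fixed number of equal-arclength divisions from a
deterministic anchor, indexing every surface point by (plane, division).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .core import Mask

_STRUCT6 = ndi.generate_binary_structure(3, 1)


@dataclass
class ClosedSurface:
    """Binary occupancy grid of a single closed object interior."""

    occupancy: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        _, n = ndi.label(self.occupancy)
        if n != 1:
            raise ValueError(f"object must be a single connected component, got {n}")
        for ax in range(3):
            edge = [slice(None)] * 3
            for side in (0, -1):
                edge[ax] = side
                if self.occupancy[tuple(edge)].any():
                    raise ValueError("object touches the grid edge; surface not closed")

    @classmethod
    def from_mask(cls, mask: Mask, label: int | None = None) -> "ClosedSurface":
        return cls(mask.binary(label), mask.spacing)

    def voxel_centers_mm(self) -> np.ndarray:
        idx = np.argwhere(self.occupancy)
        return (idx + 0.5) * np.asarray(self.spacing)

    def boundary_voxels(self) -> np.ndarray:
        m = self.occupancy
        return m & ~ndi.binary_erosion(m, structure=_STRUCT6, border_value=0)


# ---------------------------------------------------------------------------
# shape function S
# ---------------------------------------------------------------------------

def _ball_offsets(r: float, step: float) -> np.ndarray:
    # midpoint offsets (half-step shift) decorrelate the quadrature lattice
    # from the voxel grid, removing the dominant aliasing bias
    k = np.arange(-r + step / 2, r, step)
    ox, oy, oz = np.meshgrid(k, k, k, indexing="ij")
    inside = ox**2 + oy**2 + oz**2 <= r**2
    return np.stack([ox[inside], oy[inside], oz[inside]], axis=1)


def shape_function(surface: ClosedSurface, point_mm, r: float,
                   check_on_boundary: bool = True) -> float:
    """Fraction of the seed ball of radius r at ``point_mm`` inside the object.

    Computed by dense quadrature over the ball with trilinear interpolation
    of the occupancy grid, which antialiases boundary voxels.  The point
    must lie within one voxel of the object boundary.
    """
    sp = np.asarray(surface.spacing)
    if r < sp.max():
        raise ValueError(f"seed radius {r} mm below voxel size {sp.max()} mm")
    p = np.asarray(point_mm, dtype=float)
    if check_on_boundary:
        bvox = np.argwhere(surface.boundary_voxels())
        if bvox.size == 0:
            raise ValueError("object has no boundary voxels")
        centers = (bvox + 0.5) * sp
        dmin = np.sqrt(((centers - p) ** 2).sum(axis=1)).min()
        if dmin > np.linalg.norm(sp):
            raise ValueError(f"point {p} is {dmin:.2f} mm from the boundary "
                             f"(more than one voxel)")
    step = max(sp.min() / 4.0, r / 20.0)
    offs = _ball_offsets(r, step)
    pos = p[None, :] + offs
    coords = (pos / sp[None, :]) - 0.5    # voxel-center coordinates
    vals = ndi.map_coordinates(surface.occupancy.astype(np.float64), coords.T,
                               order=1, mode="constant", cval=0.0)
    return float(vals.mean())


# ---------------------------------------------------------------------------
# principal-axis alignment
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """y = R (x - c): centroid to origin, principal axes to x/y/z."""

    rotation: np.ndarray    # rows are the principal axes, descending variance
    centroid: np.ndarray

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points_mm) - self.centroid) @ self.rotation.T

    def inverse_direction(self, d: np.ndarray) -> np.ndarray:
        """Aligned-frame direction -> world-frame direction."""
        return self.rotation.T @ np.asarray(d, dtype=float)


def align_principal_axes(surface: ClosedSurface) -> RigidTransform:
    """PCA alignment with a deterministic sign convention.

    Axes are sorted by descending variance; each axis is oriented so the
    skewness of the coordinates along it is non-negative (falling back to
    making the largest-magnitude component positive for symmetric bodies).
    """
    pts = surface.voxel_centers_mm()
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 voxels for principal axes")
    c = pts.mean(axis=0)
    x = pts - c
    cov = x.T @ x / len(x)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T            # rows = axes
    if evals[-1] < 1e-9 * max(evals[0], 1.0):
        raise ValueError("degenerate occupancy: voxels are planar or collinear")
    for i in range(3):
        proj = x @ axes[i]
        sd = proj.std()
        skew = float(((proj / sd) ** 3).mean()) if sd > 0 else 0.0
        if abs(skew) > 1e-3:
            if skew < 0:
                axes[i] = -axes[i]
        else:
            j = int(np.argmax(np.abs(axes[i])))
            if axes[i][j] < 0:
                axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]   # enforce a right-handed frame on the last axis
    return RigidTransform(rotation=axes, centroid=c)


# ---------------------------------------------------------------------------
# candidate directions
# ---------------------------------------------------------------------------

def candidate_directions(fold_hemisphere: bool = False) -> np.ndarray:
    """32 unit direction vectors from a pentakis-dodecahedron sampling.

    The 12 icosahedron vertices plus the 20 dodecahedron vertices give 32
    near-uniform directions; with ``fold_hemisphere`` antipodal duplicates
    are removed, leaving 16 directions spanning a hemisphere.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    ico = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            ico += [(0, a, b), (a, b, 0), (b, 0, a)]
    dod = [(a, b, c) for a in (-1, 1) for b in (-1, 1) for c in (-1, 1)]
    for a in (-1 / phi, 1 / phi):
        for b in (-phi, phi):
            dod += [(0, a, b), (a, b, 0), (b, 0, a)]
    dirs = np.array(ico + dod, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    if fold_hemisphere:
        keep = []
        for d in dirs:
            key = d if (d[2] > 1e-9 or (abs(d[2]) <= 1e-9 and
                        (d[1] > 1e-9 or (abs(d[1]) <= 1e-9 and d[0] > 0)))) else -d
            if not any(np.allclose(key, k, atol=1e-9) for k in keep):
                keep.append(key)
        dirs = np.array(keep)
    return dirs


# ---------------------------------------------------------------------------
# convexity planes and parameterization
# ---------------------------------------------------------------------------

@dataclass
class ConvexityPlaneSet:
    normal: np.ndarray                  # world-frame unit normal
    basis_u: np.ndarray
    basis_v: np.ndarray
    origin: np.ndarray                  # mm
    offsets: np.ndarray                 # strictly increasing plane positions
    score: float                        # mean components per slice (1 = ideal)
    surface: ClosedSurface
    step_mm: float


def _plane_basis(d: np.ndarray):
    d = np.asarray(d, dtype=float)
    d = d / np.linalg.norm(d)
    e = np.zeros(3)
    e[int(np.argmin(np.abs(d)))] = 1.0
    u = np.cross(d, e)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v, d


def _sample_slice(surface: ClosedSurface, origin, u, v, d, w, extent, step,
                  order: int = 0) -> np.ndarray:
    """Occupancy resampled on the plane origin + a*u + b*v + w*d."""
    a = np.arange(-extent, extent + step / 2, step)
    A, B = np.meshgrid(a, a, indexing="ij")
    pos = (origin[None, None, :] + A[..., None] * u[None, None, :]
           + B[..., None] * v[None, None, :] + w * d[None, None, :])
    sp = np.asarray(surface.spacing)
    coords = pos / sp[None, None, :] - 0.5
    vals = ndi.map_coordinates(surface.occupancy.astype(np.float64),
                               coords.reshape(-1, 3).T, order=order,
                               mode="constant", cval=0.0).reshape(A.shape)
    return vals


def select_convexity_planes(surface: ClosedSurface, directions=None,
                            transform: RigidTransform | None = None,
                            n_planes: int = 32) -> ConvexityPlaneSet:
    """Pick the plane normal whose parallel cross-sections are most often a
    single closed curve.

    Candidates default to the canonical x/y/z axes (tried first, which fixes
    the tie rule) followed by the folded pentakis-dodecahedron directions.
    The score of a direction is the mean connected-component count over
    non-empty slices; lower is better, 1.0 is planar-convex.
    """
    if directions is None:
        directions = np.vstack([np.eye(3), candidate_directions(fold_hemisphere=True)])
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    sp = np.asarray(surface.spacing)
    step = float(sp.min())
    centroid = surface.voxel_centers_mm().mean(axis=0)
    pts = surface.voxel_centers_mm()
    extent = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1)).max()) + 2 * step

    best = None
    for d_aligned in directions:
        d_world = (transform.inverse_direction(d_aligned)
                   if transform is not None else d_aligned)
        u, v, d = _plane_basis(d_world)
        w_proj = (pts - centroid) @ d
        w_lo, w_hi = w_proj.min(), w_proj.max()
        ws = np.arange(w_lo + step / 2, w_hi, step)
        counts = []
        for w in ws:
            sl = _sample_slice(surface, centroid, u, v, d, w, extent, step) > 0.5
            if sl.any():
                _, n = measure.label(sl, connectivity=2, return_num=True)
                # a single closed curve also excludes holes (e.g. annular
                # sections of a torus): count each hole as an extra curve
                bg = measure.label(np.pad(~sl, 1), connectivity=1)
                n_holes = bg.max() - 1
                counts.append(n + n_holes)
        if not counts:
            continue
        score = float(np.mean(counts))
        if best is None or score < best.score - 1e-12:
            offsets = np.linspace(w_lo + step, w_hi - step, n_planes)
            best = ConvexityPlaneSet(normal=d, basis_u=u, basis_v=v,
                                     origin=centroid, offsets=offsets,
                                     score=score, surface=surface, step_mm=step)
    if best is None:
        raise ValueError("no direction yields finite cross sections")
    return best


@dataclass
class SurfaceParameterization:
    """Ordered surface points indexed by (plane, division)."""

    points: np.ndarray            # (n_planes, divisions, 3) mm
    divisions: int
    plane_set: ConvexityPlaneSet

    @property
    def n_planes(self) -> int:
        return self.points.shape[0]


def _slice_contour(planes: ConvexityPlaneSet, w: float):
    """The single closed cross-section curve at plane offset w, in (u,v) mm."""
    step = planes.step_mm / 2.0
    surface = planes.surface
    pts = surface.voxel_centers_mm()
    extent = float(np.sqrt(((pts - planes.origin) ** 2).sum(axis=1)).max()) + 2 * step
    sl = _sample_slice(surface, planes.origin, planes.basis_u, planes.basis_v,
                       planes.normal, w, extent, step, order=1)
    contours = measure.find_contours(sl, 0.5)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if len(closed) == 0:
        raise ValueError(f"slice at offset {w:.2f} mm has no closed cross section")
    if len(closed) > 1:
        # keep curves enclosing non-trivial area; >1 means not planar-convex
        areas = [abs(_signed_area(c)) for c in closed]
        big = [c for c, a in zip(closed, areas) if a > 2.0]
        if len(big) > 1:
            raise ValueError(f"slice at offset {w:.2f} mm has "
                             f"{len(big)} cross-section components")
        closed = [closed[int(np.argmax(areas))]]
    curve = closed[0][:-1]           # drop duplicate endpoint
    return (curve - (np.array(sl.shape) - 1) / 2.0) * step  # grid -> centred (u,v) mm


def _signed_area(curve: np.ndarray) -> float:
    x, y = curve[:, 0], curve[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def parameterize_surface(planes: ConvexityPlaneSet,
                         divisions: int) -> SurfaceParameterization:
    """Sample each slice curve at ``divisions`` equal-arclength points.

    The anchor (division 0) is the curve point with maximal first-in-plane
    coordinate; traversal is counterclockwise in the (u, v) frame.  Matched
    plane counts and divisions across two shapes give index-wise anatomical
    correspondence.
    """
    if divisions < 3:
        raise ValueError("need at least 3 divisions")
    out = np.empty((len(planes.offsets), divisions, 3), dtype=float)
    for pi, w in enumerate(planes.offsets):
        curve = _slice_contour(planes, w)
        if _signed_area(curve) < 0:
            curve = curve[::-1]
        start = int(np.argmax(curve[:, 0]))
        curve = np.roll(curve, -start, axis=0)
        curve_closed = np.vstack([curve, curve[:1]])
        seg = np.sqrt(((np.diff(curve_closed, axis=0)) ** 2).sum(axis=1))
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        targets = np.arange(divisions) * total / divisions
        uu = np.interp(targets, s, curve_closed[:, 0])
        vv = np.interp(targets, s, curve_closed[:, 1])
        out[pi] = (planes.origin[None, :] + uu[:, None] * planes.basis_u[None, :]
                   + vv[:, None] * planes.basis_v[None, :]
                   + w * planes.normal[None, :])
    return SurfaceParameterization(points=out, divisions=divisions,
                                   plane_set=planes)


# ---------------------------------------------------------------------------
# shape comparison and uncertain regions
# ---------------------------------------------------------------------------

@dataclass
class ShapeMap:
    """Per-parameterization-point shape-function values, raw and normalized."""

    s_a: np.ndarray           # (n_planes, divisions)
    s_b: np.ndarray
    s_mean: np.ndarray        # averaged at both ends of the correspondence
    s_norm: np.ndarray        # min-max normalized to [0, 1]
    seed_radius: float


def default_seed_radius(surface: ClosedSurface) -> float:
    """10 % of the smallest principal extent of the object."""
    pts = surface.voxel_centers_mm()
    x = pts - pts.mean(axis=0)
    evals = np.linalg.eigvalsh(x.T @ x / len(x))
    return max(2.0 * np.sqrt(max(evals[0], 0.0)) * 0.1,
               float(np.max(surface.spacing)))


def evaluate_shape_map(param: SurfaceParameterization, surface: ClosedSurface,
                       r: float) -> np.ndarray:
    vals = np.empty(param.points.shape[:2])
    for pi in range(param.points.shape[0]):
        for di in range(param.points.shape[1]):
            vals[pi, di] = shape_function(surface, param.points[pi, di], r,
                                          check_on_boundary=False)
    return vals


def compare_shapes(param_a: SurfaceParameterization, surface_a: ClosedSurface,
                   param_b: SurfaceParameterization, surface_b: ClosedSurface,
                   r: float | None = None) -> ShapeMap:
    """Point-to-point local shape discrepancy between two corresponded shapes.

    S is evaluated on both shapes at each corresponding index, averaged at
    both ends, then min-max normalized across points to [0, 1].
    """
    if param_a.points.shape != param_b.points.shape:
        raise ValueError("parameterizations must share plane count and divisions")
    if r is None:
        r = default_seed_radius(surface_a)
    s_a = evaluate_shape_map(param_a, surface_a, r)
    s_b = evaluate_shape_map(param_b, surface_b, r)
    s_mean = 0.5 * (s_a + s_b)
    lo, hi = s_mean.min(), s_mean.max()
    s_norm = (s_mean - lo) / (hi - lo) if hi > lo else np.zeros_like(s_mean)
    return ShapeMap(s_a=s_a, s_b=s_b, s_mean=s_mean, s_norm=s_norm, seed_radius=r)


@dataclass
class UncertainRegions:
    labels: np.ndarray          # (n_planes, divisions) int, 0 = not flagged
    seeds_mm: list[np.ndarray]  # one centroid-nearest surface point per region

    @property
    def n_regions(self) -> int:
        return len(self.seeds_mm)


def uncertain_regions(shape_map: ShapeMap, param: SurfaceParameterization,
                      threshold: float = 0.5) -> UncertainRegions:
    """Threshold the normalized S map (inclusive) and connected-component the
    flagged points on the parameterization adjacency graph.

    Adjacency: neighbouring divisions on a plane (cyclic) and the same
    division on neighbouring planes.  Each region contributes one seed: the
    flagged point nearest the region centroid.
    """
    flagged = shape_map.s_norm >= threshold
    n_p, n_d = flagged.shape
    labels = np.zeros((n_p, n_d), dtype=int)
    current = 0
    for start in zip(*np.nonzero(flagged)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            p, d = stack.pop()
            neigh = [((p + 1), d), ((p - 1), d),
                     (p, (d + 1) % n_d), (p, (d - 1) % n_d)]
            for q, e in neigh:
                if 0 <= q < n_p and flagged[q, e] and not labels[q, e]:
                    labels[q, e] = current
                    stack.append((q, e))
    seeds = []
    for k in range(1, current + 1):
        pts = param.points[labels == k]
        centroid = pts.mean(axis=0)
        seeds.append(pts[np.argmin(((pts - centroid) ** 2).sum(axis=1))])
    return UncertainRegions(labels=labels, seeds_mm=seeds)
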