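"""Automatic pose normalization of bilaterally symmetric artifacts.

The protocol has three steps:

1. translate the surface centroid to the origin;
2. rotate about X and Y to planform view, from the area-weighted scatter
   of the unit face normals: for a flat bifacial piece most surface area
   faces the two faces, so the leading eigenvector of
   ``sum_f area_f * n_f n_f^T`` is the face-normal direction, which is
   rotated onto +Z;
3. rotate about Z to the angle minimizing a bilateral-asymmetry score of
   the planform silhouette, which puts the symmetry (length) axis on Y.

The silhouette score at angle ``theta`` integrates, over equidistant
stations along the length axis, the absolute mismatch between the
outline's positive and negative X extremes: ``sum_j |x_max(y_j) +
x_min(y_j)| * dy`` (mm^2); it vanishes exactly when the outline is
mirror-symmetric about the plane x = 0.

Sign ambiguities remain by construction: the protocol determines the pose
only up to the Klein group of half-turns about the three axes (which face
is "dorsal", which end is "up").  :func:`apply_review` applies the
reviewer's batch flip/quarter-turn decisions exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .mesh_io import MeshFormatError, TriangleMesh, face_geometry

# discrete pose ambiguity left by the protocol: half-turns about X, Y, Z
FLIP_GROUP: tuple[np.ndarray, ...] = (
    np.eye(3),
    np.diag([1.0, -1.0, -1.0]),   # half-turn about X
    np.diag([-1.0, 1.0, -1.0]),   # half-turn about Y ("flip")
    np.diag([-1.0, -1.0, 1.0]),   # half-turn about Z
)


class PlanformAmbiguityWarning(UserWarning):
    """Normal scatter has no clear dominant axis (near-isotropic object)."""


class SymmetryTieWarning(UserWarning):
    """Several symmetry angles score within 1% of the optimum."""


class SilhouetteStationWarning(UserWarning):
    """Some silhouette stations had no outline crossings and were skipped."""


@dataclass
class PoseResult:
    """Rigid transform taking the input mesh to canonical pose.

    ``canonical = (input + translation) @ rotation.T``; the asymmetry
    score (mm^2) is the silhouette mismatch at the chosen angle.
    """

    rotation: np.ndarray
    translation: np.ndarray
    asymmetry: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant {det} != 1")
        if self.asymmetry < 0:
            raise ValueError("asymmetry score must be non-negative")


def center_mesh(mesh: TriangleMesh) -> tuple[TriangleMesh, np.ndarray]:
    """Translate the area-weighted surface centroid to the origin."""
    translation = -face_geometry(mesh)[2]
    return mesh.transformed(translation=translation), translation


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation mapping unit vector ``axis`` onto +Z.

    The rotation axis lies in the XY plane, i.e. the rotation decomposes
    into rotations about X and Y only.
    """
    z = np.array([0.0, 0.0, 1.0])
    if axis[2] < 0:
        axis = -axis
    c = float(np.clip(axis @ z, -1.0, 1.0))
    cross = np.cross(axis, z)
    s = float(np.linalg.norm(cross))
    if s < 1e-15:
        return np.eye(3)
    k = cross / s
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def orient_planform(
    mesh: TriangleMesh, ambiguity_ratio: float = 0.01
) -> tuple[TriangleMesh, np.ndarray]:
    """Rotate the dominant face-normal axis onto Z (planform view).

    Warns with :class:`PlanformAmbiguityWarning` when the two leading
    eigenvalues of the normal scatter matrix differ by less than
    ``ambiguity_ratio`` of the largest (isotropic objects such as
    spheres have no planform).
    """
    normals, areas, _ = face_geometry(mesh)
    scatter = (normals * areas[:, None]).T @ normals
    eigvals, eigvecs = np.linalg.eigh(scatter)
    if eigvals[-1] - eigvals[-2] < ambiguity_ratio * eigvals[-1]:
        warnings.warn(
            "planform ambiguous: no dominant face-normal axis",
            PlanformAmbiguityWarning,
            stacklevel=2,
        )
    rotation = _rotation_to_z(eigvecs[:, -1])
    return mesh.transformed(rotation=rotation), rotation


# ---------------------------------------------------------------------------
# silhouette asymmetry

def _mesh_edges_xy(mesh: TriangleMesh) -> np.ndarray:
    """Unique mesh edges projected to the XY plane, shape (e, 2, 2)."""
    f = mesh.faces
    edges = np.sort(
        np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    edges = np.unique(edges, axis=0)
    return mesh.vertices[:, :2][edges]


def _silhouette_scores(
    edges_xy: np.ndarray, angles: np.ndarray, stations: int
) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetry score for each Z-rotation angle (radians), vectorized.

    Returns (scores, skipped-station counts).  Memory is bounded by
    chunking over angles.
    """
    scores = np.empty(len(angles))
    skips = np.zeros(len(angles), dtype=int)
    x0 = edges_xy[:, :, 0]
    y0 = edges_xy[:, :, 1]
    for a, angle in enumerate(angles):
        c, s = np.cos(angle), np.sin(angle)
        ex = c * x0 - s * y0  # (e, 2)
        ey = s * x0 + c * y0
        y_lo = ey.min(axis=1)
        y_hi = ey.max(axis=1)
        y_min, y_max = y_lo.min(), y_hi.max()
        dy = (y_max - y_min) / stations
        first = y_min + 0.5 * dy
        # station index range each edge's y-span covers (few per edge)
        i_lo = np.maximum(np.ceil((y_lo - first) / dy), 0.0).astype(np.int64)
        i_hi = np.minimum(np.floor((y_hi - first) / dy), stations - 1).astype(np.int64)
        counts = np.maximum(i_hi - i_lo + 1, 0)
        total = int(counts.sum())
        if total == 0:
            scores[a] = 0.0
            skips[a] = stations
            continue
        edge_id = np.repeat(np.arange(len(edges_xy)), counts)
        offsets = np.repeat(np.cumsum(counts) - counts, counts)
        station = np.repeat(i_lo, counts) + (np.arange(total) - offsets)
        ys = first + station * dy
        y1, y2 = ey[edge_id, 0], ey[edge_id, 1]
        x1, x2 = ex[edge_id, 0], ex[edge_id, 1]
        denom = y2 - y1
        vertical = np.abs(denom) < 1e-300
        t = np.where(vertical, 0.5, (ys - y1) / np.where(vertical, 1.0, denom))
        xc = x1 + t * (x2 - x1)
        x_hi = np.full(stations, -np.inf)
        x_lo = np.full(stations, np.inf)
        np.maximum.at(x_hi, station, xc)
        np.minimum.at(x_lo, station, xc)
        hit = np.isfinite(x_hi) & np.isfinite(x_lo)
        scores[a] = float(np.abs(x_hi[hit] + x_lo[hit]).sum() * dy)
        skips[a] = int(stations - hit.sum())
    return scores, skips


def asymmetry_score(
    mesh: TriangleMesh, angle: float, stations: int = 256
) -> float:
    """Bilateral-asymmetry score (mm^2) after rotating ``angle`` about Z.

    Warns with :class:`SilhouetteStationWarning` if any station has an
    empty silhouette (those stations are skipped).
    """
    edges = _mesh_edges_xy(mesh)
    scores, skips = _silhouette_scores(edges, np.atleast_1d(float(angle)), stations)
    if skips[0]:
        warnings.warn(
            f"{skips[0]} of {stations} silhouette stations empty, skipped",
            SilhouetteStationWarning,
            stacklevel=2,
        )
    return float(scores[0])


def orient_bilateral(
    mesh: TriangleMesh,
    stations: int = 256,
    coarse_step_deg: float = 0.5,
    refine_tol_deg: float = 1e-3,
    tie_ratio: float = 0.01,
) -> tuple[TriangleMesh, np.ndarray, float]:
    """Rotate about Z to the global minimum of the asymmetry score.

    The objective is 180-degree periodic, so the search covers [0, 180):
    an exhaustive coarse grid (default 0.5 deg) followed by golden-section
    refinement of the best bracket.  Ties (several separated local minima
    within ``tie_ratio`` of the optimum) are broken towards the smallest
    angle, with a :class:`SymmetryTieWarning`.
    """
    edges = _mesh_edges_xy(mesh)
    angles = np.deg2rad(np.arange(0.0, 180.0, coarse_step_deg))
    scores, _ = _silhouette_scores(edges, angles, stations)
    best = int(np.argmin(scores))

    # detect competing, non-adjacent local minima
    lower = np.minimum(np.roll(scores, 1), np.roll(scores, -1))
    local_min = scores <= lower
    near = local_min & (scores <= scores[best] + tie_ratio * max(scores[best], np.ptp(scores) * tie_ratio, 1e-300))
    candidates = np.flatnonzero(near)
    separated = candidates[np.abs(candidates - best) > 2]
    if len(separated):
        warnings.warn(
            "bilateral symmetry angle ambiguous: competing minima at "
            f"{np.rad2deg(angles[separated]).round(1).tolist()} deg",
            SymmetryTieWarning,
            stacklevel=2,
        )
        best = int(min(best, separated.min()))

    step = np.deg2rad(coarse_step_deg)
    lo, hi = angles[best] - step, angles[best] + step
    try:
        result = minimize_scalar(
            lambda a: _silhouette_scores(edges, np.atleast_1d(a), stations)[0][0],
            bracket=(lo, angles[best], hi),
            method="golden",
            options={"xtol": np.deg2rad(refine_tol_deg)},
        )
        theta, score = float(result.x), float(result.fun)
    except ValueError:  # degenerate bracket (flat objective around the minimum)
        theta, score = float(angles[best]), float(scores[best])
    theta %= np.pi
    c, s = np.cos(theta), np.sin(theta)
    rotation = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return mesh.transformed(rotation=rotation), rotation, score


def apply_review(
    mesh: TriangleMesh, flip_y: bool = False, rotate_z_quarters: int = 0
) -> TriangleMesh:
    """Apply the reviewer's exact flip / quarter-turn corrections.

    ``flip_y`` is a 180-degree turn about Y (swaps the two faces);
    ``rotate_z_quarters`` counts 90-degree turns about Z.  Both are exact
    sign/permutation matrices, so flipping twice or rotating four times
    restores the input bitwise.
    """
    if rotate_z_quarters not in (0, 1, 2, 3):
        raise ValueError("rotate_z_quarters must be 0..3")
    R = np.eye(3)
    if flip_y:
        R = np.diag([-1.0, 1.0, -1.0]) @ R
    quarter = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    for _ in range(rotate_z_quarters):
        R = quarter @ R
    return mesh.transformed(rotation=R)


def normalize_pose(
    mesh: TriangleMesh,
    stations: int = 256,
    coarse_step_deg: float = 0.5,
    refine_tol_deg: float = 1e-3,
) -> tuple[TriangleMesh, PoseResult]:
    """Run the full three-step protocol; returns the canonical mesh + pose."""
    mesh.validate()
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        centered, translation = center_mesh(mesh)
        planform, r_plan = orient_planform(centered)
        canonical, r_z, score = orient_bilateral(
            planform, stations=stations,
            coarse_step_deg=coarse_step_deg, refine_tol_deg=refine_tol_deg,
        )
    for w in caught:
        if issubclass(w.category, PlanformAmbiguityWarning):
            flags.append("planform ambiguous")
        elif issubclass(w.category, SymmetryTieWarning):
            flags.append("symmetry tie")
        elif issubclass(w.category, SilhouetteStationWarning):
            flags.append("silhouette stations skipped")
        else:
            warnings.warn_explicit(
                w.message, w.category, w.filename, w.lineno
            )
    pose = PoseResult(
        rotation=r_z @ r_plan,
        translation=translation,
        asymmetry=score,
        flags=flags,
    )
    return canonical, pose
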