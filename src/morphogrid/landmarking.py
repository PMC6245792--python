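"""Projection of the deformed L x M grid of paired semi-landmarks.

On a pose-normalized mesh (length on Y, faces towards +/-Z) the grid is
built from L cross-sections ("latitudes") equidistant along Y.  Within
each section, M stations are placed equidistant in X across the section's
width; at every station the vertical line meets the section outline in an
upper (max Z) and a lower (min Z) crossing — the two semi-landmarks of
that grid point, one per artifact face.  The first and last stations sit
on the lateral edges, where the two semi-landmarks coincide.

Exact length extremes degenerate to single points, so the end latitudes
are inset by ``delta = (y_max - y_min) / (20 * (L - 1))``; the end
sections are then small closed outlines around the tips, which is how the
grid captures the 3-D outline of the distal and proximal ends.

Homology is positional: the canonical ordering (upper-face block then
lower-face block, each latitude-major from +Y, stations from -X) is
identical for every item, so landmark j corresponds across specimens.
"""

from __future__ import annotations

import warnings

import numpy as np
import trimesh

from .mesh_io import GridConfig, LandmarkRecord, TriangleMesh


class SectionError(ValueError):
    """A latitude plane does not intersect the mesh."""


class StationWarning(UserWarning):
    """A grid station had no outline crossing; nearest point substituted."""


class OpenSectionWarning(UserWarning):
    """A section polyline was open (mesh hole) and was closed by a chord."""


def slice_section(mesh: TriangleMesh, y: float) -> list[np.ndarray]:
    """Closed loop(s) of the mesh intersection with the plane y = const.

    Returns each loop as an (n, 3) array of ordered vertices (implicitly
    closed), sorted by decreasing perimeter — the first loop is the
    section outline.  Open chains (holes in the mesh) are closed by a
    chord, with an :class:`OpenSectionWarning`.
    """
    y_min, y_max = mesh.vertices[:, 1].min(), mesh.vertices[:, 1].max()
    if not (y_min < y < y_max):
        raise SectionError(f"plane y={y} outside the mesh range [{y_min}, {y_max}]")
    tm = mesh.to_trimesh()
    path = tm.section(plane_origin=[0.0, y, 0.0], plane_normal=[0.0, 1.0, 0.0])
    if path is None or len(path.entities) == 0:
        raise SectionError(f"no intersection at y={y}")
    loops: list[np.ndarray] = []
    for entity, points in zip(path.entities, path.discrete):
        points = np.asarray(points, dtype=float)
        if np.allclose(points[0], points[-1]):
            points = points[:-1]
        elif not entity.closed:
            warnings.warn(
                f"open section chain at y={y} closed by chord",
                OpenSectionWarning,
                stacklevel=2,
            )
        if len(points) >= 3:
            loops.append(points)
    if not loops:
        raise SectionError(f"degenerate intersection at y={y}")

    def perimeter(loop: np.ndarray) -> float:
        return float(np.linalg.norm(np.diff(np.vstack([loop, loop[:1]]), axis=0), axis=1).sum())

    return sorted(loops, key=perimeter, reverse=True)


def _segment_crossings(
    segments: np.ndarray, x: float
) -> np.ndarray:
    """Z values where 3-D segments (n, 2, 3) cross the vertical plane x=const."""
    x1, x2 = segments[:, 0, 0], segments[:, 1, 0]
    mask = (x1 - x) * (x2 - x) <= 0.0
    denom = x2 - x1
    safe = mask & (np.abs(denom) > 1e-300)
    t = (x - x1[safe]) / denom[safe]
    z = segments[safe, 0, 2] + t * (segments[safe, 1, 2] - segments[safe, 0, 2])
    # vertical (in x) segments lying on the station contribute both endpoints
    flat = mask & ~safe
    return np.concatenate([z, segments[flat][:, :, 2].ravel()])


def _loop_segments(loop: np.ndarray) -> np.ndarray:
    closed = np.vstack([loop, loop[:1]])
    return np.stack([closed[:-1], closed[1:]], axis=1)


def place_latitude(section: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Place M upper + M lower semi-landmarks on one section outline.

    ``section`` is a closed loop (n, 3) at constant Y.  Stations are
    equidistant in X over the section's width; stations 1 and M are the
    lateral-edge extremes where upper = lower.  Returns (upper, lower)
    arrays of shape (M, 3), stations ordered from -X.
    """
    section = np.asarray(section, dtype=float)
    if m < 2:
        raise ValueError("need at least 2 stations per latitude")
    x = section[:, 0]
    x_min, x_max = float(x.min()), float(x.max())
    if not x_max > x_min:
        raise SectionError("section has no X extent")
    y = float(section[:, 1].mean())
    segments = _loop_segments(section)
    stations = np.linspace(x_min, x_max, m)
    upper = np.empty((m, 3))
    lower = np.empty((m, 3))
    misses = 0
    for j, xs in enumerate(stations):
        if j == 0 or j == m - 1:
            # lateral edge: the outline point at the extreme
            idx = int(np.argmin(x)) if j == 0 else int(np.argmax(x))
            point = np.array([section[idx, 0], y, section[idx, 2]])
            upper[j] = lower[j] = point
            continue
        z = _segment_crossings(segments, xs)
        if len(z) == 0:
            # concave outline with no crossing: nearest outline vertex
            idx = int(np.argmin(np.abs(x - xs)))
            point = np.array([section[idx, 0], y, section[idx, 2]])
            upper[j] = lower[j] = point
            misses += 1
            continue
        upper[j] = (xs, y, z.max())
        lower[j] = (xs, y, z.min())
    if misses:
        warnings.warn(
            f"{misses} stations had no outline crossing; nearest points used",
            StationWarning,
            stacklevel=2,
        )
    return upper, lower


def _multiplane_segments(
    mesh: TriangleMesh, heights: np.ndarray
) -> list[np.ndarray]:
    """3-D intersection segments for many y-planes in one pass."""
    tm = mesh.to_trimesh()
    origin = np.array([0.0, 0.0, 0.0])
    normal = np.array([0.0, 1.0, 0.0])
    lines_2d, transforms, _ = trimesh.intersections.mesh_multiplane(
        tm, origin, normal, heights
    )
    out = []
    for segs, transform in zip(lines_2d, transforms):
        if len(segs) == 0:
            out.append(np.empty((0, 2, 3)))
            continue
        flat = np.asarray(segs, dtype=float).reshape(-1, 2)
        hom = np.column_stack([flat, np.zeros(len(flat)), np.ones(len(flat))])
        pts = (hom @ transform.T)[:, :3]
        out.append(pts.reshape(-1, 2, 3))
    return out


def fit_grid(
    mesh: TriangleMesh,
    config: GridConfig,
    name: str = "item",
    inset: float | None = None,
    embed_mesh: bool = False,
) -> LandmarkRecord:
    """Project the full L x M grid onto a positioned mesh.

    Latitude Y stations are equidistant between the inset extremes
    (default inset ``(y_max - y_min) / (20 * (L - 1))``).  Returns the
    2*L*M landmarks in canonical order: the upper-face block then the
    lower-face block, both latitude-major from +Y, stations from -X.
    """
    mesh.validate()
    L, M = config.latitudes, config.per_latitude
    y_min, y_max = mesh.vertices[:, 1].min(), mesh.vertices[:, 1].max()
    span = y_max - y_min
    if span <= 0:
        raise SectionError("mesh has no extent along Y")
    if inset is None:
        inset = span / (20.0 * (L - 1))
    flags: list[str] = []

    def stations_for(delta: float) -> np.ndarray:
        return np.linspace(y_max - delta, y_min + delta, L)  # from +Y

    heights = stations_for(inset)
    per_plane = _multiplane_segments(mesh, heights)
    if any(len(s) == 0 for s in per_plane):
        # empty end section: widen the inset once, then give up
        flags.append("inset increased")
        heights = stations_for(2.0 * inset)
        per_plane = _multiplane_segments(mesh, heights)
        empty = [i for i, s in enumerate(per_plane) if len(s) == 0]
        if empty:
            raise SectionError(
                f"empty sections at latitudes {empty} even after doubling the inset"
            )

    upper_block = np.empty((L, M, 3))
    lower_block = np.empty((L, M, 3))
    n_misses = 0
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", StationWarning)
        for i, (y, segments) in enumerate(zip(heights, per_plane)):
            loop = segments.reshape(-1, 3)  # stations only need crossings
            upper, lower = _place_from_segments(segments, loop, float(y), M)
            upper_block[i] = upper
            lower_block[i] = lower
    for w in caught:
        if issubclass(w.category, StationWarning):
            n_misses += 1
    if n_misses:
        flags.append(f"{n_misses} latitudes with substituted stations")

    points = np.vstack([upper_block.reshape(-1, 3), lower_block.reshape(-1, 3)])
    return LandmarkRecord(
        name=name,
        coordinates=points,
        grid=config,
        mesh=mesh if embed_mesh else None,
        flags=flags,
    )


def _place_from_segments(
    segments: np.ndarray, outline_points: np.ndarray, y: float, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Station placement from raw intersection segments (fast path).

    Equivalent to :func:`place_latitude` on the ordered outline whenever
    the section is a single loop: station crossings only need the segment
    soup, and the extreme-Z crossings pick the outermost surfaces for
    non-convex sections.
    """
    x = outline_points[:, 0]
    x_min, x_max = float(x.min()), float(x.max())
    stations = np.linspace(x_min, x_max, m)
    upper = np.empty((m, 3))
    lower = np.empty((m, 3))
    misses = 0
    for j, xs in enumerate(stations):
        if j == 0 or j == m - 1:
            idx = int(np.argmin(x)) if j == 0 else int(np.argmax(x))
            point = np.array([outline_points[idx, 0], y, outline_points[idx, 2]])
            upper[j] = lower[j] = point
            continue
        z = _segment_crossings(segments, float(xs))
        if len(z) == 0:
            idx = int(np.argmin(np.abs(x - xs)))
            point = np.array([outline_points[idx, 0], y, outline_points[idx, 2]])
            upper[j] = lower[j] = point
            misses += 1
            continue
        upper[j] = (xs, y, z.max())
        lower[j] = (xs, y, z.min())
    if misses:
        warnings.warn(
            f"{misses} stations had no outline crossing; nearest points used",
            StationWarning,
            stacklevel=2,
        )
    return upper, lower
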