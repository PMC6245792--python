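"""Seeded generators of biface-like meshes and two-group assemblages.

The surface model is a superellipse planform (length along Y, width along
X) carrying a biconvex thickness profile: at normalized planform radius
``rho`` the two faces sit at ``z = +/- (T/2) * (1 - rho**q)``.  A linear
width taper towards the tip and base, an optional planform shear (breaking
bilateral symmetry) and Gaussian vertex jitter give the controlled
departures from the ideal form.  The mesh is a closed 2-manifold built
from a polar parametric grid whose equator ring is shared by both faces.

Parameter defaults emulate an experimentally knapped handaxe assemblage:
two raw-material groups of 20 and 9 items, the first with inflated
dispersion, around a ~12 cm long, bilaterally symmetric, bifacial mean
form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .mesh_io import TriangleMesh, write_mesh


@dataclass(frozen=True)
class BifaceParams:
    """Shape and sampling parameters of one synthetic biface.

    Dimensions in mm; ``length >= width >= thickness`` is enforced.
    ``planform_exponent`` is the superellipse exponent (2 = ellipse,
    larger = blockier planform); ``edge_convexity`` shapes the thickness
    fall-off towards the edge (2 = parabolic section, larger = flatter
    faces with more convex edges); ``tip_taper``/``base_taper`` linearly
    narrow the planform towards +Y/-Y; ``shear`` shifts x by
    ``shear * y``, destroying bilateral symmetry; ``noise_sd`` is the
    per-vertex isotropic Gaussian jitter.  ``resolution`` is the number of
    radial rings (angular sampling is ``4 * resolution``).
    """

    length: float = 120.0
    width: float = 70.0
    thickness: float = 32.0
    planform_exponent: float = 2.4
    tip_taper: float = 0.45
    base_taper: float = 0.10
    edge_convexity: float = 2.0
    relief_amp: float = 0.0  # RMS depth (mm) of the flake-scar relief field
    shear: float = 0.0
    noise_sd: float = 0.0
    resolution: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.length >= self.width >= self.thickness > 0):
            raise ValueError(
                "expected length >= width >= thickness > 0, got "
                f"{self.length}, {self.width}, {self.thickness}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.relief_amp < 0:
            raise ValueError("relief_amp must be non-negative")
        if self.resolution < 4:
            raise ValueError("resolution must be at least 4")


def generate_biface(params: BifaceParams) -> TriangleMesh:
    """Build one biface mesh in canonical pose (length on Y, faces on +/-Z).

    Deterministic: the same parameters (including seed) give a
    bitwise-identical mesh.
    """
    n_rings = params.resolution
    n_theta = 4 * params.resolution
    a = params.width / 2.0
    b = params.length / 2.0
    p = params.planform_exponent

    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    # superellipse boundary point for each theta
    cx = np.sign(np.cos(theta)) * np.abs(np.cos(theta)) ** (2.0 / p)
    cy = np.sign(np.sin(theta)) * np.abs(np.sin(theta)) ** (2.0 / p)

    rho = np.arange(1, n_rings + 1) / n_rings  # rings, center excluded
    # ring vertices: planform position scaled from the center
    x = np.outer(rho, a * cx)
    y = np.outer(rho, b * cy)
    y_hat = y / b
    taper = 1.0 - params.tip_taper * np.clip(y_hat, 0.0, None) \
        - params.base_taper * np.clip(-y_hat, 0.0, None)
    x = x * taper
    z = (params.thickness / 2.0) * (1.0 - rho[:, None] ** params.edge_convexity)
    z = np.broadcast_to(z, x.shape)

    # vertex table: top center, top rings 1..R (equator = ring R, z=0),
    # bottom rings R-1..1, bottom center.  The equator is shared.
    top_center = np.array([[0.0, 0.0, params.thickness / 2.0]])
    bottom_center = np.array([[0.0, 0.0, -params.thickness / 2.0]])
    ring_xyz = np.stack([x, y, z], axis=-1)  # (R, n_theta, 3)
    top_rings = ring_xyz.reshape(-1, 3)
    bottom = ring_xyz[:-1].copy()
    bottom[..., 2] *= -1.0
    bottom_rings = bottom.reshape(-1, 3)
    vertices = np.vstack([top_center, top_rings, bottom_rings, bottom_center])

    def ring_index(sheet: str, ring: int) -> np.ndarray:
        """Vertex indices of ring ``ring`` (1-based) on a sheet."""
        if sheet == "top" or ring == n_rings:
            base = 1 + (ring - 1) * n_theta
        else:
            base = 1 + n_rings * n_theta + (ring - 1) * n_theta
        return np.arange(base, base + n_theta)

    faces: list[np.ndarray] = []

    def fan(center: int, ring: np.ndarray, flip: bool) -> np.ndarray:
        nxt = np.roll(ring, -1)
        tri = np.column_stack([np.full(n_theta, center), ring, nxt])
        return tri[:, ::-1] if flip else tri

    def band(inner: np.ndarray, outer: np.ndarray, flip: bool) -> np.ndarray:
        inner_next = np.roll(inner, -1)
        outer_next = np.roll(outer, -1)
        quads = np.vstack([
            np.column_stack([inner, outer, outer_next]),
            np.column_stack([inner, outer_next, inner_next]),
        ])
        return quads[:, ::-1] if flip else quads

    faces.append(fan(0, ring_index("top", 1), flip=False))
    for ring in range(1, n_rings):
        faces.append(band(ring_index("top", ring), ring_index("top", ring + 1), False))
    bottom_center_idx = len(vertices) - 1
    faces.append(fan(bottom_center_idx, ring_index("bottom", 1), flip=True))
    for ring in range(1, n_rings):
        faces.append(
            band(ring_index("bottom", ring), ring_index("bottom", ring + 1), True)
        )

    rng = np.random.default_rng(params.seed)
    if params.relief_amp > 0:
        # flake-scar relief: a random smooth field per face, vanishing at
        # the center and at the shared edge ring (seam-safe), normalized
        # to RMS = relief_amp and added to z
        n_top = 1 + n_rings * n_theta
        for sheet, sl in (("top", slice(0, n_top)),
                          ("bottom", slice(n_top, len(vertices)))):
            rho_v = np.concatenate([[0.0], np.repeat(rho, n_theta)]) \
                if sheet == "top" else np.concatenate(
                    [np.repeat(rho[:-1], n_theta), [0.0]])
            theta_v = np.concatenate([[0.0], np.tile(theta, n_rings)]) \
                if sheet == "top" else np.concatenate(
                    [np.tile(theta, n_rings - 1), [0.0]])
            field = np.zeros(len(rho_v))
            for p_mode in (1, 2, 3):
                radial = np.sin(p_mode * np.pi * rho_v)
                for q_mode in (0, 1, 2, 3):
                    a, bq = rng.normal(size=2)
                    field += radial * (a * np.cos(q_mode * theta_v)
                                       + bq * np.sin(q_mode * theta_v))
            rms = np.sqrt((field**2).mean())
            if rms > 0:
                vertices[sl, 2] += params.relief_amp * field / rms
    if params.shear:
        vertices = vertices.copy()
        vertices[:, 0] += params.shear * vertices[:, 1]
    if params.noise_sd > 0:
        vertices = vertices + rng.normal(0.0, params.noise_sd, vertices.shape)

    return TriangleMesh(vertices, np.vstack(faces))


def random_rigid_transform(rng: np.random.Generator, max_shift: float = 100.0):
    """A uniformly random proper rotation and a uniform translation."""
    rotation = Rotation.random(random_state=rng).as_matrix()
    translation = rng.uniform(-max_shift, max_shift, 3)
    return rotation, translation


# ---------------------------------------------------------------------------
# assemblages

# dimensionless shape descriptors drawn with the group's shape dispersion;
# size (length) is drawn separately, since Procrustes scaling removes it
_SHAPE_DESCRIPTORS = ("planform_exponent", "tip_taper", "edge_convexity",
                      "relief_amp")
_TRUTH_FIELDS = ("length", "width", "thickness", "planform_exponent",
                 "tip_taper", "edge_convexity", "relief_amp")


@dataclass(frozen=True)
class GroupSpec:
    """One group of an assemblage: mean shape parameters plus dispersion.

    ``shape_sd`` is the relative SD applied to every dimensionless shape
    descriptor (elongation length/width, flatness width/thickness,
    planform exponent, tip taper, edge convexity) — this is the
    dispersion that survives Procrustes scaling and becomes shape
    variability.  ``size_sd`` disperses overall size (length) and is
    removed by GPA.
    """

    name: str
    n: int
    mean: BifaceParams = field(default_factory=BifaceParams)
    shape_sd: float = 0.05
    size_sd: float = 0.05
    shear_sd: float = 0.0  # additive SD on the (zero-mean) shear

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group '{self.name}' has no items")


@dataclass(frozen=True)
class AssemblageSpec:
    """A multi-group assemblage with known ground truth.

    Defaults mirror the study conditions the toolkit targets: 20 items in
    a high-dispersion group versus 9 in a low-dispersion group, with a
    mild mean-shape offset (the second group more elongated and flatter).
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec(
            name="basalt", n=20,
            mean=BifaceParams(length=120.0, width=70.0, thickness=34.0,
                              edge_convexity=2.4, relief_amp=1.5, noise_sd=0.1),
            shape_sd=0.075,
        ),
        GroupSpec(
            name="flint", n=9,
            mean=BifaceParams(length=126.0, width=66.0, thickness=28.0,
                              edge_convexity=1.8, relief_amp=1.0, noise_sd=0.1),
            shape_sd=0.05,
        ),
    )
    seed: int = 0

    @property
    def n_items(self) -> int:
        return sum(g.n for g in self.groups)


def _draw_params(group: GroupSpec, rng: np.random.Generator,
                 item_seed: int) -> BifaceParams:
    mean = group.mean

    def jitter(value: float, sd: float) -> float:
        return max(rng.normal(value, sd * abs(value)), 0.05 * abs(value))

    length = jitter(mean.length, group.size_sd)
    elongation = jitter(mean.length / mean.width, group.shape_sd)
    flatness = jitter(mean.width / mean.thickness, group.shape_sd)
    fields = {
        "length": length,
        "width": length / max(elongation, 1.0),
        "thickness": length / max(elongation, 1.0) / max(flatness, 1.0),
    }
    for name in _SHAPE_DESCRIPTORS:
        fields[name] = jitter(getattr(mean, name), group.shape_sd)
    shear = rng.normal(0.0, group.shear_sd) if group.shear_sd > 0 else mean.shear
    return replace(mean, shear=shear, seed=item_seed, **fields)


def generate_assemblage(
    spec: AssemblageSpec,
) -> tuple[dict[str, TriangleMesh], pd.DataFrame]:
    """Draw an assemblage: one mesh per item plus the ground-truth table.

    Item names are ``<G><ii>`` (first letter of the group name, 1-based
    index), e.g. B01..B20, F01..F09.  Reproducible from ``spec.seed`` via
    per-item child seeds.
    """
    root = np.random.SeedSequence(spec.seed)
    group_seqs = root.spawn(len(spec.groups))
    meshes: dict[str, TriangleMesh] = {}
    rows = []
    for group, seq in zip(spec.groups, group_seqs):
        rng = np.random.default_rng(seq)
        item_seeds = seq.generate_state(group.n) >> 1  # keep below 2**31
        for i in range(group.n):
            name = f"{group.name[:1].upper()}{i + 1:02d}"
            params = _draw_params(group, rng, int(item_seeds[i]))
            meshes[name] = generate_biface(params)
            rows.append({"item": name, "group": group.name,
                         **{f: getattr(params, f) for f in _TRUTH_FIELDS},
                         "shear": params.shear, "noise_sd": params.noise_sd,
                         "seed": params.seed})
    truth = pd.DataFrame(rows).set_index("item")
    return meshes, truth


def write_assemblage(spec: AssemblageSpec, folder: str | Path,
                     mesh_format: str = "wrl") -> pd.DataFrame:
    """Materialize an assemblage on disk: meshes, truth table, group table."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    meshes, truth = generate_assemblage(spec)
    for name, mesh in meshes.items():
        write_mesh(mesh, folder / f"{name}.{mesh_format}")
    truth.to_csv(folder / "truth.csv")
    truth[["group"]].rename(columns={"group": "attr1"}).to_csv(folder / "groups.csv")
    return truth
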