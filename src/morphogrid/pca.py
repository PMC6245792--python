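"""Shape-space principal component analysis and the warp tool.

PCA operates on the flattened Procrustes coordinates (covariance PCA, no
standardization — coordinates share a unit).  With n items and 3k
coordinates, 3k >> n, so the decomposition runs in dual/economy mode via
the SVD of the centered n x 3k matrix, which is exact.  At most n - 1
components carry variance.

A hypothetical shape with score s on component c (and zero on all
others) is ``mean + s * c`` — the warp tool; the per-landmark loading
magnitudes of a component highlight where on the artifact that shape
trend acts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpa import AlignedSample
from .mesh_io import GridConfig, LandmarkRecord


@dataclass
class ShapePCA:
    """Eigendecomposition of the aligned sample's shape covariance.

    ``components`` is (r, 3k) orthonormal, eigenvalues descending;
    ``scores`` (n, r) are centered projections; ``variance_fractions``
    sum to one.  Eigenvalues use the sample (n - 1) normalization, so
    their sum equals the total Procrustes variance.
    """

    names: list[str]
    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    grid: GridConfig | None = None

    @property
    def n_items(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def shape_pca(aligned: AlignedSample, grid: GridConfig | None = None) -> ShapePCA:
    """PCA of an aligned sample (needs n >= 3 items)."""
    n = aligned.n_items
    if n < 3:
        raise ValueError(f"PCA needs at least 3 items, got {n}")
    X = aligned.flattened()
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # rank cut: keep components with non-negligible singular value
    keep = S > S[0] * 1e-12 if S[0] > 0 else S > 0
    keep &= np.arange(len(S)) < n - 1
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    components = Vt
    scores = U * S
    # sign convention: each component's largest-magnitude entry positive
    for i in range(len(S)):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    eigenvalues = S**2 / (n - 1)
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return ShapePCA(
        names=list(aligned.names),
        mean=mean,
        components=components,
        eigenvalues=eigenvalues,
        scores=scores,
        variance_fractions=fractions,
        grid=grid,
    )


def variability_report(pca: ShapePCA) -> pd.DataFrame:
    """Per-PC absolute, relative and cumulative explained variability."""
    return pd.DataFrame(
        {
            "absolute": pca.eigenvalues,
            "relative": pca.variance_fractions,
            "cumulative": np.cumsum(pca.variance_fractions),
        },
        index=pd.Index(
            [f"PC{i + 1:02d}" for i in range(pca.n_components)], name="pc"
        ),
    )


def warp(
    pca: ShapePCA, pc: int, score: float, name: str | None = None
) -> tuple[LandmarkRecord, np.ndarray]:
    """Hypothetical shape with the given score on one PC, zero elsewhere.

    ``pc`` is 1-based.  Returns the warped configuration and the
    per-landmark loading magnitudes of that component, normalized so the
    most variable landmark is 1.
    """
    if not 1 <= pc <= pca.n_components:
        raise IndexError(f"PC {pc} out of range 1..{pca.n_components}")
    component = pca.components[pc - 1]
    vector = pca.mean + score * component
    loadings = np.linalg.norm(component.reshape(-1, 3), axis=1)
    peak = loadings.max()
    if peak > 0:
        loadings = loadings / peak
    record = LandmarkRecord(
        name=name or f"warp_PC{pc:02d}_{score:+g}",
        coordinates=vector.reshape(-1, 3),
        grid=pca.grid,
    )
    return record, loadings


def reconstruct(pca: ShapePCA, scores: np.ndarray) -> np.ndarray:
    """Configuration (k, 3) from a full score vector: mean + scores @ components."""
    scores = np.asarray(scores, dtype=float)
    return (pca.mean + scores @ pca.components).reshape(-1, 3)


def raw_results(pca: ShapePCA, aligned: AlignedSample) -> pd.DataFrame:
    """Per-item PC scores plus the pre-scaling centroid size (mm)."""
    frame = pd.DataFrame(
        pca.scores,
        index=pd.Index(pca.names, name="item"),
        columns=[f"PC{i + 1:02d}" for i in range(pca.n_components)],
    )
    frame["centroid_size"] = aligned.centroid_sizes
    return frame
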