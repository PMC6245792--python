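"""Generalized Procrustes superimposition.

Location is removed by centering, scale by division with centroid size,
and orientation by iteratively rotating every configuration onto the
current consensus with the Kabsch solution (proper rotations only —
artifacts have a fixed handedness after pose normalization, so
reflections are never admitted).  The consensus is the arithmetic mean of
the aligned configurations, re-normalized to unit centroid size between
iterations.  After superimposition, Euclidean distances between flattened
coordinate vectors are distances in shape space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mesh_io import LandmarkRecord


class AlignmentError(ValueError):
    """Raised when a sample cannot be superimposed."""


class RankDeficientWarning(UserWarning):
    """Cross-covariance in an orthogonal fit was rank-deficient."""


@dataclass
class AlignedSample:
    """GPA output.

    ``aligned`` is (n, k, 3) in dimensionless Procrustes coordinates (all
    configurations centered, unit centroid size); ``centroid_sizes`` are
    the pre-scaling sizes in mm; ``consensus`` is the arithmetic mean of
    the aligned configurations.
    """

    names: list[str]
    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_items(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        """(n, 3k) matrix of aligned coordinate vectors."""
        return self.aligned.reshape(self.n_items, -1)


def centroid_size(coordinates: np.ndarray | LandmarkRecord) -> float:
    """Square root of the summed squared landmark distances to the centroid."""
    if isinstance(coordinates, LandmarkRecord):
        coordinates = coordinates.coordinates
    coordinates = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    centered = coordinates - coordinates.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _center_and_scale(coordinates: np.ndarray) -> tuple[np.ndarray, float]:
    centered = coordinates - coordinates.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size <= 0:
        raise AlignmentError("configuration with zero centroid size")
    return centered / size, size


def optimal_rotation(config: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch rotation R (det +1) minimizing ``||config @ R - reference||``."""
    H = config.T @ reference
    U, S, Vt = np.linalg.svd(H)
    if S[-1] < 1e-12 * max(S[0], 1e-300):
        warnings.warn(
            "rank-deficient cross-covariance; SVD sign convention applied",
            RankDeficientWarning,
            stacklevel=2,
        )
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def opa_align(config: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Orthogonally superimpose one configuration onto a reference.

    Both inputs must be centered with unit centroid size and equal
    landmark counts; only a proper rotation is applied.
    """
    config = np.asarray(config, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if config.shape != reference.shape:
        raise AlignmentError(
            f"landmark counts differ: {config.shape} vs {reference.shape}"
        )
    return config @ optimal_rotation(config, reference)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two raw configurations."""
    a_n, _ = _center_and_scale(np.asarray(a, dtype=float))
    b_n, _ = _center_and_scale(np.asarray(b, dtype=float))
    return float(np.linalg.norm(opa_align(a_n, b_n) - b_n))


def gpa(
    sample: Sequence[LandmarkRecord] | Sequence[np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedSample:
    """Generalized Procrustes analysis of a same-configuration sample.

    Iterates rotation-to-consensus until the consensus moves by less than
    ``tol`` (RMS), at most ``max_iter`` sweeps.  The Procrustes objective
    (summed squared distances to the consensus) is non-increasing across
    iterations; the trace is kept on the result for inspection.
    """
    if len(sample) < 2:
        raise AlignmentError("GPA needs at least 2 configurations")
    names = []
    arrays = []
    for i, item in enumerate(sample):
        if isinstance(item, LandmarkRecord):
            names.append(item.name)
            arrays.append(item.coordinates)
        else:
            names.append(f"item{i + 1:03d}")
            arrays.append(np.asarray(item, dtype=float).reshape(-1, 3))
    counts = {len(a) for a in arrays}
    if len(counts) > 1:
        offenders = ", ".join(
            f"{n} ({len(a)} landmarks)" for n, a in zip(names, arrays)
        )
        raise AlignmentError(f"mismatched landmark counts: {offenders}")

    scaled = []
    sizes = []
    for a in arrays:
        s, size = _center_and_scale(a)
        scaled.append(s)
        sizes.append(size)
    aligned = np.stack(scaled)
    n = len(aligned)

    # initial reference: the first item (sample order is the caller's,
    # conventionally sorted file names)
    reference = aligned[0]
    trace = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = opa_align(aligned[i], reference)
        consensus = aligned.mean(axis=0)
        trace.append(float(((aligned - consensus) ** 2).sum()))
        consensus_size = np.sqrt((consensus**2).sum())
        if consensus_size <= 0:
            raise AlignmentError("degenerate consensus")
        new_reference = consensus / consensus_size
        shift = float(np.sqrt(((new_reference - reference) ** 2).mean()))
        reference = new_reference
        if shift <= tol:
            break

    return AlignedSample(
        names=names,
        aligned=aligned,
        consensus=aligned.mean(axis=0),
        centroid_sizes=np.asarray(sizes, dtype=float),
        iterations=iterations,
        objective_trace=np.asarray(trace),
    )
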