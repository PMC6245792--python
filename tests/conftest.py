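"""Shared fixtures: small synthetic bifaces and a reusable Monte-Carlo
harness of end-to-end two-group analyses."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import morphogrid as mg

# reduced problem sizes used by the heavier harnesses: mesh resolution 10
# (~1.5k faces), 96 silhouette stations, 2-degree coarse angular grid,
# 20x20 landmark grid
HARNESS = dict(stations=96, coarse_step_deg=2.0)
HARNESS_GRID = mg.GridConfig(20, 20)
HARNESS_RESOLUTION = 10


@pytest.fixture(scope="session")
def smooth_biface() -> mg.TriangleMesh:
    """Noise-free, perfectly bilaterally symmetric biface in canonical pose."""
    return mg.generate_biface(mg.BifaceParams())


@pytest.fixture(scope="session")
def noisy_biface() -> mg.TriangleMesh:
    """A realistic single specimen: scar relief + scanner noise."""
    return mg.generate_biface(
        mg.BifaceParams(relief_amp=1.2, noise_sd=0.1, resolution=12, seed=7)
    )


@pytest.fixture(scope="session")
def small_aligned_sample() -> tuple[mg.AlignedSample, pd.Series]:
    """One fully processed two-group assemblage at harness scale."""
    aligned, labels, _ = _run_assemblage(seed=11)
    return aligned, labels


def _reduced_spec(seed: int) -> mg.AssemblageSpec:
    base = mg.AssemblageSpec()
    groups = tuple(
        mg.GroupSpec(
            name=g.name, n=g.n,
            mean=replace(g.mean, resolution=HARNESS_RESOLUTION),
            shape_sd=g.shape_sd, size_sd=g.size_sd, shear_sd=g.shear_sd,
        )
        for g in base.groups
    )
    return mg.AssemblageSpec(groups=groups, seed=seed)


def _run_assemblage(seed: int):
    """Generate, position, landmark and superimpose one assemblage."""
    meshes, truth = mg.generate_assemblage(_reduced_spec(seed))
    records = []
    for name in sorted(meshes):
        canonical, _ = mg.normalize_pose(meshes[name], **HARNESS)
        records.append(mg.fit_grid(canonical, HARNESS_GRID, name=name))
    aligned = mg.gpa(records)
    labels = pd.Series(truth["group"], index=truth.index)[aligned.names]
    return aligned, labels, truth


N_RECOVERY_RUNS = 200


@pytest.fixture(scope="session")
def recovery_runs() -> pd.DataFrame:
    """Monte-Carlo harness: 200 independent end-to-end two-group analyses.

    Each run generates a fresh 20 + 9 item assemblage (group-1 shape
    dispersion 1.5x group-2's), runs the full pipeline at harness scale
    and records the measured variability ratio and the three test
    p-values.
    """
    rows = []
    for seed in range(N_RECOVERY_RUNS):
        aligned, labels, _ = _run_assemblage(seed)
        summary = mg.group_summaries(aligned, labels)
        tests = mg.significance_tests(aligned, labels, "basalt", "flint")
        rows.append({
            "seed": seed,
            "ratio": summary.loc["basalt", "variability"]
            / summary.loc["flint", "variability"],
            "p_variability": tests["variability"].p_value,
            "p_mean_shape": tests["mean_shape"].p_value,
            "p_size": tests["size"].p_value,
        })
    return pd.DataFrame(rows).set_index("seed")


@pytest.fixture
def rng() -> np.random.Generator:
    # fresh per test: results do not depend on test execution order
    return np.random.default_rng(20260924)
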