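"""Batch project management: the end-to-end analysis pipeline.

A project is a folder of input meshes (or landmark containers) plus a
state file.  Steps run strictly forward — position, landmark, analyze
(GPA + PCA), stats — each writing its exports into a subfolder and
updating ``project.json``; re-running a completed step is a no-op, so a
saved project can be resumed.  Item ordering is lexicographic by file
name everywhere, which (together with fixed seeds) makes every numeric
export reproducible bitwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gpa import AlignedSample, gpa
from .groupstats import (
    AttributeAssignment,
    confidence_ellipse,
    dimension_decomposition,
    group_mean_distances,
    group_summaries,
    significance_tests,
)
from .landmarking import fit_grid
from .mesh_io import (
    GridConfig,
    LandmarkFormatError,
    read_group_table,
    read_landmarks,
    read_mesh,
    write_landmarks,
    write_mesh,
)
from .pca import ShapePCA, raw_results, shape_pca, variability_report, warp
from .positioning import apply_review, normalize_pose

MESH_SUFFIXES = (".wrl", ".ply", ".obj")

log = logging.getLogger("morphogrid")


class PipelineError(RuntimeError):
    pass


@dataclass
class ProjectConfig:
    """Everything a batch run needs; serializable to/from JSON."""

    data_folder: str
    title: str = "untitled"
    latitudes: int = 20
    per_latitude: int = 20
    inset: float | None = None
    stations: int = 256
    coarse_step_deg: float = 0.5
    refine_tol_deg: float = 1e-3
    attribute_file: str | None = None
    compare: list[list[str]] = field(default_factory=list)
    review_file: str | None = None
    ellipse_level: float = 0.90

    @classmethod
    def load(cls, path: str | Path) -> "ProjectConfig":
        doc = json.loads(Path(path).read_text())
        return cls(**doc)


class Project:
    """State and exports of one analysis project."""

    def __init__(self, config: ProjectConfig):
        self.config = config
        self.data = Path(config.data_folder)
        self.folder = self.data / "project"
        self.folder.mkdir(parents=True, exist_ok=True)
        self.state_path = self.folder / "project.json"
        self.state: dict = {"title": config.title, "steps": [], "version": __version__}
        if self.state_path.exists():
            self.state = json.loads(self.state_path.read_text())
        self._configure_log()

    def _configure_log(self) -> None:
        # one logger per project folder so concurrent projects in the
        # same process do not write into each other's run.log
        self.log = log.getChild(f"project.{abs(hash(str(self.folder)))}")
        target = (self.folder / "run.log").resolve()
        if not any(
            Path(getattr(h, "baseFilename", "")) == target
            for h in self.log.handlers
        ):
            handler = logging.FileHandler(target)
            handler.setFormatter(
                logging.Formatter("%(asctime)s %(levelname)s %(message)s")
            )
            self.log.addHandler(handler)
        self.log.setLevel(logging.INFO)

    def _save(self) -> None:
        self.state_path.write_text(json.dumps(self.state, indent=2))

    def done(self, step: str) -> bool:
        return step in self.state["steps"]

    def _complete(self, step: str) -> None:
        if step not in self.state["steps"]:
            self.state["steps"].append(step)
        self._save()
        self.log.info("completed step '%s' (version %s)", step, __version__)

    # -- steps ------------------------------------------------------------

    def mesh_paths(self) -> list[Path]:
        paths = sorted(
            p for p in self.data.iterdir()
            if p.suffix.lower() in MESH_SUFFIXES and p.is_file()
        )
        if not paths:
            raise PipelineError(f"no meshes found in {self.data}")
        return paths

    def position(self) -> pd.DataFrame:
        """Pose-normalize every mesh; write positioned meshes + report."""
        report_path = self.folder / "positioning_report.csv"
        out = self.folder / "positioned"
        if self.done("position"):
            return pd.read_csv(report_path, index_col=0)
        out.mkdir(exist_ok=True)
        review = None
        if self.config.review_file:
            review = pd.read_csv(self.config.review_file).set_index("item")
        rows = []
        for path in self.mesh_paths():
            mesh = read_mesh(path)
            canonical, pose = normalize_pose(
                mesh,
                stations=self.config.stations,
                coarse_step_deg=self.config.coarse_step_deg,
                refine_tol_deg=self.config.refine_tol_deg,
            )
            applied = {"flip_y": 0, "rotate_z_quarters": 0}
            if review is not None and path.stem in review.index:
                applied = {
                    "flip_y": int(review.loc[path.stem, "flip_y"]),
                    "rotate_z_quarters": int(review.loc[path.stem, "rotate_z_quarters"]),
                }
                canonical = apply_review(
                    canonical, bool(applied["flip_y"]), applied["rotate_z_quarters"]
                )
            write_mesh(canonical, out / f"{path.stem}.ply")
            rows.append({
                "item": path.stem,
                "asymmetry_mm2": pose.asymmetry,
                "flags": ";".join(pose.flags),
                **applied,
            })
            self.log.info("positioned %s (asymmetry %.4g mm^2, flags=%s)",
                     path.stem, pose.asymmetry, pose.flags)
        report = pd.DataFrame(rows).set_index("item")
        report.to_csv(report_path)
        self._complete("position")
        return report

    def landmark(self) -> list[Path]:
        """Fit the grid on every positioned mesh; write .3dl.json files."""
        out = self.folder / "landmarks"
        if self.done("landmark"):
            return sorted(out.glob("*.3dl.json"))
        if not self.done("position"):
            self.position()
        out.mkdir(exist_ok=True)
        config = GridConfig(self.config.latitudes, self.config.per_latitude)
        written = []
        for path in sorted((self.folder / "positioned").glob("*.ply")):
            mesh = read_mesh(path)
            record = fit_grid(mesh, config, name=path.stem, inset=self.config.inset)
            target = out / f"{path.stem}.3dl.json"
            write_landmarks(record, target)
            written.append(target)
            self.log.info("landmarked %s: %d landmarks", path.stem, record.n_landmarks)
        self._complete("landmark")
        return written

    def _load_records(self):
        files = sorted((self.folder / "landmarks").glob("*.3dl.json"))
        if not files:
            raise PipelineError("no landmark files; run the landmark step first")
        records = [read_landmarks(p) for p in files]
        grids = {
            (r.grid.latitudes, r.grid.per_latitude) if r.grid else ("ungridded",)
            for r in records
        }
        if len(grids) > 1:
            detail = ", ".join(
                f"{r.name} ({r.grid.latitudes}x{r.grid.per_latitude})" if r.grid
                else f"{r.name} (ungridded)"
                for r in records
            )
            raise LandmarkFormatError(
                f"mixed grid configurations, refusing GPA: {detail}"
            )
        return records

    def analyze(self) -> tuple[AlignedSample, ShapePCA]:
        """GPA then PCA; exports aligned coordinates, sizes, scores, variance."""
        if not self.done("landmark"):
            self.landmark()
        records = self._load_records()
        aligned = gpa(records)
        pca = shape_pca(aligned, grid=records[0].grid)
        gpa_dir = self.folder / "GPA"
        pca_dir = self.folder / "PCA"
        gpa_dir.mkdir(exist_ok=True)
        pca_dir.mkdir(exist_ok=True)
        pd.DataFrame(
            aligned.flattened(), index=pd.Index(aligned.names, name="item")
        ).to_csv(gpa_dir / "aligned.csv", float_format="%.17g")
        pd.Series(
            aligned.centroid_sizes, index=pd.Index(aligned.names, name="item"),
            name="centroid_size",
        ).to_csv(gpa_dir / "centroid_sizes.csv", float_format="%.17g")
        raw_results(pca, aligned).to_csv(pca_dir / "scores.csv", float_format="%.17g")
        variability_report(pca).to_csv(pca_dir / "variance.csv", float_format="%.17g")
        self._complete("analyze")
        self.log.info("GPA converged in %d iterations; %d PCs", aligned.iterations,
                 pca.n_components)
        return aligned, pca

    def stats(self) -> dict:
        """Group summaries, distances, dendrogram and significance tests."""
        if not self.config.attribute_file:
            raise PipelineError("stats step needs an attribute file")
        aligned, pca = self.analyze()
        labels_frame = read_group_table(self.config.attribute_file)
        assignment = AttributeAssignment.from_frame(labels_frame)
        out = self.folder / "stats"
        out.mkdir(exist_ok=True)
        results: dict = {}
        attributes = assignment.attributes
        if len(attributes) == 2:
            attributes = attributes + ["combination"]
        for attribute in attributes:
            labels = assignment.column(attribute, aligned.names)
            summary = group_summaries(aligned, labels)
            summary.to_csv(out / f"summary_{attribute}.csv", float_format="%.17g")
            decomp = {}
            X3 = aligned.aligned
            for group, items in labels.groupby(labels).groups.items():
                idx = [aligned.names.index(i) for i in items]
                if len(idx) >= 2:
                    decomp[group] = dimension_decomposition(X3[idx])
            pd.DataFrame(decomp, index=["X%", "Y%", "Z%"]).T.rename_axis("group").to_csv(
                out / f"decomposition_{attribute}.csv", float_format="%.17g"
            )
            if labels.nunique() >= 2:
                matrix, _, newick = group_mean_distances(aligned, labels)
                matrix.to_csv(out / f"distances_{attribute}.csv", float_format="%.17g")
                (out / f"dendrogram_{attribute}.nwk").write_text(newick + "\n")
            ellipse_rows = []
            for group, items in labels.groupby(labels).groups.items():
                idx = [aligned.names.index(i) for i in items]
                if len(idx) < 3 or pca.n_components < 2:
                    continue
                ell = confidence_ellipse(
                    pca.scores[idx, :2], level=self.config.ellipse_level
                )
                angle = float(np.degrees(
                    np.arctan2(ell.axes[1, 0], ell.axes[0, 0])
                ))
                ellipse_rows.append({
                    "group": group, "level": ell.level,
                    "center_pc1": ell.center[0], "center_pc2": ell.center[1],
                    "semi_major": ell.semi_axes[0],
                    "semi_minor": ell.semi_axes[1],
                    "angle_deg": angle, "degenerate": ell.degenerate,
                })
            if ellipse_rows:
                pd.DataFrame(ellipse_rows).set_index("group").to_csv(
                    out / f"ellipses_{attribute}.csv", float_format="%.17g"
                )
            results[attribute] = {"summary": summary.to_dict()}
        tests: dict = {}
        for pair in self.config.compare:
            attribute = attributes[0] if len(pair) == 2 else pair[0]
            a, b = pair[-2], pair[-1]
            labels = assignment.column(attribute, aligned.names)
            outcome = significance_tests(aligned, labels, a, b)
            tests[f"{a}_vs_{b}"] = {
                name: {
                    "rank_sum": r.rank_sum, "p": r.p_value,
                    "n1": r.n1, "n2": r.n2, "method": r.method,
                }
                for name, r in outcome.items()
            }
        (out / "tests.json").write_text(json.dumps(tests, indent=2))
        results["tests"] = tests
        self._complete("stats")
        return results

    def export_warp(self, pc: int, score: float, path: str | Path) -> None:
        """Warp along one PC and export the shape as a mesh/point set."""
        aligned, pca = self.analyze()
        record, _ = warp(pca, pc, score)
        points = record.coordinates
        # gridded configurations export as a triangulated surface,
        # ungridded ones as a plain xyz point list
        if record.grid is not None:
            write_mesh(_grid_surface(points, record.grid), path)
        else:
            Path(path).write_text(
                "\n".join(f"{x!r} {y!r} {z!r}" for x, y, z in points)
            )


def _grid_surface(points: np.ndarray, grid: GridConfig):
    """Triangulate a gridded landmark configuration into a surface mesh."""
    from .mesh_io import TriangleMesh

    L, M = grid.latitudes, grid.per_latitude
    faces = []
    for block in (0, 1):
        offset = block * L * M
        for i in range(L - 1):
            for j in range(M - 1):
                a = offset + i * M + j
                b = a + 1
                c = a + M
                d = c + 1
                faces.append((a, b, d))
                faces.append((a, d, c))
    return TriangleMesh(points, np.asarray(faces, dtype=np.int64))


def run_pipeline(config: ProjectConfig) -> Project:
    """Run every configured step of a project, forward only."""
    project = Project(config)
    project.position()
    project.landmark()
    project.analyze()
    if config.attribute_file:
        project.stats()
    return project
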