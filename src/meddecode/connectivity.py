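"""Fisher-z Pearson connectivity matrices and the decoding feature table.

One square correlation matrix per (subject, condition, block); the strict
upper triangle, Fisher z-transformed, is the feature vector.  With the
default study design the expert group contributes 36 samples per class
(3 blocks x 12 subjects) and the novice group 30 per class (3 x 10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import EdgeTable, build_edge_table
from .synthetic import CONDITIONS, ROITimeSeries, StudyDataset
from .util import ValidationError, log

R_CLIP = 1.0 - 1e-7  # keeps atanh finite on degenerate (perfectly correlated) pairs


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Fisher-z matrix; diagonal is ignored (set to 0)."""

    z_values: np.ndarray
    provenance: tuple[str, str, str, int] | None = None  # (group, subject, condition, block)

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValidationError("connectivity matrix must be square")
        if not np.allclose(z, z.T, atol=1e-12):
            raise ValidationError("connectivity matrix must be symmetric")
        off = z[~np.eye(z.shape[0], dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValidationError("non-finite off-diagonal z values")
        self.z_values = z

    @property
    def n_rois(self) -> int:
        return self.z_values.shape[0]


def correlation_matrix(ts: ROITimeSeries,
                       provenance=None) -> ConnectivityMatrix:
    """Pearson correlations between ROI time courses, Fisher z-transformed.

    r is clipped to +/-(1 - 1e-7) before atanh so perfectly (anti)correlated
    pairs stay finite (z ~ +/-8.4).
    """
    if ts.n_volumes < 3:
        raise ValidationError("need at least 3 usable volumes for correlation")
    sd = ts.values.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValidationError(
            f"zero-variance ROI column(s): {dead.tolist()}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z_values=z, provenance=provenance)


def vectorize_upper(cm: ConnectivityMatrix, edges: EdgeTable) -> np.ndarray:
    """Flatten the strict upper triangle in the canonical edge order."""
    if cm.n_rois != edges.n_rois:
        raise ValidationError(
            f"matrix has {cm.n_rois} ROIs but edge table expects {edges.n_rois}")
    return cm.z_values[edges.roi_i, edges.roi_j]


def matrix_from_vector(vec: np.ndarray, edges: EdgeTable) -> np.ndarray:
    """Scatter an edge vector back into a symmetric matrix (diagonal 0)."""
    out = np.zeros((edges.n_rois, edges.n_rois))
    out[edges.roi_i, edges.roi_j] = vec
    out[edges.roi_j, edges.roi_i] = vec
    return out


@dataclass
class DecodingDataset:
    """Sample x edge-feature matrix with labels and subject bookkeeping."""

    X: np.ndarray               # (n_samples, n_edges) Fisher-z features
    y: np.ndarray               # (n_samples,) labels in {"FA", "OM"}
    subject: np.ndarray         # (n_samples,) subject id strings
    group: str
    edge_table: EdgeTable
    ages: dict[str, float] = field(default_factory=dict)  # subject -> years

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subject = np.asarray(self.subject)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != self.subject.shape[0]:
            raise ValidationError("X, y, subject must have equal sample counts")
        bad = set(np.unique(self.y)) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject:
            seen.setdefault(str(s), None)
        return list(seen)

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.y == c).sum()) for c in CONDITIONS}

    def sample_ages(self) -> np.ndarray:
        return np.array([self.ages[str(s)] for s in self.subject])

    # -- text round trip (TSV matrix + JSON manifest) -----------------------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(f"{prefix}.features.tsv", self.X, delimiter="\t", fmt="%.8g")
        manifest = {
            "group": self.group,
            "y": self.y.tolist(),
            "subject": self.subject.tolist(),
            "ages": self.ages,
            "n_rois": self.edge_table.n_rois,
        }
        Path(f"{prefix}.manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, prefix: str | Path, parcellation) -> "DecodingDataset":
        manifest = json.loads(Path(f"{prefix}.manifest.json").read_text())
        X = np.loadtxt(f"{prefix}.features.tsv", delimiter="\t", ndmin=2)
        edges = build_edge_table(parcellation)
        if parcellation.n_rois != manifest["n_rois"]:
            raise ValidationError("parcellation does not match saved dataset")
        return cls(X=X, y=np.array(manifest["y"]),
                   subject=np.array(manifest["subject"]),
                   group=manifest["group"], edge_table=edges,
                   ages={k: float(v) for k, v in manifest["ages"].items()})


def assemble_dataset(study: StudyDataset, group: str) -> DecodingDataset:
    """One feature vector per usable (subject, condition, block).

    Samples follow the deterministic (subject, condition, block) order so a
    fixed seed reproduces downstream splits exactly.  Subjects missing an
    entire condition (all blocks unusable) are dropped with a warning.
    """
    edges = build_edge_table(study.parcellation)
    by_subject: dict[str, list] = {}
    for b in study.group_blocks(group):
        if b.usable:
            by_subject.setdefault(b.subject, []).append(b)
    rows, labels, subjects = [], [], []
    for subject in study.subjects(group):
        blocks = by_subject.get(subject, [])
        conds = {b.condition for b in blocks}
        if set(CONDITIONS) - conds:
            log.warning("assemble_dataset: subject %s lacks a condition; dropped",
                        subject)
            continue
        for b in sorted(blocks, key=lambda b: (b.condition, b.block)):
            cm = correlation_matrix(
                b.ts, provenance=(b.group, b.subject, b.condition, b.block))
            rows.append(vectorize_upper(cm, edges))
            labels.append(b.condition)
            subjects.append(subject)
    counts = {c: labels.count(c) for c in CONDITIONS}
    if counts["FA"] != counts["OM"]:
        log.warning("assemble_dataset(%s): unbalanced classes %s", group, counts)
    ages = {s: study.ages[(group, s)] for s in study.subjects(group)
            if s in {str(x) for x in subjects}}
    return DecodingDataset(X=np.array(rows), y=np.array(labels),
                           subject=np.array(subjects), group=group,
                           edge_table=edges, ages=ages)


def save_matrix_csv(cm: ConnectivityMatrix, parcellation, path: str | Path) -> None:
    names = [r.name for r in parcellation.rois]
    pd.DataFrame(cm.z_values, index=names, columns=names).to_csv(path)
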