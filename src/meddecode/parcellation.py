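"""ROI/atlas metadata and the canonical edge indexing.

The parcellation table fixes ROI identity (name, network, hemisphere) and row
order defines the 0-based ``roi_id`` used by every downstream stage.  The edge
table enumerates the strict upper triangle of the ROI x ROI matrix in
row-major order; that ordering is the coordinate system for all edge features.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .util import FormatError, ValidationError

HEMISPHERES = ("left", "right", "midline")
_HEMI_TOKENS = {"L": "left", "R": "right", "M": "midline",
                "left": "left", "right": "right", "midline": "midline"}

#: hemisphere classes an edge can fall into
EDGE_CLASSES = ("intra_left", "intra_right", "inter", "other")


@dataclass(frozen=True)
class ROIRecord:
    roi_id: int
    name: str
    network: str
    hemisphere: str  # one of HEMISPHERES

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"ROI {self.name!r}: hemisphere {self.hemisphere!r} not in {HEMISPHERES}"
            )
        if not self.network:
            raise ValidationError(f"ROI {self.name!r}: empty network label")


@dataclass(frozen=True)
class ParcellationTable:
    """Ordered ROI metadata; row order defines roi_id."""

    rois: tuple[ROIRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.roi_id for r in self.rois]
        if ids != list(range(len(self.rois))):
            raise ValidationError("roi_id must be contiguous from 0 in row order")
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate ROI names: {dupes}")

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def networks(self) -> tuple[str, ...]:
        """Distinct network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.rois:
            seen.setdefault(r.network, None)
        return tuple(seen)

    @property
    def network_labels(self) -> np.ndarray:
        return np.array([r.network for r in self.rois])

    @property
    def hemisphere_labels(self) -> np.ndarray:
        return np.array([r.hemisphere for r in self.rois])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": [r.name for r in self.rois],
             "network": [r.network for r in self.rois],
             "hemisphere": [r.hemisphere for r in self.rois]}
        )


def load_parcellation(path: str | Path | None = None) -> ParcellationTable:
    """Load a parcellation TSV (columns name, network, hemisphere).

    With ``path=None`` the bundled synthetic 90-ROI / 14-network fixture is
    loaded.  The fixture mirrors the structure of the Shirer et al. functional
    atlas (ROI counts per network, network names) with synthetic ROI names and
    plausible hemisphere assignments; it is a stand-in, not the published ROI
    list.  Hemisphere tokens accepted: L, R, M (or spelled out).
    """
    if path is None:
        with resources.as_file(
            resources.files("meddecode").joinpath("data/shirer90_synthetic.tsv")
        ) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "network", "hemisphere"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"parcellation table missing columns: {sorted(missing)}")
    rois = []
    for i, row in enumerate(frame.itertuples(index=False)):
        token = str(row.hemisphere).strip()
        if token not in _HEMI_TOKENS:
            raise ValidationError(
                f"row {i} ({row.name!r}): unknown hemisphere token {token!r}"
            )
        rois.append(
            ROIRecord(roi_id=i, name=str(row.name).strip(),
                      network=str(row.network).strip(),
                      hemisphere=_HEMI_TOKENS[token])
        )
    return ParcellationTable(rois=tuple(rois))


def edge_index(i: int, j: int, n_rois: int) -> int:
    """Edge id of ROI pair (i, j), i < j, in row-major upper-triangle order."""
    if not 0 <= i < j < n_rois:
        raise ValueError(f"need 0 <= i < j < n_rois, got ({i}, {j}, {n_rois})")
    return i * (2 * n_rois - i - 1) // 2 + (j - i - 1)


@dataclass(frozen=True)
class EdgeTable:
    """Canonical enumeration of all ROI pairs (strict upper triangle)."""

    n_rois: int
    roi_i: np.ndarray          # (n_edges,) int
    roi_j: np.ndarray          # (n_edges,) int
    network_i: np.ndarray      # (n_edges,) str
    network_j: np.ndarray      # (n_edges,) str
    hemi_class: np.ndarray     # (n_edges,) str, one of EDGE_CLASSES

    @property
    def n_edges(self) -> int:
        return self.roi_i.shape[0]

    @property
    def edge_ids(self) -> np.ndarray:
        return np.arange(self.n_edges)

    def encode(self, i: int, j: int) -> int:
        return edge_index(min(i, j), max(i, j), self.n_rois)

    def decode(self, edge_id: int) -> tuple[int, int]:
        return int(self.roi_i[edge_id]), int(self.roi_j[edge_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"edge_id": self.edge_ids, "roi_i": self.roi_i, "roi_j": self.roi_j,
             "network_i": self.network_i, "network_j": self.network_j,
             "hemi_class": self.hemi_class}
        )


def classify_hemisphere(hemi_a: str, hemi_b: str) -> str:
    if "midline" in (hemi_a, hemi_b):
        return "other"
    if hemi_a == hemi_b:
        return "intra_left" if hemi_a == "left" else "intra_right"
    return "inter"


def build_edge_table(parcellation: ParcellationTable) -> EdgeTable:
    """Enumerate the n(n-1)/2 edges of the upper triangle, with metadata.

    Edge k of the row-major traversal maps bijectively to the ROI pair
    (i, j), i < j; hemisphere class derives from the endpoints, with any
    midline endpoint sending the edge to the ``other`` class (excluded from
    intra/inter-hemispheric statistics).
    """
    n = parcellation.n_rois
    if n < 2:
        raise ValidationError(f"need at least 2 ROIs to build edges, got {n}")
    iu, ju = np.triu_indices(n, k=1)
    nets = parcellation.network_labels
    hemis = parcellation.hemisphere_labels
    hemi_class = np.array(
        [classify_hemisphere(hemis[a], hemis[b]) for a, b in zip(iu, ju)]
    )
    return EdgeTable(n_rois=n, roi_i=iu, roi_j=ju,
                     network_i=nets[iu], network_j=nets[ju],
                     hemi_class=hemi_class)


def parcellation_from_lists(names: Sequence[str], networks: Sequence[str],
                            hemispheres: Sequence[str]) -> ParcellationTable:
    """Convenience constructor used by simulations and tests."""
    rois = tuple(
        ROIRecord(i, n, net, _HEMI_TOKENS.get(h, h))
        for i, (n, net, h) in enumerate(zip(names, networks, hemispheres))
    )
    return ParcellationTable(rois=rois)
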