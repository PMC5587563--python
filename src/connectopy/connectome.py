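"""Construction of weighted brain networks from streamline-count matrices.

A connectome is an undirected, weighted graph over an ordered region
parcellation.  Raw streamline counts from probabilistic tractography are
volume-normalised (divided by the product of seed and target ROI volumes),
symmetrised by averaging the two directed entries, and zeroed on the
diagonal.  Group-level density thresholding ranks the edges of the cohort
median matrix and keeps the strongest (100*kappa)% of all possible node
pairs; the same mask is applied to every subject so that a group difference
cannot be introduced by the mask itself.  Original edge weights are kept —
no binarisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .parcellation import RegionParcellation

__all__ = [
    "Connectome",
    "ThresholdMask",
    "build_connectome",
    "extract_hemisphere",
    "median_summary",
    "density_threshold",
    "apply_mask",
    "round_half_up",
    "read_matrix",
    "write_matrix",
    "read_matrix_stack",
    "write_matrix_stack",
    "read_cohort_table",
]


def _check_square_symmetric(w: np.ndarray, name: str = "matrix") -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{name} must be square, got shape {w.shape}")
    if not np.allclose(w, w.T, rtol=1e-10, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    return w


@dataclass
class Connectome:
    """A subject's weighted adjacency matrix plus region metadata.

    Invariants: ``weights`` is symmetric with zero diagonal and
    non-negative entries, and its size matches the parcellation.
    """

    weights: np.ndarray
    parcellation: RegionParcellation
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = _check_square_symmetric(self.weights, "weights")
        if np.any(w < 0):
            raise ValueError("connection weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-connections)")
        if w.shape[0] != self.parcellation.size:
            raise ValueError(
                f"matrix size {w.shape[0]} does not match parcellation "
                f"size {self.parcellation.size}"
            )
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ThresholdMask:
    """Boolean edge mask retaining the strongest (100*kappa)% node pairs."""

    kappa: float
    mask: np.ndarray
    edge_count: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if not np.array_equal(m, m.T) or np.any(np.diag(m)):
            raise ValueError("mask must be symmetric with a false diagonal")
        n = m.shape[0]
        expected = round_half_up(self.kappa * n * (n - 1) / 2)
        if int(np.triu(m, 1).sum()) != expected or expected != self.edge_count:
            raise ValueError("edge_count inconsistent with kappa and mask")
        object.__setattr__(self, "mask", m)


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    This is the convention that reproduces the retained edge counts of a
    density-thresholded network at every grid density: 0.05 and 0.95 of the
    2556 whole-brain pairs give 128 and 2428 edges, and of the 630
    single-hemisphere pairs give 32 and 599 edges.  Values are pre-rounded
    to 9 decimals so that binary-float representations of grid densities
    (e.g. 0.95 * 630 = 598.4999...97) land on the intended half.
    """
    return int(math.floor(round(x, 9) + 0.5))


def build_connectome(
    raw_counts: np.ndarray,
    parcellation: RegionParcellation,
    subject_id: str = "",
) -> Connectome:
    """Volume-normalise and symmetrise a raw streamline-count matrix.

    ``raw_counts[s, t]`` is the number of streamlines seeded in region *s*
    that reach region *t*.  Each directed entry is divided by the product
    of the seed and target ROI volumes and the two directions are averaged:

        w[s, t] = (raw[s, t] + raw[t, s]) / (2 * vol_s * vol_t)

    The diagonal is zeroed.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError(f"raw counts must be square, got shape {raw.shape}")
    if raw.shape[0] != parcellation.size:
        raise ValueError(
            f"raw counts size {raw.shape[0]} does not match parcellation "
            f"size {parcellation.size}"
        )
    if np.any(raw < 0):
        raise ValueError("streamline counts must be non-negative")
    vol = np.asarray(parcellation.volume, dtype=float)
    norm = raw / np.outer(vol, vol)
    weights = (norm + norm.T) / 2.0
    np.fill_diagonal(weights, 0.0)
    return Connectome(weights=weights, parcellation=parcellation, subject_id=subject_id)


def extract_hemisphere(c: Connectome, side: str):
    """Extract a hemisphere subnetwork or the interhemispheric block.

    ``side="left"`` / ``"right"`` return 36-node :class:`Connectome`
    objects on which graph measures can be computed.
    ``side="interhemispheric"`` returns the left-by-right rectangular
    weight block as an array — a bipartite set of connections, used only
    for connectivity-strength summaries, never for graph measures.
    """
    if side in ("left", "right"):
        idx = c.parcellation.indices(side)
        return Connectome(
            weights=c.weights[np.ix_(idx, idx)],
            parcellation=c.parcellation.subset(side),
            subject_id=c.subject_id,
        )
    if side == "interhemispheric":
        li = c.parcellation.indices("left")
        ri = c.parcellation.indices("right")
        return c.weights[np.ix_(li, ri)].copy()
    raise ValueError(f"unknown side {side!r}")


def median_summary(cohort: Sequence[Connectome]) -> np.ndarray:
    """Element-wise median connectivity matrix across all subjects.

    Both groups are pooled; the resulting summary matrix defines the
    group-level threshold masks.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one connectome")
    p0 = cohort[0].parcellation
    for c in cohort[1:]:
        if c.parcellation.labels != p0.labels:
            raise ValueError("all connectomes must share the same parcellation")
    stack = np.stack([c.weights for c in cohort])
    med = np.median(stack, axis=0)
    med = (med + med.T) / 2.0  # guard against float asymmetry
    np.fill_diagonal(med, 0.0)
    return med


def density_threshold(summary: np.ndarray, kappa: float) -> ThresholdMask:
    """Mask retaining the strongest (100*kappa)% of all node pairs.

    All n(n-1)/2 off-diagonal pairs are ranked by descending summary
    weight; zero-weight pairs rank last.  Ties break deterministically by
    ascending (row, column) index.  The retained count is
    ``round_half_up(kappa * n(n-1)/2)``, so kappa is exactly the edge
    density of the thresholded network.
    """
    if not 0 < kappa <= 1:
        raise ValueError(f"kappa must lie in (0, 1], got {kappa}")
    summary = _check_square_symmetric(summary, "summary")
    n = summary.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = summary[iu, ju]
    # lexsort: last key is primary; sort by (-value, row, col)
    order = np.lexsort((ju, iu, -vals))
    keep = round_half_up(kappa * n * (n - 1) / 2)
    sel = order[:keep]
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[sel], ju[sel]] = True
    mask |= mask.T
    return ThresholdMask(kappa=kappa, mask=mask, edge_count=keep)


def apply_mask(c: Connectome, m: ThresholdMask) -> Connectome:
    """Zero weights outside the mask; weights inside are untouched."""
    if m.mask.shape != c.weights.shape:
        raise ValueError("mask and connectome dimensions disagree")
    return Connectome(
        weights=np.where(m.mask, c.weights, 0.0),
        parcellation=c.parcellation,
        subject_id=c.subject_id,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_matrix(path, n_expected: int | None = None) -> np.ndarray:
    """Read one header-less square matrix from a CSV/TSV file."""
    w = np.loadtxt(path, delimiter=_sniff_delimiter(path))
    if n_expected is not None and w.shape != (n_expected, n_expected):
        raise ValueError(f"expected {n_expected}x{n_expected} matrix in {path}")
    return w


def write_matrix(w: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(w, dtype=float), delimiter=",", fmt="%.10g")


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_matrix_stack(path) -> dict[str, np.ndarray]:
    """Read a stacked long-format file: columns subject_id,row,col,value."""
    df = pd.read_csv(path)
    required = {"subject_id", "row", "col", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"stacked matrix file needs columns {sorted(required)}")
    n = int(max(df["row"].max(), df["col"].max())) + 1
    out: dict[str, np.ndarray] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        w = np.zeros((n, n))
        w[grp["row"], grp["col"]] = grp["value"]
        out[str(sid)] = w
    return out


def write_matrix_stack(matrices: dict[str, np.ndarray], path) -> None:
    rows = []
    for sid, w in matrices.items():
        i, j = np.nonzero(w)
        rows.append(
            pd.DataFrame({"subject_id": sid, "row": i, "col": j, "value": w[i, j]})
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    """Read the covariate table: subject_id, group, age, score.

    ``group`` must have exactly two levels; ``score`` may be missing for
    controls.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    if "score" not in df.columns:
        df["score"] = np.nan
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"group must have exactly two levels, got {levels}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df
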