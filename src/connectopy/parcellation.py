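"""Region parcellation for 72-region whole-brain connectomes.

The default scheme is the Desikan-Killiany cortical atlas (33 cortical
regions per hemisphere) augmented with three subcortical nuclei (thalamus,
caudate and lentiform nucleus), giving 36 regions per hemisphere and 72 in
total.  Regions are ordered left hemisphere first, alphabetically within a
hemisphere, and every matrix in the package follows this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REGION_NAMES",
    "RegionParcellation",
    "default_parcellation",
    "read_region_table",
    "write_region_table",
]

# 33 Desikan-Killiany cortical labels + caudate, lentiform, thalamus,
# alphabetically sorted (36 per hemisphere).
REGION_NAMES: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "caudate",
    "cuneus",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lentiform",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "thalamus",
    "transversetemporal",
)


@dataclass(frozen=True)
class RegionParcellation:
    """An ordered set of brain regions with hemisphere tags and ROI volumes.

    Parameters
    ----------
    labels
        Unique region names, left-hemisphere block first.
    hemisphere
        Per-region tag, each ``"left"`` or ``"right"``, with equally many
        regions per hemisphere.
    volume
        Per-region ROI volume in mm^3 (strictly positive); used to
        normalise raw streamline counts.
    """

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    volume: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("region labels must be unique")
        if len(self.hemisphere) != n:
            raise ValueError("hemisphere tags must match number of labels")
        bad = set(self.hemisphere) - {"left", "right"}
        if bad:
            raise ValueError(f"unknown hemisphere tags: {sorted(bad)}")
        n_left = sum(h == "left" for h in self.hemisphere)
        if n_left * 2 != n:
            raise ValueError("hemispheres must contain equally many regions")
        if not self.volume:
            object.__setattr__(self, "volume", tuple(1.0 for _ in self.labels))
        if len(self.volume) != n:
            raise ValueError("volumes must match number of labels")
        if any(v <= 0 for v in self.volume):
            raise ValueError("ROI volumes must be positive")

    @property
    def size(self) -> int:
        return len(self.labels)

    def indices(self, side: str) -> np.ndarray:
        """Integer indices of the regions in one hemisphere."""
        if side not in ("left", "right"):
            raise ValueError(f"unknown side {side!r}")
        return np.array([i for i, h in enumerate(self.hemisphere) if h == side])

    def subset(self, side: str) -> "RegionParcellation":
        idx = self.indices(side)
        return _HemiParcellation(
            labels=tuple(self.labels[i] for i in idx),
            hemisphere=tuple(self.hemisphere[i] for i in idx),
            volume=tuple(self.volume[i] for i in idx),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "hemisphere": self.hemisphere, "volume": self.volume}
        )


class _HemiParcellation(RegionParcellation):
    """Single-hemisphere parcellation: relaxes the equal-split invariant."""

    def __post_init__(self) -> None:  # noqa: D105
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("region labels must be unique")
        if len(self.hemisphere) != n or len(self.volume) != n:
            raise ValueError("field lengths must agree")
        if any(v <= 0 for v in self.volume):
            raise ValueError("ROI volumes must be positive")


def default_parcellation(volumes=None) -> RegionParcellation:
    """The standard 72-region parcellation (36 per hemisphere).

    ``volumes`` may give per-region ROI volumes (length 72); unit volumes
    are used when omitted, which makes weight normalisation a no-op.
    """
    labels = tuple(f"lh_{r}" for r in REGION_NAMES) + tuple(
        f"rh_{r}" for r in REGION_NAMES
    )
    hemis = ("left",) * len(REGION_NAMES) + ("right",) * len(REGION_NAMES)
    vols = tuple(volumes) if volumes is not None else ()
    return RegionParcellation(labels=labels, hemisphere=hemis, volume=vols)


def read_region_table(path) -> RegionParcellation:
    """Read a region table CSV with columns label, hemisphere, volume."""
    df = pd.read_csv(path)
    required = {"label", "hemisphere", "volume"}
    if not required.issubset(df.columns):
        raise ValueError(f"region table needs columns {sorted(required)}")
    return RegionParcellation(
        labels=tuple(df["label"].astype(str)),
        hemisphere=tuple(df["hemisphere"].astype(str)),
        volume=tuple(df["volume"].astype(float)),
    )


def write_region_table(parcellation: RegionParcellation, path) -> None:
    parcellation.to_frame().to_csv(path, index=False)
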