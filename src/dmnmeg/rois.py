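"""The 12-region default-mode-network (DMN) parcellation.

Six bilateral regions make up the network: medial frontal cortex (MFC),
posterior cingulate cortex (PCC), precuneus (PCu), lateral temporal lobe
(LTL), medial temporal lobe (MTL) and inferior parietal lobe (IPL).

The MNI centroids shipped as defaults are plausible literature-style
placeholders, not measured coordinates; supply a tab-separated table
(columns ``label``, ``hemisphere``, ``x``, ``y``, ``z`` in MNI mm) to use
a specific parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The six DMN region names, one per hemisphere each.
DMN_REGIONS = ("MFC", "PCC", "PCu", "LTL", "MTL", "IPL")

HEMISPHERES = ("L", "R")

# Placeholder MNI centroids (mm); |x| mirrored across hemispheres.
_PLACEHOLDER_XYZ = {
    "MFC": (6.0, 52.0, 2.0),
    "PCC": (5.0, -50.0, 30.0),
    "PCu": (7.0, -60.0, 40.0),
    "LTL": (55.0, -20.0, -10.0),
    "MTL": (28.0, -20.0, -16.0),
    "IPL": (45.0, -65.0, 30.0),
}


@dataclass(frozen=True)
class RoiSet:
    """Exactly 12 ROIs: the six DMN regions, once per hemisphere."""

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    mni_xyz: np.ndarray  # (12, 3) mm

    def __post_init__(self) -> None:
        if len(self.labels) != 12:
            raise ValueError(f"a RoiSet needs exactly 12 ROIs, got {len(self.labels)}")
        if len(self.hemispheres) != 12 or self.mni_xyz.shape != (12, 3):
            raise ValueError("hemispheres and coordinates must match the 12 labels")
        if len(set(self.labels)) != 12:
            raise ValueError("ROI labels must be unique")
        for hemi in HEMISPHERES:
            if sum(h == hemi for h in self.hemispheres) != 6:
                raise ValueError("need 6 ROIs per hemisphere")
        for region in DMN_REGIONS:
            for hemi in HEMISPHERES:
                if f"{region}-{hemi}" not in self.labels:
                    raise ValueError(f"missing ROI {region}-{hemi}")

    def __len__(self) -> int:
        return 12

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "hemisphere": self.hemispheres,
                "x": self.mni_xyz[:, 0],
                "y": self.mni_xyz[:, 1],
                "z": self.mni_xyz[:, 2],
            }
        )


def make_roi_set(coordinate_table: str | Path | None = None) -> RoiSet:
    """Build the 12-ROI DMN set, from a coordinate table or package defaults.

    Parameters
    ----------
    coordinate_table
        Optional path to a tab-separated file with columns ``label``
        (``<REGION>-<L|R>``), ``hemisphere`` (``L``/``R``) and MNI ``x y z``
        in mm. Must contain exactly 12 rows with unique labels. Without a
        table, placeholder centroids are used.
    """
    if coordinate_table is None:
        labels, hemis, xyz = [], [], []
        for region in DMN_REGIONS:
            for hemi in HEMISPHERES:
                x, y, z = _PLACEHOLDER_XYZ[region]
                labels.append(f"{region}-{hemi}")
                hemis.append(hemi)
                xyz.append((-abs(x) if hemi == "L" else abs(x), y, z))
        return RoiSet(tuple(labels), tuple(hemis), np.asarray(xyz, dtype=float))

    table = pd.read_csv(coordinate_table, sep="\t")
    required = {"label", "hemisphere", "x", "y", "z"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    if len(table) != 12:
        raise ValueError(f"ROI table must have 12 rows, got {len(table)}")
    if table["label"].duplicated().any():
        dupes = table.loc[table["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate ROI labels in table: {dupes}")
    return RoiSet(
        tuple(table["label"].astype(str)),
        tuple(table["hemisphere"].astype(str)),
        table[["x", "y", "z"]].to_numpy(dtype=float),
    )
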