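"""VOI extraction from labelled volumes and ipsi/contra region pairing.

Works with any integer label volume plus a lookup table mapping each label
to a region name, hemisphere and its homologous (mirror-hemisphere) label —
an AAL-style parcellation, but atlas-agnostic: no atlas is bundled.  Images
must already share a grid (spatial normalization is external preprocessing).
Hemisphere comes from the lookup table, never from voxel coordinates, so the
pairing is robust to image orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import FrameSchedule
from .kinetics import TissueTAC

__all__ = [
    "LabelAtlas",
    "VOISelection",
    "AtlasConsistencyError",
    "extract_voi_tacs",
    "extract_static_ac",
    "pair_regions",
]

LUT_COLUMNS = ["label_id", "name", "hemisphere", "homolog_id"]


class AtlasConsistencyError(ValueError):
    """Label volume and lookup table disagree, or a homolog is missing."""


@dataclass(frozen=True)
class LabelAtlas:
    """Integer label volume + lookup table (label_id, name, hemisphere, homolog_id)."""

    labels: np.ndarray
    lut: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or not np.issubdtype(labels.dtype, np.integer):
            raise AtlasConsistencyError("label volume must be a 3-D integer array")
        lut = self.lut
        missing_cols = set(LUT_COLUMNS) - set(lut.columns)
        if missing_cols:
            raise AtlasConsistencyError(f"lookup table missing columns {sorted(missing_cols)}")
        ids = set(lut["label_id"].astype(int))
        present = set(np.unique(labels)) - {0}
        if not present <= ids:
            raise AtlasConsistencyError(f"labels without lookup entries: {sorted(present - ids)}")
        homolog = dict(zip(lut["label_id"].astype(int), lut["homolog_id"].astype(int)))
        for i, j in homolog.items():
            if j not in homolog or homolog[j] != i:
                raise AtlasConsistencyError(f"homolog mapping is not an involution at label {i}")
        object.__setattr__(self, "labels", labels)

    def homolog(self, label_id: int) -> int:
        row = self.lut.loc[self.lut["label_id"] == label_id, "homolog_id"]
        if row.empty:
            raise AtlasConsistencyError(f"label {label_id} not in lookup table")
        return int(row.iloc[0])

    def name(self, label_id: int) -> str:
        row = self.lut.loc[self.lut["label_id"] == label_id, "name"]
        return str(row.iloc[0]) if not row.empty else str(label_id)

    @classmethod
    def from_files(cls, label_nifti_path, lut_tsv_path) -> "LabelAtlas":
        import nibabel as nib

        img = nib.load(str(label_nifti_path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        lut = pd.read_csv(lut_tsv_path, sep="\t")
        return cls(labels=labels, lut=lut, affine=img.affine)


@dataclass(frozen=True)
class VOISelection:
    """Per-subject epileptogenic and reference label ids plus the focus side.

    Each entry may be a single label id or a tuple of ids (a merged VOI
    pooled with volume weighting, e.g. supramarginal + angular).
    """

    epileptogenic: tuple
    reference: tuple
    focus_side: str  # left | right

    def __post_init__(self) -> None:
        def flat(ids):
            out = []
            for x in ids:
                out.extend(x if isinstance(x, (tuple, list, set, frozenset)) else [x])
            return out

        epi, ref = set(flat(self.epileptogenic)), set(flat(self.reference))
        if epi & ref:
            raise ValueError("epileptogenic and reference label sets must be disjoint")
        if self.focus_side not in ("left", "right"):
            raise ValueError("focus_side must be 'left' or 'right'")


def _as_id_group(voi) -> tuple[int, ...]:
    if isinstance(voi, (tuple, list, set, frozenset)):
        return tuple(int(x) for x in voi)
    return (int(voi),)


def _voi_mask(atlas: LabelAtlas, voi) -> np.ndarray:
    group = _as_id_group(voi)
    mask = np.isin(atlas.labels, group)
    if not mask.any():
        raise AtlasConsistencyError(f"VOI {voi!r} has no voxels in the label volume")
    return mask


def _voi_key(voi) -> str:
    group = _as_id_group(voi)
    return "+".join(str(i) for i in group)


def extract_voi_tacs(
    dynamic_volume: np.ndarray,
    atlas: LabelAtlas,
    ids,
    schedule: FrameSchedule,
    side: str = "",
) -> dict[str, TissueTAC]:
    """Frame-wise mean TAC per VOI from a 4-D (x, y, z, frame) volume.

    ``ids`` is an iterable of label ids; an element that is itself a
    tuple/list is treated as one merged VOI with a volume-weighted pooled
    mean.  Returns a dict keyed by the VOI id string (ids joined by ``+``).
    """
    data = np.asarray(dynamic_volume, dtype=float)
    if data.ndim != 4:
        raise ValueError("dynamic volume must be 4-D (x, y, z, frame)")
    if data.shape[:3] != atlas.labels.shape:
        raise ValueError("dynamic volume and atlas are on different grids")
    if data.shape[3] != schedule.n_frames:
        raise ValueError("frame count does not match the schedule")
    out: dict[str, TissueTAC] = {}
    for voi in ids:
        mask = _voi_mask(atlas, voi)
        values = data[mask].mean(axis=0)
        out[_voi_key(voi)] = TissueTAC(schedule=schedule, values=values,
                                       voi_id=_voi_key(voi), side=side)
    return out


def extract_static_ac(static_volume: np.ndarray, atlas: LabelAtlas, ids) -> dict[str, float]:
    """Mean static activity concentration (kBq/mL) per VOI from a 3-D volume."""
    data = np.asarray(static_volume, dtype=float)
    if data.ndim != 3:
        raise ValueError("static volume must be 3-D")
    if data.shape != atlas.labels.shape:
        raise ValueError("static volume and atlas are on different grids")
    return {_voi_key(voi): float(data[_voi_mask(atlas, voi)].mean()) for voi in ids}


def pair_regions(atlas: LabelAtlas, selection: VOISelection) -> list[dict]:
    """Resolve (ipsilateral, contralateral) label pairs for a subject.

    The ipsilateral label of each selected VOI is the one on the subject's
    focus side; its contralateral partner is the homologous label.  Selected
    ids are interpreted as the ipsilateral members (callers select VOIs on
    the focus side); merged VOIs are paired element-wise.
    """
    pairs = []
    for region_class, vois in (("epileptogenic", selection.epileptogenic),
                               ("non_epileptogenic", selection.reference)):
        for voi in vois:
            group = _as_id_group(voi)
            contra = tuple(atlas.homolog(i) for i in group)
            pairs.append({
                "region_class": region_class,
                "ipsi": group if len(group) > 1 else group[0],
                "contra": contra if len(contra) > 1 else contra[0],
                "name": "+".join(atlas.name(i) for i in group),
                "side": selection.focus_side,
            })
    return pairs
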