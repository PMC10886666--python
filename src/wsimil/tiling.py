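"""Hierarchical patch grids, tissue-content filtering, and composition clusters.

A slide is tiled into non-overlapping 1024-px patches; patches with at least
50% tissue (stroma + epithelium pixels in the label mask) are retained and
recursively subdivided into four 512-px and sixteen 256-px patches. Every
patch is assigned a composition cluster from its stroma/epithelium fractions:

* ``C1`` — predominantly (>50%) stroma,
* ``C3`` — predominantly (>50%) epithelium,
* ``C2`` — everything else (mixed).

Coordinates are 0-based pixel offsets with half-open extents
``[origin, origin + level_px)``, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

# Mask label conventions (single-channel integer mask).
LABEL_BACKGROUND = 0
LABEL_STROMA = 1
LABEL_EPITHELIUM = 2
LABEL_ARTIFACT = 3

LEVELS = (1024, 512, 256)

MANIFEST_COLUMNS = [
    "wsi_id",
    "patch_id",
    "parent_id",
    "level_px",
    "row",
    "col",
    "stroma_frac",
    "epithelium_frac",
    "tissue_frac",
    "cluster",
]


def assign_cluster(stroma_frac: float, epithelium_frac: float) -> str:
    """Map composition fractions to one of the clusters C1/C2/C3."""
    if not (0.0 <= stroma_frac <= 1.0 and 0.0 <= epithelium_frac <= 1.0):
        raise ValueError(
            f"fractions must lie in [0, 1]; got ({stroma_frac}, {epithelium_frac})"
        )
    if stroma_frac > 0.5:
        return "C1"
    if epithelium_frac > 0.5:
        return "C3"
    return "C2"


@dataclass
class PatchRecord:
    """One patch at one pyramid level."""

    wsi_id: str
    level_px: int
    row: int  # pixel offset of the top edge
    col: int  # pixel offset of the left edge
    stroma_frac: float
    epithelium_frac: float
    parent_id: str | None = None
    cluster: str = field(default="")

    def __post_init__(self) -> None:
        if self.level_px not in LEVELS:
            raise ValueError(f"level_px must be one of {LEVELS}, got {self.level_px}")
        if not self.cluster:
            self.cluster = assign_cluster(self.stroma_frac, self.epithelium_frac)

    @property
    def patch_id(self) -> str:
        return f"{self.wsi_id}:{self.level_px}:{self.row}:{self.col}"

    @property
    def tissue_frac(self) -> float:
        return self.stroma_frac + self.epithelium_frac


def _fractions(mask: np.ndarray) -> tuple[float, float]:
    n = mask.size
    stroma = float(np.count_nonzero(mask == LABEL_STROMA)) / n
    epi = float(np.count_nonzero(mask == LABEL_EPITHELIUM)) / n
    return stroma, epi


def extract_grid(
    image: np.ndarray, mask: np.ndarray, wsi_id: str = "wsi", level_px: int = 1024
) -> list[PatchRecord]:
    """Tile ``image`` into a non-overlapping grid of ``level_px`` patches."""
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape[:2]} dimensions differ"
        )
    h, w = mask.shape[:2]
    if h % level_px or w % level_px:
        raise ValueError(f"{level_px} does not divide image dimensions {h}x{w}")
    records = []
    for r in range(0, h, level_px):
        for c in range(0, w, level_px):
            s, e = _fractions(mask[r : r + level_px, c : c + level_px])
            records.append(
                PatchRecord(wsi_id=wsi_id, level_px=level_px, row=r, col=c,
                            stroma_frac=s, epithelium_frac=e)
            )
    return records


def filter_tissue(
    patches: Iterable[PatchRecord], threshold: float = 0.5
) -> list[PatchRecord]:
    """Keep patches whose tissue fraction is at least ``threshold``."""
    return [p for p in patches if p.tissue_frac >= threshold]


def subdivide(patch: PatchRecord, mask: np.ndarray) -> list[PatchRecord]:
    """Split a 1024- or 512-px patch into its four children.

    Children tile the parent exactly; composition fractions are recomputed
    from the mask per child.
    """
    if patch.level_px == 256:
        raise ValueError("256-px patches are leaves and cannot be subdivided")
    half = patch.level_px // 2
    children = []
    for dr in (0, half):
        for dc in (0, half):
            r, c = patch.row + dr, patch.col + dc
            s, e = _fractions(mask[r : r + half, c : c + half])
            children.append(
                PatchRecord(wsi_id=patch.wsi_id, level_px=half, row=r, col=c,
                            stroma_frac=s, epithelium_frac=e,
                            parent_id=patch.patch_id)
            )
    return children


def resize_to_256(patch_image: np.ndarray) -> np.ndarray:
    """Bilinear downsample of a square 512- or 1024-px patch image to 256 px."""
    h, w = patch_image.shape[:2]
    if h != w:
        raise ValueError(f"patch must be square, got {h}x{w}")
    if h == 256:
        return patch_image
    if h not in (512, 1024):
        raise ValueError(f"patch side must be 256, 512 or 1024, got {h}")
    out_shape = (256, 256) + patch_image.shape[2:]
    out = _sk_resize(
        patch_image.astype(np.float64), out_shape, order=1,
        anti_aliasing=False, preserve_range=True,
    )
    if np.issubdtype(patch_image.dtype, np.integer):
        info = np.iinfo(patch_image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(patch_image.dtype)
    return out


def tile_wsi(
    image: np.ndarray,
    mask: np.ndarray,
    wsi_id: str = "wsi",
    threshold: float = 0.5,
) -> list[PatchRecord]:
    """Full pyramid for one slide: retained 1024 patches plus all descendants.

    The tissue-content criterion is applied at the 1024 level only; children
    inherit retention from their parent.
    """
    top = filter_tissue(extract_grid(image, mask, wsi_id, 1024), threshold)
    records: list[PatchRecord] = list(top)
    for parent in top:
        mids = subdivide(parent, mask)
        records.extend(mids)
        for mid in mids:
            records.extend(subdivide(mid, mask))
    return records


def manifest_frame(records: Sequence[PatchRecord]) -> pd.DataFrame:
    rows = [
        {
            "wsi_id": p.wsi_id,
            "patch_id": p.patch_id,
            "parent_id": p.parent_id if p.parent_id is not None else "",
            "level_px": p.level_px,
            "row": p.row,
            "col": p.col,
            "stroma_frac": p.stroma_frac,
            "epithelium_frac": p.epithelium_frac,
            "tissue_frac": p.tissue_frac,
            "cluster": p.cluster,
        }
        for p in records
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def records_from_frame(frame: pd.DataFrame) -> list[PatchRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            PatchRecord(
                wsi_id=row.wsi_id, level_px=int(row.level_px),
                row=int(row.row), col=int(row.col),
                stroma_frac=float(row.stroma_frac),
                epithelium_frac=float(row.epithelium_frac),
                parent_id=(row.parent_id or None), cluster=row.cluster,
            )
        )
    return records


def patch_image(image: np.ndarray, patch: PatchRecord) -> np.ndarray:
    return image[patch.row : patch.row + patch.level_px,
                 patch.col : patch.col + patch.level_px]


@dataclass
class MultiResInstance:
    """A 256-px leaf with its ancestor features concatenated [256 ‖ 512 ‖ 1024]."""

    leaf_patch_id: str
    feature: np.ndarray
    cluster: str  # inherited from the 1024-px ancestor


def build_multires_instances(
    records: Sequence[PatchRecord],
    features: Mapping[str, np.ndarray],
) -> list[MultiResInstance]:
    """Concatenate leaf, parent, and grandparent features per 256-px leaf.

    ``features`` maps patch_id -> feature vector at any level. The cluster
    label of the instance is the 1024-px ancestor's.
    """
    by_id = {p.patch_id: p for p in records}
    instances = []
    for leaf in records:
        if leaf.level_px != 256:
            continue
        parent = by_id.get(leaf.parent_id or "")
        grand = by_id.get(parent.parent_id or "") if parent is not None else None
        if parent is None or grand is None:
            raise RuntimeError(f"leaf {leaf.patch_id} is missing its ancestor chain")
        parts = []
        for pid in (leaf.patch_id, parent.patch_id, grand.patch_id):
            if pid not in features:
                raise RuntimeError(f"no feature vector for patch {pid} "
                                   f"(required by leaf {leaf.patch_id})")
            parts.append(np.asarray(features[pid], dtype=np.float64))
        instances.append(
            MultiResInstance(
                leaf_patch_id=leaf.patch_id,
                feature=np.concatenate(parts),
                cluster=grand.cluster,
            )
        )
    return instances
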