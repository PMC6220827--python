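"""Readers, writers, and the shared raw-data types of the pipeline.

Conventions: image coordinates are 0-based with x rightward and y downward;
outlines read in pixel units are converted to micrometers once at ingest
using the pixel scale (default 9.8 px/um, the 63x oil-immersion setup).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: Default pixel scale of the high-resolution imaging setup, px per um.
DEFAULT_PIXEL_SCALE = 9.8

SPECIES = ("ritscheri", "obliquecostata", "sublinearis")
VOTE_CATEGORIES = SPECIES + ("ambiguous", "out_of_group", "missing")


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


class Unit(str, Enum):
    pixel = "pixel"
    micrometer = "micrometer"


@dataclass
class ValveOutline:
    """Ordered closed 2-D contour of a valve (last point connects to first)."""

    specimen_id: str
    points: np.ndarray  # (n, 2) float
    unit: Unit = Unit.micrometer
    pixel_scale: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise FormatError(
                f"{self.specimen_id}: outline points must be an (n, 2) array"
            )
        if len(self.points) < 3:
            raise FormatError(
                f"{self.specimen_id}: an outline needs at least 3 points, "
                f"got {len(self.points)}"
            )
        if self.unit == Unit.pixel and not self.pixel_scale:
            raise FormatError(
                f"{self.specimen_id}: pixel-unit outlines require a pixel_scale"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_micrometers(self) -> "ValveOutline":
        """Return a copy with coordinates in um (identity if already in um)."""
        if self.unit == Unit.micrometer:
            return self
        return ValveOutline(
            specimen_id=self.specimen_id,
            points=self.points / self.pixel_scale,
            unit=Unit.micrometer,
            pixel_scale=self.pixel_scale,
        )


@dataclass
class MaskedValveImage:
    """8-bit grayscale valve raster; background pixels are exactly 0."""

    specimen_id: str
    pixels: np.ndarray  # (rows, cols) uint8
    pixel_scale: float = DEFAULT_PIXEL_SCALE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"{self.specimen_id}: image must be 2-D grayscale")

    @property
    def foreground(self) -> np.ndarray:
        return self.pixels > 0


@dataclass
class Participant:
    id: str
    group: str  # "experienced" | "novice"


@dataclass
class VoteTable:
    """Per-specimen categorical labels from multiple participants.

    ``votes`` holds one row per specimen and one column per participant;
    every cell is one of the six vote categories (including "missing").
    """

    specimen_ids: list[str]
    participants: list[Participant]
    votes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.votes.to_numpy())) - set(VOTE_CATEGORIES)
        if bad:
            raise FormatError(f"unknown vote categories: {sorted(bad)}")

    def participant_ids(self, group: str | None = None) -> list[str]:
        return [p.id for p in self.participants if group is None or p.group == group]

    def subset(self, participant_ids: Sequence[str]) -> "VoteTable":
        keep = [p for p in self.participants if p.id in set(participant_ids)]
        return VoteTable(
            specimen_ids=list(self.specimen_ids),
            participants=keep,
            votes=self.votes[[p.id for p in keep]].copy(),
        )


#: Free-text spellings seen in practice, mapped to canonical categories.
#: Entries suffixed with "?" are treated as ambiguous before lookup.
DEFAULT_LABEL_MAP: dict[str, str] = {
    "ritscheri": "ritscheri",
    "rit": "ritscheri",
    "f. ritscheri": "ritscheri",
    "fragilariopsis ritscheri": "ritscheri",
    "obliquecostata": "obliquecostata",
    "obl": "obliquecostata",
    "f. obliquecostata": "obliquecostata",
    "fragilariopsis obliquecostata": "obliquecostata",
    "sublinearis": "sublinearis",
    "sub": "sublinearis",
    "f. sublinearis": "sublinearis",
    "fragilariopsis sublinearis": "sublinearis",
    "ambiguous": "ambiguous",
    "amb": "ambiguous",
    "?": "ambiguous",
    "out_of_group": "out_of_group",
    "other": "out_of_group",
    "1": "ritscheri",
    "2": "obliquecostata",
    "3": "sublinearis",
}


def read_outlines(
    path: str | Path,
    layout: str = "wide_table",
    unit: Unit = Unit.pixel,
    pixel_scale: float = DEFAULT_PIXEL_SCALE,
) -> list[ValveOutline]:
    """Read valve outlines from CSV.

    layout="wide_table": one row per specimen with columns X1..Xn, Y1..Yn
    (the layout of per-study outline exports); an ``id`` column is used as
    specimen id when present, else the row number.
    layout="per_specimen": a two-column x,y table for a single specimen
    (the per-specimen outline-file dialect); the file stem is the id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "wide_table":
        return _read_wide_outlines(path, unit, pixel_scale)
    if layout == "per_specimen":
        return [_read_xy_outline(path, unit, pixel_scale)]
    raise ValueError(f"unknown layout: {layout!r}")


def _read_wide_outlines(path: Path, unit: Unit, pixel_scale: float) -> list[ValveOutline]:
    df = pd.read_csv(path)
    xcols = sorted(
        (c for c in df.columns if re.fullmatch(r"[Xx]\d+", str(c))),
        key=lambda c: int(str(c)[1:]),
    )
    ycols = sorted(
        (c for c in df.columns if re.fullmatch(r"[Yy]\d+", str(c))),
        key=lambda c: int(str(c)[1:]),
    )
    if len(xcols) != len(ycols):
        raise FormatError(
            f"{path}: mismatched coordinate columns ({len(xcols)} X vs {len(ycols)} Y)"
        )
    if len(xcols) < 3:
        raise FormatError(f"{path}: fewer than 3 coordinate pairs in header")
    id_col = next((c for c in df.columns if str(c).lower() in ("id", "specimen_id")), None)
    outlines = []
    for i, row in df.iterrows():
        sid = str(row[id_col]) if id_col else str(i)
        try:
            xs = row[xcols].to_numpy(dtype=float)
            ys = row[ycols].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} row {i} ({sid}): non-numeric coordinate") from exc
        if np.isnan(xs).any() or np.isnan(ys).any():
            raise FormatError(f"{path} row {i} ({sid}): non-numeric coordinate")
        outlines.append(
            ValveOutline(sid, np.column_stack([xs, ys]), unit=unit, pixel_scale=pixel_scale)
        )
    return outlines


def _read_xy_outline(path: Path, unit: Unit, pixel_scale: float) -> ValveOutline:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two coordinate columns")
    try:
        pts = df.iloc[:, :2].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric coordinate") from exc
    if np.isnan(pts).any():
        raise FormatError(f"{path}: non-numeric coordinate")
    if len(pts) < 3:
        raise FormatError(f"{path}: fewer than 3 points")
    return ValveOutline(path.stem.replace(".XY_EFA", ""), pts, unit=unit, pixel_scale=pixel_scale)


def read_vote_table(
    path: str | Path,
    label_map: Mapping[str, str] | None = None,
    participant_pattern: str = r"[NE]\d+",
) -> VoteTable:
    """Read a multi-participant vote table.

    Participant columns are recognized by ``participant_pattern`` (default the
    N1..N4 / E1..E8 dialect; N = novice, E = experienced). Cells are normalized
    through ``label_map`` case-insensitively; a trailing "?" marks a vote as
    ambiguous; unmapped non-empty entries map to out_of_group with a warning;
    empty cells become missing.
    """
    path = Path(path)
    label_map = {k.lower(): v for k, v in (label_map or DEFAULT_LABEL_MAP).items()}
    df = pd.read_csv(path, dtype=str)
    id_col = next(
        (c for c in df.columns if str(c).lower() in ("id", "specimen_id", "image", "specimen")),
        df.columns[0],
    )
    pcols = [c for c in df.columns if re.fullmatch(participant_pattern, str(c))]
    if not pcols:
        raise FormatError(f"{path}: no participant columns matching {participant_pattern!r}")
    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate specimen ids {dupes}")

    def normalize(cell: object) -> str:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return "missing"
        text = str(cell).strip()
        if not text:
            return "missing"
        if text.endswith("?"):
            return "ambiguous"
        mapped = label_map.get(text.lower())
        if mapped is None:
            warnings.warn(f"unmapped vote label {text!r} -> out_of_group", stacklevel=2)
            return "out_of_group"
        return mapped

    votes = df[pcols].map(normalize)
    votes.index = ids
    participants = [
        Participant(str(c), "novice" if str(c).upper().startswith("N") else "experienced")
        for c in pcols
    ]
    return VoteTable(specimen_ids=ids, participants=participants, votes=votes)


def read_masked_image(
    path: str | Path, pixel_scale: float = DEFAULT_PIXEL_SCALE
) -> MaskedValveImage:
    """Read an 8-bit grayscale masked valve image (PNG or TIFF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:
        # accept degenerate RGB where all channels agree
        if arr.shape[2] >= 3 and np.array_equal(arr[..., 0], arr[..., 1]) and np.array_equal(
            arr[..., 0], arr[..., 2]
        ):
            arr = arr[..., 0]
        else:
            raise FormatError(f"{path}: multi-channel image with unequal channels")
    return MaskedValveImage(path.stem, arr.astype(np.uint8), pixel_scale=pixel_scale)


def write_masked_image(image: MaskedValveImage, path: str | Path) -> None:
    Image.fromarray(image.pixels.astype(np.uint8), mode="L").save(path)


# A FeatureTable is a pandas DataFrame with a "specimen_id" column and one
# row per specimen; missing measurements are NaN, serialized as empty cells.

def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV (header, stable column order, full precision)."""
    if "specimen_id" not in features.columns:
        raise ValueError("feature table must have a specimen_id column")
    features.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns:
        raise FormatError(f"{path}: missing specimen_id column")
    df["specimen_id"] = df["specimen_id"].astype(str)
    return df
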