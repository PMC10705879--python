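"""Readers and writers: B-scan CSV frames, SEM grayscale images, zone label
maps, colormap configs and depth reports.

A B-scan frame is a rectangular CSV of backscatter intensities in dB with
rows = axial pixels (depth increasing downward) and columns = lateral
A-lines.  All indices are 0-based; the enamel surface in a column is the
smallest axial index carrying tissue.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import protocol

log = logging.getLogger(__name__)

# Zone label coding, shared by OCT and SEM label maps.
LABEL_AIR = 0      # air / background
LABEL_SOUND = 1    # sound (healthy) enamel
LABEL_IE = 2       # Inter-prismatic demineralization
LABEL_IA = 3       # Intra-prismatic demineralization

#: RGB palette matching the conventional display: dark blue air/background,
#: light blue sound, yellow Ie, red Ia.
LABEL_PALETTE: dict[int, tuple[int, int, int]] = {
    LABEL_AIR: (0, 0, 128),
    LABEL_SOUND: (70, 130, 255),
    LABEL_IE: (255, 215, 0),
    LABEL_IA: (220, 20, 60),
}


class FormatError(ValueError):
    """Malformed input file (ragged rows, non-numeric cells, bad config)."""


@dataclass
class BScan:
    """A 2-D OCT intensity frame in dB with its physical pixel geometry.

    Parameters
    ----------
    intensity_db
        2-D array, shape ``(axial, lateral)``; finite dB values.  The value
        0 doubles as the background marker after background removal (a
        genuine 0 dB tissue pixel is indistinguishable by construction).
    ps_axial, ps_lateral
        Pixel sizes in um/pixel.  ``ps_axial`` is an in-tissue distance.
    refractive_index
        Enamel group refractive index (metadata; not applied to values).
    """

    intensity_db: np.ndarray
    ps_axial: float = protocol.PS_AXIAL_UM
    ps_lateral: float = protocol.PS_LATERAL_UM
    refractive_index: float = protocol.REFRACTIVE_INDEX
    frame_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity_db, dtype=float)
        if arr.ndim != 2:
            raise FormatError(f"B-scan must be 2-D, got {arr.ndim}-D")
        if arr.shape[0] < 2:
            raise FormatError(
                f"axial extent must be >= 2 rows, got {arr.shape[0]}"
            )
        if not np.all(np.isfinite(arr)):
            raise FormatError("B-scan intensities must be finite")
        if self.ps_axial <= 0 or self.ps_lateral <= 0:
            raise FormatError("pixel sizes must be positive")
        self.intensity_db = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity_db.shape

    def with_values(self, values: np.ndarray, frame_id: str | None = None) -> "BScan":
        """Copy of this frame with new intensity values, same geometry."""
        out = replace(self, intensity_db=np.asarray(values, dtype=float))
        if frame_id is not None:
            out.frame_id = frame_id
        return out


@dataclass(frozen=True)
class ColorMap:
    """Intensity-threshold colormap: dB intervals mapping pixels to zones.

    Ranges are half-open ``[lo, hi)`` except the Ia range, which is closed
    at its top; sub-surface values above ``ia_range[1]`` (specular glare)
    are clamped into Ia, and values between the background threshold and
    the sound floor are labeled sound (the only non-lesion tissue class).
    """

    background_db: float = protocol.BACKGROUND_THRESHOLD_DB
    sound_range: tuple[float, float] = (10.0, 16.0)
    ie_range: tuple[float, float] = (16.0, 28.0)
    ia_range: tuple[float, float] = (28.0, 60.0)

    def __post_init__(self) -> None:
        s_lo, s_hi = self.sound_range
        e_lo, e_hi = self.ie_range
        a_lo, a_hi = self.ia_range
        ok = (
            self.background_db < s_lo <= s_hi == e_lo <= e_hi == a_lo < a_hi
        )
        if not ok:
            raise FormatError(
                "colormap thresholds must satisfy background < sound_lo <= "
                "sound_hi = ie_lo <= ie_hi = ia_lo < ia_hi; got "
                f"bg={self.background_db}, sound={self.sound_range}, "
                f"ie={self.ie_range}, ia={self.ia_range}"
            )


def default_colormap() -> ColorMap:
    """The calibrated colormap: sound 10-16, Ie 16-28, Ia 28-60 dB, bg 5 dB."""
    return ColorMap()


def _try_float(cell: str) -> float | None:
    try:
        return float(cell)
    except ValueError:
        return None


def read_bscan_csv(
    path: str | Path,
    ps_axial: float = protocol.PS_AXIAL_UM,
    ps_lateral: float = protocol.PS_LATERAL_UM,
    refractive_index: float = protocol.REFRACTIVE_INDEX,
    frame_id: str | None = None,
) -> BScan:
    """Read a B-scan exported as rectangular numeric CSV.

    An optional single header row is auto-detected (a first row whose cells
    are all non-numeric is skipped).  Ragged rows and non-numeric cells
    raise :class:`FormatError` with the offending location.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise FormatError(f"{path}: empty CSV")
    start = 0
    if all(_try_float(c) is None for c in rows[0]):
        start = 1  # header row
    data_rows = rows[start:]
    if not data_rows:
        raise FormatError(f"{path}: no data rows")
    width = len(data_rows[0])
    out = np.empty((len(data_rows), width), dtype=float)
    for i, row in enumerate(data_rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged CSV, row {i + start} has {len(row)} fields, "
                f"expected {width}"
            )
        for j, cell in enumerate(row):
            v = _try_float(cell)
            if v is None:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row {i + start}, "
                    f"column {j}"
                )
            out[i, j] = v
    return BScan(
        out,
        ps_axial=ps_axial,
        ps_lateral=ps_lateral,
        refractive_index=refractive_index,
        frame_id=frame_id if frame_id is not None else path.stem,
    )


def write_bscan_csv(frame: BScan, path: str | Path) -> None:
    """Write a B-scan as plain CSV (lossless to printed precision)."""
    np.savetxt(path, frame.intensity_db, delimiter=",", fmt="%.10g")


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF) as a 2-D float array.

    Multi-channel color input is converted by Rec.709 luminance with a
    logged warning; an alpha channel, if present, is dropped first.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.shape[2] == 1:
            arr = arr[..., 0]
        elif np.all(arr[..., 0:1] == arr):
            arr = arr[..., 0]
        else:
            log.warning("%s: color image converted to luminance", path)
            arr = (
                0.2126 * arr[..., 0].astype(float)
                + 0.7152 * arr[..., 1].astype(float)
                + 0.0722 * arr[..., 2].astype(float)
            )
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D grayscale image")
    return arr.astype(float)


def labelmap_to_rgb(labels: np.ndarray) -> np.ndarray:
    """Map integer zone labels {0..3} to the display palette (uint8 RGB)."""
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - set(LABEL_PALETTE)
    if bad:
        raise FormatError(f"unknown labels {sorted(bad)}")
    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for lab, color in LABEL_PALETTE.items():
        rgb[labels == lab] = color
    return rgb


def write_labelmap(labels: np.ndarray, png_path: str | Path,
                   csv_path: str | Path | None = None) -> None:
    """Write a zone label map as a paletted PNG and optionally as integer CSV."""
    iio.imwrite(png_path, labelmap_to_rgb(labels))
    if csv_path is not None:
        np.savetxt(csv_path, np.asarray(labels, dtype=int), delimiter=",", fmt="%d")


def read_labels_csv(path: str | Path) -> np.ndarray:
    """Read an integer label map written by :func:`write_labelmap`."""
    return np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)


#: Column order of the per-frame depth report.
REPORT_COLUMNS = [
    "frame_id", "d_ia_um", "d_ie_um", "dl_ia_um", "dl_ie_um",
    "curvature_index", "alpha_median_rad", "n_alines",
]


def depth_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-frame depth results into the fixed-column report table."""
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df


def write_depth_report(rows: list[dict], path: str | Path) -> None:
    """Write the depth report as spreadsheet-compatible CSV (header always)."""
    depth_report(rows).to_csv(path, index=False)


def save_colormap(cmap: ColorMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(
            {
                "background_db": cmap.background_db,
                "sound_range": list(cmap.sound_range),
                "ie_range": list(cmap.ie_range),
                "ia_range": list(cmap.ia_range),
            },
            fh,
            indent=2,
        )


def load_colormap(path: str | Path) -> ColorMap:
    with Path(path).open() as fh:
        cfg = json.load(fh)
    try:
        return ColorMap(
            background_db=float(cfg["background_db"]),
            sound_range=tuple(cfg["sound_range"]),
            ie_range=tuple(cfg["ie_range"]),
            ia_range=tuple(cfg["ia_range"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing colormap key {exc}") from exc


def write_outputs(labels: np.ndarray, report_rows: list[dict],
                  out_dir: str | Path, stem: str = "frame") -> dict[str, Path]:
    """Write a label map (PNG + CSV) and the depth report into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "labels_png": out_dir / f"{stem}_labels.png",
        "labels_csv": out_dir / f"{stem}_labels.csv",
        "report_csv": out_dir / "depth_report.csv",
    }
    write_labelmap(labels, paths["labels_png"], paths["labels_csv"])
    write_depth_report(report_rows, paths["report_csv"])
    return paths
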