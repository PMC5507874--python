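"""Fixture I/O: volumes as multi-page TIFF + JSON sidecar, masks as PNG.

Formats
-------
* Volume: ``decorrelation.tif`` and ``reflectance.tif`` (float32 stacks,
  one page per depth slice) plus ``volume.json`` holding the four surface
  depth maps (µm) and the pitches.
* En-face image: single-page 16-bit grayscale PNG, value/65535 -> [0, 1].
* Binary mask: 8-bit PNG, 0/255.
* EZ annotation: CSV of half-open spans
  ``line_row,start_px,end_px,ez_status,deep_nonperfusion`` with 0-based
  raster rows and pixel columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .ez import EzLineAnnotation, N_SCAN_LINES
from .slabs import EnFaceImage, OctaVolume
from .stats import EyeRecord


def save_volume(volume: OctaVolume, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "decorrelation.tif", volume.decorrelation.astype(np.float32))
    tifffile.imwrite(directory / "reflectance.tif", volume.reflectance.astype(np.float32))
    sidecar = {
        "axial_pitch_um": volume.axial_pitch,
        "lateral_pitch_um": volume.lateral_pitch,
        "field_mm": volume.field_mm,
        "surfaces_um": {
            name: np.round(volume.surface(name), 4).tolist()
            for name in ("ilm", "ipl", "rpe_ref", "rpe_bruch")
        },
    }
    (directory / "volume.json").write_text(json.dumps(sidecar))


def load_volume(directory) -> OctaVolume:
    directory = Path(directory)
    sidecar = json.loads((directory / "volume.json").read_text())
    surfaces = {k: np.asarray(v, dtype=np.float64) for k, v in sidecar["surfaces_um"].items()}
    return OctaVolume(
        decorrelation=tifffile.imread(directory / "decorrelation.tif"),
        reflectance=tifffile.imread(directory / "reflectance.tif"),
        surface_ilm=surfaces["ilm"],
        surface_ipl=surfaces["ipl"],
        surface_rpe_ref=surfaces["rpe_ref"],
        surface_rpe_bruch=surfaces["rpe_bruch"],
        axial_pitch=sidecar["axial_pitch_um"],
        lateral_pitch=sidecar["lateral_pitch_um"],
        field_mm=sidecar["field_mm"],
    )


def save_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def load_mask_png(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def save_enface_png(path, image: EnFaceImage) -> None:
    data = np.clip(image.pixels, 0.0, 1.0)
    iio.imwrite(Path(path), np.round(data * 65535).astype(np.uint16))


def load_enface_png(path, lateral_pitch: float, kind: str = "decorrelation") -> EnFaceImage:
    raw = np.asarray(iio.imread(Path(path)))
    scale = 65535.0 if raw.dtype == np.uint16 else 255.0
    return EnFaceImage(raw.astype(np.float64) / scale, lateral_pitch, kind, provenance="external file")


def records_to_dataframe(records: Sequence[EyeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "eye_id": [r.eye_id for r in records],
            "dr_grade": [r.dr_grade for r in records],
            "logmar_va": [r.logmar_va for r in records],
            "csf_thickness_um": [r.csf_thickness_um for r in records],
            "ssi": [r.ssi for r in records],
            "dme": [r.dme for r in records],
            "age_years": [r.age_years for r in records],
            "hba1c_pct": [r.hba1c_pct for r in records],
            "diabetes_duration_years": [r.diabetes_duration_years for r in records],
            "laterality": [r.laterality for r in records],
        }
    )


def save_records_csv(records: Sequence[EyeRecord], path) -> None:
    records_to_dataframe(records).to_csv(Path(path), index=False)


def save_ez_annotation_csv(annotation: EzLineAnnotation, path) -> None:
    """Serialize per-line spans; only non-default spans are written."""
    rows: List[dict] = []
    for i, line_row in enumerate(annotation.line_rows):
        for vec, label in ((annotation.deep_nonperfusion[i], "nonperfusion"), (~annotation.intact[i], "disrupted")):
            padded = np.concatenate([[False], vec, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            for start, end in zip(edges[::2], edges[1::2]):
                rows.append(
                    {
                        "line_row": int(line_row),
                        "start_px": int(start),
                        "end_px": int(end),
                        "ez_status": "disrupted" if label == "disrupted" else "intact",
                        "deep_nonperfusion": int(label == "nonperfusion"),
                    }
                )
    pd.DataFrame(rows, columns=["line_row", "start_px", "end_px", "ez_status", "deep_nonperfusion"]).to_csv(
        Path(path), index=False
    )


def load_ez_annotation_csv(path, width: int) -> EzLineAnnotation:
    """Rebuild an annotation from half-open spans.

    Rows with ``deep_nonperfusion == 1`` mark nonperfusion spans; rows with
    ``ez_status == 'disrupted'`` mark non-intact spans.  Lines default to
    intact and perfused.
    """
    df = pd.read_csv(Path(path))
    line_rows = sorted(df["line_row"].unique())
    if len(line_rows) != N_SCAN_LINES:
        raise ParameterError(f"annotation must cover exactly {N_SCAN_LINES} lines, got {len(line_rows)}")
    intact = np.ones((N_SCAN_LINES, width), bool)
    nonperf = np.zeros((N_SCAN_LINES, width), bool)
    index = {row: i for i, row in enumerate(line_rows)}
    for _, row in df.iterrows():
        i = index[row["line_row"]]
        sl = slice(int(row["start_px"]), int(row["end_px"]))
        if int(row["deep_nonperfusion"]):
            nonperf[i, sl] = True
        if str(row["ez_status"]) == "disrupted":
            intact[i, sl] = False
    return EzLineAnnotation(np.asarray(line_rows), intact, nonperf)
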