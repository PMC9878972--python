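"""TIFF / CSV / JSON plumbing.

Images are read through tifffile and converted to float64 (8/16-bit
unsigned and 32-bit float TIFFs all come back as real-valued arrays);
localization and track tables go through pandas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidParameterError

__all__ = ["read_image", "read_stack", "write_image", "write_stack",
           "localizations_to_frame", "write_localizations", "tracks_to_frame", "write_tracks"]


def read_image(path) -> np.ndarray:
    """Read a single-page grayscale TIFF as float64."""
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise InvalidParameterError(f"{path}: expected one grayscale page, got shape {arr.shape}")
    return np.asarray(arr, dtype=float)


def read_stack(path) -> list[np.ndarray]:
    """Read a single- or multi-page grayscale TIFF as a list of float64 frames."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        return [np.asarray(arr, dtype=float)]
    if arr.ndim != 3:
        raise InvalidParameterError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    return [np.asarray(a, dtype=float) for a in arr]


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_stack(path, stack) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def localizations_to_frame(locs, frames=None) -> pd.DataFrame:
    """Tabulate LocalizationResults with the standard column set."""
    rows = []
    for i, loc in enumerate(locs):
        rows.append({
            "frame": loc.frame_index if loc.frame_index is not None else (
                frames[i] if frames is not None else i),
            "x_px": loc.x,
            "y_px": loc.y,
            "n_lines": loc.n_lines,
            "residual_px": loc.residual,
            "z_value": loc.z_value if loc.z_value is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "n_lines", "residual_px", "z_value"])


def write_localizations(path, locs, frames=None) -> None:
    localizations_to_frame(locs, frames).to_csv(path, index=False)


def tracks_to_frame(trajectories) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        for f, loc in tr.points:
            rows.append({
                "particle_id": tr.particle_id,
                "frame": f,
                "x_px": loc.x,
                "y_px": loc.y,
                "z_value": loc.z_value if loc.z_value is not None else np.nan,
                "n_lines": loc.n_lines,
                "residual_px": loc.residual,
            })
    return pd.DataFrame(
        rows, columns=["particle_id", "frame", "x_px", "y_px", "z_value", "n_lines", "residual_px"]
    )


def write_tracks(path, trajectories) -> None:
    tracks_to_frame(trajectories).to_csv(path, index=False)
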