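"""Reading images and writing per-image statistics as delimited text."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import pandas as pd

from .scene_stats import compute_scene_stats, to_luminance

__all__ = ["load_luminance", "compute_stats_for_images", "write_stats"]

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def load_luminance(path: str | Path):
    """Read a PNG/JPEG file and return its luminance plane in [0, 1]."""
    return to_luminance(iio.imread(path))


def compute_stats_for_images(
    image_dir: str | Path,
    scales=(1.0, 2.0, 4.0, 8.0, 16.0),
    route: str = "weibull",
) -> pd.DataFrame:
    """Score every PNG/JPEG in a directory; returns the stats table.

    Columns: ``image_id, CE, SC, n_samples, route`` (image_id is the file
    stem).  Files are processed in sorted order for reproducibility.
    """
    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not paths:
        raise FileNotFoundError(f"no PNG/JPEG images found in {image_dir}")
    rows = []
    for p in paths:
        stats = compute_scene_stats(load_luminance(p), scales=tuple(scales), route=route)
        rows.append({"image_id": p.stem, "CE": stats.CE, "SC": stats.SC,
                     "n_samples": stats.n_samples, "route": stats.route})
    return pd.DataFrame(rows)


def write_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Write a statistics table as comma-delimited text."""
    stats.to_csv(path, index=False)
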