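"""Readers/writers and run configuration.

Images travel as plain multi-page TIFF (one page per channel/frame,
16-bit unsigned); tables as headered CSV; configuration as YAML.  Pixel
values are preserved bit-exactly on a write/read round trip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "SchemaError",
    "RunConfig",
    "write_image_stack",
    "read_image_stack",
    "write_distances_csv",
]


class SchemaError(ValueError):
    """An input file does not match the documented layout."""


def write_image_stack(path, images: Sequence[np.ndarray]) -> None:
    """Write images as a multi-page uint16 TIFF (values rounded + clipped)."""
    pages = [
        np.clip(np.round(np.asarray(img)), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        for img in images
    ]
    tifffile.imwrite(str(path), np.stack(pages))


def read_image_stack(path, n_channels: Optional[int] = None) -> List[np.ndarray]:
    """Read a (multi-page) TIFF back as a list of 2D float arrays.

    With ``n_channels`` given, the page count must be divisible by it;
    otherwise a :class:`SchemaError` names the file and its page count.
    """
    path = Path(path)
    try:
        data = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise SchemaError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        pages = [data]
    else:
        pages = [data[i] for i in range(data.shape[0])]
    if n_channels is not None and len(pages) % n_channels != 0:
        raise SchemaError(
            f"{path}: {len(pages)} page(s) not divisible by {n_channels} channel(s)"
        )
    return [p.astype(float) for p in pages]


@dataclass
class RunConfig:
    """Whole-pipeline configuration; YAML round-trips exactly.

    Lengths in nm, times in minutes (units recorded in the schema written
    alongside results).
    """

    seed: int = 0
    n_cells: int = 100
    mode: str = "tethered"  # locus placement mode
    tether_distance_mean: float = 83.0
    tether_distance_sd: float = 30.0
    forespore_diameter: float = 600.0
    pixel_size: float = 65.0
    frame_interval: float = 2.0
    detection_threshold_multiplier: float = 2.0
    null_variant: str = "disk_1d"
    null_n_samples: int = 100_000
    version: str = "sporeloc-0.1.0"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("pixel_size", "frame_interval", "forespore_diameter"):
            if getattr(self, name) is None or getattr(self, name) <= 0:
                raise SchemaError(f"config field {name} must be a positive number")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


DISTANCES_COLUMNS = [
    "cell_id",
    "d_nm",
    "a_focus_px",
    "a_membrane_px",
    "A_focus",
    "b_focus",
    "A_membrane",
    "b_membrane",
    "accepted",
    "reject_reason",
]


def write_distances_csv(path, measurements) -> pd.DataFrame:
    """Serialise DistanceMeasurements with the documented column schema."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "cell_id": m.cell_id,
                "d_nm": m.d_nm,
                "a_focus_px": m.focus_fit.a if m.focus_fit else None,
                "a_membrane_px": m.membrane_fit.a if m.membrane_fit else None,
                "A_focus": m.focus_fit.A if m.focus_fit else None,
                "b_focus": m.focus_fit.b if m.focus_fit else None,
                "A_membrane": m.membrane_fit.A if m.membrane_fit else None,
                "b_membrane": m.membrane_fit.b if m.membrane_fit else None,
                "accepted": m.accepted,
                "reject_reason": m.reject_reason,
            }
        )
    df = pd.DataFrame(rows, columns=DISTANCES_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df
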