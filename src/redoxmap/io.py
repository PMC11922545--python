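"""File round-trips for the package's containers.

Section images travel as single-page TIFF with the acquisition metadata in
the image description (JSON); decay cubes as HDF5 or NPZ with bin width and
repetition rate attributes; landmark pairs as tidy CSV
(image_id, frame, point_index, x, y).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .calibration import SectionImage
from .phasor import DecayCube

__all__ = [
    "save_section_image",
    "load_section_image",
    "save_decay_cube",
    "load_decay_cube",
    "save_landmarks",
    "load_landmarks",
]


def save_section_image(image: SectionImage, path) -> None:
    meta = {
        "pixel_size": image.pixel_size,
        "excitation_nm": image.excitation_nm,
        "emission_channel": image.emission_channel,
        "power": image.power,
        "gain": image.gain,
        "day": image.day,
        "units": image.units,
    }
    stack = np.stack([image.pixels.astype(np.float32), image.mask.astype(np.float32)])
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def load_section_image(path) -> SectionImage:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    return SectionImage(
        pixels=stack[0].astype(float),
        mask=stack[1] > 0.5,
        **meta,
    )


def save_decay_cube(cube: DecayCube, path) -> None:
    """Write counts plus bin/rate attributes to ``.h5``/``.hdf5`` or ``.npz``."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("counts", data=cube.counts, compression="gzip")
            ds.attrs["bin_width_ns"] = cube.bin_width_ns
            ds.attrs["rep_rate_MHz"] = cube.rep_rate_mhz
    elif path.suffix == ".npz":
        np.savez_compressed(
            path, counts=cube.counts,
            bin_width_ns=cube.bin_width_ns, rep_rate_MHz=cube.rep_rate_mhz,
        )
    else:
        raise ValueError(f"unsupported decay-cube format {path.suffix!r}")


def load_decay_cube(path) -> DecayCube:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["counts"]
            return DecayCube(
                counts=ds[...],
                bin_width_ns=float(ds.attrs["bin_width_ns"]),
                rep_rate_mhz=float(ds.attrs["rep_rate_MHz"]),
            )
    if path.suffix == ".npz":
        with np.load(path) as data:
            return DecayCube(
                counts=data["counts"],
                bin_width_ns=float(data["bin_width_ns"]),
                rep_rate_mhz=float(data["rep_rate_MHz"]),
            )
    raise ValueError(f"unsupported decay-cube format {path.suffix!r}")


def save_landmarks(pair_fixed: np.ndarray, pair_moving: np.ndarray, path,
                   image_id: str = "section") -> None:
    rows = []
    for frame, pair in (("fixed", pair_fixed), ("moving", pair_moving)):
        for i, (x, y) in enumerate(np.asarray(pair, dtype=float).reshape(2, 2), start=1):
            rows.append({"image_id": image_id, "frame": frame, "point_index": i,
                         "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_landmarks(path, image_id: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if image_id is not None:
        df = df[df.image_id == image_id]
    out = []
    for frame in ("fixed", "moving"):
        sub = df[df.frame == frame].sort_values("point_index")
        if len(sub) != 2:
            raise ValueError(f"expected exactly 2 {frame} landmarks")
        out.append(sub[["x", "y"]].to_numpy(dtype=float))
    return out[0], out[1]
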