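"""Reading raw image series and writing TIF / HDF5 results.

Input series can be a folder of single-page TIF files, a zip archive of
such files, or one multi-page TIF stack.  Files are ordered by
numeric-aware name sort (``img_2`` before ``img_10``), stacks by page
order, so the series order never depends on filesystem enumeration.
Acquisition times come from the TIF DateTime tag when present, else the
file modification time, else an index-based fallback
``(index - 1) * time_interval_s``.

Outputs are a multi-page float32 TIF with interleaved phase/amplitude
pages and an HDF5 store ``sensor_data.h5`` with per-image groups
(``/image_<i>/{phase,amplitude}``) and per-ROI subgroups
(``/image_<i>/roi_<j>/{phase,phase_fit}``).
"""

from __future__ import annotations

import datetime
import hashlib
import io as _io
import json
import os
import re
import zipfile
from dataclasses import dataclass

import h5py
import numpy as np
import tifffile

from .holo import QPImage

__all__ = ["RawImage", "read_image_series", "write_qpi_stack",
           "read_qpi_stack", "ResultsStore", "dataset_identifier",
           "natural_sort_key"]

_EPOCH = datetime.datetime(1970, 1, 1)


@dataclass
class RawImage:
    """One acquired camera frame plus acquisition metadata."""

    pixels: np.ndarray
    source_name: str
    time: float
    index: int  # 1-based position in the series

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 16:
            raise ValueError(f"{self.source_name}: image must be 2-D, "
                             ">= 16x16 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"{self.source_name}: non-finite pixels")


def natural_sort_key(name: str):
    """Numeric-aware sort key: ``img_2`` sorts before ``img_10``."""
    parts = re.split(r"(\d+)", name)
    return [int(p) if p.isdigit() else p for p in parts]


def _parse_tif_datetime(value: str) -> float | None:
    try:
        dt = datetime.datetime.strptime(value.strip("\x00 "),
                                        "%Y:%m:%d %H:%M:%S")
        return (dt - _EPOCH).total_seconds()
    except (ValueError, AttributeError):
        return None


def _check_sid4bio(tif: tifffile.TiffFile, name: str) -> None:
    for page in tif.pages[:1]:
        desc = page.tags.get("ImageDescription")
        if desc is not None and "SID4" in str(desc.value):
            raise ValueError("unsupported format: SID4Bio")


def _read_single(data: bytes, name: str, mtime: float | None):
    """All pages of one TIF file -> list of (pixels, time-or-None)."""
    try:
        with tifffile.TiffFile(_io.BytesIO(data)) as tif:
            _check_sid4bio(tif, name)
            out = []
            for pageno, page in enumerate(tif.pages):
                pixels = page.asarray()
                tag = page.tags.get("DateTime")
                t = _parse_tif_datetime(str(tag.value)) if tag else None
                if t is None:
                    t = mtime
                out.append((pixels, t))
            return out
    except Exception as err:
        if "SID4Bio" in str(err):
            raise
        raise ValueError(f"unreadable TIF {name!r}: {err}") from err


def read_image_series(path, time_interval_s: float = 1.0) -> list[RawImage]:
    """Load an ordered series of raw frames from a folder, zip archive or
    multi-page TIF stack.

    Raises ``ValueError("no images found")`` for an empty source and a
    file-naming error for unreadable pages.
    """
    path = os.fspath(path)
    entries = []  # (pixels, name, time-or-None)
    if os.path.isdir(path):
        names = sorted((n for n in os.listdir(path)
                        if n.lower().endswith((".tif", ".tiff"))),
                       key=natural_sort_key)
        for name in names:
            full = os.path.join(path, name)
            with open(full, "rb") as fh:
                data = fh.read()
            for pixels, t in _read_single(data, name, os.path.getmtime(full)):
                entries.append((pixels, name, t))
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            names = sorted((n for n in zf.namelist()
                            if n.lower().endswith((".tif", ".tiff"))
                            and not n.startswith("__MACOSX")),
                           key=natural_sort_key)
            for name in names:
                info = zf.getinfo(name)
                mtime = (datetime.datetime(*info.date_time)
                         - _EPOCH).total_seconds()
                for pixels, t in _read_single(zf.read(name), name, mtime):
                    entries.append((pixels, name, t))
    elif os.path.isfile(path):
        with open(path, "rb") as fh:
            data = fh.read()
        name = os.path.basename(path)
        for pixels, t in _read_single(data, name, None):
            entries.append((pixels, name, t))
    else:
        raise ValueError(f"input not found: {path}")

    if not entries:
        raise ValueError("no images found")
    images = []
    for idx, (pixels, name, t) in enumerate(entries, start=1):
        if t is None:
            t = (idx - 1) * time_interval_s
        images.append(RawImage(pixels=pixels, source_name=name,
                               time=float(t), index=idx))
    return images


def dataset_identifier(path) -> str:
    """First 5 hex digits of a content hash over the raw input bytes."""
    h = hashlib.sha256()
    path = os.fspath(path)
    if os.path.isdir(path):
        for name in sorted(os.listdir(path), key=natural_sort_key):
            if name.lower().endswith((".tif", ".tiff")):
                with open(os.path.join(path, name), "rb") as fh:
                    h.update(fh.read())
    else:
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
    return h.hexdigest()[:5]


# ---------------------------------------------------------------------------
# multi-page TIF output
# ---------------------------------------------------------------------------

def write_qpi_stack(images: list[QPImage], path) -> None:
    """Write phase/amplitude pairs as a multi-page float32 TIF.

    Page order is (phase_1, amplitude_1, phase_2, amplitude_2, ...); each
    page's description tag carries identifier, time, pixel size and
    wavelength as JSON.  All images must share pixel size and wavelength.
    """
    if not images:
        raise ValueError("nothing to write")
    first = images[0]
    for q in images[1:]:
        if (q.pixel_size != first.pixel_size
                or q.wavelength != first.wavelength):
            raise ValueError("mixed metadata: pixel size / wavelength differ")
    with tifffile.TiffWriter(os.fspath(path)) as tw:
        for q in images:
            for kind, arr in (("phase", q.phase), ("amplitude", q.amplitude)):
                desc = json.dumps({
                    "kind": kind, "identifier": q.identifier,
                    "time_s": q.time,
                    "pixel_size_um": q.pixel_size * 1e6,
                    "wavelength_nm": q.wavelength * 1e9,
                    "medium_index": q.medium_index,
                })
                tw.write(arr.astype(np.float32), description=desc,
                         contiguous=False)


def read_qpi_stack(path) -> list[QPImage]:
    """Inverse of :func:`write_qpi_stack`."""
    out = []
    with tifffile.TiffFile(os.fspath(path)) as tif:
        pages = tif.pages
        if len(pages) % 2:
            raise ValueError("odd page count: not a phase/amplitude stack")
        for i in range(0, len(pages), 2):
            meta = json.loads(pages[i].tags["ImageDescription"].value)
            out.append(QPImage(
                phase=pages[i].asarray().astype(float),
                amplitude=pages[i + 1].asarray().astype(float),
                wavelength=meta["wavelength_nm"] * 1e-9,
                pixel_size=meta["pixel_size_um"] * 1e-6,
                medium_index=meta["medium_index"],
                time=meta["time_s"], identifier=meta["identifier"]))
    return out


# ---------------------------------------------------------------------------
# HDF5 results store
# ---------------------------------------------------------------------------

class ResultsStore:
    """Hierarchical store for sensor and per-ROI data.

    Layout: ``/image_<i>/phase``, ``/image_<i>/amplitude`` (image metadata
    as group attributes) and ``/image_<i>/roi_<j>/{phase,phase_fit}`` with
    fit parameters as attributes.  Re-running a stage with unchanged
    configuration rewrites identical content.
    """

    def __init__(self, path, mode: str = "a"):
        self.path = os.fspath(path)
        self._h5 = h5py.File(self.path, mode)

    def close(self):
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def write_image(self, index: int, qpi: QPImage) -> None:
        name = f"image_{index}"
        if name in self._h5:
            del self._h5[name]
        grp = self._h5.create_group(name)
        grp.create_dataset("phase", data=qpi.phase.astype(np.float32))
        grp.create_dataset("amplitude", data=qpi.amplitude.astype(np.float32))
        grp.attrs.update({
            "identifier": qpi.identifier, "time_s": qpi.time,
            "pixel_size_um": qpi.pixel_size * 1e6,
            "wavelength_nm": qpi.wavelength * 1e9,
            "medium_index": qpi.medium_index,
        })

    def read_image(self, index: int) -> QPImage:
        grp = self._h5[f"image_{index}"]
        return QPImage(
            phase=grp["phase"][()].astype(float),
            amplitude=grp["amplitude"][()].astype(float),
            wavelength=grp.attrs["wavelength_nm"] * 1e-9,
            pixel_size=grp.attrs["pixel_size_um"] * 1e-6,
            medium_index=float(grp.attrs["medium_index"]),
            time=float(grp.attrs["time_s"]),
            identifier=str(grp.attrs["identifier"]))

    @property
    def image_indices(self) -> list[int]:
        return sorted(int(k.split("_")[1]) for k in self._h5
                      if k.startswith("image_"))

    def write_roi(self, image_index: int, roi_index: int,
                  phase: np.ndarray, phase_fit: np.ndarray | None = None,
                  attrs: dict | None = None) -> None:
        name = f"image_{image_index}/roi_{roi_index}"
        if name in self._h5:
            del self._h5[name]
        grp = self._h5.create_group(name)
        grp.create_dataset("phase", data=np.asarray(phase, np.float32))
        if phase_fit is not None:
            grp.create_dataset("phase_fit",
                               data=np.asarray(phase_fit, np.float32))
        if attrs:
            grp.attrs.update(attrs)
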