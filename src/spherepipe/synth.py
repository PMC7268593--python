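"""Synthetic phantoms and off-axis holograms with known ground truth.

Generates the inputs every pipeline stage is tested against: spherical
phase objects (projection or Rytov profiles), quadratic phase backgrounds,
off-axis carrier fringes and additive Gaussian noise.  Defaults mimic the
cell-nucleus use case: lambda = 550 nm, 0.107 um pixels, aqueous medium
(n_med = 1.335), radii 2-7 um.  All randomness flows from a single seed;
the same spec and seed reproduce byte-identical output.
"""

from __future__ import annotations

import datetime
import os
import zipfile
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .holo import CarrierSpec, QPImage
from .io_series import RawImage
from .models import Grid, SphereParams, projection_phase, rytov_field

__all__ = ["PhantomSpec", "gen_sphere_qpi", "gen_hologram", "gen_dataset",
           "DEFAULTS"]

#: imaging defaults for generated fixtures
DEFAULTS = dict(wavelength=550e-9, pixel_size=0.107e-6, medium_index=1.335)

# fixed epoch for synthetic timestamps (TIF DateTime has 1 s resolution)
_T0 = datetime.datetime(2020, 1, 1, 12, 0, 0)


@dataclass
class PhantomSpec:
    """Full description of one synthetic frame.

    ``bg_poly`` are the six coefficients (a..f) of a quadratic phase
    background ``a + b x + c y + d x^2 + e y^2 + f x y`` on coordinates
    scaled to [-1, 1]; ``noise_sigma`` is additive Gaussian phase noise in
    rad (or intensity noise relative to the fringe amplitude for
    holograms); ``fringe_contrast`` scales the interference term.
    """

    spheres: list[SphereParams]
    grid: Grid
    bg_poly: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    noise_sigma: float = 0.0
    # fringe period ~2.4 px, typical of off-axis setups; keeps the
    # sideband filter passband wide enough to preserve the sphere rim
    carrier: CarrierSpec = field(
        default_factory=lambda: CarrierSpec(kx=2.2, ky=1.5, mode="fixed"))
    fringe_contrast: float = 1.0
    seed: int = 0

    def __post_init__(self):
        px = self.grid.pixel_size
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1:]:
                dist = np.hypot(a.cx - b.cx, a.cy - b.cy) * px
                if dist <= a.r + b.r + 5 * px:
                    raise ValueError("spheres overlap (need center distance "
                                     "> r_i + r_j + 5 px)")


def _poly_background(shape, coeffs) -> np.ndarray:
    H, W = shape
    y = np.linspace(-1, 1, H)[:, None]
    x = np.linspace(-1, 1, W)[None, :]
    a, b, c, d, e, f = coeffs
    return a + b * x + c * y + d * x ** 2 + e * y ** 2 + f * x * y


def gen_sphere_qpi(spec: PhantomSpec, model: str = "projection"):
    """Phase/amplitude image of the phantom plus its ground-truth record.

    The phase is the superposition of the sphere model phases, the
    quadratic background, and Gaussian noise drawn from ``spec.seed``.
    Amplitude is 1 for the projection model and the Rytov amplitude
    otherwise.  Returns ``(QPImage, truth)`` where ``truth`` is the list
    of sphere parameters.
    """
    g = spec.grid
    phase = _poly_background(g.shape, spec.bg_poly)
    amplitude = np.ones(g.shape)
    for p in spec.spheres:
        if model == "projection":
            phase = phase + projection_phase(p, g)
        elif model == "rytov":
            ph, am = rytov_field(p, g)
            phase = phase + ph
            amplitude = amplitude * am
        else:
            raise ValueError(f"unknown phantom model {model!r}")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        phase = phase + rng.normal(0.0, spec.noise_sigma, g.shape)
    qpi = QPImage(phase=phase, amplitude=amplitude,
                  wavelength=g.wavelength, pixel_size=g.pixel_size,
                  medium_index=g.medium_index)
    return qpi, list(spec.spheres)


def gen_hologram(qpi: QPImage, spec: PhantomSpec) -> RawImage:
    """Off-axis hologram of a quantitative phase image.

    ``I(x, y) = 1 + a^2 + 2 a c cos(kx x + ky y - phi)`` with
    ``a = amplitude`` and fringe contrast ``c``, plus Gaussian counts
    noise of ``noise_sigma`` times the fringe amplitude (seeded).
    """
    k = spec.carrier
    if np.hypot(k.kx, k.ky) >= np.pi:
        raise ValueError("carrier above Nyquist")
    H, W = qpi.shape
    yy, xx = np.indices((H, W), dtype=float)
    a = qpi.amplitude
    c = spec.fringe_contrast
    I = 1.0 + a ** 2 + 2 * a * c * np.cos(k.kx * xx + k.ky * yy - qpi.phase)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        I = I + rng.normal(0.0, spec.noise_sigma * 2 * c, (H, W))
    I = I - min(0.0, float(I.min()))  # counts are non-negative
    return RawImage(pixels=I, source_name="synthetic", time=qpi.time,
                    index=1)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _place_spheres(rng, shape, k, px, radius_range, index_range):
    """One sphere per jittered grid cell: guaranteed non-overlapping."""
    H, W = shape
    ncols = int(np.ceil(np.sqrt(k)))
    nrows = int(np.ceil(k / ncols))
    cell_h, cell_w = H / nrows, W / ncols
    spheres = []
    cells = [(i, j) for i in range(nrows) for j in range(ncols)][:k]
    for (i, j) in cells:
        r = rng.uniform(*radius_range)
        n = rng.uniform(*index_range)
        r_px = r / px
        margin = r_px + 8
        jy = rng.uniform(margin, cell_h - margin) if cell_h > 2 * margin \
            else cell_h / 2
        jx = rng.uniform(margin, cell_w - margin) if cell_w > 2 * margin \
            else cell_w / 2
        spheres.append(SphereParams(n=n, r=r, cx=j * cell_w + jx,
                                    cy=i * cell_h + jy))
    return spheres


def gen_dataset(n_images: int, spheres_per_image: int, out_path,
                seed: int = 0, shape=(700, 700), model: str = "projection",
                radius_range=(2e-6, 7e-6), index_range=(1.34, 1.38),
                bg_poly=(0.2, 0.4, -0.3, 0.15, -0.1, 0.05),
                noise_sigma: float = 0.01,
                fringe_contrast: float = 1.0) -> str:
    """Write a synthetic hologram series (folder or ``.zip``) plus a
    ground-truth manifest TSV.

    Frames are timestamped 1 s apart (via the TIF DateTime tag).  The
    manifest columns are image, sphere, n, r_um, cx_px, cy_px.  Returns
    the manifest path (next to the dataset).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_path = os.fspath(out_path)
    grid = Grid(shape=shape, pixel_size=DEFAULTS["pixel_size"],
                wavelength=DEFAULTS["wavelength"],
                medium_index=DEFAULTS["medium_index"])
    rng = np.random.default_rng(seed)

    frames = []
    manifest = ["image\tsphere\tn\tr_um\tcx_px\tcy_px"]
    for i in range(1, n_images + 1):
        spheres = _place_spheres(rng, shape, spheres_per_image,
                                 grid.pixel_size, radius_range, index_range)
        spec = PhantomSpec(spheres=spheres, grid=grid, bg_poly=bg_poly,
                           noise_sigma=noise_sigma,
                           fringe_contrast=fringe_contrast,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        qpi, truth = gen_sphere_qpi(spec, model=model)
        qpi.time = float(i - 1)
        holo = gen_hologram(qpi, spec)
        frames.append(holo.pixels.astype(np.float32))
        for j, p in enumerate(truth, start=1):
            manifest.append(f"{i}\t{j}\t{p.n:.6f}\t{p.r * 1e6:.4f}"
                            f"\t{p.cx:.2f}\t{p.cy:.2f}")

    def page_bytes(pixels, i):
        import io as _io
        buf = _io.BytesIO()
        dt = (_T0 + datetime.timedelta(seconds=i - 1))
        tifffile.imwrite(buf, pixels, datetime=dt)
        return buf.getvalue()

    if out_path.endswith(".zip"):
        with zipfile.ZipFile(out_path, "w", zipfile.ZIP_STORED) as zf:
            for i, pixels in enumerate(frames, start=1):
                info = zipfile.ZipInfo(f"img_{i}.tif",
                                       date_time=(2020, 1, 1, 12, 0, 0))
                zf.writestr(info, page_bytes(pixels, i))
        manifest_path = out_path[:-4] + "_manifest.tsv"
    else:
        os.makedirs(out_path, exist_ok=True)
        for i, pixels in enumerate(frames, start=1):
            with open(os.path.join(out_path, f"img_{i}.tif"), "wb") as fh:
                fh.write(page_bytes(pixels, i))
        manifest_path = os.path.join(out_path, "manifest.tsv")

    with open(manifest_path, "w") as fh:
        fh.write("\n".join(manifest) + "\n")
    return manifest_path
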