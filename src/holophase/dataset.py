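"""Datasets, flat/dark correction, rigid alignment and parallel mapping.

Two on-disk layouts are supported, one per format:

* HDF5: ``/entry/data/dist_<k>`` datasets shaped ``(n_proj, ny, nx)`` with a
  ``z1_m`` attribute per distance, optional ``/entry/flats/dist_<k>`` and
  ``/entry/darks/dist_<k>`` (single 2D frames), root attributes
  ``energy_kev``, ``zd_m``, ``pixel_m`` and optionally ``seed``, optional
  ground truth under ``/truth/phi`` and ``/truth/B``, optional per-image
  shifts under ``/entry/shifts`` shaped ``(n_proj, n_dist, 2)``.
* TIFF directory: ``dist<k>/proj_<n:05d>.tif`` (32-bit float), optional
  ``dist<k>/flat.tif`` / ``dist<k>/dark.tif``, geometry in ``geometry.yml``
  (same key names).

Alignment is rigid translation by phase correlation with sub-pixel parabolic
peak interpolation — adequate for simulated or magnification-matched data;
strongly magnification-mismatched stacks need deformable registration, which
is out of scope here.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ProcessPoolExecutor
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np
import tifffile
import yaml

from .exceptions import AlignmentError, CorrectionError, DataError
from .geometry import AcquisitionGeometry

__all__ = [
    "Dataset",
    "HDF5Dataset",
    "TiffDataset",
    "open_dataset",
    "write_hdf5_dataset",
    "write_tiff_dataset",
    "correct_image",
    "phase_correlation",
    "align_stack",
    "apply_shift",
    "parallel_map",
    "load_config",
    "geometry_from_config",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# flat/dark correction

def correct_image(
    image: np.ndarray,
    flat: np.ndarray | None = None,
    dark: np.ndarray | None = None,
) -> np.ndarray:
    """Flat/dark correction ``(I - dark) / (flat - dark)``.

    Without flats/darks the image is returned unchanged.  A non-positive
    denominator anywhere is an error; negative corrected values are clipped
    at 0 (count logged).
    """
    image = np.asarray(image, dtype=np.float64)
    if flat is None and dark is None:
        return image
    dark = np.zeros_like(image) if dark is None else np.asarray(dark, dtype=np.float64)
    flat = np.ones_like(image) if flat is None else np.asarray(flat, dtype=np.float64)
    denom = flat - dark
    n_bad = int(np.count_nonzero(denom <= 0))
    if n_bad:
        raise CorrectionError(f"flat - dark <= 0 at {n_bad} pixels")
    out = (image - dark) / denom
    n_neg = int(np.count_nonzero(out < 0))
    if n_neg:
        logger.warning("correct_image: clipped %d negative pixels to 0", n_neg)
        out = np.clip(out, 0.0, None)
    return out


# ---------------------------------------------------------------------------
# datasets

class Dataset:
    """Read access to a multi-distance projection dataset.

    Indices are 0-based with half-open ranges; images are addressed as
    ``(projection_index, distance_index)``.
    """

    n_projections: int
    n_distances: int

    def raw(self, proj: int, dist: int) -> np.ndarray:
        raise NotImplementedError

    def flat(self, dist: int) -> np.ndarray | None:
        raise NotImplementedError

    def dark(self, dist: int) -> np.ndarray | None:
        raise NotImplementedError

    def read_corrected(self, proj: int, dist: int) -> np.ndarray:
        """Flat/dark-corrected projection (identity without flats/darks)."""
        return correct_image(self.raw(proj, dist), self.flat(dist), self.dark(dist))

    @property
    def geometry(self) -> AcquisitionGeometry | None:
        return None

    @property
    def z1_list(self) -> list[float] | None:
        return None


class HDF5Dataset(Dataset):
    """Dataset stored in the HDF5 layout documented in this module."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        with h5py.File(self.path, "r") as f:
            keys = sorted(f["entry/data"].keys(), key=lambda k: int(k.split("_")[1]))
            self._keys = keys
            self.n_distances = len(keys)
            self.n_projections = f["entry/data"][keys[0]].shape[0]
            self._z1 = [float(f["entry/data"][k].attrs.get("z1_m", np.nan)) for k in keys]
            self._attrs = dict(f.attrs)
            self._has_flats = "entry/flats" in f
            self._has_darks = "entry/darks" in f

    def raw(self, proj: int, dist: int) -> np.ndarray:
        with h5py.File(self.path, "r") as f:
            return f["entry/data"][self._keys[dist]][proj].astype(np.float64)

    def flat(self, dist: int) -> np.ndarray | None:
        if not self._has_flats:
            return None
        with h5py.File(self.path, "r") as f:
            return f["entry/flats"][self._keys[dist]][...].astype(np.float64)

    def dark(self, dist: int) -> np.ndarray | None:
        if not self._has_darks:
            return None
        with h5py.File(self.path, "r") as f:
            return f["entry/darks"][self._keys[dist]][...].astype(np.float64)

    def truth(self) -> tuple[np.ndarray, np.ndarray] | None:
        with h5py.File(self.path, "r") as f:
            if "truth" not in f:
                return None
            return f["truth/phi"][...], f["truth/B"][...]

    def shifts(self) -> np.ndarray | None:
        with h5py.File(self.path, "r") as f:
            if "entry/shifts" not in f:
                return None
            return f["entry/shifts"][...]

    @property
    def geometry(self) -> AcquisitionGeometry | None:
        a = self._attrs
        needed = ("energy_kev", "z1_m", "zd_m", "pixel_m")
        if not all(k in a for k in needed):
            return None
        return AcquisitionGeometry(
            energy_kev=float(a["energy_kev"]),
            z1_m=float(a["z1_m"]),
            zd_m=float(a["zd_m"]),
            pixel_m=float(a["pixel_m"]),
        )

    @property
    def z1_list(self) -> list[float] | None:
        return None if any(math.isnan(z) for z in self._z1) else list(self._z1)


class TiffDataset(Dataset):
    """Dataset stored as ``dist<k>/proj_<n:05d>.tif`` under one directory."""

    def __init__(self, path: str | Path):
        self.root = Path(path)
        dist_dirs = sorted(
            (d for d in self.root.iterdir() if d.is_dir() and d.name.startswith("dist")),
            key=lambda d: int(d.name[4:]),
        )
        if not dist_dirs:
            raise DataError(f"no dist<k> directories under {self.root}")
        self._dirs = dist_dirs
        self.n_distances = len(dist_dirs)
        self.n_projections = len(sorted(dist_dirs[0].glob("proj_*.tif")))
        self._config = {}
        cfg_path = self.root / "geometry.yml"
        if cfg_path.exists():
            self._config = load_config(cfg_path)

    def raw(self, proj: int, dist: int) -> np.ndarray:
        return tifffile.imread(self._dirs[dist] / f"proj_{proj:05d}.tif").astype(
            np.float64
        )

    def _aux(self, dist: int, name: str) -> np.ndarray | None:
        p = self._dirs[dist] / f"{name}.tif"
        return tifffile.imread(p).astype(np.float64) if p.exists() else None

    def flat(self, dist: int) -> np.ndarray | None:
        return self._aux(dist, "flat")

    def dark(self, dist: int) -> np.ndarray | None:
        return self._aux(dist, "dark")

    @property
    def geometry(self) -> AcquisitionGeometry | None:
        c = self._config
        needed = ("energy_kev", "z1_m", "zd_m", "pixel_m")
        if not all(k in c for k in needed):
            return None
        return geometry_from_config(c)

    @property
    def z1_list(self) -> list[float] | None:
        z = self._config.get("z1_list")
        return [float(v) for v in z] if z is not None else None


def open_dataset(path: str | Path) -> Dataset:
    """Open a dataset, dispatching on layout (HDF5 file vs TIFF directory)."""
    p = Path(path)
    if p.is_dir():
        return TiffDataset(p)
    return HDF5Dataset(p)


def write_hdf5_dataset(
    path: str | Path,
    images: Sequence[np.ndarray],
    z1_list: Sequence[float],
    geometry: AcquisitionGeometry | None = None,
    flats: Sequence[np.ndarray] | None = None,
    darks: Sequence[np.ndarray] | None = None,
    truth: tuple[np.ndarray, np.ndarray] | None = None,
    shifts: np.ndarray | None = None,
    seed: int | None = None,
) -> None:
    """Write a dataset in the HDF5 layout.

    ``images`` is one array per distance, shaped ``(n_proj, ny, nx)`` (a
    single 2D frame is accepted and treated as one projection).
    """
    with h5py.File(path, "w") as f:
        grp = f.create_group("entry/data")
        for k, (im, z1) in enumerate(zip(images, z1_list)):
            im = np.asarray(im, dtype=np.float32)
            if im.ndim == 2:
                im = im[None]
            ds = grp.create_dataset(f"dist_{k}", data=im)
            ds.attrs["z1_m"] = float(z1)
        for name, frames in (("flats", flats), ("darks", darks)):
            if frames is not None:
                g = f.create_group(f"entry/{name}")
                for k, fr in enumerate(frames):
                    g.create_dataset(f"dist_{k}", data=np.asarray(fr, dtype=np.float32))
        if truth is not None:
            f.create_dataset("truth/phi", data=np.asarray(truth[0], dtype=np.float32))
            f.create_dataset("truth/B", data=np.asarray(truth[1], dtype=np.float32))
        if shifts is not None:
            f.create_dataset("entry/shifts", data=np.asarray(shifts, dtype=np.float64))
        if geometry is not None:
            f.attrs["energy_kev"] = geometry.energy_kev
            f.attrs["z1_m"] = geometry.z1_m
            f.attrs["zd_m"] = geometry.zd_m
            f.attrs["pixel_m"] = geometry.pixel_m
        if seed is not None:
            f.attrs["seed"] = int(seed)


def write_tiff_dataset(
    root: str | Path,
    images: Sequence[np.ndarray],
    z1_list: Sequence[float] | None = None,
    geometry: AcquisitionGeometry | None = None,
    flats: Sequence[np.ndarray] | None = None,
    darks: Sequence[np.ndarray] | None = None,
) -> None:
    """Write a dataset in the TIFF-directory layout (32-bit float frames)."""
    root = Path(root)
    for k, im in enumerate(images):
        im = np.asarray(im, dtype=np.float32)
        if im.ndim == 2:
            im = im[None]
        d = root / f"dist{k}"
        d.mkdir(parents=True, exist_ok=True)
        for n in range(im.shape[0]):
            tifffile.imwrite(d / f"proj_{n:05d}.tif", im[n])
        if flats is not None:
            tifffile.imwrite(d / "flat.tif", np.asarray(flats[k], dtype=np.float32))
        if darks is not None:
            tifffile.imwrite(d / "dark.tif", np.asarray(darks[k], dtype=np.float32))
    cfg: dict = {}
    if geometry is not None:
        cfg.update(
            energy_kev=geometry.energy_kev,
            z1_m=geometry.z1_m,
            zd_m=geometry.zd_m,
            pixel_m=geometry.pixel_m,
        )
    if z1_list is not None:
        cfg["z1_list"] = [float(z) for z in z1_list]
    if cfg:
        (root / "geometry.yml").write_text(yaml.safe_dump(cfg))


# ---------------------------------------------------------------------------
# alignment

def _parabolic_offset(m1: float, m0: float, p1: float) -> float:
    denom = m1 - 2.0 * m0 + p1
    if denom == 0:
        return 0.0
    return 0.5 * (m1 - p1) / denom


def phase_correlation(ref: np.ndarray, image: np.ndarray) -> tuple[float, float]:
    """Rigid shift (dy, dx) of ``image`` relative to ``ref``.

    Peak of the inverse DFT of the normalized cross-power spectrum, with a
    3-point parabolic fit per axis for sub-pixel precision.  For
    ``image = roll(ref, (dy, dx))`` the returned shift is exactly (dy, dx)
    (wrapped into [-N/2, N/2)).
    """
    ref = np.asarray(ref, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if ref.shape != image.shape:
        raise AlignmentError("images must share a shape")
    if not np.any(ref) or not np.any(image):
        raise AlignmentError("phase correlation undefined for an all-zero image")
    cross = np.conj(np.fft.fft2(ref)) * np.fft.fft2(image)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    corr = np.real(np.fft.ifft2(cross / mag))
    py, px = np.unravel_index(np.argmax(corr), corr.shape)
    ny, nx = corr.shape
    dy = py + _parabolic_offset(
        corr[(py - 1) % ny, px], corr[py, px], corr[(py + 1) % ny, px]
    )
    dx = px + _parabolic_offset(
        corr[py, (px - 1) % nx], corr[py, px], corr[py, (px + 1) % nx]
    )
    if dy > ny / 2:
        dy -= ny
    if dx > nx / 2:
        dx -= nx
    return float(dy), float(dx)


def align_stack(images: Sequence[np.ndarray]) -> list[tuple[float, float]]:
    """Shifts of every image relative to the first ((0, 0) for the first).

    Images must share a shape and be resampled to a common pixel size.
    """
    images = list(images)
    if len(images) < 2:
        raise AlignmentError("need at least two images to align")
    shifts = [(0.0, 0.0)]
    for im in images[1:]:
        shifts.append(phase_correlation(images[0], im))
    return shifts


def apply_shift(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Shift an image by (dy, dx) pixels via the Fourier shift theorem.

    Equals ``np.roll(image, (dy, dx), axis=(0, 1))`` for integer shifts;
    periodic boundary.  To undo a shift measured by
    :func:`phase_correlation`, apply ``(-dy, -dx)``.
    """
    image = np.asarray(image, dtype=np.float64)
    ny, nx = image.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    ramp_y = np.exp(-2j * np.pi * fy * dy)
    ramp_x = np.exp(-2j * np.pi * fx * dx)
    # keep each 1D ramp Hermitian at its unpaired Nyquist bin (even sizes):
    # real part there, so real images stay real and integer shifts are rolls
    if ny % 2 == 0:
        ramp_y[ny // 2, 0] = ramp_y[ny // 2, 0].real
    if nx % 2 == 0:
        ramp_x[0, nx // 2] = ramp_x[0, nx // 2].real
    return np.real(np.fft.ifft2(np.fft.fft2(image) * ramp_y * ramp_x))


# ---------------------------------------------------------------------------
# parallel mapping over projections

def _run_chunk(fn: Callable, indices: list[int]):
    out = []
    for i in indices:
        try:
            out.append(fn(i))
        except Exception as exc:  # annotate with the projection index
            raise RuntimeError(f"parallel_map: projection {i} raised {exc!r}") from exc
    return out


def parallel_map(
    fn: Callable,
    projection_range: Sequence[int] | range,
    backend: str = "serial",
    n_workers: int = 1,
) -> list:
    """Map ``fn`` over projection indices, serially or over processes.

    Results are returned in input order and are identical between backends
    (``fn`` must be a pure, picklable function of the index).  The range is
    split into ``ceil(n / n_workers)``-sized chunks.
    """
    indices = list(projection_range)
    if not indices:
        return []
    if backend == "serial":
        return _run_chunk(fn, indices)
    if backend != "process":
        raise DataError(f"unknown backend {backend!r} (use 'serial' or 'process')")
    chunk = math.ceil(len(indices) / n_workers)
    chunks = [indices[i : i + chunk] for i in range(0, len(indices), chunk)]
    results: list = []
    with ProcessPoolExecutor(max_workers=n_workers) as pool:
        for part in pool.map(_run_chunk, [fn] * len(chunks), chunks):
            results.extend(part)
    return results


# ---------------------------------------------------------------------------
# config

def load_config(path: str | Path) -> dict:
    """Load a flat key/value YAML config file."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise DataError(f"config {path} must be a mapping")
    return cfg


def geometry_from_config(cfg: dict) -> AcquisitionGeometry:
    """Build an :class:`AcquisitionGeometry` from config keys
    ``energy_kev``, ``z1_m``, ``zd_m``, ``pixel_m``."""
    try:
        return AcquisitionGeometry(
            energy_kev=float(cfg["energy_kev"]),
            z1_m=float(cfg["z1_m"]),
            zd_m=float(cfg["zd_m"]),
            pixel_m=float(cfg["pixel_m"]),
        )
    except KeyError as exc:
        raise DataError(f"config missing geometry key {exc}") from exc
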