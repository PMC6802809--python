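"""Image ingestion, synthetic natural-image generation, and patch extraction.

Dictionary learning operates on small square patches cut out of large
grayscale scenes.  Natural scenes have two statistical signatures that matter
here: an amplitude spectrum falling off roughly as 1/f, and a high density of
oriented edge segments.  :func:`synthesize_images` emulates both so that the
whole learning pipeline can be exercised without an external image database;
:func:`load_images` accepts any user-supplied folder of PNG/JPEG/TIFF scenes.

Patches are circularly masked (pixels outside the inscribed disc are zeroed)
to avoid square-window artifacts in the learned atoms, and each patch has its
mean over the mask support removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: ITU-R 601 luma weights used to collapse RGB images to luminance.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Patches whose variance over the mask support falls below this fraction of
#: the source-image variance are rejected and resampled.
VARIANCE_FLOOR_FRACTION = 1e-6

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


@dataclass
class ImageSet:
    """A collection of 2-D luminance arrays plus a tag naming their origin."""

    images: list[np.ndarray]
    source_tag: str = "folder"

    def __post_init__(self) -> None:
        for im in self.images:
            if im.ndim != 2:
                raise ValueError("ImageSet requires 2-D luminance arrays")
            if not np.all(np.isfinite(im)):
                raise ValueError("ImageSet images must be finite-valued")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class SyntheticParams:
    """Parameters of the synthetic natural-scene generator.

    Attributes
    ----------
    n_images:
        Number of images to synthesize.
    image_size:
        Side length in pixels of each (square) image.
    spectral_exponent:
        Target decay of the radially averaged amplitude spectrum,
        ``amplitude ∝ 1/f**spectral_exponent``.  Natural scenes sit near 1.
    n_edges:
        Number of straight oriented edge segments superposed per image.
    edge_contrast:
        Peak luminance amplitude of each edge segment, in units of the
        (unit-variance) background field.
    noise_std:
        Standard deviation of the iid Gaussian pixel noise added last.
    seed:
        Seed of the generator; synthesis is bit-reproducible per seed.
    """

    n_images: int = 12
    image_size: int = 128
    spectral_exponent: float = 1.0
    n_edges: int = 24
    edge_contrast: float = 2.0
    noise_std: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.spectral_exponent < 0:
            raise ValueError("spectral_exponent must be >= 0")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


@dataclass
class PatchBatch:
    """K circularly-masked, mean-removed patch vectors of length M.

    ``data`` is a (K, M) matrix with M = patch_size**2; entries outside the
    circular mask are exactly zero and each row has zero mean over the mask
    support.
    """

    data: np.ndarray
    patch_size: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = circular_mask(self.patch_size)
        if self.data.ndim != 2 or self.data.shape[1] != self.patch_size**2:
            raise ValueError("data must be (K, patch_size**2)")

    @property
    def K(self) -> int:
        return self.data.shape[0]

    @property
    def M(self) -> int:
        return self.data.shape[1]


def circular_mask(patch_size: int) -> np.ndarray:
    """Boolean length-``patch_size**2`` vector, True strictly inside the disc.

    The disc has radius ``patch_size / 2`` and is centred on the patch centre
    ``((s-1)/2, (s-1)/2)``; the inside test is strict, giving a hard binary
    mask (row-major ravel order).
    """
    s = patch_size
    c = (s - 1) / 2.0
    r = np.arange(s)
    d2 = (r[:, None] - c) ** 2 + (r[None, :] - c) ** 2
    return (d2 < (s / 2.0) ** 2).ravel()


def _spectral_field(rng: np.random.Generator, size: int, exponent: float) -> np.ndarray:
    """Gaussian random field with amplitude spectrum ∝ 1/f**exponent, zero DC."""
    white = rng.standard_normal((size, size))
    fx = np.fft.fftfreq(size)
    f = np.hypot(fx[:, None], fx[None, :])
    gain = np.zeros_like(f)
    nz = f > 0
    gain[nz] = f[nz] ** (-exponent)
    return np.fft.ifft2(np.fft.fft2(white) * gain).real


def _add_edges(
    img: np.ndarray, rng: np.random.Generator, n_edges: int, contrast: float
) -> None:
    """Superpose straight edge segments with a Gaussian ridge profile in place."""
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    width = 1.0  # ridge half-width (px); keeps edges sharp but band-limited
    for _ in range(n_edges):
        cy, cx = rng.uniform(0, size, 2)
        theta = rng.uniform(0, np.pi)
        half_len = rng.uniform(size / 16, size / 8)
        ty, tx = np.sin(theta), np.cos(theta)  # tangent
        dy, dx = yy - cy, xx - cx
        along = dy * ty + dx * tx
        perp = -dy * tx + dx * ty
        ridge = np.exp(-0.5 * (perp / width) ** 2)
        ridge[np.abs(along) > half_len] = 0.0
        img += contrast * rng.choice([-1.0, 1.0]) * ridge


def synthesize_images(params: SyntheticParams, patch_size: int | None = None) -> ImageSet:
    """Generate a deterministic synthetic image set emulating natural scenes.

    Each image is a 1/f**exponent filtered Gaussian field, plus ``n_edges``
    oriented edge segments at ``edge_contrast``, plus iid Gaussian noise,
    standardized to zero mean and unit variance.

    Parameters
    ----------
    params:
        Generator settings; see :class:`SyntheticParams`.
    patch_size:
        If given, reject image sizes below ``2 * patch_size`` (too small to
        sample diverse patches from).
    """
    if patch_size is not None and params.image_size < 2 * patch_size:
        raise ValueError(
            f"image_size={params.image_size} < 2*patch_size={2 * patch_size}"
        )
    rng = np.random.default_rng(params.seed)
    images = []
    for _ in range(params.n_images):
        img = _spectral_field(rng, params.image_size, params.spectral_exponent)
        std = img.std()
        if std > 0:
            img /= std
        if params.n_edges > 0:
            _add_edges(img, rng, params.n_edges, params.edge_contrast)
        if params.noise_std > 0:
            img += params.noise_std * rng.standard_normal(img.shape)
        img -= img.mean()
        std = img.std()
        if std > 0:
            img /= std
        images.append(img)
    return ImageSet(images=images, source_tag="synthetic")


def load_images(folder_path: str | Path, grayscale_conversion: str = "itu601") -> ImageSet:
    """Load all PNG/JPEG/TIFF images in a folder as luminance arrays in [0, 1].

    RGB(A) images are collapsed with ITU-R 601 luma weights; unreadable files
    are skipped with a logged warning; an image-free folder is an error.
    """
    import imageio.v3 as iio

    if grayscale_conversion != "itu601":
        raise ValueError(f"unknown grayscale conversion {grayscale_conversion!r}")
    folder = Path(folder_path)
    paths = sorted(p for p in folder.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    images = []
    for p in paths:
        try:
            arr = np.asarray(iio.imread(p), dtype=float)
        except Exception as exc:  # unreadable/corrupt file
            logger.warning("skipping unreadable image %s: %s", p, exc)
            continue
        if arr.ndim == 3:
            arr = arr[..., :3] @ LUMA_WEIGHTS
        if arr.max() > 1.0:
            arr = arr / 255.0
        images.append(arr)
    if not images:
        raise FileNotFoundError(f"no readable images found in {folder}")
    return ImageSet(images=images, source_tag="folder")


def extract_patches(
    imageset: ImageSet,
    patch_size: int = 21,
    K: int = 256,
    seed: int = 0,
    max_attempts_factor: int = 50,
) -> PatchBatch:
    """Sample K masked, mean-removed patches at uniformly random positions.

    Patches whose variance over the mask support is below
    ``VARIANCE_FLOOR_FRACTION`` times the source-image variance are rejected
    and resampled; failure to collect K patches within
    ``max_attempts_factor * K`` attempts is an error.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    for im in imageset.images:
        if min(im.shape) < patch_size:
            raise ValueError("every image must be at least patch_size on each side")
    mask = circular_mask(patch_size)
    rng = np.random.default_rng(seed)
    img_vars = np.array([im.var() for im in imageset.images])
    rows, attempts = [], 0
    max_attempts = max_attempts_factor * K
    while len(rows) < K:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not find {K} patches above the variance floor "
                f"({VARIANCE_FLOOR_FRACTION} of image variance) in "
                f"{max_attempts} attempts"
            )
        attempts += 1
        j = int(rng.integers(len(imageset.images)))
        im = imageset.images[j]
        r = int(rng.integers(im.shape[0] - patch_size + 1))
        c = int(rng.integers(im.shape[1] - patch_size + 1))
        patch = im[r : r + patch_size, c : c + patch_size].ravel().copy()
        patch[~mask] = 0.0
        sup = patch[mask]
        if sup.var() <= VARIANCE_FLOOR_FRACTION * img_vars[j]:
            continue
        patch[mask] = sup - sup.mean()
        rows.append(patch)
    return PatchBatch(data=np.array(rows), patch_size=patch_size, mask=mask)
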