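"""The three predictors of colour change blindness for one image pair.

Given an original scene ``s`` and a changed scene ``s*`` that differ in the
colour of a single object, the model summarises the pair with three numbers:

* **change magnitude** ``f_cm`` — the mean perceptual colour difference
  (Euclidean distance in the uniform colour space) over *changed pixels
  only*, so the area of the change does not enter;
* **salience imbalance** ``f_si`` — the normalised Hamming distance between
  the signs of the 2-D DCT coefficients of the two images, averaged over the
  three colour channels.  The DCT sign pattern is a compact signature of the
  bottom-up salience map, so this fraction measures how many spatial
  frequency components the change perturbs;
* **user experience** ``f_ue`` — the squared mean position of the pair in
  the observers' randomised viewing sequences (1-based), a proxy for the
  practice observers have accumulated before meeting the pair.

The changed-pixel set is decided in the source 8-bit sRGB integers (any
channel differs), which is exact and tolerance-free; colour differences are
then measured in the uniform space.  The DCT is the orthonormal type-II
transform of each full channel (no blocking), with ``sign(0) = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import dctn

from . import colour
from .exceptions import NoChangeError, RangeError, ShapeMismatchError

__all__ = [
    "ImagePair",
    "ChangeMask",
    "FeatureVector",
    "change_mask",
    "change_magnitude",
    "dct_sign_map",
    "salience_imbalance",
    "user_experience",
    "extract_features",
    "extract_features_manifest",
]


@dataclass
class ImagePair:
    """An original/changed scene pair — the unit of prediction.

    Both images are 8-bit sRGB arrays of identical shape; the changed scene
    differs from the original in the colour of one (possibly multi-part)
    region.
    """

    original: np.ndarray
    changed: np.ndarray
    pair_id: str = "pair"

    def __post_init__(self) -> None:
        self.original = np.asarray(self.original)
        self.changed = np.asarray(self.changed)
        for img in (self.original, self.changed):
            if img.ndim != 3 or img.shape[2] != 3:
                raise ShapeMismatchError(
                    f"pair {self.pair_id}: images must be H×W×3, got {img.shape}"
                )
        if self.original.shape != self.changed.shape:
            raise ShapeMismatchError(
                f"pair {self.pair_id}: image shapes differ "
                f"({self.original.shape} vs {self.changed.shape})"
            )


@dataclass
class ChangeMask:
    """Set of pixel positions where the two scenes differ."""

    mask: np.ndarray  # H×W boolean
    count: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.count = int(self.mask.sum())

    @property
    def coords(self) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(self.mask)
        return set(zip(rows.tolist(), cols.tolist()))


@dataclass
class FeatureVector:
    """(f_cm, f_si, f_ue) for one pair."""

    f_cm: float
    f_si: float
    f_ue: float
    pair_id: str = "pair"

    def as_array(self) -> np.ndarray:
        return np.array([self.f_cm, self.f_si, self.f_ue], dtype=float)


def change_mask(pair: ImagePair) -> ChangeMask:
    """Pixels where any sRGB channel differs between the two scenes."""
    return ChangeMask(np.any(pair.original != pair.changed, axis=2))


def change_magnitude(pair: ImagePair, mode: str = "lab2000hl") -> float:
    """Mean perceptual colour difference over the changed pixels.

    Independent of how many unchanged pixels surround the change, so padding
    a pair with identical border pixels leaves the value untouched.
    """
    mask = change_mask(pair)
    if mask.count == 0:
        raise NoChangeError(f"pair {pair.pair_id}: images are identical")
    p = colour.srgb_to_lab2000hl(pair.original[mask.mask], mode=mode)
    q = colour.srgb_to_lab2000hl(pair.changed[mask.mask], mode=mode)
    return float(np.mean(colour.delta_e_2000hl(p, q)))


#: Coefficients below this fraction of the largest magnitude count as zero
#: (an exact DCT of e.g. a constant channel leaves ±1e-16 roundoff in the AC
#: terms, which must not masquerade as signs).
DCT_ZERO_RTOL = 1e-12


def dct_sign_map(channel: np.ndarray) -> np.ndarray:
    """Element-wise sign of the orthonormal 2-D type-II DCT of a channel.

    Entries are in {-1, 0, +1}; ``sign(0) = 0``, where zero means any
    coefficient within ``DCT_ZERO_RTOL`` of zero relative to the largest
    coefficient magnitude.
    """
    arr = np.asarray(channel, dtype=float)
    if not np.isfinite(arr).all():
        raise RangeError("non-finite values in DCT input")
    coef = dctn(arr, type=2, norm="ortho")
    signs = np.sign(coef).astype(np.int8)
    signs[np.abs(coef) <= DCT_ZERO_RTOL * np.abs(coef).max(initial=0.0)] = 0
    return signs


def salience_imbalance(
    pair: ImagePair,
    mode: str = "lab2000hl",
    _converted: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Fraction of DCT coefficient signs that disagree between the scenes.

    Averaged over the three colour channels and normalised by the pixel
    count, hence a dimensionless value in [0, 1]; symmetric in the two
    images.
    """
    if _converted is not None:
        a, b = _converted
    else:
        a = colour.srgb_to_lab2000hl(pair.original, mode=mode)
        b = colour.srgb_to_lab2000hl(pair.changed, mode=mode)
    n = a.shape[0] * a.shape[1]
    unequal = sum(
        int(np.sum(dct_sign_map(a[:, :, k]) != dct_sign_map(b[:, :, k])))
        for k in range(3)
    )
    return unequal / (3.0 * n)


def user_experience(indices, ue_mode: str = "squared_mean") -> float:
    """Pool per-observer sequence indices (1-based) into the experience term.

    ``squared_mean`` is the square of the average index; ``mean_of_squares``
    averages the squared indices instead (alternative pooling, exposed as a
    configuration switch).
    """
    idx = np.asarray(indices, dtype=float)
    if idx.size == 0:
        raise ValueError("empty sequence-index table")
    if np.any(idx < 1):
        raise ValueError("sequence indices are 1-based and must be >= 1")
    if ue_mode == "squared_mean":
        return float(np.mean(idx) ** 2)
    if ue_mode == "mean_of_squares":
        return float(np.mean(idx**2))
    raise ValueError(f"unknown ue_mode: {ue_mode!r}")


def extract_features(
    pair: ImagePair,
    indices,
    mode: str = "lab2000hl",
    ue_mode: str = "squared_mean",
) -> FeatureVector:
    """Compute the full (f_cm, f_si, f_ue) vector for one pair.

    Each image is converted to the uniform colour space once and the
    conversion is shared between the magnitude and imbalance features.
    """
    mask = change_mask(pair)
    if mask.count == 0:
        raise NoChangeError(f"pair {pair.pair_id}: images are identical")
    a = colour.srgb_to_lab2000hl(pair.original, mode=mode)
    b = colour.srgb_to_lab2000hl(pair.changed, mode=mode)
    f_cm = float(np.mean(colour.delta_e_2000hl(a[mask.mask], b[mask.mask])))
    f_si = salience_imbalance(pair, mode=mode, _converted=(a, b))
    f_ue = user_experience(indices, ue_mode=ue_mode)
    return FeatureVector(f_cm=f_cm, f_si=f_si, f_ue=f_ue, pair_id=pair.pair_id)


# ---------------------------------------------------------------------------
# Batch interface
# ---------------------------------------------------------------------------

def _read_image(path: str | Path, alpha_flatten: bool = False) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 2:  # greyscale file: replicate to 3 channels
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        if not alpha_flatten:
            raise RangeError(f"{path}: alpha channel present (set alpha_flatten)")
        alpha = img[..., 3:4].astype(float) / 255.0
        img = np.round(img[..., :3] * alpha + 255.0 * (1 - alpha)).astype(np.uint8)
    return img[..., :3]


def extract_features_manifest(
    manifest_path: str | Path,
    index_tables: dict[str, np.ndarray] | None = None,
    mode: str = "lab2000hl",
    ue_mode: str = "squared_mean",
    alpha_flatten: bool = False,
) -> pd.DataFrame:
    """Run feature extraction over a manifest CSV.

    The manifest has columns ``pair_id, path_original, path_changed``;
    ``index_tables`` maps pair_id to that pair's observer sequence indices
    (when absent, ``f_ue`` is reported as NaN).  Failures are recorded
    per-row in an ``error`` column rather than aborting the batch.
    """
    manifest = pd.read_csv(manifest_path)
    rows = []
    for rec in manifest.itertuples(index=False):
        row = {"pair_id": rec.pair_id, "f_cm": np.nan, "f_si": np.nan,
               "f_ue": np.nan, "error": ""}
        try:
            pair = ImagePair(
                _read_image(rec.path_original, alpha_flatten),
                _read_image(rec.path_changed, alpha_flatten),
                pair_id=str(rec.pair_id),
            )
            row["f_cm"] = change_magnitude(pair, mode=mode)
            row["f_si"] = salience_imbalance(pair, mode=mode)
            if index_tables is not None and rec.pair_id in index_tables:
                row["f_ue"] = user_experience(index_tables[rec.pair_id], ue_mode)
        except Exception as exc:  # recorded, batch continues
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
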