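"""Event-to-model-input transforms for both instruments.

Holography events need almost nothing: the two images pass through unchanged
(already [0, 1]) and the 3x5 fluorescence matrix is normalized row-wise
relative to the summed intensity per excitation source.

Rapid-E+-style events go through a fixed chain: the two interference-prone
spectrum detectors (1-based indices 7 and 8, ~450/462 nm) are dropped;
the spectrum and all three scattering images are Savitzky-Golay smoothed;
each fluorescence-lifetime band is shifted so the trace starts at the first
occurrence of its global maximum (zero-padded tail); spectrum and lifetime
are rasterized into image-like 2-D arrays; and every modality is min-max
scaled into [0, 1] per event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .events import N_SPECTRUM_DETECTORS, PolenoEvent, RapidEEvent

__all__ = [
    "PreprocessConfig",
    "ModelInputs",
    "normalize_fluorescence_per_source",
    "drop_detectors",
    "align_lifetime",
    "savgol_smooth",
    "to_image_like",
    "minmax_scale",
    "preprocess_poleno",
    "preprocess_rapide",
]


@dataclass(frozen=True)
class PreprocessConfig:
    savgol_window: int = 7
    savgol_order: int = 2
    #: 1-based detector indices removed from the 32-point spectrum.
    dropped_detectors: tuple[int, ...] = (7, 8)
    image_like_shape: tuple[int, int] = (30, 30)

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValueError("savgol_window must be odd and exceed savgol_order")
        for idx in self.dropped_detectors:
            if not 1 <= idx <= N_SPECTRUM_DETECTORS:
                raise ValueError(f"detector index {idx} outside 1..{N_SPECTRUM_DETECTORS}")


@dataclass
class ModelInputs:
    """Named per-modality arrays ready for a classifier, plus degeneracy flags."""

    modalities: dict[str, np.ndarray]
    flags: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.modalities[name]


def normalize_fluorescence_per_source(
    fluorescence: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each excitation-source row by its summed intensity.

    Returns ``(normalized, zero_row_flags)``; rows summing to zero are left
    as zeros and flagged True rather than dividing by zero.
    """
    fl = np.asarray(fluorescence, dtype=float)
    if fl.min() < 0:
        raise ValueError("fluorescence intensities must be non-negative")
    sums = fl.sum(axis=-1, keepdims=True)
    zero = sums[..., 0] == 0
    out = np.divide(fl, sums, out=np.zeros_like(fl), where=sums > 0)
    return out, zero


def drop_detectors(
    spectrum: np.ndarray, indices: tuple[int, ...] = (7, 8)
) -> np.ndarray:
    """Remove 1-based detector positions from a spectrum vector."""
    sp = np.asarray(spectrum)
    if len(set(indices)) != len(indices):
        raise ValueError("detector indices must be unique")
    for idx in indices:
        if not 1 <= idx <= sp.shape[-1]:
            raise ValueError(f"detector index {idx} outside 1..{sp.shape[-1]}")
    keep = [i for i in range(sp.shape[-1]) if i + 1 not in set(indices)]
    return sp[..., keep]


def align_lifetime(trace: np.ndarray) -> np.ndarray:
    """Shift a lifetime trace so it starts at the first global maximum.

    The samples from the first occurrence of the maximum onward move to the
    front; the tail is zero-padded (wrapping would fabricate decay signal).
    Idempotent: an aligned trace starts at its maximum already.
    """
    t = np.asarray(trace, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("trace must be a non-empty 1-D array")
    start = int(np.argmax(t))
    out = np.zeros_like(t)
    out[: t.size - start] = t[start:]
    return out


def savgol_smooth(signal: np.ndarray, window: int = 7, order: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing (length preserved)."""
    sig = np.asarray(signal, dtype=float)
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and exceed the polynomial order")
    if sig.shape[-1] < window:
        raise ValueError(
            f"signal length {sig.shape[-1]} shorter than window {window}"
        )
    return savgol_filter(sig, window, order, axis=-1)


def to_image_like(
    data: np.ndarray, shape: tuple[int, int] = (30, 30)
) -> np.ndarray:
    """Rasterize a vector or matrix into a [0, 1] image of ``shape``.

    Vectors are resampled along the second axis and broadcast down the rows;
    matrices are resampled per row and their rows repeated block-wise
    (row-major) to fill the target height. The result is min-max scaled;
    constant inputs map to all-zeros.
    """
    a = np.asarray(data, dtype=float)
    if a.size == 0:
        raise ValueError("cannot rasterize an empty input")
    rows_out, cols_out = shape
    if a.ndim == 1:
        a = a[None, :]
    elif a.ndim != 2:
        raise ValueError("input must be 1-D or 2-D")
    xs = np.linspace(0.0, a.shape[1] - 1.0, cols_out)
    resampled = np.stack([np.interp(xs, np.arange(a.shape[1]), r) for r in a])
    reps = int(np.ceil(rows_out / resampled.shape[0]))
    img = np.repeat(resampled, reps, axis=0)[:rows_out]
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(shape)
    return (img - lo) / (hi - lo)


def minmax_scale(arr: np.ndarray) -> np.ndarray:
    """Per-event min-max scaling into [0, 1]; constant arrays map to zeros."""
    a = np.asarray(arr, dtype=float)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def preprocess_poleno(event: PolenoEvent) -> ModelInputs:
    """Model inputs for a holography event: both images pass through
    unchanged; fluorescence is normalized per excitation source.

    Events must be filtered first — a missing image is a usage error here.
    """
    if event.image_a is None or event.image_b is None:
        raise ValueError(
            "event has a missing holographic image; run the missing-image "
            "filter before preprocessing"
        )
    fluor, zero_rows = normalize_fluorescence_per_source(event.fluorescence)
    return ModelInputs(
        modalities={
            "image_a": np.asarray(event.image_a),
            "image_b": np.asarray(event.image_b),
            "fluorescence": fluor,
        },
        flags={"zero_fluorescence_rows": zero_rows},
    )


def preprocess_rapide(
    event: RapidEEvent, config: PreprocessConfig = PreprocessConfig()
) -> ModelInputs:
    """Full preprocessing chain for a Rapid-E+-style event.

    Order: detector removal -> Savitzky-Golay smoothing of the spectrum and
    of every scattering trace (both polarization planes and the 675 nm
    array) -> lifetime alignment per band -> image-like rasterization of
    spectrum and lifetime -> per-event [0, 1] scaling of scattering and
    infrared. Smoothing can push values slightly negative; arrays are
    clipped at zero before scaling.
    """
    w, o = config.savgol_window, config.savgol_order
    spectrum = drop_detectors(np.asarray(event.spectrum), config.dropped_detectors)
    spectrum = np.clip(savgol_smooth(spectrum, w, o), 0.0, None)
    scattering = np.clip(savgol_smooth(np.asarray(event.scattering), w, o), 0.0, None)
    infrared = np.clip(savgol_smooth(np.asarray(event.infrared), w, o), 0.0, None)
    lifetime = np.stack([align_lifetime(band) for band in np.asarray(event.lifetime)])
    return ModelInputs(
        modalities={
            "spectrum": to_image_like(spectrum, config.image_like_shape),
            "lifetime": to_image_like(lifetime, config.image_like_shape),
            "scattering": minmax_scale(scattering),
            "infrared": minmax_scale(infrared),
        },
        flags={"n_detectors": spectrum.shape[-1]},
    )
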