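"""Event data model for the two airflow cytometers.

A *Poleno-style* event holds two orthogonal holography images (either may be
missing on badly imaged particles), the particle's signed offset from the
measurement-channel centre, and a 3x5 matrix of fluorescence intensities
(three excitation sources x five emission wavebands).

A *Rapid-E+-style* event holds 447 nm scattering at 14 angles in two
polarization planes over time, a 32-point fluorescence spectrum covering
350-530 nm, fluorescence-lifetime traces in three spectral bands, and 675 nm
scattering from a 4x4 detector array (stored flattened as 16 rows) over time.

Pixel pitch of the holography images is 0.595 um/px; the default image side
is 200 px (~119 um field of view). All image values live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

from .taxonomy import SPECIES_LABELS, VocabularyError

__all__ = [
    "PIXEL_PITCH_UM",
    "DEFAULT_IMAGE_SIZE",
    "N_EXCITATION_SOURCES",
    "N_WAVEBANDS",
    "N_SPECTRUM_DETECTORS",
    "N_SCATTERING_ANGLES",
    "N_LIFETIME_BANDS",
    "N_INFRARED_PIXELS",
    "SchemaError",
    "PolenoEvent",
    "RapidEEvent",
    "EventDataset",
]

PIXEL_PITCH_UM = 0.595
DEFAULT_IMAGE_SIZE = 200
N_EXCITATION_SOURCES = 3  # 280 nm LED, 365 nm LED, 405 nm laser
N_WAVEBANDS = 5  # emission bands spanning 333-694 nm
N_SPECTRUM_DETECTORS = 32  # 350-530 nm at 12 nm resolution
N_SCATTERING_ANGLES = 14
N_LIFETIME_BANDS = 3  # 375-397, 415-450, 467-487 nm
N_INFRARED_PIXELS = 16  # flattened 4x4 detector array


class SchemaError(ValueError):
    """An event or container violating the event-schema invariants."""


def _check_label(label: str | None) -> None:
    if label is not None and label not in SPECIES_LABELS:
        raise SchemaError(f"unknown species label {label!r}")


@dataclass
class PolenoEvent:
    """One particle measured by the holography + fluorescence instrument."""

    image_a: np.ndarray | None
    image_b: np.ndarray | None
    channel_position_um: float
    fluorescence: np.ndarray  # (3, 5), non-negative
    label: str | None = None

    def validate(self) -> None:
        for name, img in (("image_a", self.image_a), ("image_b", self.image_b)):
            if img is None:
                continue
            if img.ndim != 2 or img.shape[0] != img.shape[1]:
                raise SchemaError(f"{name} must be a square 2-D array, got {img.shape}")
            if img.size and (img.min() < 0.0 or img.max() > 1.0):
                raise SchemaError(f"{name} pixel values must lie in [0, 1]")
        if self.image_a is not None and self.image_b is not None:
            if self.image_a.shape != self.image_b.shape:
                raise SchemaError(
                    f"image shapes differ: {self.image_a.shape} vs {self.image_b.shape}"
                )
        fl = np.asarray(self.fluorescence)
        if fl.shape != (N_EXCITATION_SOURCES, N_WAVEBANDS):
            raise SchemaError(
                f"fluorescence must be {N_EXCITATION_SOURCES}x{N_WAVEBANDS}, got {fl.shape}"
            )
        if fl.min() < 0:
            raise SchemaError("fluorescence intensities must be non-negative")
        _check_label(self.label)

    @property
    def fully_recorded(self) -> bool:
        """True iff both holographic images were captured."""
        return self.image_a is not None and self.image_b is not None


@dataclass
class RapidEEvent:
    """One particle measured by the scattering + fluorescence instrument."""

    scattering: np.ndarray  # (2, 14, T_s)
    spectrum: np.ndarray  # (32,)
    lifetime: np.ndarray  # (3, T_l)
    infrared: np.ndarray  # (16, T_ir)
    label: str | None = None

    def validate(self) -> None:
        sc = np.asarray(self.scattering)
        if sc.ndim != 3 or sc.shape[:2] != (2, N_SCATTERING_ANGLES):
            raise SchemaError(
                f"scattering must be 2x{N_SCATTERING_ANGLES}xT, got {sc.shape}"
            )
        sp = np.asarray(self.spectrum)
        if sp.shape != (N_SPECTRUM_DETECTORS,):
            raise SchemaError(
                f"spectrum must have exactly {N_SPECTRUM_DETECTORS} detectors, got {sp.shape}"
            )
        lt = np.asarray(self.lifetime)
        if lt.ndim != 2 or lt.shape[0] != N_LIFETIME_BANDS:
            raise SchemaError(
                f"lifetime must have exactly {N_LIFETIME_BANDS} bands, got {lt.shape}"
            )
        ir = np.asarray(self.infrared)
        if ir.ndim != 2 or ir.shape[0] != N_INFRARED_PIXELS:
            raise SchemaError(
                f"infrared must have {N_INFRARED_PIXELS} detector rows, got {ir.shape}"
            )
        for name, arr in (("scattering", sc), ("lifetime", lt), ("infrared", ir)):
            if arr.size and arr.min() < 0:
                raise SchemaError(f"{name} values must be non-negative")
        _check_label(self.label)


Instrument = Literal["poleno", "rapid_e"]


@dataclass
class EventDataset:
    """An ordered, instrument-homogeneous collection of events."""

    events: list[PolenoEvent] | list[RapidEEvent]
    instrument: Instrument
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator:
        return iter(self.events)

    def validate(self) -> None:
        if self.instrument not in ("poleno", "rapid_e"):
            raise SchemaError(f"unknown instrument {self.instrument!r}")
        want = PolenoEvent if self.instrument == "poleno" else RapidEEvent
        for i, ev in enumerate(self.events):
            if not isinstance(ev, want):
                raise SchemaError(
                    f"event {i} is {type(ev).__name__}, expected {want.__name__}"
                )
            try:
                ev.validate()
            except SchemaError as exc:
                raise SchemaError(f"event {i}: {exc}") from None

    @property
    def labels(self) -> list[str | None]:
        return [ev.label for ev in self.events]

    def subset(self, indices: Sequence[int]) -> "EventDataset":
        """New dataset containing ``events[i]`` for i in ``indices`` (shared arrays)."""
        return EventDataset(
            [self.events[i] for i in indices], self.instrument, dict(self.provenance)
        )
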