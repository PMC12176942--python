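"""Dataset-cleaning rules for both instruments.

The cleaning is deliberately simple and species-blind. Holography events are
removed when an image is missing, when the images are "empty" (grayscale
range below 0.1 on [0, 1]-normalized pixels), or when the particle sits far
outside the measurement-channel centre (beyond +/- 500 um). Rapid-E+-style
events are removed when the maximum spectral intensity falls below 4000
units. Boundary conventions: an image is empty iff its range is strictly
below the threshold; positions with |x| <= 500 um are retained; spectra with
max >= 4000 are retained. Rules apply in the fixed order missing -> empty ->
off-centre, each event counted under the first rule it violates. No
fluorescence threshold is ever applied to holography data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .events import EventDataset, PolenoEvent, RapidEEvent

__all__ = [
    "FilterConfig",
    "FilterReport",
    "is_empty_image",
    "filter_poleno",
    "filter_rapide",
]


@dataclass(frozen=True)
class FilterConfig:
    position_halfwidth_um: float = 500.0
    empty_image_threshold: float = 0.1
    spectrum_min_max: float = 4000.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class FilterReport:
    """Per-rule removal counts; ``n_output = n_input - sum(removals)``."""

    n_input: int
    removed_missing_image: int = 0
    removed_empty_image: int = 0
    removed_offcentre: int = 0
    removed_subthreshold: int = 0
    n_output: int = 0

    def check(self) -> None:
        removed = (
            self.removed_missing_image
            + self.removed_empty_image
            + self.removed_offcentre
            + self.removed_subthreshold
        )
        assert self.n_output == self.n_input - removed
        assert min(
            self.removed_missing_image,
            self.removed_empty_image,
            self.removed_offcentre,
            self.removed_subthreshold,
        ) >= 0

    def as_dict(self) -> dict:
        return asdict(self)


def is_empty_image(image: np.ndarray, threshold: float = 0.1) -> bool:
    """True iff the image's grayscale range (max - min) is strictly below
    ``threshold``."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("cannot judge emptiness of an empty array")
    return float(img.max() - img.min()) < threshold


def filter_poleno(
    dataset: EventDataset, config: FilterConfig = FilterConfig()
) -> tuple[EventDataset, FilterReport]:
    """Apply the three holography cleaning rules, preserving event order."""
    if dataset.instrument != "poleno":
        raise ValueError(
            f"filter_poleno expects a poleno dataset, got {dataset.instrument!r}"
        )
    report = FilterReport(n_input=len(dataset.events))
    survivors: list[PolenoEvent] = []
    for ev in dataset.events:
        if ev.image_a is None or ev.image_b is None:
            report.removed_missing_image += 1
        elif is_empty_image(ev.image_a, config.empty_image_threshold) or is_empty_image(
            ev.image_b, config.empty_image_threshold
        ):
            report.removed_empty_image += 1
        elif abs(ev.channel_position_um) > config.position_halfwidth_um:
            report.removed_offcentre += 1
        else:
            survivors.append(ev)
    report.n_output = len(survivors)
    report.check()
    out = EventDataset(survivors, "poleno", dict(dataset.provenance))
    return out, report


def filter_rapide(
    dataset: EventDataset, config: FilterConfig = FilterConfig()
) -> tuple[EventDataset, FilterReport]:
    """Drop events whose spectral maximum falls below the intensity floor."""
    if dataset.instrument != "rapid_e":
        raise ValueError(
            f"filter_rapide expects a rapid_e dataset, got {dataset.instrument!r}"
        )
    report = FilterReport(n_input=len(dataset.events))
    survivors: list[RapidEEvent] = []
    for ev in dataset.events:
        if float(np.max(ev.spectrum)) < config.spectrum_min_max:
            report.removed_subthreshold += 1
        else:
            survivors.append(ev)
    report.n_output = len(survivors)
    report.check()
    out = EventDataset(survivors, "rapid_e", dict(dataset.provenance))
    return out, report
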