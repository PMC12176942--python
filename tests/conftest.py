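import numpy as np
import pytest

from sporoclass.events import EventDataset, PolenoEvent, RapidEEvent
from sporoclass.synth import SimulationConfig, generate_dataset, separable_profiles


def make_poleno_event(
    position: float = 0.0,
    gray_range: float = 0.5,
    missing: str | None = None,
    label: str = "Botrytis cinerea",
    size: int = 8,
) -> PolenoEvent:
    """Minimal valid holography event with a controlled grayscale range."""
    img = np.zeros((size, size))
    img[0, 0] = gray_range
    return PolenoEvent(
        image_a=None if missing == "a" else img.copy(),
        image_b=None if missing == "b" else img.copy(),
        channel_position_um=position,
        fluorescence=np.ones((3, 5)),
        label=label,
    )


def make_rapide_event(
    spectrum_max: float = 5000.0,
    label: str = "Botrytis cinerea",
    t: int = 16,
) -> RapidEEvent:
    spectrum = np.linspace(0.0, 1.0, 32) * spectrum_max
    return RapidEEvent(
        scattering=np.ones((2, 14, t)),
        spectrum=spectrum,
        lifetime=np.ones((3, t)),
        infrared=np.ones((16, t)),
        label=label,
    )


@pytest.fixture(scope="session")
def tiny_poleno_dataset() -> EventDataset:
    """3 separable classes x 30 events at reduced image size, pre-filtered
    so every event carries both holography images."""
    from sporoclass.filtering import filter_poleno

    config = SimulationConfig(
        separable_profiles(3), n_per_class=30, seed=2024, image_size=48
    )
    filtered, _ = filter_poleno(generate_dataset(config))
    return filtered


@pytest.fixture(scope="session")
def tiny_rapide_dataset() -> EventDataset:
    config = SimulationConfig(
        separable_profiles(3, corruption=0.0),
        n_per_class=30,
        seed=2025,
        instrument="rapid_e",
    )
    return generate_dataset(config)
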