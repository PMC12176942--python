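import numpy as np
import pytest
from scipy import ndimage

from sporoclass.events import PIXEL_PITCH_UM
from sporoclass.filtering import filter_poleno
from sporoclass.synth import (
    SimulationConfig,
    SpeciesProfile,
    default_profiles,
    generate_dataset,
    render_spore_images,
    separable_profiles,
    simulate_poleno_event,
    simulate_rapide_event,
)


def _silhouette(img, thresh=0.5):
    return img < thresh


class TestRendering:
    def test_spherical_spore_views_have_equal_area(self):
        prof = SpeciesProfile("Botrytis cinerea", 10.0, 10.0)
        a, b = render_spore_images(
            prof, np.random.default_rng(0), n_spores=1, noise_sd=0, rings=False
        )
        area_a, area_b = _silhouette(a).sum(), _silhouette(b).sum()
        assert abs(area_a - area_b) / area_a < 0.02

    def test_major_axis_extent_matches_pixel_pitch(self):
        """A 25 um spore viewed in-plane spans ~25/0.595 = 42 px."""
        prof = SpeciesProfile("Botrytis cinerea", 25.0, 8.0)
        a, _ = render_spore_images(
            prof, np.random.default_rng(1), orientation=(1, 0, 0),
            n_spores=1, noise_sd=0, rings=False,
        )
        cols = np.where(_silhouette(a, thresh=0.6).any(axis=0))[0]
        extent = cols.max() - cols.min() + 1
        assert abs(extent - 25.0 / PIXEL_PITCH_UM) <= 2

    def test_chain_is_single_component_with_larger_bbox(self):
        prof = SpeciesProfile("Botrytis cinerea", 12.0, 8.0)
        kw = dict(orientation=(1, 0, 0), noise_sd=0, rings=False)
        single, _ = render_spore_images(prof, np.random.default_rng(2), n_spores=1, **kw)
        chain, _ = render_spore_images(prof, np.random.default_rng(2), n_spores=3, **kw)
        _, n_comp = ndimage.label(_silhouette(chain),
                                  structure=np.ones((3, 3), dtype=int))
        assert n_comp == 1
        width = lambda m: np.ptp(np.where(m.any(axis=0))[0]) + 1
        assert width(_silhouette(chain)) >= 2 * width(_silhouette(single))

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError):
            SpeciesProfile("Botrytis cinerea", 10.0, 0.0)

    def test_images_in_unit_range(self):
        prof = default_profiles("poleno")[0]
        a, b = render_spore_images(prof, np.random.default_rng(3), image_size=64)
        for img in (a, b):
            assert img.shape == (64, 64)
            assert 0.0 <= img.min() and img.max() <= 1.0


class TestPolenoSimulation:
    def test_clean_profile_passes_every_filter(self):
        prof = separable_profiles(2, corruption=0.0)[0]
        from sporoclass.events import EventDataset

        events = [
            simulate_poleno_event(prof, np.random.default_rng(i), image_size=32)
            for i in range(20)
        ]
        _, rep = filter_poleno(EventDataset(events, "poleno"))
        assert rep.n_output == rep.n_input == 20

    def test_same_seed_reproduces_event(self):
        prof = default_profiles("poleno")[5]
        e1 = simulate_poleno_event(prof, np.random.default_rng(7), image_size=32)
        e2 = simulate_poleno_event(prof, np.random.default_rng(7), image_size=32)
        np.testing.assert_array_equal(e1.image_a, e2.image_a)
        np.testing.assert_array_equal(e1.fluorescence, e2.fluorescence)
        assert e1.channel_position_um == e2.channel_position_um

    @pytest.mark.parametrize(
        "channel,prob",
        [("missing", 0.12), ("empty", 0.2), ("offcentre", 0.25)],
    )
    def test_corruption_rate_recovery(self, channel, prob):
        """Empirical corrupted fraction within 3 binomial SE of the target."""
        prof = SpeciesProfile(
            "Botrytis cinerea", 8.0, 6.0,
            missing_image_prob=prob if channel == "missing" else 0.0,
            empty_image_prob=prob if channel == "empty" else 0.0,
            offcentre_prob=prob if channel == "offcentre" else 0.0,
        )
        n = 5000
        rng = np.random.default_rng(101)
        count = 0
        for _ in range(n):
            ev = simulate_poleno_event(prof, rng, image_size=16)
            if channel == "missing":
                count += not ev.fully_recorded
            elif channel == "empty":
                img = ev.image_a if ev.image_a is not None else ev.image_b
                count += float(img.max() - img.min()) < 0.1
            else:
                count += abs(ev.channel_position_um) > 500.0
        se = np.sqrt(prob * (1 - prob) / n)
        assert abs(count / n - prob) <= 3 * se


class TestRapideSimulation:
    def test_zero_subthreshold_means_all_spectra_above_4000(self):
        prof = separable_profiles(2, corruption=0.0)[0]
        rng = np.random.default_rng(11)
        for _ in range(100):
            ev = simulate_rapide_event(prof, rng)
            assert ev.spectrum.max() >= 4000.0

    def test_subthreshold_rate_recovery(self):
        prof = default_profiles("rapid_e")[1]  # 37% below threshold
        p = prof.subthreshold_prob
        n = 5000
        rng = np.random.default_rng(12)
        below = sum(
            simulate_rapide_event(prof, rng).spectrum.max() < 4000.0
            for _ in range(n)
        )
        se = np.sqrt(p * (1 - p) / n)
        assert abs(below / n - p) <= 3 * se

    def test_delayed_decay_peaks_after_start(self):
        prof = default_profiles("rapid_e")[0]
        rng = np.random.default_rng(13)
        delayed_seen = 0
        for _ in range(50):
            ev = simulate_rapide_event(prof, rng)
            for band in ev.lifetime:
                idx = int(np.argmax(band))
                if idx > 0:
                    delayed_seen += 1
                # onset sample holds the global maximum of the trace
                assert band[idx] == band.max()
        assert delayed_seen > 0


class TestProfilesAndDriver:
    def test_default_profile_counts(self):
        poleno = default_profiles("poleno")
        rapide = default_profiles("rapid_e")
        assert len(poleno) == 17
        assert len(rapide) == 7
        for p in poleno + rapide:
            p.validate()

    def test_poleno_missing_rates_follow_fully_recorded_percentages(self):
        from sporoclass.synth import FULLY_RECORDED_PCT

        for p in default_profiles("poleno"):
            expected = 1.0 - FULLY_RECORDED_PCT[p.species_label] / 100.0
            assert p.missing_image_prob == pytest.approx(expected)

    def test_generate_counts_and_determinism(self):
        config = SimulationConfig(separable_profiles(3), 10, seed=5, image_size=24)
        d1 = generate_dataset(config)
        d2 = generate_dataset(config)
        assert len(d1) == 30
        for a, b in zip(d1.events, d2.events):
            np.testing.assert_array_equal(a.image_a, b.image_a)
            np.testing.assert_array_equal(a.fluorescence, b.fluorescence)
        d3 = generate_dataset(
            SimulationConfig(separable_profiles(3), 10, seed=6, image_size=24)
        )
        assert any(
            not np.array_equal(a.fluorescence, b.fluorescence)
            for a, b in zip(d1.events, d3.events)
        )
        assert d1.provenance["config_hash"] != d3.provenance["config_hash"]

    def test_nearest_centroid_baseline_separates_clean_classes(self):
        """With corruptions off and separated profiles, simple features
        (mean relative fluorescence per band, silhouette area, aspect ratio)
        give >= 95% — so the end-to-end model test has signal to find."""
        config = SimulationConfig(
            separable_profiles(3, corruption=0.0), 40, seed=77, image_size=48
        )
        ds = generate_dataset(config)

        def features(ev):
            mask = ev.image_a < 0.5
            area = mask.sum()
            cols = np.where(mask.any(axis=0))[0]
            rows = np.where(mask.any(axis=1))[0]
            aspect = (np.ptp(cols) + 1) / (np.ptp(rows) + 1) if area else 1.0
            rel = ev.fluorescence / ev.fluorescence.sum(axis=1, keepdims=True)
            return [*rel.mean(axis=0), area, aspect]

        x = np.array([features(ev) for ev in ds.events])
        y = np.array([ev.label for ev in ds.events])
        x = (x - x.mean(0)) / x.std(0)
        train = np.arange(len(y)) % 2 == 0
        centroids = {c: x[train & (y == c)].mean(0) for c in np.unique(y)}
        classes = list(centroids)
        pred = [
            classes[int(np.argmin([np.linalg.norm(v - centroids[c]) for c in classes]))]
            for v in x[~train]
        ]
        acc = np.mean(np.array(pred) == y[~train])
        assert acc >= 0.95
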