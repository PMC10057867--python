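import numpy as np
import pytest

from pollenoptics.instrument import ChannelHistogram, InstrumentConfig
from pollenoptics.simulate import ContaminationModel, SpeciesProfile, simulate_frame
from pollenoptics.speciation import (
    InversionRangeError,
    NoSignalError,
    histogram_to_density,
    invert_density,
    optical_signature,
    signature_from_frame,
    signatures_per_bin,
    speciation_index,
)

from oracles import speciation_scan_oracle


def geometric_hist(channel, counts, lo=1.0, ratio=2.0):
    counts = np.asarray(counts, dtype=float)
    edges = lo * ratio ** np.arange(len(counts) + 1)
    return ChannelHistogram(channel=channel, bin_edges=edges, counts=counts)


def lognormal_hist(channel, edges, median, sigma, total=1e5, shift=1.0):
    """Deterministic dense histogram: expected lognormal counts per bin."""
    from scipy.stats import norm

    z = (np.log(edges / shift) - np.log(median)) / sigma
    cdf = norm.cdf(z)
    return ChannelHistogram(channel=channel, bin_edges=edges, counts=total * np.diff(cdf))


class TestDensity:
    def test_counts_over_width_at_geometric_center(self):
        h = ChannelHistogram(1, np.array([10.0, 20.0]), np.array([5.0]))
        d = histogram_to_density(h)
        assert d.density[0] == pytest.approx(0.5)
        assert d.support[0] == pytest.approx(np.sqrt(200.0))

    def test_all_zero_histogram_gives_zero_density(self):
        d = histogram_to_density(geometric_hist(1, [0, 0, 0]))
        assert np.all(d.density == 0)

    def test_integral_recovers_total_counts(self, rng):
        counts = rng.integers(0, 100, 6).astype(float)
        h = geometric_hist(2, counts)
        d = histogram_to_density(h)
        assert (d.density * np.diff(h.bin_edges)).sum() == pytest.approx(counts.sum())


class TestSpeciationIndex:
    def test_identical_channels_give_unit_index(self):
        d1 = histogram_to_density(geometric_hist(1, [0, 10, 40, 25, 5, 0]))
        dc = histogram_to_density(geometric_hist(2, [0, 10, 40, 25, 5, 0]))
        f1 = 2.0**2  # lower bound of a populated bin
        assert speciation_index(d1, dc, f1) == pytest.approx(1.0, rel=1e-12)

    def test_one_bin_shift_gives_inverse_edge_ratio(self):
        # counts moved one geometric bin up = pure gain by the edge ratio
        ratio = 2.0
        d1 = histogram_to_density(geometric_hist(1, [0, 10, 40, 25, 5, 0, 0]))
        dc = histogram_to_density(geometric_hist(2, [0, 0, 10, 40, 25, 5, 0]))
        s = speciation_index(d1, dc, ratio**2)
        assert s == pytest.approx(1.0 / ratio, rel=0.01)

    def test_four_bin_toy_matches_scan_oracle(self):
        edges = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        d1 = histogram_to_density(ChannelHistogram(1, edges, np.array([0.0, 40, 10, 0])))
        dc = histogram_to_density(ChannelHistogram(2, edges, np.array([0.0, 10, 40, 0])))
        got = speciation_index(d1, dc, 2.0)
        expected = speciation_scan_oracle(d1, dc, 2.0)
        assert got == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_toys_match_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d1 = histogram_to_density(geometric_hist(1, rng.integers(1, 100, 6)))
        dc = histogram_to_density(geometric_hist(2, rng.integers(1, 100, 6)))
        f1 = float(d1.support[0] * 1.3)
        got = speciation_index(d1, dc, f1)
        expected = speciation_scan_oracle(d1, dc, f1)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_level_above_target_curve_is_range_error(self):
        d1 = histogram_to_density(geometric_hist(1, [0, 5, 1000, 5, 0]))
        dc = histogram_to_density(geometric_hist(2, [0, 5, 8, 5, 0]))
        with pytest.raises(InversionRangeError):
            speciation_index(d1, dc, 2.0**2)

    def test_empty_channel_is_no_signal_error(self):
        d1 = histogram_to_density(geometric_hist(1, [0, 10, 20, 0]))
        dc = histogram_to_density(geometric_hist(2, [0, 3, 0, 0]))
        with pytest.raises(NoSignalError):
            speciation_index(d1, dc, 2.0)

    def test_first_crossing_rule_reports_multiplicity(self):
        d1 = histogram_to_density(geometric_hist(1, [0, 10, 40, 25, 5, 0]))
        dc = histogram_to_density(geometric_hist(2, [0, 10, 40, 25, 5, 0]))
        res = invert_density(d1, dc, 8.0, warn_multiple=False)
        assert res.n_crossings >= 2  # rising and falling branch
        assert res.f_c <= 8.0 * 1.0001  # first = lowest-intensity crossing


class TestOpticalSignature:
    def test_four_identical_channels_give_all_ones(self):
        hists = [geometric_hist(c, [0, 10, 40, 25, 5, 0]) for c in (1, 2, 3, 4)]
        sig = optical_signature(hists)
        assert np.allclose(sig.as_vector(), 1.0)
        assert sig.valid

    def test_gain_shift_triple(self, cfg):
        # channels 2-4 = channel 1 shifted 1, 2, 3 geometric bins up:
        # signature ≈ (1/r, 1/r², 1/r³, r, r², r)
        r_f = (100 / 5) ** (2 / 19)
        base = np.zeros(19)
        base[6:12] = [5, 25, 60, 40, 15, 3]
        hists = [ChannelHistogram(1, cfg.intensity_edges, base)]
        for c, shift in zip((2, 3, 4), (1, 2, 3)):
            hists.append(ChannelHistogram(c, cfg.intensity_edges, np.roll(base, shift)))
        sig = optical_signature(hists)
        expected = [1 / r_f, 1 / r_f**2, 1 / r_f**3, r_f, r_f**2, r_f]
        assert np.allclose(sig.as_vector(), expected, rtol=0.01)

    def test_ratio_entries_are_exact_quotients(self, rng):
        # channels are jittered copies of channel 1 so every inversion
        # is guaranteed to succeed
        base = np.array([0.0, 8, 30, 55, 22, 6])
        hists = [geometric_hist(1, base)]
        hists += [
            geometric_hist(c, base * rng.uniform(0.8, 1.2, 6)) for c in (2, 3, 4)
        ]
        sig = optical_signature(hists)
        assert sig.valid
        assert sig.s2_over_s3 == pytest.approx(sig.s2 / sig.s3, rel=1e-12)
        assert sig.s2_over_s4 == pytest.approx(sig.s2 / sig.s4, rel=1e-12)
        assert sig.s3_over_s4 == pytest.approx(sig.s3 / sig.s4, rel=1e-12)

    def test_failing_channel_flags_signature(self):
        hists = [geometric_hist(1, [0, 5, 1000, 5, 0])]
        hists += [geometric_hist(c, [0, 5, 1000, 5, 0]) for c in (2, 3)]
        hists.append(geometric_hist(4, [0, 3, 0, 0, 0]))  # too little signal
        sig = optical_signature(hists)
        assert not sig.valid
        assert sig.failed_channels == (4,)
        assert np.isnan(sig.s4)

    def test_f1_stability_on_smooth_unimodal_curves(self, cfg):
        # adjacent F1 choices on dense smooth histograms move the
        # indices by well under 10 %
        edges = cfg.intensity_edges
        h1 = lognormal_hist(1, edges, median=600.0, sigma=0.5)
        hists = [h1] + [
            lognormal_hist(c, edges, median=600.0, sigma=0.5, shift=1 / g)
            for c, g in zip((2, 3, 4), (2.0, 3.0, 5.0))
        ]
        populated = np.nonzero(h1.counts > h1.counts.max() * 0.05)[0]
        sigs = []
        for b in populated[1:4]:
            sigs.append(optical_signature(hists, f1=float(edges[b])).as_vector())
        for a, b in zip(sigs[:-1], sigs[1:]):
            assert np.all(np.abs(a / b - 1.0) < 0.10)

    def test_per_bin_signatures_cover_populated_bins(self, cfg, clean, rng):
        profile = SpeciesProfile(name="x", median_diameter=30.0, gains=(0.5, 0.4, 0.3),
                                 mean_rate=3000)
        frame = simulate_frame(profile, clean, cfg, rng)
        sigs = signatures_per_bin(frame, cfg)
        assert len(sigs) == np.count_nonzero(frame.counts[0])

    def test_simulated_gain_covariance(self, cfg, clean):
        # binned gains aligned with the intensity grid: S_c = 1/g exactly
        r_f = (100 / 5) ** (2 / 19)
        g2, g3, g4 = r_f, r_f**3, r_f**2
        profile = SpeciesProfile(
            name="x", median_diameter=25.0, gains=(1 / g2, 1 / g3, 1 / g4), mean_rate=20000
        )
        frame = simulate_frame(profile, clean, cfg, np.random.default_rng(3), noise_sigma=0.0)
        sig = signature_from_frame(frame, cfg)
        assert np.allclose(sig.as_vector()[:3], [g2, g3, g4], rtol=0.02)
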