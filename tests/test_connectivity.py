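import numpy as np
import pytest

import hypnoconn as hc
from hypnoconn.connectivity import edge_pairs, matrix_from_edges, \
    vectorize_edges
from hypnoconn.preprocess import EpochSet
from hypnoconn.simulate import _narrowband, _phase_lagged


def _spectra(eps, fs=500.0, labels=None):
    n_ep, n_ch, n = eps.shape
    labels = labels or tuple(hc.default_montage().labels[:n_ch])
    es = EpochSet(eps, np.ones(n_ep, bool), fs, labels)
    ax = hc.frequency_axis(n, fs)
    return hc.epoch_cross_spectra(es, ax), ax


class TestCoherency:
    def test_identical_channels_have_unit_real_coherency(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 1, 1024))
        eps = np.concatenate([x, x], axis=1)
        se, _ = _spectra(eps)
        coh = hc.coherency(se)
        np.testing.assert_allclose(coh[0, 1].real, 1.0, atol=1e-9)
        np.testing.assert_allclose(coh[0, 1].imag, 0.0, atol=1e-9)

    def test_instantaneous_mixture_has_no_imaginary_part(self):
        """y = 0.5 x, the volume-conduction case: COH = 1, iCOH = 0."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 1, 1024))
        eps = np.concatenate([x, 0.5 * x], axis=1)
        se, _ = _spectra(eps)
        coh = hc.coherency(se)
        np.testing.assert_allclose(np.abs(coh[0, 1]), 1.0, atol=1e-9)
        np.testing.assert_allclose(np.abs(coh[0, 1].imag), 0.0, atol=1e-9)

    def test_quadrature_coupling_is_almost_all_imaginary(self):
        """A 90 deg-lagged narrowband copy plus independent noise: at the
        carrier, iCOH approaches COH (checked against the cross-spectrum
        computed directly per epoch)."""
        rng = np.random.default_rng(2)
        fs, n, n_ep = 500.0, 1024, 200
        carrier = 20 * fs / n  # exactly bin 20 (9.765625 Hz)
        src = _narrowband(rng, (n_ep,), n, fs, carrier, 2.0)
        lagged = _phase_lagged(src, 90.0)
        noise = rng.normal(size=(n_ep, 2, n)) * 0.5
        eps = np.stack([src, lagged], axis=1) + noise
        se, ax = _spectra(eps)
        coh = hc.coherency(se)
        b = np.argmin(np.abs(ax.freqs - carrier))
        assert np.abs(coh[0, 1, b]) > 0.5
        assert abs(np.abs(coh[0, 1, b].imag)
                   - np.abs(coh[0, 1, b])) < 0.05
        # independent oracle: coherency from the raw epoch DFTs
        w = np.hamming(n)
        X = np.fft.rfft(eps * w, axis=-1)[..., ax.bin_indices[b]]
        s01 = (X[:, 0] * X[:, 1].conj()).mean()
        s00 = (np.abs(X[:, 0]) ** 2).mean()
        s11 = (np.abs(X[:, 1]) ** 2).mean()
        expected = s01 / np.sqrt(s00 * s11)
        np.testing.assert_allclose(coh[0, 1, b], expected, atol=1e-12)

    def test_zero_autospectrum_names_channel_and_bin(self, axis_1024):
        se = hc.SpectralEstimate(
            axis_1024, np.zeros((2, 2, 92), complex), np.zeros((2, 92)),
            np.zeros((2, 92)), 1, ("Fz", "Cz"))
        with pytest.raises(ValueError, match="Fz"):
            hc.coherency(se)


class TestBandConnectivity:
    def test_band_average_is_mean_of_per_bin_measure(self):
        tensor = np.zeros((2, 2, 2), complex)
        tensor[0, 1] = [0.2j, 0.4j]
        tensor[1, 0] = [-0.2j, -0.4j]
        tensor[0, 0] = tensor[1, 1] = [1.0, 1.0]
        cm = hc.band_connectivity(tensor, np.array([0, 1]), "iCOH", "b",
                                  ("Fz", "Cz"))
        assert cm.values[0, 1] == pytest.approx(0.3)

    def test_diagonals_are_exact(self, mixed_coherency):
        coh, se, _ = mixed_coherency
        bb = hc.band_bins(hc.Config().bands, se.axis)
        for measure, diag in (("COH", 1.0), ("iCOH", 0.0)):
            cm = hc.band_connectivity(coh, bb["alpha"], measure, "alpha",
                                      se.channel_labels)
            np.testing.assert_array_equal(np.diag(cm.values),
                                          np.full(28, diag))

    def test_icoh_never_exceeds_coh(self, mixed_coherency):
        coh, se, _ = mixed_coherency
        bb = hc.band_bins(hc.Config().bands, se.axis)
        for band, bins in bb.items():
            c = hc.band_connectivity(coh, bins, "COH", band,
                                     se.channel_labels)
            i = hc.band_connectivity(coh, bins, "iCOH", band,
                                     se.channel_labels)
            assert (i.values <= c.values + 1e-12).all()

    def test_values_in_unit_interval(self, mixed_coherency):
        coh, se, _ = mixed_coherency
        bb = hc.band_bins(hc.Config().bands, se.axis)
        cm = hc.band_connectivity(coh, bb["theta"], "COH", "theta",
                                  se.channel_labels)
        assert cm.values.min() >= 0 and cm.values.max() <= 1 + 1e-9

    def test_rescaling_channels_leaves_measures_unchanged(self):
        rng = np.random.default_rng(4)
        eps = rng.normal(size=(30, 3, 1024))
        gains = np.array([1.0, 3.7, 0.2])[None, :, None]
        se_a, ax = _spectra(eps)
        se_b, _ = _spectra(eps * gains)
        bins = hc.band_bins({"alpha": (8.0, 12.9)}, ax)["alpha"]
        for measure in ("COH", "iCOH"):
            a = hc.band_connectivity(hc.coherency(se_a), bins, measure,
                                     "alpha", se_a.channel_labels)
            b = hc.band_connectivity(hc.coherency(se_b), bins, measure,
                                     "alpha", se_b.channel_labels)
            np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        eps = rng.normal(size=(20, 4, 1024))
        labels = ("Fz", "Cz", "Pz", "Oz")
        perm = np.array([2, 0, 3, 1])
        se_a, ax = _spectra(eps, labels=labels)
        se_b, _ = _spectra(eps[:, perm],
                           labels=tuple(labels[i] for i in perm))
        bins = hc.band_bins({"theta": (4.0, 7.9)}, ax)["theta"]
        a = hc.band_connectivity(hc.coherency(se_a), bins, "iCOH", "theta",
                                 labels)
        b = hc.band_connectivity(hc.coherency(se_b), bins, "iCOH", "theta",
                                 tuple(labels[i] for i in perm))
        np.testing.assert_allclose(b.values, a.values[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_unknown_measure(self, mixed_coherency):
        coh, se, _ = mixed_coherency
        with pytest.raises(ValueError, match="measure"):
            hc.band_connectivity(coh, np.array([0]), "PLI", "x",
                                 se.channel_labels)


class TestEdgeVectorization:
    def test_28_channels_give_378_edges(self):
        assert len(edge_pairs(28)) == 378

    def test_canonical_order_for_three_channels(self):
        assert edge_pairs(3) == [(0, 1), (0, 2), (1, 2)]

    def test_round_trip_identity(self):
        rng = np.random.default_rng(6)
        m = rng.uniform(size=(28, 28))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        vec, pairs = vectorize_edges(m)
        assert len(vec) == 378 and len(pairs) == 378
        back = matrix_from_edges(vec, 28)
        np.testing.assert_array_equal(back, m)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            vectorize_edges(m)


class TestHubDegree:
    def test_triangle_counts(self, montage):
        deg = hc.hub_degree([("Pz", "F3"), ("Pz", "O1"), ("F3", "O1")],
                            montage)
        assert deg["Pz"] == deg["F3"] == deg["O1"] == 2
        assert deg.sum() == 6
        assert set(deg.attrs["max_labels"]) == {"Pz", "F3", "O1"}

    def test_empty_edge_set(self, montage):
        deg = hc.hub_degree([], montage)
        assert (deg == 0).all() and deg.attrs["max_labels"] == []

    def test_star_flags_center(self, montage):
        edges = [("Pz", nb) for nb in ("Cz", "P3", "P4", "O1", "O2")]
        deg = hc.hub_degree(edges, montage)
        assert deg["Pz"] == 5
        assert deg.attrs["max_labels"] == ["Pz"]
        assert deg.drop("Pz").max() <= 1

    def test_unknown_label_is_error(self, montage):
        with pytest.raises(KeyError):
            hc.hub_degree([("Pz", "QQ7")], montage)
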