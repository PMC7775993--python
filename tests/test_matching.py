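"""Maximum inner product search: identity, invariances, oracle, noise."""

import numpy as np
import pytest

from mrfmorph.matching import match_signal, match_signals, match_volume


def brute_force_match(signal, dictionary):
    """Independent argmax oracle: explicit loop over atoms."""
    best, best_val = -1, -1.0
    for k in range(dictionary.n_atoms):
        val = abs(np.vdot(dictionary.atoms[k], signal))
        if val > best_val:
            best, best_val = k, val
    return dictionary.t1_lookup_ms[best], dictionary.t2_lookup_ms[best]


def grid_step_bound(values, truth):
    """Distance from truth to nearest grid value plus one local step."""
    idx = np.searchsorted(values, truth)
    lo = values[max(idx - 1, 0)]
    hi = values[min(idx, values.size - 1)]
    return max(truth - lo, hi - truth)


class TestMatchSignal:
    def test_atom_identity(self, reduced_dictionary, rng):
        for k in rng.integers(0, reduced_dictionary.n_atoms, 25):
            t1, t2, score, scale = match_signal(
                reduced_dictionary.atoms[k], reduced_dictionary
            )
            assert t1 == reduced_dictionary.t1_lookup_ms[k]
            assert t2 == reduced_dictionary.t2_lookup_ms[k]
            assert score == pytest.approx(1.0, abs=1e-10)

    def test_scale_and_phase_invariance(self, reduced_dictionary):
        k = 321
        atom = reduced_dictionary.atoms[k]
        for c in (5.0, 0.01, 3.0 * np.exp(1.7j)):
            t1, t2, score, scale = match_signal(c * atom, reduced_dictionary)
            assert (t1, t2) == (
                reduced_dictionary.t1_lookup_ms[k],
                reduced_dictionary.t2_lookup_ms[k],
            )
            assert score == pytest.approx(1.0, abs=1e-10)
            assert scale == pytest.approx(abs(c), rel=1e-10)

    def test_off_grid_query_lands_within_one_step(
        self, reduced_dictionary, short_schedule
    ):
        from mrfmorph.epg import epg_simulate

        t1_true, t2_true = 1275.0, 57.0
        sig = epg_simulate(short_schedule, t1_true, t2_true).samples
        t1, t2, _, _ = match_signal(sig, reduced_dictionary)
        # agrees with the independent brute-force argmax
        assert (t1, t2) == brute_force_match(sig, reduced_dictionary)
        t1_axis = np.unique(reduced_dictionary.t1_lookup_ms)
        t2_axis = np.unique(reduced_dictionary.t2_lookup_ms)
        assert abs(t1 - t1_true) <= grid_step_bound(t1_axis, t1_true)
        assert abs(t2 - t2_true) <= grid_step_bound(t2_axis, t2_true)

    def test_zero_signal_gets_sentinel(self, reduced_dictionary):
        t1, t2, score, scale = match_signal(
            np.zeros(reduced_dictionary.n_samples, complex), reduced_dictionary
        )
        assert (t1, t2, score, scale) == (0.0, 0.0, 0.0, 0.0)

    def test_length_mismatch_rejected(self, reduced_dictionary):
        with pytest.raises(ValueError):
            match_signal(np.ones(7), reduced_dictionary)


class TestMatchVolume:
    def test_single_voxel_equals_scalar_path(self, reduced_dictionary):
        atom = reduced_dictionary.atoms[500]
        vol = np.zeros((3, 3, 3, reduced_dictionary.n_samples), complex)
        mask = np.zeros((3, 3, 3), bool)
        vol[1, 1, 1] = atom
        mask[1, 1, 1] = True
        maps = match_volume(vol, reduced_dictionary, mask)
        t1, t2, score, scale = match_signal(atom, reduced_dictionary)
        assert maps.t1_map[1, 1, 1] == t1
        assert maps.t2_map[1, 1, 1] == t2
        assert maps.match_score[1, 1, 1] == pytest.approx(score)

    def test_empty_mask_gives_zero_maps(self, reduced_dictionary):
        vol = np.ones((2, 2, 2, reduced_dictionary.n_samples), complex)
        maps = match_volume(vol, reduced_dictionary, np.zeros((2, 2, 2), bool))
        assert np.all(maps.t1_map == 0) and np.all(maps.match_score == 0)

    def test_uniform_block_matches_constant(self, reduced_dictionary, short_schedule):
        from mrfmorph.epg import epg_simulate

        sig = epg_simulate(short_schedule, 820.0, 42.0).samples
        vol = np.broadcast_to(sig, (8, 8, 8, sig.size)).copy()
        maps = match_volume(vol, reduced_dictionary)
        expected = brute_force_match(sig, reduced_dictionary)
        assert np.all(maps.t1_map == expected[0])
        assert np.all(maps.t2_map == expected[1])

    def test_shape_mismatch_rejected(self, reduced_dictionary):
        vol = np.ones((2, 2, 2, reduced_dictionary.n_samples), complex)
        with pytest.raises(ValueError):
            match_volume(vol, reduced_dictionary, np.ones((3, 3, 3), bool))


class TestNoiseBehaviour:
    def test_accuracy_non_decreasing_in_snr(self, reduced_dictionary, rng):
        """On-grid match error rate shrinks as noise shrinks; vanishes at
        high SNR."""
        idx = rng.integers(0, reduced_dictionary.n_atoms, 300)
        atoms = reduced_dictionary.atoms[idx]
        rates = []
        for sigma in (0.05, 0.01, 0.001):
            noisy = atoms + sigma * (
                rng.standard_normal(atoms.shape) + 1j * rng.standard_normal(atoms.shape)
            ) / np.sqrt(atoms.shape[1])
            t1, t2, _, _ = match_signals(noisy, reduced_dictionary)
            wrong = np.mean(
                (t1 != reduced_dictionary.t1_lookup_ms[idx])
                | (t2 != reduced_dictionary.t2_lookup_ms[idx])
            )
            rates.append(wrong)
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[2] == 0.0


class TestCompressedMatching:
    def test_full_rank_equals_uncompressed(self, reduced_dictionary):
        from mrfmorph.dictionary import compress

        comp = compress(
            reduced_dictionary,
            min(reduced_dictionary.n_atoms, reduced_dictionary.n_samples),
        )
        q = reduced_dictionary.atoms[::11]
        a = match_signals(q, reduced_dictionary)
        b = match_signals(q, comp)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_rank10_agreement_on_noiseless_queries(
        self, reduced_dictionary, compressed_dictionary
    ):
        q = reduced_dictionary.atoms
        t1_full, t2_full, _, _ = match_signals(q, reduced_dictionary)
        t1_c, t2_c, _, _ = match_signals(q, compressed_dictionary)
        agree = np.mean((t1_full == t1_c) & (t2_full == t2_c))
        assert agree >= 0.99
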