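"""Phase extraction, delay rule, bin rules, and the pTE estimator."""

from collections import Counter

import numpy as np
import pytest

from ptenet.cohort import CouplingSpec, simulate_subject
from ptenet.pte import (
    PhaseMatrix,
    PteParams,
    _digitize_phases,
    choose_bin_count,
    estimate_delay,
    instantaneous_phase,
    phase_randomized_surrogate,
    phase_transfer_entropy,
    pte_adjacency,
    subject_connectome,
)

FS = 600.0


def _brute_force_pte(x, y, delay, n_bins):
    """Independent oracle: explicit histogram cells via a Counter."""
    bx = _digitize_phases(np.asarray(x), n_bins)
    by = _digitize_phases(np.asarray(y), n_bins)
    y_fut, y_now, x_now = by[delay:], by[:-delay], bx[:-delay]

    def entropy(*arrs):
        counts = Counter(zip(*arrs))
        n = len(arrs[0])
        return -sum((c / n) * np.log(c / n) for c in counts.values())

    return entropy(y_now, y_fut) + entropy(y_now, x_now) - entropy(y_now) - entropy(
        y_fut, y_now, x_now
    )


class TestInstantaneousPhase:
    def test_cosine_phase_ramp_slope(self):
        t = np.arange(6000) / FS
        ph = instantaneous_phase(np.cos(2 * np.pi * 10 * t), FS)
        # ignore Hilbert edge effects
        slope = np.diff(np.unwrap(ph.phases[0, 200:-200])).mean()
        assert slope == pytest.approx(2 * np.pi * 10 / FS, rel=0.01)

    def test_wrapping_contract(self, rng):
        ph = instantaneous_phase(rng.standard_normal((4, 2000)), FS)
        assert np.all(ph.phases > -np.pi) and np.all(ph.phases <= np.pi)

    def test_sign_flip_shifts_phase_by_pi(self, rng):
        x = rng.standard_normal((1, 3000))
        a = instantaneous_phase(x, FS).phases
        b = instantaneous_phase(-x, FS).phases
        circ_diff = np.angle(np.exp(1j * (b - a)))
        np.testing.assert_allclose(np.abs(circ_diff), np.pi, atol=1e-8)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            instantaneous_phase(np.ones((1, 500)), FS)


class TestEstimateDelay:
    def test_pure_tone_delay_is_half_period(self):
        t = np.arange(6000) / FS
        ph = instantaneous_phase(np.cos(2 * np.pi * 10 * t), FS)
        # 10 Hz at 600 Hz: 60-sample period, two phase sign changes per cycle
        assert estimate_delay(ph) == 30

    def test_uniform_phases_give_two_samples(self, rng):
        # adjacent independent phases differ in sign with probability 1/2
        ph = PhaseMatrix(phases=rng.uniform(-np.pi, np.pi, (8, 5000)), fs=FS)
        assert estimate_delay(ph) == 2

    def test_no_sign_flips_rejected(self):
        ph = PhaseMatrix(phases=np.full((1, 100), 0.5), fs=FS)
        with pytest.raises(ValueError, match="sign"):
            estimate_delay(ph)


class TestChooseBinCount:
    def test_fixed_and_scott_rules(self):
        assert choose_bin_count(4800, "fixed_49") == 49
        assert choose_bin_count(4800, "scott_style") == 56
        assert choose_bin_count(4800, "joint_adequate") == 8

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            choose_bin_count(50, "fixed_49")


class TestPhaseTransferEntropy:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_on_small_alphabet(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-np.pi, np.pi, 64)
        y = rng.uniform(-np.pi, np.pi, 64)
        params = PteParams(delay=3, n_bins=4)
        assert phase_transfer_entropy(x, y, params) == pytest.approx(
            _brute_force_pte(x, y, 3, 4), abs=1e-12
        )

    def test_pure_copy_direction(self):
        spec = CouplingSpec(n_nodes=1, edges=())
        src = simulate_subject(spec, 10_200 / FS, FS, seed=1).data[0]
        delay = 25
        x, y = src[delay:], src[:-delay]  # y is x delayed by `delay`
        ph = instantaneous_phase(np.vstack([x, y]), FS).phases
        params = PteParams(delay=delay, n_bins=8)
        fwd = phase_transfer_entropy(ph[0], ph[1], params)
        rev = phase_transfer_entropy(ph[1], ph[0], params)
        assert fwd > rev

    def test_time_axis_reversal_flips_direction(self, coupled_pair):
        data = coupled_pair.data
        for sign, arr in ((1, data), (-1, data[:, ::-1])):
            ph = instantaneous_phase(arr, FS)
            params = PteParams(delay=estimate_delay(ph), n_bins=8)
            diff = phase_transfer_entropy(
                ph.phases[0], ph.phases[1], params
            ) - phase_transfer_entropy(ph.phases[1], ph.phases[0], params)
            assert sign * diff > 0

    def test_independent_phases_inside_null_band(self, rng):
        params = PteParams(delay=2, n_bins=8)
        null = []
        for k in range(100):
            g = np.random.default_rng(1000 + k)
            a, b = g.uniform(-np.pi, np.pi, (2, 10_000))
            null.append(
                abs(
                    phase_transfer_entropy(a, b, params)
                    - phase_transfer_entropy(b, a, params)
                )
            )
        band = np.quantile(null, 0.95)
        a, b = rng.uniform(-np.pi, np.pi, (2, 10_000))
        diff = abs(
            phase_transfer_entropy(a, b, params) - phase_transfer_entropy(b, a, params)
        )
        assert diff <= band

    def test_invariant_to_bin_aligned_phase_offset(self, coupled_pair_phases):
        params = PteParams(delay=10, n_bins=8)
        p = coupled_pair_phases.phases
        shift = 3 * (2 * np.pi / 8)
        shifted = np.angle(np.exp(1j * (p + shift)))
        shifted[shifted == -np.pi] = np.pi
        a = phase_transfer_entropy(p[0], p[1], params)
        b = phase_transfer_entropy(shifted[0], shifted[1], params)
        assert a == pytest.approx(b, abs=1e-10)

    def test_excessive_delay_rejected(self, rng):
        x = rng.uniform(-np.pi, np.pi, 100)
        with pytest.raises(ValueError, match="delay"):
            phase_transfer_entropy(x, x, PteParams(delay=99, n_bins=4))


@pytest.fixture(scope="module")
def chain_phases():
    spec = CouplingSpec(n_nodes=3, edges=((0, 1, 0.7, 15), (1, 2, 0.7, 20)))
    ts = simulate_subject(spec, 8.0, FS, seed=3)
    return instantaneous_phase(ts.data, FS)


class TestPteAdjacency:
    def test_chain_directions_recovered(self, chain_phases):
        params = PteParams(delay=estimate_delay(chain_phases), n_bins=8)
        w = pte_adjacency(chain_phases, params).weights
        assert w[0, 1] > w[1, 0]
        assert w[1, 2] > w[2, 1]

    def test_diagonal_zero(self, chain_phases):
        params = PteParams(delay=5, n_bins=6)
        w = pte_adjacency(chain_phases, params).weights
        np.testing.assert_array_equal(np.diag(w), 0)

    def test_node_relabeling_equivariance(self, chain_phases):
        params = PteParams(delay=5, n_bins=6)
        w = pte_adjacency(chain_phases, params).weights
        perm = [2, 0, 1]
        permuted = PhaseMatrix(phases=chain_phases.phases[perm], fs=FS)
        w_perm = pte_adjacency(permuted, params).weights
        np.testing.assert_allclose(w_perm, w[np.ix_(perm, perm)], atol=1e-12)


class TestSubjectConnectome:
    def test_identical_epochs_reduce_to_zscore(self, rng):
        m = rng.standard_normal((6, 6))
        np.fill_diagonal(m, 0)
        from ptenet.pte import Connectome

        epochs = [Connectome(weights=m.copy(), weight_kind="raw_pte") for _ in range(4)]
        z = subject_connectome(epochs)
        off = ~np.eye(6, dtype=bool)
        expected = (m[off] - m[off].mean()) / m[off].std()
        np.testing.assert_allclose(z.weights[off], expected, atol=1e-12)

    def test_zscore_contract(self, rng):
        from ptenet.pte import Connectome

        epochs = [
            Connectome(weights=rng.standard_normal((8, 8)) * (~np.eye(8, dtype=bool)),
                       weight_kind="raw_pte")
            for _ in range(5)
        ]
        z = subject_connectome(epochs)
        off = ~np.eye(8, dtype=bool)
        assert z.weights[off].mean() == pytest.approx(0, abs=1e-10)
        assert z.weights[off].std() == pytest.approx(1, abs=1e-10)
        np.testing.assert_array_equal(np.diag(z.weights), 0)

    def test_epoch_averaging_reduces_variance(self, rng):
        from ptenet.pte import Connectome

        single = [rng.standard_normal((10, 10)) * (~np.eye(10, dtype=bool)) for _ in range(8)]
        mean = np.mean(single, axis=0)
        off = ~np.eye(10, dtype=bool)
        assert mean[off].var() < np.mean([m[off].var() for m in single])


class TestSurrogates:
    def test_amplitude_spectrum_preserved(self, rng):
        x = rng.standard_normal((3, 1024))
        s = phase_randomized_surrogate(x, seed=1)
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(s, axis=1)), np.abs(np.fft.rfft(x, axis=1)), atol=1e-8
        )

    def test_same_seed_identical(self, rng):
        x = rng.standard_normal((2, 500))
        np.testing.assert_array_equal(
            phase_randomized_surrogate(x, seed=9), phase_randomized_surrogate(x, seed=9)
        )

    def test_coupling_asymmetry_collapses(self, coupled_pair):
        params_bins = 8
        ph = instantaneous_phase(coupled_pair.data, FS)
        params = PteParams(delay=estimate_delay(ph), n_bins=params_bins)
        orig = phase_transfer_entropy(ph.phases[0], ph.phases[1], params) - (
            phase_transfer_entropy(ph.phases[1], ph.phases[0], params)
        )
        diffs = []
        for k in range(10):
            surr = phase_randomized_surrogate(coupled_pair.data, seed=k)
            phs = instantaneous_phase(surr, FS)
            ps = PteParams(delay=estimate_delay(phs), n_bins=params_bins)
            diffs.append(
                phase_transfer_entropy(phs.phases[0], phs.phases[1], ps)
                - phase_transfer_entropy(phs.phases[1], phs.phases[0], ps)
            )
        assert orig > 0.1
        assert np.max(np.abs(diffs)) < orig / 3
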