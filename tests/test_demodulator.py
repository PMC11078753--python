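"""Matched-filter banks, clock/slot recovery, thresholding, event detection."""

import numpy as np
import pytest

from asbit.demodulator import (DEFAULT_K_CONTINUOUS, FilterBank,
                               StreamCorrelator, build_filter_bank,
                               correlate_and_combine, detect_events,
                               detect_events_at_slots, demodulate_node,
                               recover_clock, recover_slot, score_at_slots,
                               synthesize_matched_filter)
from asbit.goldcode import assign_identifier
from asbit.metrics import compute_error_rate
from asbit.network_sim import EventTrain, build_population, superpose
from asbit.signal_model import (ClockModel, ReceiverChain, apply_noise,
                                sigma_for_snr, synthesize_packet)


def clean_packet_stream(code, rx, offset=4000, total=20000, f_clk=30e6,
                        phi=0.0, a=1.0, offset_ppm=0.0):
    clock = ClockModel(f_nominal=f_clk, mode="oscillator", drift_ppm=1000,
                       offset_ppm=offset_ppm) if offset_ppm else \
        ClockModel(f_nominal=f_clk, mode="divider", drift_ppm=0)
    pkt = synthesize_packet(code, clock, rx, a_prime=a, phi_prime=phi)
    y = np.zeros(total, dtype=complex)
    y[offset:offset + len(pkt)] += pkt.samples
    return y, len(pkt)


class TestMatchedFilter:
    def test_identity_with_own_packet(self, ident511, rx30):
        """A clean packet correlated with its own filter peaks at the start
        sample, at the 3-phase product value 1.5 * (E/2)^2."""
        y, L = clean_packet_stream(ident511, rx30, phi=1.1)
        bank = build_filter_bank(ident511, rx30, clock_mode="divider")
        trace = correlate_and_combine(y, bank)
        assert int(np.argmax(trace)) == 4000
        E = 1533.0
        assert trace[4000] == pytest.approx(1.5 * (E / 2) ** 2, rel=1e-3)

    def test_peak_invariant_to_carrier_phase(self, ident511, rx30):
        bank = build_filter_bank(ident511, rx30, clock_mode="divider")
        peaks = []
        for phi in np.linspace(0, 2 * np.pi, 7):
            y, _ = clean_packet_stream(ident511, rx30, phi=phi)
            peaks.append(correlate_and_combine(y, bank).max())
        assert np.ptp(peaks) / np.mean(peaks) < 1e-6

    def test_phase_pi_negates_branches(self, ident511, rx30):
        i0, q0 = synthesize_matched_filter(ident511, 30e6, 0.3, rx30)
        i1, q1 = synthesize_matched_filter(ident511, 30e6, 0.3 + np.pi, rx30)
        np.testing.assert_allclose(i1, -i0, atol=1e-9)
        np.testing.assert_allclose(q1, -q0, atol=1e-9)

    def test_clock_mismatch_reduces_peak(self, ident511, rx30):
        """A +1,000 ppm packet against the nominal-clock filter loses
        correlation to accumulated chip slip."""
        y, _ = clean_packet_stream(ident511, rx30, offset_ppm=1000.0)
        bank = build_filter_bank(ident511, rx30, clock_mode="divider")
        mismatched = correlate_and_combine(y, bank).max()
        y0, _ = clean_packet_stream(ident511, rx30)
        matched = correlate_and_combine(y0, bank).max()
        assert mismatched < 0.75 * matched

    def test_fast_equals_naive(self, ident511, rx30, rng):
        y = (rng.standard_normal(9000) + 1j * rng.standard_normal(9000))
        y[2000:2000 + 1533] += synthesize_packet(
            ident511, ClockModel(mode="divider", drift_ppm=0), rx30,
            phi_prime=0.77).samples
        bank = build_filter_bank(ident511, rx30, clock_mode="oscillator",
                                 n_clock_points=3)
        fast = correlate_and_combine(y, bank, method="fast")
        naive = correlate_and_combine(y, bank, method="naive")
        np.testing.assert_allclose(fast, naive, rtol=1e-9, atol=1e-6)

    def test_stream_correlator_matches_direct(self, ident511, rx30, rng):
        y = (rng.standard_normal(50000) + 1j * rng.standard_normal(50000)
             ).astype(np.complex64)
        bank = build_filter_bank(ident511, rx30, clock_mode="divider")
        direct = correlate_and_combine(y, bank)
        cached = correlate_and_combine(StreamCorrelator(y, bank.filter_length), bank)
        np.testing.assert_allclose(cached, direct, rtol=2e-3, atol=2e-1)


class TestBank:
    def test_standard_drift_bank_is_93_filters(self, ident511, rx30):
        bank = build_filter_bank(ident511, rx30, clock_mode="oscillator",
                                 drift_ppm=1005, n_clock_points=31, n_phases=3)
        assert bank.n_filters == 93
        span = bank.clock_points.max() - bank.clock_points.min()
        assert span == pytest.approx(2 * 30e6 * 1005e-6)

    def test_divider_bank_is_three_filters(self, ident511, rx30):
        bank = build_filter_bank(ident511, rx30, clock_mode="divider")
        assert bank.n_filters == 3

    def test_single_filter_bank(self, ident511, rx30):
        bank = build_filter_bank(ident511, rx30, clock_mode="oscillator",
                                 n_clock_points=1, n_phases=1)
        assert bank.n_filters == 1

    def test_even_point_count_rejected(self, ident511, rx30):
        with pytest.raises(ValueError, match="odd"):
            build_filter_bank(ident511, rx30, n_clock_points=30)


class TestClockRecovery:
    def test_recovers_offset_clock(self, ident511, rx30):
        y, _ = clean_packet_stream(ident511, rx30, f_clk=29.4e6, total=12000)
        est = recover_clock(y, ident511, rx30, grid=(29e6, 30e6, 0.1e6))
        assert abs(est - 29.4e6) <= 0.1e6

    def test_pure_noise_reports_absent(self, ident511, rx30, rng):
        y = (rng.standard_normal(12000) + 1j * rng.standard_normal(12000)) / np.sqrt(2)
        assert recover_clock(y, ident511, rx30, grid=(29.5e6, 30.5e6, 0.25e6)) is None

    def test_empty_clip_rejected(self, ident511, rx30):
        with pytest.raises(ValueError, match="empty"):
            recover_clock(np.empty(0, dtype=complex), ident511, rx30)


class TestDetection:
    def test_all_zero_trace_no_detections(self):
        det = detect_events(np.zeros(90000), 30e6, 51.1e-6)
        assert len(det) == 0

    def test_single_clean_packet_one_detection(self, ident511, rx30):
        y, L = clean_packet_stream(ident511, rx30, offset=33000, total=120000)
        y = apply_noise(y, sigma_for_snr(1.0, 1.7), 3)
        bank = build_filter_bank(ident511, rx30, clock_mode="divider")
        trace = correlate_and_combine(y, bank)
        det = detect_events(trace, 30e6, L / 30e6)
        assert list(det.bins) == [1]  # 33000 samples = 1.1 ms -> bin 1

    def test_threshold_monotone_in_k(self, ident511, rx30, rng):
        y, L = clean_packet_stream(ident511, rx30, offset=10000, total=90000)
        y = apply_noise(y, 0.5, 5)
        bank = build_filter_bank(ident511, rx30, clock_mode="divider")
        trace = correlate_and_combine(y, bank)
        n_low = len(detect_events(trace, 30e6, L / 30e6, k=5.0))
        n_high = len(detect_events(trace, 30e6, L / 30e6, k=1e9))
        assert n_high == 0 and n_low >= 1

    def test_collision_robustness(self, family_m7, rx30):
        """Two overlapping packets with distinct Gold codes, equal amplitude,
        zero noise: both recovered for at least 95 of 100 random overlaps."""
        rx = rx30
        rng = np.random.default_rng(99)
        code_a = family_m7.identifier(3)
        code_b = family_m7.identifier(60)
        clock = ClockModel(mode="divider", drift_ppm=0)
        pkt_a = synthesize_packet(code_a, clock, rx, phi_prime=0.4).samples
        pkt_b = synthesize_packet(code_b, clock, rx, phi_prime=2.1).samples
        L = len(pkt_a)
        banks = {0: build_filter_bank(code_a, rx, clock_mode="divider"),
                 1: build_filter_bank(code_b, rx, clock_mode="divider")}
        ok = 0
        for _ in range(100):
            off = int(rng.integers(0, L))
            y = np.zeros(3 * L + off, dtype=complex)
            y[L:L + L] += pkt_a
            y[L + off:L + off + L] += pkt_b
            ta = correlate_and_combine(y, banks[0])
            tb = correlate_and_combine(y, banks[1])
            if int(np.argmax(ta)) == L and int(np.argmax(tb)) == L + off:
                ok += 1
        assert ok >= 95

    def test_dedup_keeps_one_peak_per_packet(self, ident511, rx30):
        y, L = clean_packet_stream(ident511, rx30, offset=40000, total=150000)
        bank = build_filter_bank(ident511, rx30, clock_mode="divider")
        trace = correlate_and_combine(y, bank)
        det = detect_events(trace, 30e6, L / 30e6, k=0.001)
        assert len(det) >= 1
        assert len(np.unique(det.bins)) == len(det.bins)


class TestSlottedMode:
    def make_divider_net(self, rng, n_nodes=8, rate=50.0, epoch=0.3, snr=5.0):
        pop = build_population(n_nodes, 0, snr_policy=("fixed", snr),
                               clock_policy=("divider",), rng=rng)
        from asbit.network_sim import generate_poisson_events
        events = generate_poisson_events(rate, epoch, [n.node_id for n in pop], rng)
        rx = ReceiverChain(noise_sigma=sigma_for_snr(1.0, snr))
        agg = superpose(pop, events, rx, duration=epoch + 0.002,
                        rng=np.random.default_rng(0))
        return pop, events, agg, rx

    def test_slot_recovery_finds_tau(self, rng):
        pop, events, agg, rx = self.make_divider_net(rng)
        node = pop[0]
        bank = build_filter_bank(node.code, rx, clock_mode="divider")
        slot = recover_slot(agg.samples, bank)
        assert slot == int(round(node.tau * rx.sample_rate))

    def test_divider_only_scores_predicted_slots(self, rng):
        pop, events, agg, rx = self.make_divider_net(rng)
        node = pop[0]
        bank = build_filter_bank(node.code, rx, clock_mode="divider")
        slot = int(round(node.tau * rx.sample_rate))
        scores = score_at_slots(agg.samples, bank, slot)
        assert len(scores) <= int(0.302 / 1e-3)

    def test_divider_false_count_not_worse_than_continuous(self, rng):
        """On an identical stream, slot-gated detection yields no more false
        positives than continuous-trace detection."""
        pop, events, agg, rx = self.make_divider_net(rng, snr=3.0)
        truth = {tr.node_id: tr for tr in events}
        false_d = false_c = 0
        for node in pop[:4]:
            slot = int(round(node.tau * rx.sample_rate))
            det_d = demodulate_node(agg.samples, node.code, rx, clock_mode="divider",
                                    slot_offset=slot, node_id=node.node_id)
            det_c = demodulate_node(agg.samples, node.code, rx,
                                    clock_mode="oscillator", n_clock_points=1,
                                    node_id=node.node_id)
            tb = set(truth[node.node_id].bins().tolist())
            false_d += len(set(det_d.bins.tolist()) - tb)
            false_c += len(set(det_c.bins.tolist()) - tb)
        assert false_d <= false_c

    def test_lossless_single_node_both_modes(self, ident511, rx30, rng):
        """Zero noise, zero drift, one node: every event recovered, none
        invented, in continuous and slotted demodulation alike."""
        for mode in ("divider", "oscillator"):
            pop = build_population(1, 0, snr_policy=("fixed", 30.0),
                                   clock_policy=(mode, 0.0) if mode == "oscillator"
                                   else ("divider",), rng=np.random.default_rng(4))
            from asbit.network_sim import generate_poisson_events
            events = generate_poisson_events(50.0, 0.2, [0], np.random.default_rng(5))
            rx = ReceiverChain(noise_sigma=0.0)
            agg = superpose(pop, events, rx, duration=0.202)
            det = demodulate_node(agg.samples, pop[0].code, rx, clock_mode=mode,
                                  n_clock_points=1,
                                  slot_offset=int(round(pop[0].tau * 30e6)),
                                  node_id=0)
            report = compute_error_rate(events, {0: det}, targets=[0], n_bins=200)
            assert report.mean_eer == 0.0

    def test_bank_width_helps_under_drift(self, ident511, rx30):
        """With a drifting clock, the 31-point bank recovers more of the
        matched peak than a single nominal-clock filter."""
        y, _ = clean_packet_stream(ident511, rx30, offset_ppm=700.0, total=12000)
        wide = build_filter_bank(ident511, rx30, clock_mode="oscillator",
                                 n_clock_points=31)
        narrow = build_filter_bank(ident511, rx30, clock_mode="oscillator",
                                   n_clock_points=1)
        assert correlate_and_combine(y, wide).max() > \
            1.5 * correlate_and_combine(y, narrow).max()
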