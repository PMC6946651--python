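import numpy as np
import pytest

from camelscan import (
    QuartetConfig,
    block_jackknife_z,
    f3_test,
    f4_test,
    f_d_statistic,
    introgression_scan,
    make_camel_scenario,
    mask_introgressed,
    patterson_d,
    simulate,
    total_migration_rate,
)
from camelscan.simpop import _drift

from conftest import CAMEL_QUARTET
from helpers import freq_table, make_matrix, make_popmap
from naive_stats import naive_d, naive_f3, naive_f4, naive_fd

Q = QuartetConfig("Y", "Z", "W", "X")


def random_quartet(rng, n=50):
    return freq_table({k: rng.uniform(0, 1, n) for k in "YZWX"})


class TestPattersonD:
    def test_equal_ingroups_give_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 30)
        freqs = freq_table({"Y": p, "Z": p.copy(), "W": rng.uniform(0, 1, 30), "X": rng.uniform(0, 1, 30)})
        assert patterson_d(freqs, Q) == 0.0

    def test_pure_shared_derived_pattern(self):
        freqs = freq_table({"Y": [0.0], "Z": [1.0], "W": [0.0], "X": [1.0]})
        assert patterson_d(freqs, Q) == 1.0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            freqs = random_quartet(rng)
            got = patterson_d(freqs, Q)
            exp = naive_d(*(freqs.column(k) for k in "YZWX"))
            assert got == pytest.approx(exp, abs=1e-12)

    def test_empty_site_set_is_undefined(self):
        freqs = freq_table({k: np.array([np.nan]) for k in "YZWX"})
        assert np.isnan(patterson_d(freqs, Q))


class TestFd:
    def test_complete_replacement_limit_is_one(self):
        rng = np.random.default_rng(2)
        px = rng.uniform(0.6, 1.0, 40)
        freqs = freq_table({
            "Y": rng.uniform(0.0, 0.2, 40), "Z": px.copy(),
            "W": rng.uniform(0.0, 0.2, 40), "X": px,
        })
        assert patterson_d(freqs, Q) > 0
        assert f_d_statistic(freqs, Q) == pytest.approx(1.0)

    def test_zero_numerator_gives_zero(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 30)
        freqs = freq_table({"Y": p, "Z": p.copy(), "W": rng.uniform(0, 1, 30), "X": rng.uniform(0, 1, 30)})
        assert f_d_statistic(freqs, Q) == 0.0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            freqs = random_quartet(rng)
            got = f_d_statistic(freqs, Q)
            exp = naive_fd(*(freqs.column(k) for k in "YZWX"))
            assert got == pytest.approx(exp, abs=1e-12)

    def test_recovers_mixture_proportion(self):
        # p_Z = (1-f) q + f p_X with f = 0.3 under tree-structured drift
        rng = np.random.default_rng(5)
        n = 20_000
        anc = rng.uniform(0.05, 0.95, n)
        px = _drift(rng, anc, 0.35)
        b = _drift(rng, anc, 0.08)
        pw = _drift(rng, b, 0.08)
        c = _drift(rng, b, 0.04)
        py = _drift(rng, c, 0.04)
        q = _drift(rng, c, 0.04)
        pz = 0.7 * q + 0.3 * px
        freqs = freq_table({"Y": py, "Z": pz, "W": pw, "X": px})
        assert f_d_statistic(freqs, Q) == pytest.approx(0.3, abs=0.05)

    def test_polarization_invariance(self):
        rng = np.random.default_rng(6)
        freqs = random_quartet(rng, 80)
        flip = rng.random(80) < 0.5
        flipped = freq_table({k: np.where(flip, 1 - freqs.column(k), freqs.column(k)) for k in "YZWX"})
        assert patterson_d(flipped, Q) == pytest.approx(patterson_d(freqs, Q), abs=1e-12)
        assert f_d_statistic(flipped, Q) == pytest.approx(f_d_statistic(freqs, Q), abs=1e-12)


class TestBlockJackknife:
    def test_three_block_toy(self):
        values = np.array([0.0, 1.0, 2.0])
        blocks = np.array([0, 1, 2])
        z, pseudo = block_jackknife_z(lambda keep: values[keep].mean(), blocks)
        assert pseudo.tolist() == [1.5, 1.0, 0.5]
        assert z == pytest.approx(1.0 / np.sqrt(0.25 * 3))

    def test_delete_one_convention_differs(self):
        values = np.array([0.0, 1.0, 2.0])
        blocks = np.array([0, 1, 2])
        z, _ = block_jackknife_z(lambda k: values[k].mean(), blocks, convention="delete-one")
        assert z == pytest.approx(1.0 / np.sqrt(0.25 * 4 / 3))

    def test_identical_blocks_give_infinite_flag(self):
        values = np.array([1.0, 1.0, 1.0, 1.0])
        blocks = np.array([0, 0, 1, 1])
        z, _ = block_jackknife_z(lambda k: values[k].mean(), blocks)
        assert np.isposinf(z)

    def test_all_zero_statistic_resolves_to_zero(self):
        blocks = np.array([0, 1, 2])
        z, _ = block_jackknife_z(lambda k: 0.0, blocks)
        assert z == 0.0

    def test_fewer_than_two_blocks_raises(self):
        with pytest.raises(ValueError, match="2 blocks"):
            block_jackknife_z(lambda k: 0.0, np.array([0, 0]))


class TestF3F4:
    def test_f3_midpoint_mixture(self):
        freqs = freq_table({"Z": np.full(600, 0.5), "X": np.full(600, 0.2), "Y": np.full(600, 0.8)})
        res = f3_test(freqs, "Z", "X", "Y", block_size=100)
        assert res.statistic == pytest.approx(-0.09)

    def test_f3_identical_source_is_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 400)
        freqs = freq_table({"Z": p, "X": p.copy(), "Y": rng.uniform(0, 1, 400)})
        assert f3_test(freqs, "Z", "X", "Y", block_size=100).statistic == 0.0

    def test_f3_matches_naive_loop(self):
        rng = np.random.default_rng(8)
        freqs = freq_table({k: rng.uniform(0, 1, 300) for k in "ZXY"})
        res = f3_test(freqs, "Z", "X", "Y", block_size=50)
        exp = naive_f3(freqs.column("Z"), freqs.column("X"), freqs.column("Y"))
        assert res.statistic == pytest.approx(exp, abs=1e-12)

    def test_f4_outgroup_equality_gives_zero(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 300)
        freqs = freq_table({"Y": rng.uniform(0, 1, 300), "Z": rng.uniform(0, 1, 300), "W": p, "X": p.copy()})
        assert f4_test(freqs, "Y", "Z", "W", "X", block_size=50).statistic == 0.0

    def test_f4_single_site_pattern(self):
        freqs = freq_table({k: np.full(300, v) for k, v in zip("YZWX", (1.0, 0.0, 1.0, 0.0))})
        assert f4_test(freqs, "Y", "Z", "W", "X", block_size=50).statistic == 1.0

    def test_f4_antisymmetric_in_ingroup_order(self):
        rng = np.random.default_rng(10)
        freqs = freq_table({k: rng.uniform(0, 1, 400) for k in "YZWX"})
        a = f4_test(freqs, "Y", "Z", "W", "X", block_size=80)
        b = f4_test(freqs, "Z", "Y", "W", "X", block_size=80)
        assert a.statistic == -b.statistic
        assert naive_f4(*(freqs.column(k) for k in "YZWX")) == pytest.approx(a.statistic, abs=1e-12)

    def test_f4_detects_simulated_pulse_into_z(self, pulse_sim):
        from camelscan import allele_frequencies

        _, matrix, popmap, _, _ = pulse_sim
        freqs = allele_frequencies(
            matrix, popmap, ["east_asian", "central_asian", "wild_bactrian", "dromedary"]
        )
        res = f4_test(freqs, "east_asian", "central_asian", "wild_bactrian", "dromedary")
        assert res.z_score > 3


class TestScanAndMask:
    def test_d_sign_convention_follows_pulse_direction(self, pulse_sim):
        from camelscan import allele_frequencies

        _, matrix, popmap, _, _ = pulse_sim
        labels = ["east_asian", "central_asian", "wild_bactrian", "dromedary"]
        freqs = allele_frequencies(matrix, popmap, labels)
        d = patterson_d(freqs, CAMEL_QUARTET)
        assert d > 0  # donor pulses went into Z (central_asian)
        swapped = QuartetConfig("central_asian", "east_asian", "wild_bactrian", "dromedary")
        assert patterson_d(freqs, swapped) < 0

    def test_fd_bounded_on_truth_windows(self, pulse_scan, pulse_sim):
        truth = {(c, s, e) for c, s, e in pulse_sim[3].introgressed_windows}
        hit = pulse_scan.apply(lambda r: (r.chrom, r.start, r.end) in truth, axis=1)
        assert (pulse_scan[hit].f_d.abs() <= 1.0 + 1e-9).all()

    def test_fd_monotone_in_pulse_proportion(self):
        means = []
        for f in (0.05, 0.2, 0.5):
            cfg = make_camel_scenario(
                chromosome_length=2_000_000, seed=13,
                pulse_proportions={"IRAN": f, "KAZA": f, "RUS": f},
            )
            matrix, popmap, truth, _ = simulate(cfg)
            scan = introgression_scan(matrix, popmap, CAMEL_QUARTET)
            t = {(c, s, e) for c, s, e in truth.introgressed_windows}
            hit = scan.apply(lambda r: (r.chrom, r.start, r.end) in t, axis=1)
            means.append(scan[hit].f_d.mean())
        assert means[0] < means[1] < means[2]

    def test_monomorphic_window_is_undefined(self):
        geno = np.zeros((40, 8), dtype=np.int8)
        matrix = make_matrix(geno, pos=np.arange(1, 41) * 100)
        popmap = make_popmap({"Y": 2, "Z": 2, "W": 2, "X": 2})
        scan = introgression_scan(matrix, popmap, Q, window_size=4000, block_size=1000)
        assert (scan.classification == "undefined").all()

    def test_window_smaller_than_block_raises(self):
        matrix = make_matrix(np.zeros((4, 8), dtype=np.int8))
        popmap = make_popmap({"Y": 2, "Z": 2, "W": 2, "X": 2})
        with pytest.raises(ValueError):
            introgression_scan(matrix, popmap, Q, window_size=1000, block_size=10_000)

    def test_mask_removes_windows_beyond_threshold_both_directions(self):
        import pandas as pd

        scan = pd.DataFrame(
            {
                "chrom": ["chr1"] * 5,
                "start": np.arange(5) * 100,
                "end": (np.arange(5) + 1) * 100,
                "Z": [3.0, -3.0, 0.0, 1.0, np.nan],
                "classification": ["into_Z", "into_Y", "none", "none", "undefined"],
            }
        )
        matrix = make_matrix(np.zeros((5, 2), dtype=np.int8), pos=[50, 150, 250, 350, 450])
        masked, removed = mask_introgressed(matrix, scan)
        assert len(removed) == 2 and masked.n_sites == 3
        assert masked.pos.tolist() == [250, 350, 450]

    def test_mask_without_hits_is_identity(self):
        import pandas as pd

        scan = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100], "Z": [0.5], "classification": ["none"]}
        )
        matrix = make_matrix(np.zeros((2, 2), dtype=np.int8), pos=[10, 20])
        masked, removed = mask_introgressed(matrix, scan)
        assert removed == [] and masked == matrix


class TestMigrationRate:
    def test_products(self):
        assert total_migration_rate(0.0, 2.7) == 0.0
        assert total_migration_rate(0.001, 2.7) == pytest.approx(0.0027)
        rng = np.random.default_rng(11)
        for _ in range(20):
            m, tau = rng.uniform(0, 5, 2)
            assert total_migration_rate(m, tau) == pytest.approx(m * tau)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            total_migration_rate(-0.1, 1.0)
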