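import dataclasses

import numpy as np
import pytest

from bacscreen.decoder import DecodeStatus
from bacscreen.pooling_design import pool_volume
from bacscreen.reaction_calculator import budget_paper_mode
from bacscreen.simulator import (
    SPIKED_DEFAULT_NEGATIVES,
    SimConfig,
    build_spiked_superpool,
    evaluate,
    replicate_screens,
    run_screen,
    simulate_library,
)


def single_clone_marker_positions(library, n, distinct_plates=True):
    """Positions covered by exactly one clone (on distinct plates if asked)."""
    starts = np.array([c.start for c in library.clones])
    lengths = np.array([c.length for c in library.clones])
    chosen, plates = [], set()
    for clone in library.clones:
        pos = clone.start + clone.length // 2
        if np.sum((starts <= pos) & (pos < starts + lengths)) != 1:
            continue
        if distinct_plates and clone.address.plate in plates:
            continue
        chosen.append(pos)
        plates.add(clone.address.plate)
        if len(chosen) == n:
            return tuple(chosen)
    raise AssertionError("fixture library has too few single-clone positions")


# 24-plate, 3x/100 kb library: the genome size that fills exactly 24 plates
GENOME_24_PLATES = 24 * 384 * 100_000 // 3


@pytest.fixture(scope="module")
def noiseless_config():
    base = SimConfig(genome_size=GENOME_24_PLATES, coverage=3.0,
                     insert_mean=100_000, n_markers=0, seed=11)
    library = simulate_library(base)
    positions = single_clone_marker_positions(library, 3)
    return dataclasses.replace(base, marker_positions=positions)


class TestLibraryGeneration:
    def test_clone_count_from_coverage(self):
        cfg = SimConfig(genome_size=16_000_000_000, coverage=3.0,
                        insert_mean=100_000, n_markers=0, n_plates=1250)
        lib = simulate_library(cfg)
        assert len(lib.clones) == 480_000
        assert lib.layout.n_plates == 1250

    def test_no_markers_empty_truth(self):
        cfg = SimConfig(genome_size=10**7, coverage=1.0, n_markers=0, seed=1)
        lib = simulate_library(cfg)
        assert lib.markers == {}
        assert lib.truth == {}

    def test_determinism_same_seed_identical_library(self):
        cfg = SimConfig(genome_size=10**8, coverage=2.0, n_markers=3, seed=42)
        a, b = simulate_library(cfg), simulate_library(cfg)
        assert a.clones == b.clones
        assert a.markers == b.markers
        assert a.truth == b.truth

    def test_truth_consistent_with_intervals(self):
        cfg = SimConfig(genome_size=10**8, coverage=2.0, n_markers=5, seed=5)
        lib = simulate_library(cfg)
        for mid, pos in lib.markers.items():
            expect = {
                c.index for c in lib.clones
                if c.start <= pos < c.start + c.length
            }
            assert set(lib.truth[mid]) == expect

    def test_mean_clones_per_marker_approximates_coverage(self):
        # each clone covers a fixed interior marker with p = insert/genome,
        # so the expected clone count at the marker equals the coverage
        coverage, n_rep = 3.0, 200
        counts = []
        for seed in range(n_rep):
            cfg = SimConfig(genome_size=10**7, coverage=coverage,
                            insert_mean=100_000,
                            marker_positions=(5_000_000,), seed=seed)
            counts.append(len(simulate_library(cfg).truth["M1"]))
        n_clones = 300  # coverage * genome / insert
        p = 100_000 / 10**7
        sd_of_mean = np.sqrt(n_clones * p * (1 - p) / n_rep)
        assert abs(np.mean(counts) - coverage) < 3 * sd_of_mean

    def test_overfull_library_rejected(self):
        cfg = SimConfig(genome_size=10**8, coverage=3.0, n_markers=0,
                        n_plates=1)
        with pytest.raises(ValueError, match="exceed"):
            simulate_library(cfg)


class TestSpikedSuperpool:
    def test_default_emulates_rare_single_locus(self):
        m = build_spiked_superpool()
        assert SPIKED_DEFAULT_NEGATIVES == 3200  # (25 x 384) / 3
        assert len(m.members) == 3201
        assert pool_volume(m) == 5 + 3200 * 15  # 48,005 uL

    def test_single_member_pool(self):
        m = build_spiked_superpool(n_negatives=0)
        assert len(m.members) == 1
        assert pool_volume(m) == 5.0


class TestScreen:
    def test_noiseless_round_trip_recovers_every_marker(self, noiseless_config):
        lib = simulate_library(noiseless_config)
        out = run_screen(lib)
        for mid, dec in out.decoded.items():
            assert dec.status is DecodeStatus.UNIQUE
            truth_addr = next(iter(lib.truth_addresses(mid)))
            assert dec.candidates == [truth_addr]
        assert evaluate(out, lib).sensitivity == 1.0

    def test_noiseless_reactions_reconcile_with_budget(self, noiseless_config):
        # 3 single-clone markers on distinct plates of a 24-plate library:
        # consumed reactions equal the whole-library budget (0 + 10 + 3x18)
        lib = simulate_library(noiseless_config)
        out = run_screen(lib)
        assert out.total_reactions == budget_paper_mode(24).total_simplex == 64

    def test_total_false_negative_rate_loses_everything(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, beta=1.0)
        lib = simulate_library(cfg)
        out = run_screen(lib)
        assert evaluate(out, lib).sensitivity == 0.0

    def test_screen_deterministic_under_fixed_seed(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, alpha=0.1, beta=0.1)
        lib = simulate_library(cfg)
        a, b = run_screen(lib, seed=99), run_screen(lib, seed=99)
        assert a.reactions == b.reactions
        assert {m: d.candidates for m, d in a.decoded.items()} == \
            {m: d.candidates for m, d in b.decoded.items()}

    def test_exhaustive_noiseless_recovery_on_toy_library(self):
        # ten-plate library, marker positions swept along the genome: every
        # single-clone marker must decode to exactly its clone
        base = SimConfig(genome_size=10 * 384 * 100_000 // 3, coverage=3.0,
                         insert_mean=100_000, n_markers=0, seed=23)
        lib0 = simulate_library(base)
        positions = single_clone_marker_positions(lib0, 12,
                                                  distinct_plates=False)
        for pos in positions:
            cfg = dataclasses.replace(base, marker_positions=(int(pos),))
            lib = simulate_library(cfg)
            out = run_screen(lib)
            assert out.decoded["M1"].status is DecodeStatus.UNIQUE
            assert out.decoded["M1"].candidates == \
                [next(iter(lib.truth_addresses("M1")))]

    def test_sensitivity_matches_closed_form_path_probability(self):
        # single-superpool library: a unique decode needs all 6 pools on the
        # true path (2 matrix + 4 single-plate) called positive, so per-clone
        # recovery probability is (1-beta)^6
        beta, n_rep = 0.05, 400
        base = SimConfig(genome_size=GENOME_24_PLATES, coverage=3.0,
                         insert_mean=100_000, n_markers=0, seed=17, beta=beta)
        lib0 = simulate_library(dataclasses.replace(base, beta=0.0))
        pos = single_clone_marker_positions(lib0, 1)
        cfg = dataclasses.replace(base, marker_positions=pos)
        lib = simulate_library(cfg)
        hits = sum(
            evaluate(run_screen(lib, seed=1000 + s), lib).sensitivity
            for s in range(n_rep)
        )
        p = (1 - beta) ** 6
        sd = np.sqrt(n_rep * p * (1 - p))
        assert abs(hits - n_rep * p) < 3.5 * sd

    def test_replicate_aggregation_reports_spread(self):
        cfg = SimConfig(genome_size=10 * 384 * 100_000 // 3, coverage=3.0,
                        insert_mean=100_000, n_markers=1, beta=0.1, seed=0)
        rep = replicate_screens(cfg, seeds=list(range(8)))
        assert rep.n_replicates == 8
        assert 0.0 <= rep.sensitivity <= 1.0
        assert rep.sensitivity_sd >= 0.0

    def test_recovery_monotone_in_false_negative_rate(self, noiseless_config):
        # common random numbers: the same noise seeds at every beta level,
        # on a fixed library whose markers each sit in a single clone
        seeds = list(range(60))
        sens = []
        for beta in (0.0, 0.1, 0.3):
            cfg = dataclasses.replace(noiseless_config, beta=beta)
            lib = simulate_library(cfg)
            sens.append(np.mean([
                evaluate(run_screen(lib, seed=s), lib).sensitivity
                for s in seeds
            ]))
        assert sens[0] >= sens[1] >= sens[2]
        assert sens[0] == 1.0

    def test_phantom_rate_monotone_in_false_positive_rate(self, noiseless_config):
        seeds = list(range(60))
        rates = []
        for alpha in (0.0, 0.1, 0.3):
            cfg = dataclasses.replace(noiseless_config, alpha=alpha)
            lib = simulate_library(cfg)
            rates.append(np.mean([
                evaluate(run_screen(lib, seed=s), lib).phantom_rate
                for s in seeds
            ]))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[0] == 0.0
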