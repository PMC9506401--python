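"""Generator contracts: determinism, depth accounting, limiting regimes,
closed-form occupancy and call evaluation."""

import numpy as np
import pandas as pd
import pytest

from rarebiome.synthetic import (
    SimulationConfig,
    SyntheticTruth,
    deterministic_regime,
    evaluate_calls,
    expected_occupancy,
    simulate,
)
from rarebiome.transmission import TransmissionCall


SMALL = dict(
    n_core_seed=3, n_rare_seed_deterministic=5, n_rare_seed_stochastic=5,
    n_soil_common=4, n_soil_rare=6, n_host_specialist=4, n_contaminant=2,
)


@pytest.fixture(scope="module")
def small_sim():
    return simulate(SimulationConfig(rng_seed=123, **SMALL))


class TestSimulate:
    def test_same_seed_bit_identical(self):
        a = simulate(SimulationConfig(rng_seed=5, **SMALL))
        b = simulate(SimulationConfig(rng_seed=5, **SMALL))
        for marker in ("16S", "ITS"):
            pd.testing.assert_frame_equal(a.counts[marker].counts, b.counts[marker].counts)
        pd.testing.assert_frame_equal(a.truth.events, b.truth.events)

    def test_depths_within_bounds_and_exact(self, small_sim):
        cfg = small_sim.config
        for marker in ("16S", "ITS"):
            sums = small_sim.counts[marker].counts.sum(axis=1)
            nonzero = sums[sums > 0]
            assert (nonzero >= cfg.depth_min).all()
            assert (nonzero <= cfg.depth_max).all()

    def test_sample_design_shape(self, small_sim):
        cfg = small_sim.config
        meta = small_sim.metadata.frame
        plant = meta[meta["tissue"].isin(["shoot", "root", "rhizosphere"])]
        assert len(plant) == cfg.n_hosts * 3 * 2 * cfg.replicates
        seedlike = meta[meta["tissue"].isin(["seed", "spermosphere"])]
        assert len(seedlike) == cfg.n_hosts * 2 * cfg.seed_replicates
        assert (seedlike["substrate"] == "none").all()

    def test_lambda_zero_soil_rare_absent(self):
        sim = simulate(SimulationConfig(rng_seed=2, lambda_soil=0.0, **SMALL))
        for otu in sim.truth.otus_of_class("soil_rare"):
            marker = "16S" if otu.startswith("Bact") else "ITS"
            assert sim.counts[marker].counts[otu].sum() == 0

    def test_saturated_regime_fills_every_jar_and_lot(self):
        sim = simulate(deterministic_regime(SimulationConfig(rng_seed=4, **SMALL)))
        cfg = sim.config
        n_jars = cfg.n_hosts * cfg.replicates
        for otu in sim.truth.otus_of_class("soil_rare"):
            assert len(sim.truth.soil_jars[otu]) == n_jars
        for otu in sim.truth.otus_of_class("rare_seed_stochastic"):
            assert len(sim.truth.carriage[otu]) == cfg.n_hosts

    def test_seed_class_reaches_sand_samples(self, small_sim):
        # every deterministic seed OTU appears somewhere in its carriers'
        # sand-grown samples (establishment prob < 1 can drop single tissues
        # but three tissues x reps make total absence essentially impossible
        # at the module's fixed seed)
        counts = small_sim.counts["ITS"].counts
        meta = small_sim.metadata.frame
        for otu in small_sim.truth.otus_of_class("rare_seed_deterministic"):
            if not otu.startswith("Fung"):
                continue
            carriers = small_sim.truth.carriage[otu]
            sand = meta.index[(meta["substrate"] == "sand") & (meta["host"].isin(carriers))]
            assert counts.loc[sand, otu].sum() > 0

    def test_nonzero_counts_trace_to_inoculation(self, small_sim):
        """Every read belongs to an OTU with a recorded inoculation event or
        carriage entry for that host."""
        ev = small_sim.truth.events
        meta = small_sim.metadata.frame
        counts = small_sim.counts["ITS"].counts
        sourced = set(map(tuple, ev[["otu_id", "host"]].to_numpy()))
        for sid, row in counts.iterrows():
            host = meta.at[sid, "host"]
            for otu in row.index[row > 0]:
                cls = small_sim.truth.classes[otu]
                if cls in ("core_seed", "rare_seed_deterministic",
                           "rare_seed_stochastic", "host_specialist"):
                    assert host in small_sim.truth.carriage[otu]
                else:
                    assert (otu, host) in sourced


class TestExpectedOccupancy:
    def test_closed_forms(self):
        cfg = SimulationConfig(p_seed_carriage=0.0, lambda_soil=0.5)
        assert expected_occupancy("rare_seed_stochastic", cfg) == 0.0
        assert expected_occupancy("soil_rare", cfg) == pytest.approx(1 - np.exp(-0.5))
        cfg2 = SimulationConfig(p_seed_carriage=0.3)
        assert expected_occupancy("rare_seed_stochastic", cfg2) == pytest.approx(17 * 0.3)
        assert expected_occupancy("soil_common", cfg2) == 17.0

    def test_monte_carlo_within_three_se(self):
        """Empirical class occupancy at n=2000 OTUs sits within 3 standard
        errors of the closed form."""
        n = 2000
        cfg = SimulationConfig(
            rng_seed=8,
            n_core_seed=0, n_rare_seed_deterministic=0, n_host_specialist=0,
            n_contaminant=0, n_soil_common=0,
            n_rare_seed_stochastic=n, n_soil_rare=n,
            depth_log_mean=float(np.log(200)), depth_log_sigma=0.5,
        )
        sim = simulate(cfg)
        h, p = cfg.n_hosts, cfg.p_seed_carriage
        occ = np.array([
            len(sim.truth.carriage[o]) for o in sim.truth.otus_of_class("rare_seed_stochastic")
        ])
        se = np.sqrt(h * p * (1 - p) / len(occ))
        assert abs(occ.mean() - expected_occupancy("rare_seed_stochastic", cfg)) < 3 * se

        n_jars = h * cfg.replicates
        jar_frac = np.array([
            len(sim.truth.soil_jars[o]) / n_jars for o in sim.truth.otus_of_class("soil_rare")
        ])
        q = expected_occupancy("soil_rare", cfg)
        se_jar = np.sqrt(q * (1 - q) / (n_jars * len(jar_frac)))
        assert abs(jar_frac.mean() - q) < 3 * se_jar


class TestEvaluateCalls:
    def _truth(self):
        classes = {f"o{i}": cls for i, cls in enumerate(
            ["rare_seed_deterministic"] * 4 + ["soil_rare"] * 4 + ["contaminant"] * 4
        )}
        carriage = {f"o{i}": frozenset({"maize"}) for i in range(4)}
        soil_jars = {f"o{i}": frozenset({("maize", 1)}) for i in range(4, 8)}
        return SyntheticTruth(classes=classes, carriage=carriage, soil_jars=soil_jars)

    def _call(self, otu, source):
        ev = {"sand_detections": 1 if source == "seed" else 0}
        return TransmissionCall(otu, "maize", "root", source, evidence=ev)

    def test_perfect_calls_all_f1_one(self):
        truth = self._truth()
        calls = [self._call(f"o{i}", "seed") for i in range(4)]
        calls += [self._call(f"o{i}", "soil") for i in range(4, 8)]
        calls += [self._call(f"o{i}", "unknown") for i in range(8, 12)]
        ev = evaluate_calls(calls, truth)
        assert ev.accuracy == 1.0
        for cls in ("seed", "soil", "unknown"):
            assert ev.f1(cls) == 1.0
        assert ev.unscreened == []

    def test_all_unknown_zero_recall(self):
        truth = self._truth()
        calls = [self._call(f"o{i}", "unknown") for i in range(12)]
        ev = evaluate_calls(calls, truth)
        assert ev.per_class.at["seed", "recall"] == 0.0
        assert ev.per_class.at["soil", "recall"] == 0.0

    def test_hand_tallied_confusion(self):
        """12-OTU toy: 3 seed mistakes to unknown, 1 soil mistake to seed."""
        truth = self._truth()
        calls = [self._call(f"o{i}", "seed") for i in range(1)]
        calls += [self._call(f"o{i}", "unknown") for i in range(1, 4)]
        calls += [self._call("o4", "seed")]
        calls += [self._call(f"o{i}", "soil") for i in range(5, 8)]
        calls += [self._call(f"o{i}", "unknown") for i in range(8, 12)]
        ev = evaluate_calls(calls, truth)
        assert ev.confusion.at["seed", "seed"] == 1
        assert ev.confusion.at["seed", "unknown"] == 3
        assert ev.confusion.at["soil", "seed"] == 1
        assert ev.confusion.at["soil", "soil"] == 3
        assert ev.confusion.at["unknown", "unknown"] == 4
        assert ev.per_class.at["seed", "precision"] == pytest.approx(1 / 2)
        assert ev.per_class.at["seed", "recall"] == pytest.approx(1 / 4)

    def test_mismatched_universe_rejected(self):
        truth = self._truth()
        with pytest.raises(ValueError, match="outside the truth universe"):
            evaluate_calls([self._call("mystery", "seed")], truth)
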