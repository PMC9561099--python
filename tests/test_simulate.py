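"""Synthetic flock generator: structure, determinism, statistical fidelity."""

import numpy as np
import pandas as pd
import pytest

from flockparam.pedigree import relationship_matrix
from flockparam.simulate import (
    SimConfig,
    SimulationError,
    TraitTruth,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_records,
    simulate_repeatability_records,
)
from flockparam.traits import filter_chamber_records


class TestPedigree:
    def test_zero_matings_founders_only(self):
        cfg = SimConfig(n_sires=5, progeny_per_sire=0, daughters_per_sire=0)
        ped = simulate_pedigree(cfg)
        assert len(ped) == 5
        assert (ped.sire == -1).all() and (ped.dam == -1).all()

    def test_progeny_counts_and_known_sires(self):
        cfg = SimConfig(n_sires=20, progeny_per_sire=10, daughters_per_sire=0)
        ped = simulate_pedigree(cfg)
        non_founders = [i for i in range(len(ped)) if ped.sire[i] >= 0]
        assert len(non_founders) == 200
        assert all(ped.ids[ped.sire[i]].startswith("S") for i in non_founders)

    def test_fixed_seed_is_deterministic(self):
        cfg = SimConfig(seed=42)
        p1, p2 = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert p1.ids == p2.ids
        assert np.array_equal(p1.sire, p2.sire)

    def test_multigeneration_needs_enough_males(self):
        cfg = SimConfig(
            n_sires=30, progeny_per_sire=1, daughters_per_sire=0, n_generations=2
        )
        with pytest.raises(SimulationError, match="male candidates"):
            simulate_pedigree(cfg)

    def test_multigeneration_sires_come_from_previous_generation(self):
        cfg = SimConfig(
            n_sires=5, progeny_per_sire=20, daughters_per_sire=0, n_generations=2
        )
        ped = simulate_pedigree(cfg)
        gen2 = [i for i, a in enumerate(ped.ids) if ped.sire[i] >= 0
                and ped.ids[ped.sire[i]].startswith("P")]
        assert len(gen2) == 100


class TestBreedingValues:
    def test_zero_genetic_covariance_gives_zero_values(self):
        ped = simulate_pedigree(SimConfig(n_sires=3, daughters_per_sire=2))
        bv = simulate_breeding_values(ped, np.zeros((2, 2)), seed=0)
        assert np.all(bv == 0.0)

    def test_founder_covariance_matches_g(self):
        from flockparam.pedigree import Pedigree

        ped = Pedigree.from_triples([(f"F{i}", None, None) for i in range(10000)])
        g = np.array([[1.0, 0.5], [0.5, 1.0]])
        bv = simulate_breeding_values(ped, g, seed=1)
        emp = np.cov(bv.T)
        assert np.abs(emp - g).max() < 0.05

    def test_parent_offspring_covariance_is_half_g(self):
        from flockparam.pedigree import Pedigree

        triples = []
        for i in range(10000):
            triples.append((f"S{i}", None, None))
            triples.append((f"O{i}", f"S{i}", None))
        ped = Pedigree.from_triples(triples)
        bv = simulate_breeding_values(ped, np.array([[1.0]]), seed=2)
        s_ix = [ped.index[f"S{i}"] for i in range(10000)]
        o_ix = [ped.index[f"O{i}"] for i in range(10000)]
        cov = np.cov(bv[s_ix, 0], bv[o_ix, 0])[0, 1]
        assert cov == pytest.approx(0.5, abs=0.03)

    def test_inbred_line_variance_follows_a_matrix(self):
        """Repeated full-sib matings: var(a_i) = a_ii, not 1."""
        from flockparam.pedigree import Pedigree

        triples = [("P1", None, None), ("P2", None, None)]
        for g in range(3):
            p1 = f"X{g-1}a" if g else "P1"
            p2 = f"X{g-1}b" if g else "P2"
            triples += [(f"X{g}a", p1, p2), (f"X{g}b", p1, p2)]
        ped = Pedigree.from_triples(triples)
        a_ii = relationship_matrix(ped)[ped.index["X2a"], ped.index["X2a"]]
        reps = 20000
        vals = np.empty(reps)
        rng = np.random.default_rng(3)
        for r in range(reps):
            vals[r] = simulate_breeding_values(ped, np.array([[1.0]]), rng)[
                ped.index["X2a"], 0
            ]
        assert np.var(vals) == pytest.approx(a_ii, rel=0.05)

    def test_non_psd_g_rejected(self):
        ped = simulate_pedigree(SimConfig(n_sires=2, daughters_per_sire=1))
        with pytest.raises(SimulationError, match="PSD"):
            simulate_breeding_values(ped, np.array([[1.0, 2.0], [2.0, 1.0]]), seed=0)


@pytest.fixture(scope="module")
def flock():
    cfg = SimConfig(seed=9)
    ped = simulate_pedigree(cfg)
    return cfg, ped, simulate_records(ped, cfg)


class TestRecords:
    def test_all_variances_zero_gives_constant_records(self):
        cfg = SimConfig(
            seed=1,
            n_sires=4,
            daughters_per_sire=2,
            seal_break_rate=0.0,
            refusal_rate=0.0,
            missing_rate=0.0,
            cg_sd_chamber=0.0,
            bdev_slope=0.0,
        )
        cfg.traits["ch4"] = TraitTruth(24.0, 0.0, {"wgpe": 0.0, "agpe": 0.0}, 0.0)
        cfg.rg_with_ch4 = {}
        ped = simulate_pedigree(cfg)
        data = simulate_records(ped, cfg)
        assert np.allclose(data.chamber.ch4_g, 24.0)

    def test_refusal_rate_reflected_in_filter(self):
        cfg = SimConfig(
            seed=11, n_sires=25, progeny_per_sire=10, daughters_per_sire=0,
            refusal_rate=0.1, seal_break_rate=0.0, missing_rate=0.0,
        )
        ped = simulate_pedigree(cfg)
        data = simulate_records(ped, cfg)
        n = len(data.chamber)
        _, log = filter_chamber_records(data.chamber)
        n_refused = (log.reason == "refusal").sum()
        # binomial: mean n*0.1, tolerance 3 SD
        assert abs(n_refused - 0.1 * n) < 3 * np.sqrt(n * 0.1 * 0.9)

    def test_design_shape_matches_study_scale(self, flock):
        cfg, ped, data = flock
        n_chamber = data.chamber.animal.nunique()
        assert n_chamber == cfg.n_sires * cfg.progeny_per_sire
        per_animal = data.chamber.groupby("animal").size()
        assert (per_animal == cfg.rounds * cfg.days_per_round).all()
        ages = data.maternal.ageclass.unique()
        assert set(ages) <= {2, 3, 4, 5}

    def test_simulated_phenotypic_variance_matches_truth(self):
        cfg = SimConfig(
            seed=13, n_sires=100, progeny_per_sire=10, daughters_per_sire=0,
            cg_sd_chamber=0.0, bdev_slope=0.0,
            seal_break_rate=0.0, refusal_rate=0.0, missing_rate=0.0,
        )
        cfg.rg_with_ch4 = {}
        ped = simulate_pedigree(cfg)
        data = simulate_records(ped, cfg)
        s2p = cfg.traits["ch4"].sigma2_p
        emp = data.chamber.ch4_g.var()
        assert emp == pytest.approx(s2p, rel=0.15)

    def test_tables_roundtrip_through_csv(self, flock, tmp_path):
        _, _, data = flock
        for name, df in (("chamber", data.chamber), ("maternal", data.maternal)):
            p = tmp_path / f"{name}.csv"
            df.to_csv(p, index=False, na_rep="NA")
            back = pd.read_csv(p, na_values=["NA"])
            pd.testing.assert_frame_equal(
                back, df.reset_index(drop=True), check_dtype=False, atol=1e-12
            )

    def test_determinism_of_records(self):
        cfg = SimConfig(seed=21, n_sires=5, daughters_per_sire=3)
        ped = simulate_pedigree(cfg)
        d1 = simulate_records(ped, cfg)
        d2 = simulate_records(ped, cfg)
        pd.testing.assert_frame_equal(d1.chamber, d2.chamber)
        pd.testing.assert_frame_equal(d1.maternal, d2.maternal)

    def test_truth_records_generating_parameters(self, flock):
        cfg, _, data = flock
        assert data.truth["traits"]["ch4"]["sigma2_a"] == cfg.traits["ch4"].sigma2_a
        assert data.truth["n_chamber_animals"] == cfg.n_sires * cfg.progeny_per_sire

    def test_egg_counts_on_count_scale(self, flock):
        _, _, data = flock
        assert (data.eggs.fec_raw >= 0).all()
        logs = np.log(data.eggs.fec_raw + 50.0)
        assert abs(logs.mean() - 6.07) < 0.3


class TestRepeatabilityGenerator:
    def test_balanced_structure(self):
        ped, df = simulate_repeatability_records(10, 5, rounds=2, days_per_round=2, seed=0)
        assert df.animal.nunique() == 50
        assert len(df) == 200
        assert set(df.columns) >= {"animal", "sire", "round", "day", "y"}

    def test_truth_variances_recovered_in_raw_moments(self):
        ped, df = simulate_repeatability_records(
            200, 10, G=0.25, PE=0.15, E=0.6, seed=5
        )
        assert df.y.var() == pytest.approx(1.0, rel=0.1)
        # intraclass correlation of animal means ~ repeatability
        between = df.groupby("animal").y.mean().var()
        assert between == pytest.approx(0.25 + 0.15 + 0.6 / 4, rel=0.2)
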