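"""Ground-truth generators: determinism, noiseless recovery, noise statistics."""

import numpy as np
import pandas as pd
import pytest

from pdcore import occupancy, seqdiscrim, synth
from pdcore.synth import OccupancyScenario, SeqScenario


class TestSimulateCores:
    def test_noiseless_three_trimers_give_nine_detections(self):
        sim = synth.simulate_cores(
            OccupancyScenario(n_cores=30, trimer_dist=3, fp_rate=0.0, fn_rate=0.0, seed=7)
        )
        det = occupancy.mapback_count(sim.flags, known_cores=sim.particles["core_id"])
        assert (det["detection_count"] == 9).all()

    def test_total_false_negative_rate_silences_everything(self):
        sim = synth.simulate_cores(
            OccupancyScenario(n_cores=20, trimer_dist=4, fp_rate=0.0, fn_rate=1.0, seed=2)
        )
        assert not sim.flags["occupied"].any()

    def test_noiseless_mixed_counts_recover_ground_truth(self):
        sim = synth.simulate_cores(
            OccupancyScenario(
                n_cores=200,
                trimer_dist={0: 0.2, 1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2},
                fp_rate=0.0,
                fn_rate=0.0,
                seed=13,
            )
        )
        det = occupancy.mapback_count(sim.flags, known_cores=sim.particles["core_id"])
        merged = det.merge(sim.truth, on="core_id")
        assert (merged["detection_count"] == 3 * merged["k_true"]).all()
        assert (
            occupancy.bin_detections(merged["detection_count"].to_numpy())
            == merged["k_true"].to_numpy()
        ).all()

    def test_planted_sites_are_pairwise_compatible(self, geometry):
        sim = synth.simulate_cores(
            OccupancyScenario(n_cores=50, trimer_dist=4, fp_rate=0.0, fn_rate=0.0, seed=5)
        )
        angles = geometry.pairwise_angles_deg()
        for sites in sim.truth["sites"]:
            for a in range(len(sites)):
                for b in range(a + 1, len(sites)):
                    assert angles[sites[a], sites[b]] > 71.0

    def test_overfull_request_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            synth.simulate_cores(OccupancyScenario(n_cores=5, trimer_dist=5, seed=1))

    def test_orientations_are_valid(self):
        sim = synth.simulate_cores(OccupancyScenario(n_cores=40, seed=21))
        tilt = sim.particles["tilt"]
        assert ((tilt >= 0) & (tilt <= 180)).all()

    def test_determinism_identical_seed_identical_output(self, tmp_path):
        scen = OccupancyScenario(n_cores=60, seed=42)
        a = synth.emulate_fig1e_table(scen)
        b = synth.emulate_fig1e_table(scen)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        a = synth.emulate_fig1e_table(OccupancyScenario(n_cores=60, seed=1))
        b = synth.emulate_fig1e_table(OccupancyScenario(n_cores=60, seed=2))
        assert not a.equals(b)


class TestNoiseStatistics:
    def test_mean_detection_count_matches_noise_model(self):
        """E[d] = 3k(1-q) + (60-3k)p within 3 standard errors."""
        k, p, q = 3, 0.02, 0.10
        means = []
        for seed in range(12):
            det = synth.emulate_fig1e_table(
                OccupancyScenario(n_cores=150, trimer_dist=k, fp_rate=p, fn_rate=q, seed=seed)
            )
            means.append(det["detection_count"].mean())
        expected = 3 * k * (1 - q) + (60 - 3 * k) * p
        var_d = 3 * k * (1 - q) * q + (60 - 3 * k) * p * (1 - p)
        se = np.sqrt(var_d / (150 * len(means)))
        assert abs(np.mean(means) - expected) < 3 * se


class TestEmulateFig1e:
    def test_majority_at_three_to_four_trimers(self):
        det = synth.emulate_fig1e_table(OccupancyScenario(n_cores=400, seed=8))
        s = occupancy.occupancy_summary(det, at_least=(5,))
        frac_3_4 = s.trimer_fractions.get(3, 0) + s.trimer_fractions.get(4, 0)
        assert frac_3_4 > 0.5

    def test_empty_scenario_rejected(self):
        with pytest.raises(ValueError):
            OccupancyScenario(n_cores=0, seed=1)


class TestSimulateSequences:
    def test_zero_mutation_e3bp_set_votes_unanimously(self):
        msa, truth = synth.simulate_sequences(
            SeqScenario(n_per_group={"Asc": 10, "Pez": 10}, mutation_prob=0.0, seed=3)
        )
        votes = [
            seqdiscrim.scan_motifs(s, group=g).vote for s, g in zip(msa.seqs, msa.groups)
        ]
        assert votes == ["E3BP"] * 20
        assert (truth["label"] == "E3BP").all()

    def test_planted_triad_state_recovered(self):
        msa, _ = synth.simulate_sequences(
            SeqScenario(n_per_group={"Sac": 5}, triad_state="inactive", mutation_prob=0.0, seed=4)
        )
        for s in msa.seqs:
            assert seqdiscrim.triad_activity(s, synth.TRIAD_COLUMN)[0] == "inactive"

    def test_scrubbing_a_motif_removes_its_match(self):
        msa, _ = synth.simulate_sequences(
            SeqScenario(
                n_per_group={"Pez": 3},
                plant={"GxI_termination": False},
                mutation_prob=0.0,
                seed=5,
            )
        )
        for s in msa.seqs:
            scan = seqdiscrim.scan_motifs(s, group="Pez")
            assert not scan.results["GxI_termination"]["matched"]
            assert scan.results["Asp_Leu_hydrophobic"]["matched"]

    def test_unknown_motif_name_rejected(self):
        with pytest.raises(ValueError, match="unknown motif"):
            synth.simulate_sequences(
                SeqScenario(n_per_group={"Asc": 2}, plant={"no_such": True}, seed=1)
            )

    def test_full_mutation_accuracy_matches_random_sequence_chance(self):
        """At mutation probability 1 the vote accuracy approaches the rate at
        which uniformly random sequences happen to vote E3BP (binomial CI)."""
        rng = np.random.default_rng(99)
        aa = np.array(list(seqdiscrim.AMINO_ACIDS))
        n_rand = 600
        rand_hits = sum(
            seqdiscrim.scan_motifs(
                "".join(rng.choice(aa, synth.REF_FRAME_LENGTH)), group="Pez"
            ).vote
            == "E3BP"
            for _ in range(n_rand)
        )
        chance = rand_hits / n_rand

        hits = total = 0
        for seed in range(20):
            msa, truth = synth.simulate_sequences(
                SeqScenario(n_per_group={"Pez": 30}, mutation_prob=1.0, seed=seed)
            )
            for s, g, label in zip(msa.seqs, msa.groups, truth["label"]):
                hits += seqdiscrim.scan_motifs(s, group=g).vote == label
                total += 1
        acc = hits / total
        se = np.sqrt(chance * (1 - chance) / n_rand + acc * (1 - acc) / total)
        assert abs(acc - chance) < 4 * se + 1e-9

    def test_determinism(self):
        scen = SeqScenario(n_per_group={"Asc": 5}, mutation_prob=0.2, seed=6)
        a, _ = synth.simulate_sequences(scen)
        b, _ = synth.simulate_sequences(scen)
        assert a.seqs == b.seqs


def test_operator_site_labels_three_per_site(icosa, geometry):
    labels = synth.operator_site_labels(icosa, geometry)
    values, counts = np.unique(labels, return_counts=True)
    assert len(values) == 20 and (counts == 3).all()
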