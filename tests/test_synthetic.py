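import numpy as np
import pandas as pd
import pytest

from aqpfam.family_classifier import assign_subfamily
from aqpfam.io_formats import read_fasta, read_gff3, write_fasta, write_gff3
from aqpfam.motif_extraction import extract_npa, extract_positions, map_to_reference
from aqpfam.specificity_classifier import load_profiles, predict_substrates
from aqpfam.synthetic_data import (
    TEMPLATES,
    SimConfig,
    mutate_copy,
    simulate_counts,
    simulate_family,
    subgroup_base_sequence,
)
from aqpfam.synthetic_reference import SDP_CLASSES


class TestConfig:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(substitution_rate=1.0)
        with pytest.raises(ValueError):
            SimConfig(indel_rate=-0.1)
        with pytest.raises(ValueError):
            SimConfig(n_per_subfamily={"PIP": -1})


class TestDeterminism:
    def test_same_seed_same_family(self):
        a = simulate_family(SimConfig(rng_seed=5))
        b = simulate_family(SimConfig(rng_seed=5))
        assert a.proteins == b.proteins
        assert a.cds == b.cds
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_same_seed_byte_identical_files(self, tmp_path):
        for tag in ("x", "y"):
            sim = simulate_family(SimConfig(rng_seed=9))
            write_fasta(sim.proteins, tmp_path / f"{tag}.faa")
            write_gff3(sim.models, tmp_path / f"{tag}.gff3")
        assert (tmp_path / "x.faa").read_bytes() == (tmp_path / "y.faa").read_bytes()
        assert (tmp_path / "x.gff3").read_bytes() == (tmp_path / "y.gff3").read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_family(SimConfig(rng_seed=1))
        b = simulate_family(SimConfig(rng_seed=2))
        assert a.proteins != b.proteins


class TestFamilyStructure:
    def test_default_composition_is_9_9_8_4_2(self, default_sim):
        counts = default_sim.truth["subfamily"].value_counts().to_dict()
        assert counts == {"PIP": 9, "TIP": 9, "NIP": 8, "SIP": 4, "XIP": 2}
        assert len(default_sim.truth) == 32

    def test_truth_row_per_gene(self, default_sim):
        assert set(default_sim.truth["gene"]) == {
            r.id for r in default_sim.proteins
        }
        for col in ("arr", "froger", "npa_lb", "npa_le", "npa_spacing",
                    "pair_id", "n_introns"):
            assert col in default_sim.truth.columns
        for cls in SDP_CLASSES:
            assert f"sdp_{cls}" in default_sim.truth.columns

    def test_subfamily_typical_intron_counts(self, default_sim):
        truth = default_sim.truth.set_index("gene")
        by_subgroup = truth.groupby("subgroup")["n_introns"].unique()
        assert list(by_subgroup["PIP1"]) == [3]
        assert list(by_subgroup["TIP1"]) == [2]
        assert list(by_subgroup["NIP1"]) == [4]
        assert list(by_subgroup["NIP5"]) == [3]
        assert list(by_subgroup["SIP1"]) == [0]
        assert list(by_subgroup["SIP2"]) == [2]
        assert list(by_subgroup["XIP1"]) == [1]

    def test_gene_models_carry_the_intron_lengths(self, default_sim):
        truth = default_sim.truth.set_index("gene")
        for model in default_sim.models:
            recorded = truth.loc[model.gene_id, "introns"]
            expected = [] if recorded == "-" else [
                int(x) for x in recorded.split(",")
            ]
            assert model.intron_lengths == expected
            assert model.cds_length == truth.loc[model.gene_id, "cds_len"]

    def test_planted_duplicate_pairs(self, default_sim):
        truth = default_sim.truth
        tandem = truth[truth["pair_id"] == "SIP1_tandem"]
        assert len(tandem) == 2
        assert tandem["scaffold"].nunique() == 1
        assert tandem["strand"].nunique() == 1
        dispersed = truth[truth["pair_id"] == "NIP3_dispersed"]
        assert len(dispersed) == 2
        assert dispersed["chromosome"].nunique() == 2

    def test_outputs_pass_the_io_validators(self, tmp_path, default_sim):
        write_fasta(default_sim.proteins, tmp_path / "f.faa")
        write_gff3(default_sim.models, tmp_path / "f.gff3")
        assert len(read_fasta(tmp_path / "f.faa")) == 32
        assert len(read_gff3(tmp_path / "f.gff3")) == 32


class TestMutateCopy:
    def test_zero_rate_identity_and_empty_log(self):
        rng = np.random.default_rng(0)
        seq = subgroup_base_sequence("PIP1")
        out, log = mutate_copy(seq, rng, 0.0, 0.0)
        assert out == seq
        assert log == []

    def test_protected_positions_untouched(self, topology):
        rng = np.random.default_rng(1)
        seq = subgroup_base_sequence("NIP2")
        protected = frozenset(topology.annotated_columns())
        out, log = mutate_copy(seq, rng, 0.5, 0.02, protected=protected)
        touched = {pos for _, pos, _, _ in log}
        assert touched.isdisjoint(protected)
        for col in topology.arr_cols:
            # no indels upstream shift check needed for substitution log:
            # verify via the log that the planted columns never appear
            assert col not in touched

    def test_edit_log_matches_hamming_distance(self):
        rng = np.random.default_rng(2)
        seq = subgroup_base_sequence("TIP1")
        out, log = mutate_copy(seq, rng, 0.30, 0.0)
        hamming = sum(1 for a, b in zip(seq, out) if a != b)
        assert hamming == sum(1 for op, *_ in log if op == "sub")
        assert 0 < hamming < len(seq)


class TestCounts:
    def test_zero_fpkm_always_zero_counts(self, default_sim):
        truth = default_sim.truth.copy()
        for t in ("root", "leaf", "seed"):
            truth[f"fpkm_{t}"] = 0.0
        table = simulate_counts(truth, SimConfig(rng_seed=1))
        assert (table.counts.values == 0).all()

    def test_fixed_seed_reproducible(self, default_sim):
        cfg = SimConfig(rng_seed=3)
        t1 = simulate_counts(default_sim.truth, cfg)
        t2 = simulate_counts(default_sim.truth, cfg)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_poisson_mean_recovered(self):
        # one gene with expected count 100, replicated across seeds
        truth = pd.DataFrame(
            [{"gene": "g", "cds_len": 1000,
              "fpkm_root": 100 * 1e9 / (1000 * 30_000_000)}]
        )
        draws = [
            int(
                simulate_counts(
                    truth, SimConfig(rng_seed=s, tissues=("root",))
                ).counts.iloc[0, 0]
            )
            for s in range(300)
        ]
        mean = np.mean(draws)
        se = np.sqrt(100 / len(draws))
        assert abs(mean - 100) < 3 * se


class TestEndToEnd:
    def test_zero_rate_extraction_exact_for_all_genes(self, topology, clean_sim):
        truth = clean_sim.truth.set_index("gene")
        for rec in clean_sim.proteins:
            posmap = map_to_reference(rec.seq, topology)
            row = truth.loc[rec.id]
            lb, le, spacing = extract_npa(rec.seq, posmap, topology)
            assert (lb, le, spacing) == (
                row["npa_lb"], row["npa_le"], int(row["npa_spacing"])
            )
            assert "".join(
                extract_positions(rec.seq, posmap, topology.arr_cols)
            ) == row["arr"]
            for cls in SDP_CLASSES:
                assert "".join(
                    extract_positions(rec.seq, posmap, topology.sdp_cols[cls])
                ) == row[f"sdp_{cls}"]

    def test_zero_rate_substrate_predictions_match_planted_truth(
        self, topology, clean_sim
    ):
        profiles = load_profiles()
        truth = clean_sim.truth.set_index("gene")
        for rec in clean_sim.proteins:
            posmap = map_to_reference(rec.seq, topology)
            vectors = {
                cls: extract_positions(rec.seq, posmap, topology.sdp_cols[cls])
                for cls in SDP_CLASSES
            }
            report = predict_substrates(vectors, profiles)
            row = truth.loc[rec.id]
            expected = {
                cls
                for cls in SDP_CLASSES
                if not [
                    i for i, (r, allowed) in enumerate(
                        zip(row[f"sdp_{cls}"], profiles[cls].allowed)
                    )
                    if r not in allowed
                ]
            }
            assert report.substrates == expected, rec.id

    def test_default_pipeline_recovers_subfamilies(self, default_sim, panel):
        truth = default_sim.truth.set_index("gene")
        hits = sum(
            assign_subfamily(r.id, r.seq, panel).subfamily
            == truth.loc[r.id, "subfamily"]
            for r in default_sim.proteins
        )
        assert hits >= 0.95 * len(default_sim.proteins)
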