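"""Ground-truth generators: helices, globular decoys, read pools, alignments."""

import networkx as nx
import numpy as np
import pytest

from memtol.structure_contacts import build_contact_map, load_chain
from memtol.synthetic_data import (
    PlantedMsaTruth,
    PlantedScreenTruth,
    SyntheticDataError,
    default_screen_truth,
    hokc_reference,
    make_globular_decoy,
    make_ideal_helix,
    simulate_msa,
    simulate_read_pools,
    write_pdb,
)
from memtol.variant_calling import Substitution, VariantGenotype, call_read_pools


class TestIdealHelix:
    def test_consecutive_ca_distance(self):
        helix = make_ideal_helix(2)
        d = np.linalg.norm(helix.residues[0].atoms["CA"] - helix.residues[1].atoms["CA"])
        assert d == pytest.approx(3.8, abs=0.05)

    def test_single_residue_has_no_contacts(self):
        helix = make_ideal_helix(1)
        assert len(helix) == 1
        cg = build_contact_map(helix, 5.0)
        assert cg.order == 0

    def test_helical_contact_pattern(self, helix20):
        edges = set(build_contact_map(helix20, 5.0).edges())
        for i in range(1, 17):
            assert (i, i + 3) in edges and (i, i + 4) in edges

    def test_rise_and_twist_are_canonical(self, helix20):
        ca = np.array([r.atoms["CA"] for r in helix20.residues])
        centered = ca - ca.mean(axis=0)
        axis = np.linalg.svd(centered)[2][0]
        rise = np.mean(np.diff(np.sort(centered @ axis)))
        assert abs(rise) == pytest.approx(1.5, abs=0.1)
        perp = centered - np.outer(centered @ axis, axis)
        twists = [
            np.degrees(
                np.arccos(
                    np.clip(
                        perp[i] @ perp[i + 1] / (np.linalg.norm(perp[i]) * np.linalg.norm(perp[i + 1])),
                        -1,
                        1,
                    )
                )
            )
            for i in range(len(ca) - 1)
        ]
        assert np.mean(twists) == pytest.approx(100.0, abs=2.0)

    def test_jitter_is_seed_reproducible(self):
        a = make_ideal_helix(10, seed=5, jitter=0.2)
        b = make_ideal_helix(10, seed=5, jitter=0.2)
        for ra, rb in zip(a.residues, b.residues):
            for name in ra.atoms:
                assert np.allclose(ra.atoms[name], rb.atoms[name])

    def test_invalid_size_rejected(self):
        with pytest.raises(SyntheticDataError):
            make_ideal_helix(0)

    def test_pdb_round_trip(self, tmp_path):
        helix = make_ideal_helix(8)
        path = tmp_path / "helix.pdb"
        write_pdb(helix, path)
        loaded = load_chain(path)
        assert loaded.sequence == "A" * 8
        assert set(build_contact_map(loaded, 5.0).edges()) == set(
            build_contact_map(helix, 5.0).edges()
        )


class TestGlobularDecoy:
    def test_minimum_inter_residue_distance(self):
        for seed in range(5):
            decoy = make_globular_decoy(40, seed=seed)
            pts = np.array([r.atoms["CA"] for r in decoy.residues])
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 3.5
            assert d.min(axis=1).mean() < 6.0

    def test_contact_graph_connected_across_seeds(self):
        for seed in range(10):
            decoy = make_globular_decoy(50, seed=seed)
            cg = build_contact_map(decoy, 5.0)
            assert nx.is_connected(cg.graph)

    def test_deterministic_per_seed(self):
        a = make_globular_decoy(30, seed=7)
        b = make_globular_decoy(30, seed=7)
        assert a.sequence == b.sequence
        for ra, rb in zip(a.residues, b.residues):
            assert np.allclose(ra.atoms["CA"], rb.atoms["CA"])


class TestScreenSimulation:
    def test_noiseless_deleterious_counts(self, hokc):
        sub = Substitution.from_string("M7W")
        truth = PlantedScreenTruth(
            reference=hokc,
            deleterious_singles=frozenset({sub}),
            compensatory_pairs=(),
            tolerated_singles=frozenset(),
            depth=100,
            error_rate=0.0,
            seed=0,
        )
        pools = simulate_read_pools(truth)
        assert len(pools.wt_reads) == 0 and len(pools.mut_reads) == 100
        result = call_read_pools(pools.wt_reads, pools.mut_reads, hokc)
        assert result.tables.substitution_counts[sub] == (0, 100)

    def test_compensated_pair_goes_to_wild_type_pool(self, hokc):
        m7w, i12s = Substitution.from_string("M7W"), Substitution.from_string("I12S")
        truth = PlantedScreenTruth(
            reference=hokc,
            deleterious_singles=frozenset({m7w, i12s}),
            compensatory_pairs=(frozenset({m7w, i12s}),),
            tolerated_singles=frozenset(),
            depth=50,
            error_rate=0.0,
            seed=0,
        )
        pools = simulate_read_pools(truth)
        result = call_read_pools(pools.wt_reads, pools.mut_reads, hokc)
        pair = VariantGenotype((m7w, i12s))
        assert result.tables.genotype_counts[pair] == (50, 0)
        assert result.tables.genotype_counts[VariantGenotype((m7w,))] == (0, 50)

    def test_phenotype_rule_requires_uncompensated_deleterious(self):
        truth = default_screen_truth(seed=0)
        m7w, i12s = Substitution.from_string("M7W"), Substitution.from_string("I12S")
        k2r = Substitution.from_string("K2R")
        assert truth.phenotype_of(VariantGenotype((m7w,))) == "mutant"
        assert truth.phenotype_of(VariantGenotype((m7w, i12s))) == "wild_type"
        assert truth.phenotype_of(VariantGenotype((k2r,))) == "wild_type"
        # compensated pair plus an extra deleterious single stays mutant
        i14s = Substitution.from_string("I14S")
        assert truth.phenotype_of(VariantGenotype((m7w, i12s, i14s))) == "wild_type"
        v19g = Substitution.from_string("V19G")
        assert truth.phenotype_of(VariantGenotype((m7w, v19g))) == "mutant"

    def test_compensatory_pair_must_contain_deleterious(self, hokc):
        k2r = Substitution.from_string("K2R")
        with pytest.raises(SyntheticDataError):
            PlantedScreenTruth(
                reference=hokc,
                deleterious_singles=frozenset(),
                compensatory_pairs=(frozenset({k2r}),),
                tolerated_singles=frozenset(),
            )

    def test_error_rate_cap(self, hokc):
        with pytest.raises(SyntheticDataError):
            PlantedScreenTruth(
                reference=hokc,
                deleterious_singles=frozenset(),
                compensatory_pairs=(),
                tolerated_singles=frozenset(),
                error_rate=0.2,
            )

    def test_reproducible_per_seed(self):
        truth = default_screen_truth(seed=3, depth=5)
        a, b = simulate_read_pools(truth), simulate_read_pools(truth)
        assert a.wt_reads == b.wt_reads and a.mut_reads == b.mut_reads

    def test_files_written_with_truth_table(self, tmp_path):
        truth = default_screen_truth(seed=1, depth=2)
        paths = simulate_read_pools(truth).write(tmp_path)
        for p in paths.values():
            assert p.exists()


class TestMsaSimulation:
    def test_zero_rates_give_reference_rows(self):
        truth = PlantedMsaTruth(reference="MKQHKA", n_rows=10, background_rate=0.0, seed=0)
        sim = simulate_msa(truth)
        assert all(seq == "MKQHKA" for _, seq in sim.alignment.rows)

    def test_comutation_rate_concentrates(self):
        fractions = []
        for seed in range(5):
            truth = PlantedMsaTruth(
                reference="MKQHKAMIVALIVICITAVV",
                n_rows=200,
                background_rate=0.0,
                correlated_pairs=((7, 12, 0.5),),
                seed=seed,
            )
            sim = simulate_msa(truth)
            aln = sim.alignment
            c7, c12 = aln.column_of(7), aln.column_of(12)
            ref = truth.reference
            co = sum(
                1
                for rid, seq in aln.rows
                if rid != "REF" and seq[c7] != ref[6] and seq[c12] != ref[11]
            )
            fractions.append(co / 200)
            # both-or-neither: no single-sided planted mutation events
            single = sum(
                1
                for rid, seq in aln.rows
                if rid != "REF" and (seq[c7] != ref[6]) != (seq[c12] != ref[11])
            )
            assert single == 0
        # binomial concentration: each seed within ~3.5 sigma, the mean tighter
        assert all(abs(f - 0.5) <= 0.12 for f in fractions)
        assert abs(np.mean(fractions) - 0.5) <= 0.05

    def test_truth_table_matches_alignment(self):
        truth = PlantedMsaTruth(
            reference="MKQHKAMIVA",
            n_rows=50,
            background_rate=0.0,
            correlated_pairs=((2, 9, 0.3),),
            seed=5,
        )
        sim = simulate_msa(truth)
        fired = set(sim.truth_frame[sim.truth_frame.comutated_pairs != ""].row_id)
        aln = sim.alignment
        c2, c9 = aln.column_of(2), aln.column_of(9)
        observed = {
            rid
            for rid, seq in aln.rows
            if rid != "REF" and seq[c2] != "K" and seq[c9] != "V"
        }
        assert fired == observed

    def test_invalid_pairs_rejected(self):
        with pytest.raises(SyntheticDataError):
            PlantedMsaTruth(reference="MKQ", correlated_pairs=((1, 9, 0.5),))
        with pytest.raises(SyntheticDataError):
            PlantedMsaTruth(reference="MKQ", correlated_pairs=((1, 1, 0.5),))


def test_reference_matches_screen_coordinate_labels():
    ref = hokc_reference()
    for label in ["K2", "A6", "M7", "L11", "I12", "V13", "I14", "C15", "T17", "V19", "A21", "A22", "V24"]:
        assert ref.residue(int(label[1:])) == label[0]
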