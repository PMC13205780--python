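"""Ground-truth integrity of the synthetic-data generators."""

import numpy as np
import pytest

from cmcpminer.seq_io import extract_orfs
from cmcpminer.synthetic_data import (
    SimScenario,
    reverse_translate,
    simulate_cohorts,
    simulate_family,
    simulate_genome,
)


class TestSimulateFamily:
    def test_zero_divergence_gives_identical_members(self):
        sc = SimScenario(seed=1, family_size=8, divergence=0.0,
                         protein_length=40)
        fam, truth = simulate_family(sc)
        assert all(m.residues == truth.root_protein for m in fam.members)

    def test_divergence_monotonically_lowers_identity(self):
        means = []
        for d in (0.05, 0.15, 0.30):
            idents = []
            for seed in range(5):
                sc = SimScenario(seed=seed, family_size=10, divergence=d,
                                 protein_length=60)
                fam, truth = simulate_family(sc)
                for m in fam.members:
                    idents.append(np.mean([a == b for a, b in
                                           zip(m.residues, truth.root_protein)]))
            means.append(np.mean(idents))
        assert means[0] > means[1] > means[2]

    def test_seed_reproducibility(self):
        sc = SimScenario(seed=9, family_size=10, divergence=0.2,
                         n_confounders=2, protein_length=50)
        f1, t1 = simulate_family(sc)
        f2, t2 = simulate_family(sc)
        assert [m.residues for m in f1.members] == \
            [m.residues for m in f2.members]
        assert t1.confounder_ids == t2.confounder_ids

    def test_confounders_labelled(self):
        sc = SimScenario(seed=2, family_size=8, n_confounders=3,
                         protein_length=40)
        fam, truth = simulate_family(sc)
        assert len(truth.confounder_ids) == 3
        assert set(truth.confounder_ids) <= set(fam.member_ids)


@pytest.fixture(scope="module")
def genome():
    sc = SimScenario(seed=5, n_families=2, family_size=8,
                     divergence=0.1, protein_length=60,
                     n_contigs=6, contig_length=2500, n_planted_orfs=6)
    fams = [simulate_family(sc, name=f"fam{i+1}", family_index=i)[0]
            for i in range(2)]
    contigs, truth = simulate_genome(sc, fams)
    return contigs, truth


class TestSimulateGenome:
    def test_extraction_recovers_every_plant(self, genome):
        contigs, truth = genome
        orf_proteins = {}
        for c in contigs:
            for o in extract_orfs(c, min_nt=150):
                orf_proteins[(c.id, o.start, o.end, o.strand)] = \
                    o.protein.residues
        for _, row in truth.iterrows():
            key = (row["contig"], row["start"], row["end"], row["strand"])
            assert key in orf_proteins
            assert orf_proteins[key] == row["protein"]

    def test_truth_coordinates_are_codon_aligned(self, genome):
        _, truth = genome
        assert ((truth["end"] - truth["start"] + 1) % 3 == 0).all()
        assert ((truth["end"] - truth["start"] + 1) >= 150).all()

    def test_reverse_translation_round_trips(self, rng):
        from cmcpminer.seq_io import translate
        protein = "MKVLQWERTYHISAKDEFGH"
        nt = reverse_translate(protein, rng)
        assert translate(nt) == protein

    def test_impossible_placement_raises(self):
        sc = SimScenario(seed=5, n_families=1, family_size=8,
                         protein_length=60, n_contigs=1,
                         contig_length=150, n_planted_orfs=1)
        fam, _ = simulate_family(sc)
        with pytest.raises(ValueError, match="too short|overlap"):
            simulate_genome(sc, [fam])


class TestSimulateCohorts:
    def test_null_scenario_has_equal_group_means(self):
        sc = SimScenario(seed=12, n_cohorts=1, n_case=200, n_control=200,
                         n_features=30, dispersion=0.2)
        counts, meta, effects = simulate_cohorts(sc)
        assert all(v == 0.0 for v in effects.values())
        case = meta.index[meta["condition"] == "case"]
        ctrl = meta.index[meta["condition"] == "control"]
        ratio = counts[case].mean(axis=1) / counts[ctrl].mean(axis=1)
        assert 0.85 < ratio.median() < 1.15

    def test_planted_fold_change_reflected_in_group_ratio(self):
        eff = {f"feat{i:04d}": 2.0 for i in range(10)}
        sc = SimScenario(seed=13, n_cohorts=1, n_case=20, n_control=20,
                         n_features=40, dispersion=0.2, planted_effects=eff)
        counts, meta, effects = simulate_cohorts(sc)
        case = meta.index[meta["condition"] == "case"]
        ctrl = meta.index[meta["condition"] == "control"]
        planted = [f for f, v in effects.items() if v != 0]
        ratios = (counts.loc[planted, case].mean(axis=1)
                  / counts.loc[planted, ctrl].mean(axis=1))
        assert 3.2 < ratios.mean() < 5.0

    def test_matrix_is_reproducible_and_integral(self):
        sc = SimScenario(seed=14, n_cohorts=2, n_case=5, n_control=5,
                         n_features=20)
        c1, m1, _ = simulate_cohorts(sc)
        c2, m2, _ = simulate_cohorts(sc)
        assert c1.equals(c2) and m1.equals(m2)
        assert (c1 >= 0).all().all()
        assert (c1 == c1.astype(int)).all().all()

    def test_metadata_covers_every_sample(self):
        sc = SimScenario(seed=15, n_cohorts=3, n_case=4, n_control=6,
                         n_features=10)
        counts, meta, _ = simulate_cohorts(sc)
        assert set(counts.columns) == set(meta.index)
        assert set(meta["condition"]) == {"case", "control"}
        assert meta["cohort"].nunique() == 3

    def test_unknown_planted_feature_rejected(self):
        sc = SimScenario(seed=1, n_features=5,
                         planted_effects={"nope": 2.0})
        with pytest.raises(ValueError, match="unknown features"):
            simulate_cohorts(sc)
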