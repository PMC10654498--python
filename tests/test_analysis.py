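"""Descriptors, fingerprints, latent map and generation summaries."""

import numpy as np
import pytest
from rdkit import Chem

import gapdesign as gd
from gapdesign.analysis import (
    aromaticity_ratio,
    dbe,
    descriptor_table,
    ecfp,
    generation_summary,
    hc_ratio,
    is_fully_aromatic,
    latent_map,
    ring_screen,
)
from gapdesign.db import PopulationDB, PropertyRecord
from gapdesign.errors import DegenerateInput, NoCarbonError


class TestDbe:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("c1ccccc1", 4.0),  # C6H6: 6 - 3 + 1
            ("C", 0.0),
            ("FC(F)(F)F", 0.0),  # 1 - 4/2 + 1
            ("C=Cc1ccccc1", 5.0),  # styrene C8H8
            ("N#CC", 2.0),
            ("C1CC1", 1.0),
        ],
    )
    def test_known_values(self, smiles, expected):
        assert dbe(gd.parse_smiles(smiles)) == expected

    def test_agrees_with_ring_plus_pi_count(self, seed_population):
        """DBE equals rings + double bonds + 2*(triple bonds), counted independently."""
        for smiles in seed_population[:50]:
            mol = Chem.MolFromSmiles(smiles)
            Chem.Kekulize(mol, clearAromaticFlags=True)
            n_rings = len(Chem.GetSSSR(mol))
            n_double = sum(1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE)
            n_triple = sum(1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE)
            assert dbe(gd.parse_smiles(smiles)) == n_rings + n_double + 2 * n_triple

    def test_invariant_under_smiles_rewriting(self, seed_population):
        for smiles in seed_population[:20]:
            variant = Chem.MolToSmiles(Chem.MolFromSmiles(smiles), canonical=False, doRandom=True)
            assert dbe(gd.parse_smiles(variant)) == dbe(gd.parse_smiles(smiles))


class TestRatios:
    def test_benzene(self):
        mol = gd.parse_smiles("c1ccccc1")
        assert hc_ratio(mol) == 1.0
        assert np.isnan(aromaticity_ratio(mol))
        assert is_fully_aromatic(mol)

    def test_ethane(self):
        mol = gd.parse_smiles("CC")
        assert hc_ratio(mol) == 3.0
        assert aromaticity_ratio(mol) == 0.0

    def test_styrene(self):
        assert hc_ratio(gd.parse_smiles("C=Cc1ccccc1")) == 1.0

    def test_toluene_ratio_counts_heteroatom_free_case(self):
        assert aromaticity_ratio(gd.parse_smiles("Cc1ccccc1")) == 6.0

    def test_no_carbon_raises(self):
        with pytest.raises(NoCarbonError):
            hc_ratio(gd.parse_smiles("OO"))


class TestEcfp:
    def test_length_is_2048(self):
        assert ecfp(gd.parse_smiles("CCO")).shape == (2048,)

    def test_canonical_invariance(self):
        assert np.array_equal(ecfp(gd.parse_smiles("CCO")), ecfp(gd.parse_smiles("OCC")))

    def test_distinct_molecules_differ(self):
        assert not np.array_equal(
            ecfp(gd.parse_smiles("c1ccccc1")), ecfp(gd.parse_smiles("c1ccncc1"))
        )


class TestLatentMap:
    def test_duplicated_clusters_have_zero_spread(self):
        a, b = np.zeros(2048), np.zeros(2048)
        a[:5] = 1
        b[10:20] = 1
        fps = np.array([a, a, a, b, b, b])
        lm = latent_map(fps)
        for cluster in (lm.coordinates[:3], lm.coordinates[3:]):
            assert np.allclose(cluster.std(axis=0), 0.0, atol=1e-9)

    def test_explained_variance_non_increasing(self, seed_population):
        fps = np.array([ecfp(gd.parse_smiles(s)) for s in seed_population[:40]])
        lm = latent_map(fps)
        assert lm.explained_variance[0] >= lm.explained_variance[1]
        assert lm.coordinates.shape == (40, 2)

    def test_matches_independent_eigendecomposition(self):
        """Coordinates agree with a brute-force covariance eigensolver."""
        rng = np.random.default_rng(2)
        fps = (rng.random((10, 32)) > 0.5).astype(float)
        lm = latent_map(fps)
        centered = fps - fps.mean(axis=0)
        cov = centered.T @ centered / (fps.shape[0] - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1][:2]
        expected = centered @ eigvecs[:, order]
        for k in range(2):
            col = expected[:, k]
            load = eigvecs[:, order[k]]
            if load[np.argmax(np.abs(load))] < 0:
                col = -col
            assert np.allclose(lm.coordinates[:, k], col, atol=1e-8)

    def test_degenerate_input_raises(self):
        fps = np.ones((5, 64))
        with pytest.raises(DegenerateInput):
            latent_map(fps)


class TestRingScreen:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("C1CCCCC1", True),
            ("C1CCC1", False),
            ("CCCCCC", True),  # acyclic: vacuously true
            ("C1CCCCCC1", False),  # 7-ring strained out
            ("c1ccc2ccccc2c1", True),  # fused 6-rings
            ("C1CC1c1ccccc1", False),  # one bad ring taints the molecule
        ],
    )
    def test_screen(self, smiles, expected):
        assert ring_screen(gd.parse_smiles(smiles)) is expected


class TestTables:
    def test_descriptor_table_columns(self, seed_population):
        pairs = [(s, float(i)) for i, s in enumerate(seed_population[:10])]
        table = descriptor_table(pairs)
        assert len(table) == 10
        assert {"canonical_smiles", "gap_eV", "hc_ratio", "aromaticity_ratio",
                "dbe", "n_heavy", "ring_screen"} <= set(table.columns)

    def test_generation_summary_partitions_db(self):
        db = PopulationDB()
        for i, (gen, gap) in enumerate([(0, 2.0), (0, 4.0), (1, 1.0), (1, 3.0), (1, 5.0)]):
            db.add(PropertyRecord(smiles="C" * (i + 1), gap=gap, generation=gen, split="train"))
        table = generation_summary(db)
        assert table["n_molecules"].sum() == len(db)
        assert table.loc[table.generation == 0, "mean_gap_eV"].item() == 3.0
        # strict inequality: generation 0 never counts below its own minimum
        assert table.loc[table.generation == 0, "count_below_seed_min"].item() == 0
        assert table.loc[table.generation == 1, "count_below_seed_min"].item() == 1
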