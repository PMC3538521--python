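"""Descriptor panel: frozen examples, structural identities, enumeration
oracles and atom-order invariance."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from molprofiler import descriptors as D
from molprofiler.molgraph import MoleculeError, parse_smiles, perceive_rings

from conftest import FIXTURE_SMILES, enumerate_subgraph_counts


def dv(smiles):
    return D.compute_all(parse_smiles(smiles))


class TestComposition:
    def test_benzene(self):
        v = dv("c1ccccc1")
        assert v["N_C"] == 6 and v["N_Atom"] == 6 and v["N_Bonds"] == 6
        assert v["MW"] == pytest.approx(78.11, abs=0.01)

    def test_formal_charge_counts_and_halogens(self):
        zw = dv("C(C(=O)[O-])[NH3+]")
        assert zw["N_positive"] == 1 and zw["N_negative"] == 1
        assert dv("C(Cl)(Cl)Cl")["N_Halogen"] == 3


class TestHBondsAndRotatable:
    @pytest.mark.parametrize("smi,hbd,hba,hbdl,hbal", [
        ("CCO", 1, 1, 1, 1),
        ("CC(N)=O", 1, 1, 2, 2),       # amide N excluded from generic acceptors
        ("c1ccccc1", 0, 0, 0, 0),
        ("c1cc[nH]c1", 1, 0, 1, 1),    # pyrrole N: donor but no acceptor
    ])
    def test_hbond_variants(self, smi, hbd, hba, hbdl, hbal):
        v = dv(smi)
        assert (v["N_HBD"], v["N_HBA"], v["N_HBDL"], v["N_HBAL"]) == (hbd, hba, hbdl, hbal)

    @pytest.mark.parametrize("smi,nrot", [
        ("CCO", 0), ("CCCC", 1), ("c1ccccc1", 0),
        ("CC(=O)NC", 0),               # amide C-N excluded
        ("CCOCC", 2),
    ])
    def test_rotatable_bond_rule(self, smi, nrot):
        assert dv(smi)["N_rot"] == nrot


class TestRingDescriptors:
    def test_norbornane_bridged_system(self):
        v = dv("C1CC2CCC1C2")
        assert v["N_Rings"] == 2 and v["N_R5"] == 2
        assert v["N_Bridge"] == 8 and v["N_BHA"] == 2 and v["N_Spiro"] == 0

    def test_decalin_simple_fusion_is_not_bridged(self):
        v = dv("C1CCC2CCCCC2C1")
        assert v["N_Rings"] == 2 and v["N_Bridge"] == 0 and v["N_BHA"] == 0
        assert v["N_RA"] == 1

    def test_spiro_nonane(self):
        v = dv("C1CCC2(C1)CCCC2")
        assert v["N_Spiro"] == 1 and v["N_Bridge"] == 0

    def test_adamantane_fully_bridged(self):
        v = dv("C1C2CC3CC1CC(C2)C3")
        assert v["N_Rings"] == 3 and v["N_Bridge"] == 12 and v["N_BHA"] == 4

    def test_ring_identities_over_fixture_set(self, fixture_mols):
        for m in fixture_mols:
            v = D.compute_all(m) if len(m.components()) == 1 else None
            if v is None:
                continue
            ring_sum = sum(v[f"N_R{k}"] for k in range(3, 9)) + v["N_R9+"]
            assert ring_sum == v["N_Rings"], m.smiles
            assert v["N_AR"] <= v["N_Rings"]
            assert v["N_aromatic"] <= v["N_Ringb"] <= v["N_Bonds"]
            assert v["N_BHA"] <= v["N_Atom"]


class TestChainsAndStereo:
    def test_toluene_methyl_is_the_only_chain_atom(self):
        v = dv("Cc1ccccc1")
        assert v["N_ChainA"] == 1 and v["N_Chains"] == 4  # CH3 with hydrogens

    @pytest.mark.parametrize("smi,n_stereo", [
        ("FC(Cl)Br", 1),            # four distinct substituents incl. H
        ("CC(C)C", 0),
        ("CC(N)C(=O)O", 1),         # alanine backbone
        ("OCC1OC(O)C(O)C(O)C1O", 5),
    ])
    def test_potential_stereocenters(self, smi, n_stereo):
        assert dv(smi)["N_Stereo"] == n_stereo

    @pytest.mark.parametrize("smi,n_sb", [
        ("CC=CC", 1), ("C=C", 0), ("CC=C(C)C", 0), ("CC=CCC=CC", 2),
    ])
    def test_potential_ez_bonds(self, smi, n_sb):
        assert dv(smi)["N_StereoB"] == n_sb


class TestSubgraphCounts:
    def test_benzene_frozen_values(self):
        v = dv("c1ccccc1")
        assert (v["SC0"], v["SC1"], v["SC2"], v["SC3P"], v["SC3C"], v["SC3CH"]) \
            == (6, 6, 6, 6, 0, 0)

    def test_neopentane_frozen_values(self):
        # enumeration oracle: 6 two-edge paths, 4 stars (choose 3 of the
        # central atom's 4 bonds), no 3-edge paths, no triangles
        v = dv("CC(C)(C)C")
        assert (v["SC2"], v["SC3P"], v["SC3C"], v["SC3CH"]) == (6, 0, 4, 0)

    def test_cyclopropane_one_triangle(self):
        v = dv("C1CC1")
        assert v["SC3CH"] == 1 and v["SC3CH"] == v["N_R3"]

    def test_matches_enumeration_oracle_on_small_fixtures(self, fixture_mols):
        checked = 0
        for m in fixture_mols:
            if m.n_atoms > 12 or len(m.components()) != 1:
                continue
            got = D.subgraph_counts(m)
            want = enumerate_subgraph_counts(m)
            for k, v in want.items():
                assert got[k] == v, f"{m.smiles}: {k}"
            checked += 1
        assert checked >= 30


class TestHydrophobicityAndPSA:
    def test_methane_is_pure_atom_contributions(self):
        from molprofiler.config import load
        t = load("crippen_logp")["contributions"]
        assert dv("C")["AlogP"] == pytest.approx(t["C.sp3"] + 4 * t["H.C"])

    def test_chain_growth_raises_logp_and_hydroxyl_lowers_it(self):
        assert dv("CCCCCC")["AlogP"] > dv("CC")["AlogP"]
        assert dv("CCCO")["AlogP"] < dv("CCC")["AlogP"]

    def test_psa_zero_without_heteroatoms_and_ordering(self):
        assert dv("c1ccccc1")["PSA"] == 0.0
        assert dv("CCO")["PSA"] > dv("CCOCC")["PSA"] > 0

    def test_logd_equals_alogp_without_ionizable_groups(self):
        v = dv("c1ccccc1")
        assert v["logD7.4"] == pytest.approx(v["AlogP"])

    def test_acid_penalty_applies_at_ph74(self):
        aspirin = dv("CC(=O)Oc1ccccc1C(=O)O")
        ester = dv("CC(=O)Oc1ccccc1C(=O)OC")
        assert aspirin["logD7.4"] < aspirin["AlogP"]
        assert ester["logD7.4"] == pytest.approx(ester["AlogP"])

    def test_logs_decreases_with_mw_at_fixed_other_terms(self):
        # homologous series: AlogP and MW both rise, logS must fall
        assert dv("CCCCCCCC")["logS"] < dv("CCCC")["logS"]


class TestSurfaceAndRatioDescriptors:
    def test_sign_partition_and_zero_charge_rule(self, fixture_mols):
        for m in fixture_mols[::4]:
            if len(m.components()) != 1:
                continue
            v = D.compute_all(m)
            assert 0 <= v["FASA+"] + v["FASA-"] <= 1 + 1e-9, m.smiles
            assert v["FASA_H"] + v["FASA_P"] == pytest.approx(1.0)
            assert v["FVSA_H"] + v["FVSA_P"] == pytest.approx(1.0)

    def test_homonuclear_molecule_has_no_signed_area(self):
        v = dv("S1SSSSSSS1")
        assert v["FASA+"] == 0.0 and v["FASA-"] == 0.0

    def test_oxygen_raises_fasa_minus(self):
        assert dv("CCO")["FASA-"] > dv("CCCCCC")["FASA-"]

    def test_c3p_and_unc_c3(self):
        cyclohexane = dv("C1CCCCC1")
        assert cyclohexane["C3P"] == 1.0 and cyclohexane["UNC_C3"] == 0.0
        benzene = dv("c1ccccc1")
        assert benzene["C3P"] == 0.0 and benzene["UNC_C3"] == 0.0
        assert benzene.is_flagged("UNC_C3")
        styrene = dv("C=Cc1ccccc1")
        assert styrene.is_flagged("UNC_C3") and styrene["UNC_C3"] == 0.0

    def test_f_rot_is_rotatable_fraction(self):
        v = dv("CCCCC")
        assert v["f_rot"] == pytest.approx(v["N_rot"] / v["N_Bonds"])


class TestFullPanel:
    def test_schema_has_exactly_sixty_names(self):
        v = dv("CC(=O)Nc1ccc(O)cc1")
        assert list(v.values) == D.DESCRIPTOR_NAMES
        assert len(v.values) == 60

    def test_identities_sc0_sc1_sc3ch(self, fixture_mols):
        for m in fixture_mols:
            if len(m.components()) != 1:
                continue
            v = D.compute_all(m)
            assert v["SC0"] == v["N_Atom"]
            assert v["SC1"] == v["N_Bonds"]
            assert v["SC3CH"] == v["N_R3"], m.smiles

    def test_multifragment_input_rejected(self):
        with pytest.raises(MoleculeError):
            dv("CC(=O)O.[Na+]")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        smi=st.sampled_from([s for s in FIXTURE_SMILES if "." not in s]),
        seed=st.integers(0, 2**16),
    )
    def test_atom_order_invariance(self, smi, seed):
        mol = parse_smiles(smi)
        perm = list(range(mol.n_atoms))
        random.Random(seed).shuffle(perm)
        v1 = D.compute_all(mol)
        v2 = D.compute_all(mol.permute(perm))
        for k in D.DESCRIPTOR_NAMES:
            assert v1[k] == pytest.approx(v2[k], abs=1e-9), k

    def test_table_encodes_flags_as_nan(self):
        table = D.compute_table([parse_smiles("c1ccccc1"), parse_smiles("CCO")])
        assert math.isnan(table.loc[0, "UNC_C3"])
        assert "UNC_C3" in table.loc[0, "flags"]
        assert not math.isnan(table.loc[1, "UNC_C3"])


class TestClassContrasts:
    def test_natural_class_is_oxygen_rich_nitrogen_poor(self, benchmark_tables):
        nat = benchmark_tables["naturallike"]
        drug = benchmark_tables["druglike"]
        assert nat["N_O"].mean() > drug["N_O"].mean()
        assert nat["N_N"].mean() < drug["N_N"].mean()
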