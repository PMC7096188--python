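"""Stage-by-stage and end-to-end tests of the curation pipeline."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from monopka.chem_io import MoleculeRecord, PkaMeasurement, read_sdf
from monopka.curation import (
    CurationConfig,
    LookupPkaPredictor,
    RuleBasedPkaPredictor,
    deduplicate_test_against_train,
    element_and_group_filter,
    lipinski_filter,
    lipinski_violations,
    merge_duplicates,
    monoprotic_filter,
    pka_window_filter,
    protonate_at_ph,
    remove_prediction_outliers,
    run_curation,
    standardize_tautomer,
    strip_salts,
)
from monopka.chem_io import CuratedEntry

CFG = CurationConfig()


def smiles_of(m):
    return Chem.MolToSmiles(m)


class TestStripSalts:
    def test_sodium_acetate_keeps_acetate(self, mol):
        out = strip_salts(mol("CC(=O)[O-].[Na+]"))
        assert smiles_of(out) == "CC(=O)[O-]"

    def test_single_fragment_unchanged(self, mol):
        m = mol("c1ccccc1")
        assert strip_salts(m) is m

    def test_largest_organic_fragment_wins(self, mol):
        """12- vs 5-heavy-atom organic fragments: enumeration oracle."""
        m = mol("c1ccc2ccccc2c1CC.CCCCC")  # 12 vs 5 heavy atoms
        frags = Chem.GetMolFrags(m, asMols=True)
        expected = max(frags, key=lambda f: f.GetNumHeavyAtoms())
        assert smiles_of(strip_salts(m)) == smiles_of(expected)

    def test_pure_inorganic_is_drop_signal(self, mol):
        assert strip_salts(mol("[Na+].[Cl-]")) is None


class TestElementAndGroupFilter:
    @pytest.mark.parametrize("smiles,keep,reason_part", [
        ("O=[N+]([O-])c1ccccc1", False, "nitro"),       # charge-separated
        ("O=N(=O)c1ccccc1", False, "nitro"),             # pentavalent depiction
        ("CCB(CC)CC", False, "element B"),
        ("C[Se]C", False, "element Se"),
        ("C[Si](C)(C)C", False, "element Si"),
        ("Cn1cnc2c1c(=O)n(C)c(=O)n2C", True, None),      # caffeine
        ("c1ccccc1", True, None),
    ])
    def test_rules(self, mol, smiles, keep, reason_part):
        got_keep, reason = element_and_group_filter(mol(smiles), CFG)
        assert got_keep is keep
        if reason_part:
            assert reason_part in reason

    def test_caffeine_clean_by_substructure_scan(self, mol):
        """Independent oracle: no atom is B/Se/Si and no N has two O neighbours
        both double/charged in the nitro arrangement."""
        m = mol("Cn1cnc2c1c(=O)n(C)c(=O)n2C")
        assert all(a.GetSymbol() not in {"B", "Se", "Si"} for a in m.GetAtoms())
        for atom in m.GetAtoms():
            if atom.GetSymbol() == "N":
                o_neighbours = [n for n in atom.GetNeighbors()
                                if n.GetSymbol() == "O"]
                assert len(o_neighbours) < 2


class TestLipinskiFilter:
    def test_ethanol_descriptors_independently_computed(self, mol):
        """MW 46.07, logP < 5, 1 donor, 1 acceptor -> zero violations."""
        from rdkit.Chem import Descriptors, Lipinski
        m = mol("CCO")
        assert Descriptors.MolWt(m) == pytest.approx(46.069, abs=0.01)
        assert Lipinski.NumHDonors(m) == 1
        assert Lipinski.NumHAcceptors(m) == 1
        keep, n = lipinski_filter(m, CFG)
        assert keep and n == 0

    def test_one_violation_allowed(self, mol):
        # hexadecane: logP > 5 only (MW 226, no donors/acceptors)
        keep, n = lipinski_filter(mol("C" * 16), CFG)
        assert keep and n == 1

    def test_two_violations_dropped(self, mol):
        # C40 alkane: MW 563 > 500 and logP >> 5
        keep, n = lipinski_filter(mol("C" * 40), CFG)
        assert not keep and n == 2


class TestPkaWindow:
    @pytest.mark.parametrize("value,keep", [
        (1.9, False), (7.4, True), (12.0, True), (2.0, True),
        (12.01, False), (2.0 - 1e-9, False),
    ])
    def test_inclusive_bounds(self, value, keep):
        assert pka_window_filter(value, CFG) is keep


class TestTautomerStandardization:
    def test_pyridone_pair_converges(self, mol):
        a = standardize_tautomer(mol("O=c1cccc[nH]1"))   # 2-pyridone
        b = standardize_tautomer(mol("Oc1ccccn1"))        # 2-hydroxypyridine
        assert smiles_of(a) == smiles_of(b)

    def test_idempotent_on_fixture_molecules(self):
        from monopka.fixtures import CLEAN_MOLECULES
        for smiles, _ in CLEAN_MOLECULES:
            once = standardize_tautomer(Chem.MolFromSmiles(smiles))
            twice = standardize_tautomer(once)
            assert smiles_of(once) == smiles_of(twice)

    def test_adapter_output_used_verbatim(self, mol):
        marker = mol("C")
        out = standardize_tautomer(mol("Oc1ccccn1"), adapter=lambda m: marker)
        assert out is marker


class TestProtonation:
    @pytest.mark.parametrize("smiles,expected", [
        ("CC(=O)O", "CC(=O)[O-]"),          # acetic acid -> acetate
        ("CN", "C[NH3+]"),                   # methylamine -> methylammonium
        ("c1ccccc1", "c1ccccc1"),            # no ionizable group
        ("CS(=O)(=O)O", "CS(=O)(=O)[O-]"),   # methanesulfonic acid
        ("Nc1ccccc1", "Nc1ccccc1"),          # aniline stays neutral at 7.4
    ])
    def test_default_rules(self, mol, smiles, expected):
        assert smiles_of(protonate_at_ph(mol(smiles), CFG)) == expected

    def test_idempotent(self, mol):
        for smiles in ("CC(=O)O", "CN", "CCN(CC)CC", "CS(=O)(=O)O",
                       "NC(=N)c1ccccc1"):
            once = protonate_at_ph(mol(smiles), CFG)
            twice = protonate_at_ph(once, CFG)
            assert smiles_of(once) == smiles_of(twice)


class TestMonoproticFilter:
    def test_single_prediction_kept(self, mol):
        m = mol("c1ccccc1")
        predictor = LookupPkaPredictor({smiles_of(m): [4.2]})
        assert monoprotic_filter(m, predictor, CFG)

    def test_two_predictions_dropped(self, mol):
        m = mol("c1ccccc1")
        predictor = LookupPkaPredictor({smiles_of(m): [3.1, 9.8]})
        assert not monoprotic_filter(m, predictor, CFG)

    def test_zero_predictions_kept(self, mol):
        """The literal rule is "not more than one": zero passes."""
        m = mol("c1ccccc1")
        assert monoprotic_filter(m, LookupPkaPredictor({}), CFG)

    def test_out_of_window_predictions_ignored(self, mol):
        m = mol("c1ccccc1")
        predictor = LookupPkaPredictor({smiles_of(m): [1.0, 7.0, 13.0]})
        assert monoprotic_filter(m, predictor, CFG)

    def test_rule_based_default_on_known_groups(self, mol):
        predictor = RuleBasedPkaPredictor()
        # glutamic-acid-like: two carboxylic acids + amine = multiprotic
        assert not monoprotic_filter(mol("NC(CCC(=O)O)C(=O)O"), predictor, CFG)
        assert monoprotic_filter(mol("Oc1ccccc1"), predictor, CFG)


class TestPredictionOutliers:
    def test_boundary_is_strict(self, mol):
        m = mol("c1ccccc1")
        predictor = LookupPkaPredictor({smiles_of(m): [7.5]})
        kept = remove_prediction_outliers([(m, 3.5)], predictor, CFG)
        assert len(kept) == 1  # |7.5-3.5| = 4.0, not strictly greater
        predictor = LookupPkaPredictor({smiles_of(m): [8.0]})
        assert remove_prediction_outliers([(m, 3.5)], predictor, CFG) == []

    def test_engineered_set_oracle(self, mol, rng):
        """30 entries, 6 engineered beyond the cut -> 24 kept."""
        m = mol("c1ccccc1")
        predictor = LookupPkaPredictor({smiles_of(m): [7.0]})
        values = list(7.0 + rng.uniform(-3.5, 3.5, size=24))
        values += [7.0 + 4.5, 7.0 - 4.5, 11.5, 2.5, 11.2, 2.8]
        # oracle: per-entry check with plain arithmetic
        expected = [v for v in values if abs(7.0 - v) <= 4.0]
        assert len(expected) == 24
        kept = remove_prediction_outliers([(m, v) for v in values],
                                          predictor, CFG)
        assert [v for _, v in kept] == expected

    def test_unpredicted_structures_pass_through(self, mol):
        m = mol("c1ccccc1")
        kept = remove_prediction_outliers([(m, 3.0)], LookupPkaPredictor({}), CFG)
        assert len(kept) == 1


class TestMergeDuplicates:
    def test_singleton(self):
        entries = merge_duplicates({"CCO": [7.1]})
        assert entries[0].pka == pytest.approx(7.1)
        assert entries[0].n_used == 1 and entries[0].n_removed == 0

    def test_hand_derived_outlier_case(self):
        """[4.0 x5, 9.0]: mean 4.833, pop SD 1.863 / sample SD 2.041;
        9.0 deviates by 4.167 > 2*SD under either convention -> removed."""
        entries = merge_duplicates({"CCO": [4.0] * 5 + [9.0]})
        assert entries[0].pka == pytest.approx(4.0)
        assert entries[0].n_used == 5 and entries[0].n_removed == 1

    def test_size_two_skips_sd_step(self):
        entries = merge_duplicates({"CCO": [6.0, 6.2]})
        assert entries[0].pka == pytest.approx(6.1)
        assert entries[0].n_used == 2

    def test_identical_values_all_kept(self):
        entries = merge_duplicates({"CCO": [5.0, 5.0, 5.0, 5.0]})
        assert entries[0].pka == 5.0 and entries[0].n_used == 4

    @settings(deadline=None, max_examples=50)
    @given(values=st.lists(st.floats(min_value=2.0, max_value=12.0,
                                     allow_nan=False), min_size=1, max_size=8),
           seed=st.integers(0, 1000))
    def test_order_invariance_and_bounds(self, values, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(values))
        a = merge_duplicates({"CCO": values})[0]
        b = merge_duplicates({"CCO": shuffled})[0]
        assert a.pka == pytest.approx(b.pka)
        assert a.n_used == b.n_used
        # the aggregated value lies within the retained values' range
        assert min(values) - 1e-12 <= a.pka <= max(values) + 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            merge_duplicates({"CCO": []})


class TestDeduplicateTestAgainstTrain:
    def _entries(self, smiles_values):
        return [CuratedEntry(s, v) for s, v in smiles_values]

    def test_disjoint_unchanged(self):
        test = self._entries([("CCO", 5.0), ("c1ccccc1", 6.0)])
        train = self._entries([("c1ccncc1", 5.2)])
        assert deduplicate_test_against_train(test, train) == test

    def test_subset_gives_empty(self):
        test = self._entries([("CCO", 5.0)])
        train = self._entries([("CCO", 4.9), ("c1ccccc1", 6.0)])
        assert deduplicate_test_against_train(test, train) == []

    def test_engineered_overlaps_removed(self):
        from monopka.fixtures import CLEAN_MOLECULES
        pool = [s for s, _ in CLEAN_MOLECULES]
        test = self._entries([(s, 5.0) for s in pool[:20]])
        train = self._entries([(s, 5.0) for s in pool[5:8]])  # 3 overlaps
        cleaned = deduplicate_test_against_train(test, train)
        assert len(cleaned) == 17
        assert not ({e.canonical_smiles for e in cleaned}
                    & {e.canonical_smiles for e in train})


class TestRunCuration:
    def test_fixture_manifest_is_the_oracle(self, curation_fixture):
        """Every record's fate matches the construction-time manifest."""
        records, _ = read_sdf(curation_fixture.sdf_path)
        entries, report = run_curation(records,
                                       predictor=curation_fixture.predictor)
        manifest = curation_fixture.manifest
        expected = curation_fixture.expected_survivors
        got = {e.canonical_smiles: e for e in entries}
        assert set(got) == set(expected.base_smiles)
        for _, row in expected.iterrows():
            assert got[row.base_smiles].pka == pytest.approx(row.expected_pka,
                                                             abs=1e-9)
            assert got[row.base_smiles].n_used == row.expected_n_used
        # per-stage drop counts match the manifest's fate labels
        drops = {s.stage: len(s.drops) for s in report.stages}
        fates = manifest.expected_fate.value_counts()
        for stage, n in fates.items():
            if stage != "survive":
                assert drops[stage] == n, stage

    def test_counts_telescope_and_drops_attributable(self, curation_fixture):
        records, _ = read_sdf(curation_fixture.sdf_path)
        _, report = run_curation(records, predictor=curation_fixture.predictor)
        for prev, nxt in itertools.pairwise(report.stages):
            assert prev.n_out == nxt.n_in
        for stage in report.stages[:-1]:  # merge stage groups, others filter
            assert stage.n_in == stage.n_out + len(stage.drops)

    def test_empty_input(self):
        entries, report = run_curation([])
        assert entries == []
        assert all(s.n_in == s.n_out == 0 for s in report.stages)

    def test_pipeline_idempotent_on_entries(self, curation_fixture):
        records, _ = read_sdf(curation_fixture.sdf_path)
        entries, _ = run_curation(records, predictor=curation_fixture.predictor)
        rerun_records = [
            MoleculeRecord(e.mol, "user", [PkaMeasurement(e.pka)],
                           e.canonical_smiles) for e in entries]
        entries2, _ = run_curation(rerun_records,
                                   predictor=curation_fixture.predictor)
        assert {(e.canonical_smiles, round(e.pka, 9)) for e in entries} == \
               {(e.canonical_smiles, round(e.pka, 9)) for e in entries2}

    def test_deterministic_rerun(self, curation_fixture):
        records, _ = read_sdf(curation_fixture.sdf_path)
        a, _ = run_curation(records, predictor=curation_fixture.predictor)
        b, _ = run_curation(records, predictor=curation_fixture.predictor)
        assert [(e.canonical_smiles, e.pka) for e in a] == \
               [(e.canonical_smiles, e.pka) for e in b]


def test_config_validation():
    with pytest.raises(ValueError):
        CurationConfig(pka_min=12.0, pka_max=2.0)
    with pytest.raises(ValueError):
        CurationConfig(sd_multiplier=-1.0)
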