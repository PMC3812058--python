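"""Parsing, contact detection, pocket extraction, and curation filters."""

import numpy as np
import pytest

from pocketspace import structure_io as sio
from pocketspace import synthetic_data as sd
from pocketspace.errors import DomainError, EmptyPocketError
from conftest import PDB_ALTLOC, PDB_MINIMAL, PDB_WITH_HYDROGENS, random_rotation


@pytest.fixture
def minimal_structure(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(PDB_MINIMAL)
    return sio.parse_structure(str(path))


class TestParsing:
    def test_minimal_pdb(self, minimal_structure):
        st = minimal_structure
        assert len(st.chains) == 1
        assert len(st.chains[0].residues) == 3
        assert [r.aa for r in st.chains[0].residues] == ["A", "A", "A"]
        assert len(st.het_groups) == 1  # water excluded
        assert st.het_groups[0].het_code == "XYZ"
        assert len(st.het_groups[0].atoms) == 12
        assert st.deposition_year == 2012
        assert st.resolution == pytest.approx(1.8)

    def test_hydrogens_ignored(self, tmp_path, minimal_structure):
        path = tmp_path / "withh.pdb"
        path.write_text(PDB_WITH_HYDROGENS)
        st = sio.parse_structure(str(path))
        assert len(st.chains[0].residues[0].atoms) == len(
            minimal_structure.chains[0].residues[0].atoms
        )
        assert len(st.het_groups[0].atoms) == 12

    def test_altloc_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(PDB_ALTLOC)
        st = sio.parse_structure(str(path))
        ca = st.chains[0].residues[0].atom("CA")
        assert ca.pos[0] == pytest.approx(0.0)  # occupancy 0.6 conformer kept

    def test_unreadable_or_proteinless_file(self, tmp_path):
        path = tmp_path / "junk.pdb"
        path.write_text("\x00\x01 not a pdb at all\n")
        with pytest.raises((sio.ParseError, sio.EmptyStructureError)):
            sio.parse_structure(str(path))


class TestContacts:
    def test_threshold_rule(self):
        """C-C contact iff distance < 1.70 + 1.70 + 2.8 = 6.20 A."""
        def build(d):
            res = sio.ProteinResidue(
                "A", "A", 1, "", [sio.AtomRecord("CA", "C", np.zeros(3))]
            )
            st = sio.Structure("TEST", None, None, [sio.Chain("A", [res])], [])
            het = sio.HetGroup("LIG", 1, "L", 1,
                               [sio.AtomRecord("C1", "C", np.array([d, 0.0, 0.0]))])
            return st, het

        st, het = build(6.1)
        assert len(sio.find_contacts(st, het)) == 1
        st, het = build(6.3)
        assert len(sio.find_contacts(st, het)) == 0
        st, het = build(1e-9)  # coincident atoms still recorded
        recs = sio.find_contacts(st, het)
        assert len(recs) == 1 and recs[0].distance < 1e-6

    def test_exhaustive_double_loop_oracle(self):
        """KD-tree contact search matches a brute-force distance check."""
        st, _ = sd.make_complex(n_contact_residues=13, seed=11)
        het = st.het_groups[0]
        found = {
            (c.residue_key, c.protein_atom.name, c.ligand_atom.name)
            for c in sio.find_contacts(st, het)
        }
        brute = set()
        for ch in st.chains:
            for res in ch.residues:
                for a in res.atoms:
                    for la in het.atoms:
                        if np.linalg.norm(a.pos - la.pos) < 1.70 + 1.70 + 2.8:
                            brute.add((res.key, a.name, la.name))
        assert found == brute

    def test_missing_radius_raises(self):
        res = sio.ProteinResidue("A", "A", 1, "", [sio.AtomRecord("CA", "C", np.zeros(3))])
        st = sio.Structure("TEST", None, None, [sio.Chain("A", [res])], [])
        het = sio.HetGroup("LIG", 1, "L", 1,
                           [sio.AtomRecord("X1", "XX", np.array([3.0, 0, 0]))])
        with pytest.raises(sio.ConfigurationError):
            sio.find_contacts(st, het, fallback_radius=None)
        assert len(sio.find_contacts(st, het)) == 1  # default fallback radius


class TestPocketExtraction:
    def test_constructed_contact_count(self):
        st, expected = sd.make_complex(n_contact_residues=15, seed=3)
        pocket = sio.extract_pocket(st, st.het_groups[0])
        assert pocket.L == 15
        assert sorted(r.key for r in pocket.residues) == sorted(expected)

    def test_distant_ligand_is_empty_pocket(self):
        st, _ = sd.make_complex(n_contact_residues=12, seed=3, displace_ligand=50.0)
        with pytest.raises(EmptyPocketError):
            sio.extract_pocket(st, st.het_groups[0])

    def test_two_chain_pocket_and_primary_chain(self):
        st, expected = sd.make_complex(n_contact_residues=12, seed=5, split_chain_at=4)
        pocket = sio.extract_pocket(st, st.het_groups[0])
        chains = {r.chain_id for r in pocket.residues}
        assert chains == {"A", "B"}
        counts = {c: sum(r.chain_id == c for r in pocket.residues) for c in chains}
        assert pocket.primary_chain == max(sorted(counts), key=lambda c: counts[c])

    def test_rigid_invariance(self):
        """The extracted residue set is unchanged by rotating the whole complex."""
        st, _ = sd.make_complex(n_contact_residues=14, seed=8)
        keys = {r.key for r in sio.extract_pocket(st, st.het_groups[0]).residues}
        R = random_rotation(np.random.default_rng(4))
        t = np.array([11.0, -7.0, 3.0])
        for ch in st.chains:
            for res in ch.residues:
                for a in res.atoms:
                    a.pos = R @ a.pos + t
        for a in st.het_groups[0].atoms:
            a.pos = R @ a.pos + t
        keys2 = {r.key for r in sio.extract_pocket(st, st.het_groups[0]).residues}
        assert keys == keys2


class TestSequenceIdentity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("ACDEF", "ACDEF", 1.0), ("ACDEF", "ACDEG", 0.8), ("AAAA", "CCCC", 0.0)],
    )
    def test_examples(self, a, b, expected):
        assert sio.sequence_identity(a, b) == pytest.approx(expected)

    def test_symmetry_and_shorter_denominator(self):
        a, b = "ACDEFGHIKL", "ACDEF"
        assert sio.sequence_identity(a, b) == sio.sequence_identity(b, a) == 1.0

    def test_empty_sequence(self):
        with pytest.raises(DomainError):
            sio.sequence_identity("", "ACD")


class TestCuration:
    @staticmethod
    def _entries(**overrides):
        """Synthetic complexes: same geometry/sequence (seed), varying metadata."""
        defaults = dict(n_contact_residues=13, seed=21)
        defaults.update(overrides)
        return sd.make_complex(**defaults)[0]

    def test_ligand_atom_window(self):
        small = self._entries(entry_id="E1", n_ligand_atoms=9)
        ok = self._entries(entry_id="E2", n_ligand_atoms=10)
        assert sio.curate_dataset([small]) == []
        assert len(sio.curate_dataset([ok])) == 1

    def test_pocket_size_threshold(self):
        ten = self._entries(entry_id="E1", n_contact_residues=10)
        eleven = self._entries(entry_id="E2", n_contact_residues=11)
        assert sio.curate_dataset([ten]) == []
        kept = sio.curate_dataset([eleven])
        assert len(kept) == 1 and kept[0].L == 11

    def test_redundant_entry_resolution_tiebreak(self):
        """Identical chains + same HET code: only the better-resolution pocket survives."""
        lo = self._entries(entry_id="AAAA", resolution=1.8)
        hi = self._entries(entry_id="BBBB", resolution=2.5)
        kept = sio.curate_dataset([lo, hi])
        assert [p.entry_id for p in kept] == ["AAAA"]

    def test_different_ligands_both_kept(self):
        a = self._entries(entry_id="AAAA", het_code="LG1")
        b = self._entries(entry_id="BBBB", het_code="LG2")
        assert len(sio.curate_dataset([a, b])) == 2

    def test_unrelated_sequences_not_clustered(self):
        a = self._entries(entry_id="AAAA", seed=21)
        b = self._entries(entry_id="BBBB", seed=77)  # different random sequence
        assert len(sio.curate_dataset([a, b])) == 2

    def test_idempotence(self):
        structures = [
            self._entries(entry_id="AAAA", resolution=1.8),
            self._entries(entry_id="BBBB", resolution=2.5),
            self._entries(entry_id="CCCC", seed=77),
        ]
        kept = sio.curate_dataset(structures)
        kept_ids = {p.entry_id for p in kept}
        again = sio.curate_dataset([s for s in structures if s.entry_id in kept_ids])
        assert [p.pocket_id for p in again] == [p.pocket_id for p in kept]

    def test_curated_invariants(self):
        structures = [
            self._entries(entry_id="AAAA"),
            self._entries(entry_id="BBBB", seed=77, n_contact_residues=15),
        ]
        for p in sio.curate_dataset(structures):
            assert p.L >= 11
            assert len({r.key for r in p.residues}) == p.L


class TestPocketIO:
    def test_json_round_trip(self, tmp_path):
        st, _ = sd.make_complex(n_contact_residues=12, seed=2)
        pocket = sio.extract_pocket(st, st.het_groups[0])
        path = tmp_path / "pockets.json"
        sio.write_pockets_json([pocket], str(path))
        back = sio.read_pockets_json(str(path))
        assert len(back) == 1
        assert back[0].pocket_id == pocket.pocket_id
        assert np.allclose(back[0].ca, pocket.ca, atol=1e-3)

    def test_index_columns(self):
        st, _ = sd.make_complex(n_contact_residues=12, seed=2)
        pocket = sio.extract_pocket(st, st.het_groups[0])
        df = sio.pocket_index([pocket])
        assert list(df.columns) == ["pocket_id", "entry_id", "het_code", "L", "year", "resolution"]
        assert df.iloc[0]["L"] == 12
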