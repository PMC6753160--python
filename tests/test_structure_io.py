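import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdcfit import (
    FixtureSpec,
    extract_nh_vectors,
    load_structure,
    make_structure,
    read_sse_config,
    select_sse_vectors,
    write_pdb,
    write_sse_config,
)
from rdcfit.structure import (
    Atom,
    BondVectorSet,
    SseDefinition,
    SseElement,
    Structure,
    StructureError,
)


def make_tiny_pdb(path, n_models=1, with_h=True, icode=False):
    names = ["N", "CA", "C", "H"] if with_h else ["N", "CA", "C", "O"]
    with open(path, "w") as fh:
        for m in range(1, n_models + 1):
            fh.write(f"MODEL     {m:4d}\n")
            serial = 0
            for res in range(1, 4):
                for j, name in enumerate(names):
                    serial += 1
                    ic = "A" if icode and res == 2 else " "
                    x = res * 3.0 + j * 0.5 + m  # model-dependent coords
                    fh.write(
                        f"ATOM  {serial:5d}  {name:<3s} ALA A{res:4d}{ic}  "
                        f"{x:8.3f}{1.0:8.3f}{2.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
                        f"          {name[0]:>2s}\n"
                    )
            fh.write("ENDMDL\n")
        fh.write("END\n")


class TestLoadStructure:
    def test_counts_all_atoms_of_requested_model(self, tmp_path):
        p = tmp_path / "t.pdb"
        make_tiny_pdb(p)
        s = load_structure(p, model=1)
        assert len(s.atoms) == 12

    def test_model_selection(self, tmp_path):
        p = tmp_path / "t.pdb"
        make_tiny_pdb(p, n_models=2)
        s1 = load_structure(p, model=1)
        s2 = load_structure(p, model=2)
        # model-dependent x offsets distinguish the two
        assert s2.coords("A", 1, "N")[0] == pytest.approx(
            s1.coords("A", 1, "N")[0] + 1.0
        )

    def test_absent_model_errors(self, tmp_path):
        p = tmp_path / "t.pdb"
        make_tiny_pdb(p)
        with pytest.raises(StructureError, match="model 3"):
            load_structure(p, model=3)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises((FileNotFoundError, StructureError)):
            load_structure(tmp_path / "absent.pdb")

    def test_insertion_codes_rejected(self, tmp_path):
        p = tmp_path / "t.pdb"
        make_tiny_pdb(p, icode=True)
        with pytest.raises(StructureError, match="insertion"):
            load_structure(p)

    def test_structure_without_h_loads_but_vectors_fail(self, tmp_path):
        p = tmp_path / "t.pdb"
        make_tiny_pdb(p, with_h=False)
        s = load_structure(p)
        assert len(s.atoms) == 12
        with pytest.raises(StructureError, match="no N-H vectors"):
            extract_nh_vectors(s, "A")


class TestRoundTrip:
    def test_write_then_load_preserves_coordinates(self, tmp_path):
        structure, _ = make_structure(FixtureSpec(kind="ideal_helix", n_residues=8))
        p = tmp_path / "h.pdb"
        write_pdb(structure, p)
        reloaded = load_structure(p)
        assert len(reloaded.atoms) == len(structure.atoms)
        for a in structure.atoms:
            b = reloaded.get_atom(a.chain, a.resnum, a.name)
            assert b is not None
            assert np.allclose(a.pos, b.pos, atol=5.1e-4)  # PDB 3-decimal precision


class TestExtractVectors:
    def test_unit_vector_from_explicit_pair(self):
        atoms = [
            Atom("A", 1, "ALA", "N", 0.0, 0.0, 0.0),
            Atom("A", 1, "ALA", "H", 0.0, 0.0, 1.02),
            Atom("A", 1, "ALA", "CA", 1.4, 0.0, 0.0),
        ]
        v = extract_nh_vectors(Structure(atoms=atoms), "A")
        assert np.allclose(v.entries[1], [0.0, 0.0, 1.0])

    def test_residue_missing_h_reported(self):
        atoms = [
            Atom("A", 1, "ALA", "N", 0.0, 0.0, 0.0),
            Atom("A", 1, "ALA", "H", 0.0, 0.0, 1.02),
            Atom("A", 2, "ALA", "N", 3.0, 0.0, 0.0),
        ]
        v = extract_nh_vectors(Structure(atoms=atoms), "A")
        assert 2 not in v.entries
        assert v.missing == [2]

    def test_hn_naming_dialect_accepted(self):
        atoms = [
            Atom("A", 1, "ALA", "N", 0.0, 0.0, 0.0),
            Atom("A", 1, "ALA", "HN", 1.02, 0.0, 0.0),
        ]
        v = extract_nh_vectors(Structure(atoms=atoms), "A")
        assert np.allclose(v.entries[1], [1.0, 0.0, 0.0])

    def test_prolines_skipped(self):
        atoms = [
            Atom("A", 1, "PRO", "N", 0.0, 0.0, 0.0),
            Atom("A", 1, "PRO", "H", 1.02, 0.0, 0.0),
            Atom("A", 2, "ALA", "N", 3.0, 0.0, 0.0),
            Atom("A", 2, "ALA", "H", 3.0, 1.02, 0.0),
        ]
        v = extract_nh_vectors(Structure(atoms=atoms), "A")
        assert list(v.entries) == [2]

    def test_helix_has_one_vector_per_residue_after_first(self):
        structure, _ = make_structure(FixtureSpec(kind="ideal_helix", n_residues=12))
        v = extract_nh_vectors(structure, "A")
        assert len(v) == 11  # N-terminal residue carries no amide H

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_vectors_unit_norm_for_random_geometry(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.normal(size=3) * 5
        h = n + rng.normal(size=3)
        atoms = [
            Atom("A", 1, "ALA", "N", *map(float, n)),
            Atom("A", 1, "ALA", "H", *map(float, h)),
        ]
        v = extract_nh_vectors(Structure(atoms=atoms), "A")
        assert abs(np.linalg.norm(v.entries[1]) - 1.0) < 1e-9


class TestSseSelection:
    def vectors(self, residues):
        return BondVectorSet(entries={r: np.array([0.0, 0.0, 1.0]) for r in residues})

    def test_range_intersection(self):
        sses = SseDefinition([SseElement("H1", 5, 10, "helix")])
        out = select_sse_vectors(self.vectors(range(1, 21)), sses)
        assert out.residues() == list(range(5, 11))

    def test_empty_definition_errors(self):
        with pytest.raises(StructureError):
            select_sse_vectors(self.vectors([1, 2]), SseDefinition([]))

    def test_adjacent_elements_union(self):
        sses = SseDefinition(
            [SseElement("H1", 1, 5, "helix"), SseElement("S1", 6, 9, "strand")]
        )
        out = select_sse_vectors(self.vectors(range(1, 15)), sses)
        assert out.residues() == list(range(1, 10))

    def test_overlapping_elements_rejected(self):
        with pytest.raises(StructureError, match="overlap"):
            SseDefinition(
                [SseElement("H1", 1, 5, "helix"), SseElement("H2", 5, 9, "helix")]
            )

    def test_config_round_trip(self, tmp_path):
        sses = SseDefinition(
            [SseElement("H1", 1, 5, "helix"), SseElement("S1", 8, 12, "strand")]
        )
        p = tmp_path / "sse.cfg"
        write_sse_config(sses, p)
        back = read_sse_config(p)
        assert back.elements == sses.elements
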