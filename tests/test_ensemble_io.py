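"""PDB ingestion, residue intersection, numbering map and manifest parsing."""

import numpy as np
import pytest

from mechbridge import (
    ResidueKey,
    StructureModel,
    intersect_residues,
    load_manifest,
    load_numbering_map,
    load_structures,
    write_pdb,
)
from mechbridge.ensemble_io import normalize_state


def atom_line(serial, name, resname, chain, seq, x, y, z, occ=1.0, alt=" ",
              icode=" "):
    return (
        f"ATOM  {serial:5d} {name:^4s}{alt}{resname:>3s} {chain}{seq:4d}{icode}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          "
        f"{name.strip()[0]:>2s}\n"
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """GLY1, ALA2, SER3 Cα trace plus records that must be ignored."""
    lines = [
        atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CA", "GLY", "A", 1, 1.0, 0.0, 0.0),
        atom_line(3, "CA", "ALA", "A", 2, 4.8, 0.0, 0.0),
        atom_line(4, "CB", "ALA", "A", 2, 5.0, 1.0, 0.0),
        atom_line(5, "CA", "SER", "A", 3, 8.6, 0.0, 0.0),
        "HETATM 6666  O   HOH A 101      9.000   9.000   9.000  1.00  0.00           O\n",
        "END\n",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("".join(lines))
    return path


def test_parse_minimal_trace(toy_pdb):
    (model,) = load_structures([toy_pdb])
    assert [r.residue_name for r in model.residues] == ["GLY", "ALA", "SER"]
    assert [r.seq_number for r in model.residues] == [1, 2, 3]
    np.testing.assert_allclose(model.coordinates[:, 0], [1.0, 4.8, 8.6])


def test_altloc_resolves_to_highest_occupancy(tmp_path):
    lines = [
        atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CA", "ALA", "A", 2, 4.0, 0.0, 0.0, occ=0.6, alt="A"),
        atom_line(3, "CA", "ALA", "A", 2, 5.0, 0.0, 0.0, occ=0.4, alt="B"),
        atom_line(4, "CA", "SER", "A", 3, 8.0, 0.0, 0.0),
        "END\n",
    ]
    path = tmp_path / "alt.pdb"
    path.write_text("".join(lines))
    (model,) = load_structures([path])
    assert model.coordinates[1, 0] == pytest.approx(4.0)


def test_multimodel_expands_and_strides(tmp_path):
    body = "".join(
        atom_line(i + 1, "CA", "GLY", "A", i + 1, 4.0 * i, 0.0, 0.0)
        for i in range(3)
    )
    text = "".join(
        f"MODEL     {m:4d}\n" + body + "ENDMDL\n" for m in range(1, 5)
    ) + "END\n"
    path = tmp_path / "multi.pdb"
    path.write_text(text)
    models = load_structures([path])
    assert len(models) == 4
    assert len({m.structure_id for m in models}) == 4
    assert len(load_structures([path], stride=2)) == 2


def test_missing_ca_skipped_and_empty_file_errors(tmp_path):
    path = tmp_path / "gap.pdb"
    path.write_text(
        atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0)
        + atom_line(2, "N", "ALA", "A", 2, 4.0, 0.0, 0.0)
        + atom_line(3, "CA", "SER", "A", 3, 8.0, 0.0, 0.0)
        + "END\n"
    )
    (model,) = load_structures([path])
    assert [r.seq_number for r in model.residues] == [1, 3]

    empty = tmp_path / "empty.pdb"
    empty.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(ValueError):
        load_structures([empty])


def _model(sid, seqs, names=None, x0=0.0):
    names = names or ["ALA"] * len(seqs)
    res = [ResidueKey("A", s, "", n) for s, n in zip(seqs, names)]
    coords = np.column_stack(
        [x0 + 3.8 * np.arange(len(seqs)), np.zeros(len(seqs)), np.zeros(len(seqs))]
    )
    return StructureModel(sid, res, coords)


class TestIntersectResidues:
    def test_identical_lists_keep_full_length(self):
        ens = intersect_residues([_model("a", range(1, 6)), _model("b", range(1, 6))])
        assert ens.n_residues == 5

    def test_overlapping_ranges(self):
        ens = intersect_residues(
            [_model("a", range(1, 11)), _model("b", range(3, 13))]
        )
        assert [r.seq_number for r in ens.residues] == list(range(3, 11))

    def test_name_mismatch_excluded(self):
        seqs = list(range(1, 8))
        a = _model("a", seqs)
        b = _model("b", seqs)
        names = ["ALA"] * 7
        names[4] = "GLY"
        c = _model("c", seqs, names=names)
        ens = intersect_residues([a, b, c])
        assert 5 not in [r.seq_number for r in ens.residues]
        assert ens.n_residues == 6

    def test_membership_order_insensitive(self):
        models = [
            _model("a", range(1, 11)),
            _model("b", range(3, 13)),
            _model("c", range(2, 9)),
        ]
        sets = []
        for perm in ([0, 1, 2], [2, 1, 0], [1, 0, 2]):
            ens = intersect_residues([models[i] for i in perm])
            sets.append(frozenset(r.seq_number for r in ens.residues))
            assert ens.n_residues <= min(len(m) for m in models)
        assert len(set(sets)) == 1

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            intersect_residues([_model("a", range(1, 5)), _model("b", range(10, 14))])


class TestNumberingMap:
    def test_direct_read(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("RHO\tA\t302\t7x52\nRHO\tA\t135\t3x50\n")
        m = load_numbering_map(p)
        assert m[("RHO", "A", 302)] == "7x52"
        assert m[("RHO", "A", 135)] == "3x50"

    def test_duplicate_key_errors(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("RHO\tA\t302\t7x52\nRHO\tA\t302\t7x53\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_numbering_map(p)

    def test_malformed_generic_number_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("RHO\tA\t302\t7x52\nRHO\tA\t303\t7-53\n")
        with pytest.raises(ValueError, match=":2"):
            load_numbering_map(p)


def test_manifest_states_normalized(tmp_path, toy_pdb):
    p = tmp_path / "manifest.tsv"
    p.write_text(
        "receptor_id\tpath\tstate\torganism\n"
        f"RHO\t{toy_pdb}\tinactive\tB. taurus\n"
        f"A2A\t{toy_pdb}\tp. active\tH. sapiens\n"
        f"NTS1\t{toy_pdb}\tactive (?)\tR. norvegicus\n"
    )
    manifest = load_manifest(p)
    assert [r.state_label for r in manifest.rows] == [
        "inactive", "partially_active", "active",
    ]
    assert manifest.receptors() == ["RHO", "A2A", "NTS1"]
    with pytest.raises(ValueError):
        normalize_state("weird")


def test_manifest_missing_file_errors(tmp_path):
    p = tmp_path / "manifest.tsv"
    p.write_text("RHO\tnope.pdb\tinactive\n")
    with pytest.raises(FileNotFoundError):
        load_manifest(p)


def test_pdb_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    res = [ResidueKey("A", i + 1, "", "ALA") for i in range(12)]
    coords = np.round(rng.uniform(-40, 40, size=(12, 3)), 3)
    model = StructureModel("orig", res, coords)
    path = tmp_path / "rt.pdb"
    write_pdb(model, path)
    (back,) = load_structures([path])
    assert [r.site for r in back.residues] == [r.site for r in res]
    assert [r.residue_name for r in back.residues] == ["ALA"] * 12
    np.testing.assert_array_equal(back.coordinates, coords)
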