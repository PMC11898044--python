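import numpy as np
import pytest

from slbind.errors import ChainSpecError, EmptyStructureError, GapRejectionError
from slbind.structure import (
    ComplexSpec,
    classify_heteroatoms,
    detect_backbone_gaps,
    preprocess,
    read_pdb,
    rename_chains,
    write_pdb,
)
from slbind.synthetic import SyntheticStructureSpec, build_structure, make_pdb


def pdb_line(record, serial, name, res, chain, seq, x, y, z, occ=1.0, alt="", elem=None):
    elem = elem or name[0]
    nm = name if len(name) == 4 else f" {name:<3}"
    return (
        f"{record:<6}{serial:>5} {nm}{alt or ' '}{res:<3} {chain}{seq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {elem:>2}"
    )


@pytest.fixture
def two_chain_file(tmp_path):
    path = tmp_path / "two_chain.pdb"
    make_pdb(SyntheticStructureSpec(chains=(("A", 10), ("B", 10))), path)
    return path


class TestReadPdb:
    def test_two_chain_polyalanine_counts(self, two_chain_file):
        model = read_pdb(two_chain_file)
        assert model.chain_order == ["A", "B"]
        assert len(model.atoms) == 100  # 5 atoms x 10 residues x 2 chains

    def test_water_only_file_is_empty_structure(self, tmp_path):
        path = tmp_path / "water.pdb"
        path.write_text(pdb_line("HETATM", 1, "O", "HOH", "A", 1, 0, 0, 0, elem="O") + "\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_pdb(path)

    def test_first_model_only(self, tmp_path):
        lines = ["MODEL     1"]
        lines += [pdb_line("ATOM", i + 1, n, "ALA", "A", 1, i, 0.0, 0.0)
                  for i, n in enumerate(["N", "CA", "C"])]
        lines += ["ENDMDL", "MODEL     2"]
        lines += [pdb_line("ATOM", i + 4, n, "ALA", "A", 1, i, 5.0, 0.0)
                  for i, n in enumerate(["N", "CA", "C"])]
        lines += ["ENDMDL", "END"]
        path = tmp_path / "multi.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_pdb(path)
        assert len(model.atoms) == 3
        assert all(a.coords[1] == 0.0 for a in model.atoms)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            pdb_line("ATOM", 1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
            pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0, occ=0.4, alt="A"),
            pdb_line("ATOM", 3, "CA", "ALA", "A", 1, 9.0, 0.0, 0.0, occ=0.6, alt="B"),
            pdb_line("ATOM", 4, "C", "ALA", "A", 1, 2.0, 0.0, 0.0),
            "END",
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_pdb(path)
        cas = [a for a in model.atoms if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].coords[0] == pytest.approx(9.0)

    def test_resolution_parsed(self, two_chain_file):
        assert read_pdb(two_chain_file).resolution == pytest.approx(1.8)


class TestGapDetection:
    def test_contiguous_chain_has_no_gaps(self):
        model, _ = build_structure(SyntheticStructureSpec())
        assert detect_backbone_gaps(model) == []

    @pytest.mark.parametrize("mode", ["numbering", "distance"])
    def test_planted_gap_found_with_reason(self, mode):
        model, manifest = build_structure(SyntheticStructureSpec(gap_at=("A", 3, mode)))
        gaps = detect_backbone_gaps(model)
        assert [(g.chain, g.res_before, g.res_after, g.reason) for g in gaps] == manifest[
            "expected_gaps"
        ]

    def test_missing_backbone_atom_flagged(self):
        model, _ = build_structure(SyntheticStructureSpec(chains=(("A", 5),)))
        # drop the CA of residue 3
        model.atoms = [a for a in model.atoms if not (a.res_seq == 3 and a.name == "CA")]
        gaps = detect_backbone_gaps(model)
        assert ("A", 3, 3, "missing heavy atoms") in [
            (g.chain, g.res_before, g.res_after, g.reason) for g in gaps
        ]

    def test_matches_brute_force_pair_oracle(self):
        # oracle: enumerate all consecutive protein residue pairs per chain
        model, _ = build_structure(
            SyntheticStructureSpec(chains=(("A", 20), ("B", 12)), gap_at=("B", 4, "numbering"))
        )
        residues = {}
        for a in model.atoms:
            if a.record == "ATOM":
                residues.setdefault(a.chain_id, {}).setdefault(a.res_seq, {})[a.name] = np.array(
                    a.coords
                )
        expected = []
        for chain in model.chain_order:
            if chain not in residues:
                continue
            seqs = sorted(residues[chain])
            for s1, s2 in zip(seqs, seqs[1:]):
                if s2 - s1 > 1:
                    expected.append((chain, s1, s2, "numbering"))
                elif np.linalg.norm(residues[chain][s1]["C"] - residues[chain][s2]["N"]) > 2.5:
                    expected.append((chain, s1, s2, "distance"))
        got = [(g.chain, g.res_before, g.res_after, g.reason) for g in detect_backbone_gaps(model)]
        assert got == expected


class TestHeteroatomClassification:
    def test_close_zinc_is_structural(self):
        model, _ = build_structure(SyntheticStructureSpec(ions=(("ZN", 1.9),)))
        structural, removable = classify_heteroatoms(model)
        assert [(i.name, i.min_distance) for i in structural] == [("ZN", pytest.approx(1.9))]
        assert removable == []

    def test_boundary_at_exactly_cutoff_is_removable(self):
        model, _ = build_structure(SyntheticStructureSpec(ions=(("ZN", 2.0),)))
        structural, removable = classify_heteroatoms(model)
        assert structural == []
        assert len(removable) == 1

    def test_close_water_is_removable(self):
        model, _ = build_structure(SyntheticStructureSpec())
        model.atoms = model.atoms + [
            type(model.atoms[0])(
                serial=999, name="O", element="O",
                coords=(model.atoms[1].coords[0], model.atoms[1].coords[1], -1.5),
                occupancy=1.0, altloc="", chain_id="W", res_seq=1, icode="",
                res_name="HOH", record="HETATM",
            )
        ]
        model.chain_order = model.chain_order + ["W"]
        structural, removable = classify_heteroatoms(model)
        assert structural == []
        assert [a.res_name for a in removable] == ["HOH"]

    def test_classification_is_total(self):
        model, _ = build_structure(
            SyntheticStructureSpec(
                ions=(("ZN", 1.0), ("MG", 3.0)), n_waters=4, n_ligand_residues=2,
                n_sugar_residues=1,
            )
        )
        structural, removable = classify_heteroatoms(model)
        n_het = sum(1 for a in model.atoms if a.record == "HETATM")
        assert len(structural) + len(removable) == n_het

    def test_structural_set_monotone_in_cutoff(self):
        model, _ = build_structure(
            SyntheticStructureSpec(ions=(("ZN", 0.5), ("CA", 1.9), ("NA", 2.5), ("K", 4.0)))
        )
        prev: set = set()
        for cutoff in (0.6, 1.0, 2.0, 3.0, 5.0):
            structural, _ = classify_heteroatoms(model, cutoff=cutoff)
            cur = {(i.name, i.chain, i.res_seq) for i in structural}
            assert prev <= cur
            prev = cur


class TestRenameChains:
    def _relabel(self, model, names):
        out = []
        for a in model.atoms:
            out.append(type(a)(**{**a.__dict__, "chain_id": names[a.chain_id]}))
        model.atoms = out
        model.chain_order = [names[c] for c in model.chain_order]
        return model

    def test_antibody_antigen_relabelling(self):
        model, _ = build_structure(SyntheticStructureSpec(chains=(("H", 4), ("L", 4), ("Y", 4))))
        spec = ComplexSpec(partner1=frozenset({"H", "L"}), partner2=frozenset({"Y"}))
        renamed, mapping, new_spec = rename_chains(model, spec)
        assert mapping == {"H": "A", "L": "B", "Y": "C"}
        assert new_spec.partner1 == {"A", "B"} and new_spec.partner2 == {"C"}

    def test_identity_when_already_canonical(self):
        model, _ = build_structure(SyntheticStructureSpec())
        spec = ComplexSpec(partner1=frozenset("A"), partner2=frozenset("B"))
        renamed, mapping, _ = rename_chains(model, spec)
        assert renamed is model
        assert mapping == {"A": "A", "B": "B"}

    def test_appearance_order_rule(self):
        model, _ = build_structure(SyntheticStructureSpec(chains=(("X", 3), ("A", 3))))
        spec = ComplexSpec(partner1=frozenset("X"), partner2=frozenset("A"))
        _, mapping, new_spec = rename_chains(model, spec)
        assert mapping == {"X": "A", "A": "B"}
        assert new_spec.partner1 == {"A"}

    def test_preserves_atom_order_and_coordinates(self):
        model, _ = build_structure(SyntheticStructureSpec(chains=(("Q", 5), ("R", 5))))
        spec = ComplexSpec(partner1=frozenset("Q"), partner2=frozenset("R"))
        renamed, mapping, _ = rename_chains(model, spec)
        assert len(set(mapping.values())) == len(mapping)  # bijection
        assert [a.coords for a in renamed.atoms] == [a.coords for a in model.atoms]
        assert [a.name for a in renamed.atoms] == [a.name for a in model.atoms]


class TestPreprocess:
    def test_planted_counts_match_manifest(self):
        spec_s = SyntheticStructureSpec(
            ions=(("ZN", 1.9),), n_waters=5, n_sugar_residues=1
        )
        model, manifest = build_structure(spec_s)
        cleaned, _, report = preprocess(
            model, ComplexSpec(partner1=frozenset("A"), partner2=frozenset("B"))
        )
        assert len(report.structural_ions) == len(manifest["expected_structural_ions"])
        assert report.removed_het["waters"] == 5
        assert report.removed_het["sugars"] == 1
        het_left = [a for a in cleaned.atoms if a.record == "HETATM"]
        assert [a.res_name for a in het_left] == ["ZN"]

    def test_clean_structure_unchanged_but_renamed(self):
        model, _ = build_structure(SyntheticStructureSpec())
        cleaned, _, report = preprocess(
            model, ComplexSpec(partner1=frozenset("A"), partner2=frozenset("B"))
        )
        assert report.gaps == []
        assert len(cleaned.atoms) == len(model.atoms)

    def test_strict_mode_rejects_gapped_structure(self):
        model, _ = build_structure(SyntheticStructureSpec(gap_at=("A", 3, "numbering")))
        with pytest.raises(GapRejectionError) as err:
            preprocess(
                model,
                ComplexSpec(partner1=frozenset("A"), partner2=frozenset("B")),
                strict=True,
            )
        assert "chain A" in str(err.value)

    def test_missing_spec_chain_rejected(self):
        model, _ = build_structure(SyntheticStructureSpec())
        with pytest.raises(ChainSpecError):
            preprocess(model, ComplexSpec(partner1=frozenset("A"), partner2=frozenset("Z")))

    def test_idempotent_up_to_bookkeeping(self):
        model, _ = build_structure(
            SyntheticStructureSpec(ions=(("ZN", 1.5),), n_waters=3, n_ligand_residues=1)
        )
        spec = ComplexSpec(partner1=frozenset("A"), partner2=frozenset("B"))
        once, spec1, _ = preprocess(model, spec)
        twice, _, report2 = preprocess(once, spec1)
        assert [a.coords for a in twice.atoms] == [a.coords for a in once.atoms]
        assert twice.chain_order == once.chain_order
        assert sum(report2.removed_het.values()) == 0


class TestWritePdb:
    def test_round_trip_preserves_atom_table(self, tmp_path):
        model, _ = build_structure(
            SyntheticStructureSpec(ions=(("ZN", 1.9),), n_waters=2)
        )
        path = tmp_path / "rt.pdb"
        write_pdb(model, path)
        back = read_pdb(path)
        assert len(back.atoms) == len(model.atoms)
        assert [a.name for a in back.atoms] == [a.name for a in model.atoms]
        assert [a.chain_id for a in back.atoms] == [a.chain_id for a in model.atoms]
        assert np.allclose(
            [a.coords for a in back.atoms], [a.coords for a in model.atoms], atol=5e-4
        )
        assert any(a.record == "HETATM" and a.res_name == "ZN" for a in back.atoms)

    def test_renamed_chain_ids_written(self, tmp_path):
        model, _ = build_structure(SyntheticStructureSpec(chains=(("H", 3), ("Y", 3))))
        spec = ComplexSpec(partner1=frozenset("H"), partner2=frozenset("Y"))
        renamed, _, _ = rename_chains(model, spec)
        path = tmp_path / "renamed.pdb"
        write_pdb(renamed, path)
        assert read_pdb(path).chain_order == ["A", "B"]
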