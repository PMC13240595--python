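"""Structure parsing, role assignment, numbering and residue pairing."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tcrpmhc_eval import (
    GeneratorConfig,
    Role,
    Window,
    RegionSpec,
    assign_roles,
    attach_numbering,
    default_regions,
    make_native,
    pair_residues,
    read_structure,
    select_region,
    write_structure,
)
from tcrpmhc_eval._errors import (
    CorrespondenceError,
    EmptyRegionError,
    FormatError,
    MappingError,
    NumberingError,
    RoleError,
)

from conftest import make_micro_complex


class TestReadWrite:
    def test_round_trip_preserves_retained_fields(self, native, tmp_path):
        path = tmp_path / "native.pdb"
        write_structure(native, path)
        back = read_structure(path, source="native")
        assert [c.chain_id for c in back.chains] == [c.chain_id for c in native.chains]
        for orig, rt in zip(native.chains, back.chains):
            assert rt.sequence == orig.sequence
            np.testing.assert_allclose(rt.coords(), orig.coords(), atol=5e-4)
        # a second write/read cycle is byte-identical (idempotence)
        path2 = tmp_path / "again.pdb"
        write_structure(back, path2)
        assert path.read_text() == path2.read_text()

    def test_four_chain_toy_pdb(self, tmp_path):
        micro = make_micro_complex()
        path = tmp_path / "micro.pdb"
        write_structure(micro, path)
        back = read_structure(path)
        assert len(back.chains) == 4
        assert back.n_residues() == 12

    def test_prediction_bfactor_becomes_plddt(self, candidates, tmp_path):
        cand = candidates[0]
        path = tmp_path / "cand.pdb"
        write_structure(cand.structure, path)
        back = read_structure(path, source="prediction")
        orig = [r.plddt for r in cand.structure.residues()]
        got = [r.plddt for r in back.residues()]
        np.testing.assert_allclose(got, orig, atol=5e-3)

    def test_fractional_bfactors_autoscale_with_warning(self, tmp_path):
        micro = make_micro_complex()
        for r in micro.residues():
            r.plddt = 0.90
        micro.chains[0].residues[0].plddt = 0.93
        micro.chains[0].residues[1].plddt = 0.87
        path = tmp_path / "frac.pdb"
        write_structure(micro, path)
        with pytest.warns(UserWarning, match="rescaling"):
            back = read_structure(path, source="prediction")
        vals = [r.plddt for r in back.chains[0].residues]
        assert vals[0] == pytest.approx(93.0)
        assert vals[1] == pytest.approx(87.0)

    def test_hetatm_only_file_is_format_error(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(FormatError):
            read_structure(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            read_structure(tmp_path / "nope.pdb")


class TestRoles:
    def _unassigned(self, tmp_path):
        micro = make_micro_complex()
        path = tmp_path / "m.pdb"
        write_structure(micro, path)
        return read_structure(path)

    def test_valid_class1_assignment(self, tmp_path):
        c = self._unassigned(tmp_path)
        assign_roles(c, {"D": "TCRA", "E": "TCRB", "C": "PEPTIDE", "A": "MHC_A"}, "I")
        assert set(c.roles) == {Role.TCRA, Role.TCRB, Role.PEPTIDE, Role.MHC_A}

    def test_missing_peptide_role(self, tmp_path):
        c = self._unassigned(tmp_path)
        with pytest.raises((RoleError, MappingError)):
            assign_roles(c, {"D": "TCRA", "E": "TCRB", "A": "MHC_A"}, "I")

    def test_duplicate_role(self, tmp_path):
        c = self._unassigned(tmp_path)
        with pytest.raises(RoleError):
            assign_roles(c, {"D": "TCRA", "E": "TCRA", "C": "PEPTIDE", "A": "MHC_A"}, "I")

    def test_unknown_chain_in_map(self, tmp_path):
        c = self._unassigned(tmp_path)
        with pytest.raises(MappingError):
            assign_roles(
                c, {"D": "TCRA", "E": "TCRB", "C": "PEPTIDE", "A": "MHC_A", "Z": "MHC_B"}, "I"
            )

    def test_class2_requires_mhc_b(self, class2_native):
        assert class2_native.has_role(Role.MHC_B)
        assert len(class2_native.chains) == 5


class TestNumbering:
    def test_numbers_attach_and_others_untouched(self, cfg):
        native, table = make_native(cfg)
        cdr3a = [r for r in native.chain(Role.TCRA).residues if r.imgt is not None
                 and 105 <= r.imgt <= 117]
        assert len(cdr3a) == 13
        assert all(r.imgt is None for r in native.chain(Role.PEPTIDE).residues)

    def test_empty_table_is_identity(self, native):
        before = [r.imgt for r in native.residues()]
        empty = pd.DataFrame(columns=["chain_id", "author_seq_id", "imgt_number"])
        attach_numbering(native, empty)
        assert [r.imgt for r in native.residues()] == before

    def test_duplicate_row_rejected(self, native):
        dup = pd.DataFrame({
            "chain_id": ["D", "D"], "author_seq_id": [1, 1], "imgt_number": [27, 28],
        })
        with pytest.raises(NumberingError):
            attach_numbering(native, dup)

    def test_absent_residue_rejected(self, native):
        bad = pd.DataFrame({"chain_id": ["D"], "author_seq_id": [9999], "imgt_number": [1]})
        with pytest.raises(NumberingError):
            attach_numbering(native, bad)


class TestSelectRegion:
    def test_cdr3_window_counts(self, native):
        regions = default_regions()
        a = select_region(native, regions["CDR3A"])
        b = select_region(native, regions["CDR3B"])
        both = select_region(native, regions["CDR3"])
        assert len(a) == 13 and len(b) == 13
        assert len(both) == len(a) + len(b)
        assert [r.key for r in both] == [r.key for r in a] + [r.key for r in b]

    def test_selection_is_order_stable(self, native):
        regions = default_regions()
        first = [r.key for r in select_region(native, regions["TCR"])]
        second = [r.key for r in select_region(native, regions["TCR"])]
        assert first == second

    def test_empty_window_raises(self, native):
        spec = RegionSpec("ghost", (Window(Role.TCRA, 200, 210),))
        with pytest.raises(EmptyRegionError):
            select_region(native, spec)


class TestPairResidues:
    def test_self_pairing_is_identity(self, native, self_corr):
        assert len(self_corr) == native.n_residues()
        assert all(nat is prd for nat, prd in self_corr.pairs)

    def test_substitution_detected_with_position(self, native):
        import copy
        mutant = copy.deepcopy(native)
        res = mutant.chain(Role.TCRA).residues[5]
        res.amino_acid = "W" if res.amino_acid != "W" else "Y"
        with pytest.raises(CorrespondenceError, match="position 5"):
            pair_residues(native, mutant)

    def test_pairing_is_by_role_not_file_order(self, native):
        reordered = type(native)(
            chains=list(reversed(native.chains)),
            mhc_class=native.mhc_class,
            metadata=dict(native.metadata),
        )
        corr = pair_residues(native, reordered)
        assert len(corr) == native.n_residues()
        for nat, prd in corr.pairs:
            assert nat.key == prd.key
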