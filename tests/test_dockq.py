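"""Interface contacts, Fnat, iRMS, LRMS, DockQ and quality classes."""

from __future__ import annotations

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcrpmhc_eval import (
    BodySplit,
    PMHC_SPLIT,
    Role,
    classify_dockq,
    dockq_score,
    evaluate_pair,
    fnat,
    interface_contacts,
    irms,
    lrms,
    pair_residues,
)
from tcrpmhc_eval._errors import DomainError, SplitError, UndefinedInterfaceError
from tcrpmhc_eval.dockq import EvalConfig, native_interface_residues

from conftest import make_micro_complex
from oracles import brute_contacts, brute_fnat, brute_irms, brute_lrms, dockq_formula

RECEPTOR = frozenset({Role.TCRA, Role.TCRB})
LIGAND = frozenset({Role.PEPTIDE, Role.MHC_A, Role.MHC_B})


class TestContacts:
    def test_threshold_is_strict(self):
        micro = make_micro_complex()
        # move TCRA residue 0 to exactly 8.0 A above peptide residue 0
        micro.chain(Role.TCRA).residues[0].ca = np.array([0.0, 0.0, 8.0])
        contacts = interface_contacts(micro, atom_mode="ca", cutoff=8.0)
        assert (("D", 0), ("C", 0)) not in contacts.contacts
        micro.chain(Role.TCRA).residues[0].ca = np.array([0.0, 0.0, 7.9])
        contacts = interface_contacts(micro, atom_mode="ca", cutoff=8.0)
        assert (("D", 0), ("C", 0)) in contacts.contacts

    def test_matches_exhaustive_enumeration(self, native):
        ours = interface_contacts(native, atom_mode="ca").contacts
        brute = brute_contacts(native, RECEPTOR, LIGAND, "ca", 8.0)
        assert ours == brute

    def test_allatom_mode_on_micro_fixture(self):
        micro = make_micro_complex(with_atoms=True)
        ours = interface_contacts(micro, atom_mode="allatom").contacts
        brute = brute_contacts(micro, RECEPTOR, LIGAND, "allatom", 5.0)
        assert ours == brute

    def test_empty_body_is_split_error(self, native):
        split = BodySplit(frozenset({Role.MHC_B}), frozenset({Role.PEPTIDE}))
        with pytest.raises(SplitError):
            interface_contacts(native, split)  # class I: no MHC_B chain


class TestFnat:
    def test_identity_is_one(self, native, self_corr):
        contacts = interface_contacts(native, atom_mode="ca")
        assert fnat(contacts, native, self_corr) == 1.0

    def test_far_translation_is_zero(self, native):
        moved = copy.deepcopy(native)
        for role in (Role.TCRA, Role.TCRB):
            for r in moved.chain(role).residues:
                r.ca = r.ca + np.array([0.0, 0.0, 50.0])
        corr = pair_residues(native, moved)
        contacts = interface_contacts(native, atom_mode="ca")
        assert fnat(contacts, moved, corr) == 0.0

    def test_partial_preservation_matches_brute_force(self, native, candidates):
        for cand in candidates[:3]:
            corr = pair_residues(native, cand.structure)
            contacts = interface_contacts(native, atom_mode="ca")
            ours = fnat(contacts, cand.structure, corr)
            brute = brute_fnat(native, cand.structure, RECEPTOR, LIGAND, "ca", 8.0)
            assert ours == pytest.approx(brute, abs=1e-12)

    def test_no_native_contacts_is_error(self, native, self_corr):
        empty = interface_contacts(native, atom_mode="ca", cutoff=0.1)
        with pytest.raises(UndefinedInterfaceError):
            fnat(empty, native, self_corr)


class TestInterfaceRmsd:
    def test_identity_and_joint_shift(self, native, self_corr):
        assert irms(native, native, self_corr) == pytest.approx(0.0, abs=1e-9)
        moved = copy.deepcopy(native)
        for r in moved.residues():
            r.ca = r.ca + np.array([3.0, -1.0, 2.0])
        corr = pair_residues(native, moved)
        assert irms(native, moved, corr) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_distortion_closed_form(self):
        micro = make_micro_complex()
        distorted = make_micro_complex()
        # every interface residue displaced by 1 A along +x: after optimal
        # superposition of the (rigidly consistent) set the RMSD is 0, so
        # distort alternating residues +/-1 A in z instead for a 1 A RMSD
        iface = native_interface_residues(micro, cutoff=10.0)
        keys = {r.key for r in iface}
        flat = [r for c in distorted.chains for r in c.residues]
        for i, r in enumerate(flat):
            if r.key in keys:
                r.ca = r.ca + np.array([0.0, 0.0, 1.0 if i % 2 == 0 else -1.0])
        corr = pair_residues(micro, distorted)
        ours = irms(micro, distorted, corr)
        brute = brute_irms(micro, distorted, RECEPTOR, LIGAND)
        assert ours == pytest.approx(brute, abs=1e-6)
        assert 0.5 < ours <= 1.0  # optimal fit can only reduce the planted 1 A

    def test_matches_brute_force_on_candidates(self, native, candidates):
        for cand in candidates[:3]:
            corr = pair_residues(native, cand.structure)
            assert irms(native, cand.structure, corr) == pytest.approx(
                brute_irms(native, cand.structure, RECEPTOR, LIGAND), abs=1e-6
            )


class TestLigandRmsd:
    def test_identity(self, native, self_corr):
        assert lrms(native, native, self_corr) == pytest.approx(0.0, abs=1e-9)

    def test_pure_ligand_translation_closed_form(self, native):
        moved = copy.deepcopy(native)
        for role in (Role.PEPTIDE, Role.MHC_A):
            for r in moved.chain(role).residues:
                r.ca = r.ca + np.array([0.0, 4.0, 0.0])
        corr = pair_residues(native, moved)
        assert lrms(native, moved, corr) == pytest.approx(4.0, abs=1e-9)

    def test_matches_brute_force(self, native, candidates):
        for cand in candidates[:3]:
            corr = pair_residues(native, cand.structure)
            assert lrms(native, cand.structure, corr) == pytest.approx(
                brute_lrms(native, cand.structure, RECEPTOR, LIGAND), abs=1e-6
            )


class TestDockqScore:
    def test_reference_points(self):
        assert dockq_score(1.0, 0.0, 0.0) == pytest.approx(1.0)
        assert dockq_score(0.5, 8.5, 1.5) == pytest.approx(0.5)
        assert dockq_score(0.0, 1e6, 1e6) == pytest.approx(0.0, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            dockq_score(1.2, 0, 0)
        with pytest.raises(DomainError):
            dockq_score(0.5, -1.0, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        f=st.floats(0, 1), l1=st.floats(0, 40), l2=st.floats(0, 40),
        i1=st.floats(0, 20), i2=st.floats(0, 20),
    )
    def test_monotone_in_each_component(self, f, l1, l2, i1, i2):
        lo_l, hi_l = sorted((l1, l2))
        lo_i, hi_i = sorted((i1, i2))
        assert dockq_score(f, hi_l, lo_i) <= dockq_score(f, lo_l, lo_i)
        assert dockq_score(f, lo_l, hi_i) <= dockq_score(f, lo_l, lo_i)
        if f < 1:
            assert dockq_score(f, lo_l, lo_i) < dockq_score(1.0, lo_l, lo_i)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            f, l, i = rng.uniform(0, 1), rng.uniform(0, 30), rng.uniform(0, 15)
            assert dockq_score(f, l, i) == pytest.approx(dockq_formula(f, l, i), abs=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.0, "incorrect"), (0.22, "incorrect"), (0.23, "acceptable"),
            (0.48, "acceptable"), (0.49, "medium"), (0.79, "medium"),
            (0.80, "high"), (1.0, "high"),
        ],
    )
    def test_half_open_intervals(self, score, expected):
        assert classify_dockq(score) == expected

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            classify_dockq(1.5)


class TestEvaluatePair:
    def test_identity_record(self, native, self_corr):
        rec = evaluate_pair(native, native, self_corr)
        assert rec.fnat == 1.0
        assert rec.dockq == pytest.approx(1.0)
        assert rec.quality_class == "high"
        assert rec.global_rmsd == pytest.approx(0.0, abs=1e-9)
        assert rec.global_tm == pytest.approx(1.0)

    def test_components_equal_individual_calls(self, native, candidates):
        cand = candidates[0]
        corr = pair_residues(native, cand.structure)
        rec = evaluate_pair(native, cand.structure, corr)
        contacts = interface_contacts(native, atom_mode="ca")
        assert rec.fnat == pytest.approx(fnat(contacts, cand.structure, corr))
        assert rec.irms == pytest.approx(irms(native, cand.structure, corr))
        assert rec.lrms == pytest.approx(lrms(native, cand.structure, corr))
        assert rec.dockq == pytest.approx(dockq_score(rec.fnat, rec.lrms, rec.irms))

    def test_prediction_without_plddt_has_no_plddt_fields(self, native):
        pred = copy.deepcopy(native)
        corr = pair_residues(native, pred)
        rec = evaluate_pair(native, pred, corr)
        assert rec.plddt == {}
        assert rec.dockq == pytest.approx(1.0)

    def test_pmhc_subcomplex_split(self, native, self_corr):
        rec = evaluate_pair(
            native, native, self_corr,
            EvalConfig(split=PMHC_SPLIT, region_frames={}, plddt_regions=(),
                       compute_global=False),
        )
        assert rec.dockq == pytest.approx(1.0)

    def test_row_round_trip(self, native, candidates):
        from tcrpmhc_eval.dockq import frame_to_records, records_to_frame

        recs = []
        for cand in candidates:
            corr = pair_residues(native, cand.structure)
            recs.append(
                evaluate_pair(native, cand.structure, corr, complex_id="c0",
                              candidate_id=cand.candidate_id,
                              original_rank=cand.original_rank, bundle=cand.bundle)
            )
        back = frame_to_records(records_to_frame(recs))
        for a, b in zip(recs, back):
            assert a.candidate_id == b.candidate_id
            assert b.dockq == pytest.approx(a.dockq)
            assert b.plddt["CDR3"] == pytest.approx(a.plddt["CDR3"])
            assert b.region["CDR3"].rmsd == pytest.approx(a.region["CDR3"].rmsd)
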