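from __future__ import annotations

import numpy as np
import pytest

from tcrpmhc_eval import GeneratorConfig, Role, make_candidates, make_native, pair_residues
from tcrpmhc_eval.structures import Chain, Residue, RoledComplex


@pytest.fixture(scope="session")
def cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def native_pair(cfg):
    """(native complex, numbering table) for a class I synthetic complex."""
    return make_native(cfg, complex_id="synth_0000")


@pytest.fixture(scope="session")
def native(native_pair):
    return native_pair[0]


@pytest.fixture(scope="session")
def class2_native():
    cfg2 = GeneratorConfig(seed=3, mhc_class="II")
    return make_native(cfg2, complex_id="synth_ii")[0]


@pytest.fixture(scope="session")
def candidates(native, cfg):
    return make_candidates(native, cfg, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def self_corr(native):
    return pair_residues(native, native)


def _residue(chain_id, idx, aa, ca, atoms=(), plddt=None, imgt=None):
    return Residue(
        chain_id=chain_id, author_seq_id=idx + 1, icode="", position_index=idx,
        amino_acid=aa, ca=np.asarray(ca, dtype=float),
        atoms=tuple((n, np.asarray(x, dtype=float)) for n, x in atoms),
        plddt=plddt, imgt=imgt,
    )


def make_micro_complex(offsets=None, with_atoms=False):
    """Hand-built 4-chain micro complex (3 residues per chain).

    The TCR chains sit ~4-6 A above the peptide, so the ca-only interface
    is non-empty.  ``offsets`` maps a Role to a translation applied to
    that chain (for building perturbed copies); ``with_atoms`` adds
    N/CA/C backbone atoms so all-atom contact mode applies.
    """
    offsets = offsets or {}
    layout = {
        Role.TCRA: ("D", [(0.0, -2.0, 5.0), (3.8, -2.0, 5.0), (7.6, -2.0, 5.0)], "ACD"),
        Role.TCRB: ("E", [(0.0, 2.0, 5.0), (3.8, 2.0, 5.5), (7.6, 2.0, 5.0)], "EFG"),
        Role.PEPTIDE: ("C", [(0.0, 0.0, 0.0), (3.8, 0.0, 0.2), (7.6, 0.0, 0.0)], "HIK"),
        Role.MHC_A: ("A", [(0.0, 5.0, -3.0), (3.8, 5.0, -2.8), (7.6, 5.0, -3.0)], "LMN"),
    }
    chains = []
    for role, (cid, coords, seq) in layout.items():
        shift = np.asarray(offsets.get(role, (0.0, 0.0, 0.0)), dtype=float)
        residues = []
        for i, (xyz, aa) in enumerate(zip(coords, seq)):
            ca = np.asarray(xyz) + shift
            atoms = []
            if with_atoms:
                atoms = [("N", ca + [-0.7, 0.5, 0.0]), ("CA", ca), ("C", ca + [0.7, 0.5, 0.0])]
            residues.append(_residue(cid, i, aa, ca, atoms=atoms))
        chains.append(Chain(chain_id=cid, residues=residues, role=role))
    return RoledComplex(chains=chains, mhc_class="I", metadata={"complex_id": "micro"})
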