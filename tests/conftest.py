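"""Shared fixtures: substitution model, reference domain, small trees.

All fixtures are generated programmatically and deterministically; nothing
is read from disk except the packaged model file.
"""

from __future__ import annotations

import numpy as np
import pytest

from sh2swap import asr, oligo_design as od
from sh2swap.seq_core import AlignedSet, ProteinSequence, read_newick

AAS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def model():
    return asr.load_paml_dat()


@pytest.fixture(scope="session")
def ref82():
    """A deterministic 82-residue reference protein with Arg at the
    307-equivalent column (column 26 when numbering starts at 281), plus a
    motif-free CDS realization of it."""
    rng = np.random.default_rng(20240901)
    residues = [AAS[i] for i in rng.integers(0, 20, 82)]
    residues[26] = "R"  # residue 307 in 281-based numbering
    protein = "".join(residues)
    cds = "".join(od.CODON_SETS[a][0] for a in protein)
    # the deterministic first-codon choice can embed the BsaI motif; recode
    # offending codons to their last synonym
    guard = 0
    while od.contains_forbidden(cds):
        window = cds.find("GGTCTC") if "GGTCTC" in cds else cds.find("GAGACC")
        i = window // 3
        options = od.CODON_SETS[protein[i]]
        cds = cds[: 3 * i] + options[-1] + cds[3 * i + 3 :]
        guard += 1
        assert guard < 100
    return protein, cds


@pytest.fixture(scope="session")
def four_leaf():
    """Rooted 4-leaf fixture tree with labelled internals and a 3-site alignment."""
    tree = read_newick("((A:0.12,B:0.3)U:0.21,(C:0.15,D:0.4)V:0.1)R;")
    msa = AlignedSet(
        [
            ProteinSequence("A", "ACD"),
            ProteinSequence("B", "AWD"),
            ProteinSequence("C", "DCD"),
            ProteinSequence("D", "-CD"),
        ]
    )
    return tree, msa
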