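import numpy as np
import pytest

from abcompare.structure_model import Atom, Residue, AntibodyComplex, annotate_regions
from abcompare.synthetic_data import (
    ComplexPlan,
    ContactSpec,
    make_complex,
    make_worked_example_standins,
)


@pytest.fixture(scope="session")
def worked_example_standins():
    """Synthetic Ab/sdAb stand-in complexes with ground truth."""
    return make_worked_example_standins()


@pytest.fixture(scope="session")
def simple_complex():
    """Four CDR residues contacting four antigen residues, one of them via a
    proximal-only (non-interacting) pair."""
    plan = ComplexPlan(
        pdb_id="SIMPLE",
        contacts=[
            ContactSpec(105, 10, "vdw"),
            ContactSpec(106, 11, "vdw_hbond"),
            ContactSpec(107, 12, "hydrophobic"),
            ContactSpec(108, 40, "proximal"),
        ],
    )
    return make_complex(plan)


def random_atom_complex(n_ab: int, n_ag: int, seed: int, box: float = 15.0):
    """A cloud of single-atom residues split into antibody and antigen."""
    rng = np.random.default_rng(seed)
    elements = ["C", "N", "O", "S"]

    def residues(chain, n, offset):
        out = []
        for i in range(n):
            pos = rng.uniform(0, box, size=3)
            el = elements[rng.integers(len(elements))]
            name = {"C": "CB", "N": "N", "O": "O", "S": "SG"}[el]
            out.append(
                Residue(chain, offset + i, "ALA" if el == "C" else "GLY",
                        [Atom(name, el, pos)])
            )
        return out

    heavy = residues("H", n_ab, 1)
    for i, r in enumerate(heavy):
        r.imgt_position = i + 1
    antigen = residues("G", n_ag, 1)
    cx = AntibodyComplex("RAND", heavy, {"G": antigen})
    annotate_regions(cx)
    return cx
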