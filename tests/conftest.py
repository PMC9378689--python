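import numpy as np
import pytest

import putec


@pytest.fixture(scope="session")
def duplex10():
    """Ideal 10-bp A-form RNA duplex with ground truth."""
    return putec.make_duplex(10)


@pytest.fixture(scope="session")
def swivel_fixture():
    """Noiseless two-module model with a 2.5 degree swivel applied."""
    return putec.make_two_module_model(angle=2.5, noise_sigma=0.0, seed=11)


@pytest.fixture()
def toy_protein_model():
    """Five-residue single-chain poly-glycine stub with CA/N/C/O atoms."""
    atoms = []
    serial = 0
    for i in range(5):
        base = np.array([3.8 * i, 0.0, 0.0])
        for name, off in (("N", [0.0, 0.0, 0.0]), ("CA", [1.2, 0.8, 0.0]),
                          ("C", [2.4, 0.0, 0.0]), ("O", [2.6, -1.2, 0.0])):
            serial += 1
            atoms.append(putec.Atom(
                serial=serial, name=name, element=name[0], residue_name="GLY",
                chain_id="A", residue_number=i + 1, insertion_code="",
                position=base + np.array(off)))
    return putec.StructureModel("toy-protein", atoms)


def make_atom(serial, name, element, resname, chain, resnum, pos, **kw):
    return putec.Atom(serial=serial, name=name, element=element,
                      residue_name=resname, chain_id=chain, residue_number=resnum,
                      insertion_code="", position=np.asarray(pos, float), **kw)
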