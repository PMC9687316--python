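import numpy as np
import pytest

from boomdock import structio, synth


@pytest.fixture
def two_residue_pdb() -> str:
    """Hand-written two-residue PDB text (fixed columns)."""
    return "\n".join([
        "ATOM      1  N   ALA A   1      11.104  13.207   9.001  1.00 95.00           N",
        "ATOM      2  CA  ALA A   1      12.560  13.300   9.100  1.00 95.00           C",
        "ATOM      3  C   ALA A   1      13.000  14.700   9.500  1.00 95.00           C",
        "ATOM      4  N   GLY A   2      14.250  14.900   9.750  1.00 91.00           N",
        "ATOM      5  CA  GLY A   2      14.800  16.200  10.100  1.00 91.00           C",
        "END",
    ]) + "\n"


@pytest.fixture
def het_water_pdb(two_residue_pdb) -> str:
    """Polymer residues plus a water and a ligand HETATM record."""
    extra = "\n".join([
        "HETATM    6  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O",
        "HETATM    7  ZN   ZN A 102      21.000  21.000  21.000  1.00  0.00          ZN",
        "END",
    ]) + "\n"
    return two_residue_pdb.replace("END\n", "") + extra


@pytest.fixture
def two_chain_pdb() -> str:
    """Two chains of five residues each, generated then serialized."""
    a = synth.make_peptide_chain("AAAAA", chain_id="A")
    b = synth.make_peptide_chain("GGGGG", chain_id="B")
    b = b.with_coords(b.coords() + np.array([0.0, 30.0, 0.0]))
    merged = structio.Structure("two_chain", a.residues + b.residues)
    return structio.write_structure(merged)


@pytest.fixture(scope="session")
def toy_complex():
    """Two-chain complex with three planted contacting residue pairs."""
    return synth.make_toy_complex(8, 8, [(2, 5), (4, 2), (7, 8)])


def multi_model_pdb(n_models: int, n_residues: int = 3, drop_atom_in_model: int = 0) -> str:
    """Multi-model PDB text built by repeating one structure's coordinates."""
    base = synth.make_peptide_chain("A" * n_residues)
    lines = []
    for m in range(1, n_models + 1):
        shifted = base.with_coords(base.coords() + np.array([0.1 * m, 0.0, 0.0]))
        body = structio.write_structure(shifted).splitlines()
        body = [l for l in body if l.startswith(("ATOM", "HETATM"))]
        if m == drop_atom_in_model:
            body = body[:-1]
        lines.append(f"MODEL     {m:4d}")
        lines.extend(body)
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
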