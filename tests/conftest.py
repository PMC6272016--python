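import numpy as np
import pytest

from stdepitope import ExchangeModel, GeneratorBasis, ProtonSet, ProtonSite


def pdb_atom_line(serial, name, resname, chain, resid, x, y, z, element):
    """One well-formed PDB ATOM record."""
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {chain:1s}{resid:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def make_pdb(atoms):
    """atoms: iterable of (name, resname, chain, resid, xyz, element)."""
    lines = [
        pdb_atom_line(i + 1, name, resname, chain, resid, *xyz, element)
        for i, (name, resname, chain, resid, xyz, element) in enumerate(atoms)
    ]
    return "\n".join(lines) + "\nEND\n"


def site(pid, xyz, role, exchangeable=False, shift=None, name=None):
    return ProtonSite(
        id=pid,
        atom_name=name or pid,
        residue=("A", "LIG" if role == "ligand" else "PRT", 1),
        coords=np.asarray(xyz, float),
        role=role,
        exchangeable=exchangeable,
        shift=shift,
    )


@pytest.fixture
def two_spin_pair():
    """One ligand proton 2.5 Å from one protein proton, bound state only."""
    ps = ProtonSet(
        [site("L1", (0, 0, 0), "ligand"), site("P1", (2.5, 0, 0), "protein")]
    )
    basis = GeneratorBasis(labels=(("L1", "bound"), ("P1", "bound")),
                           f_bound=1.0, f_free=0.0, observed=("L1",))
    return ps, basis


@pytest.fixture
def toy_model():
    return ExchangeModel(kd=100e-6, k_off=100.0, p_total=50e-6, l_total=2e-3,
                         tau_c_free=0.2, tau_c_bound=15.0, larmor=500.0)
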