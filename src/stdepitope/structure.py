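"""Proton extraction and filtering from protonated complex structures.

The relaxation-matrix prediction of saturation-transfer-difference (STD)
intensities starts from an explicit list of hydrogen atoms in a
protein–ligand complex.  This module reads a protonated PDB file, tags
every hydrogen with its role (``ligand`` receives saturation, ``protein``
is the source), classifies exchangeable hydrogens (bonded to N/O/S, which
are deuterated in D2O experiments and therefore invisible), and applies
the distance cutoff that restricts the protein protons entering the
relaxation matrix to the binding site.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ProtonSite",
    "ProtonSet",
    "parse_protonated_pdb",
    "filter_exchangeable",
    "select_binding_site",
    "assign_saturated_set",
    "distance_matrix",
]

#: Maximum H–heavy-atom distance (Å) regarded as a covalent bond when
#: classifying exchangeable hydrogens.
BOND_CUTOFF_A = 1.2

#: Heavy-atom elements whose bonded hydrogens exchange with solvent.
EXCHANGEABLE_PARTNERS = frozenset({"N", "O", "S"})


@dataclass(frozen=True)
class ProtonSite:
    """One hydrogen atom of the complex.

    Parameters
    ----------
    id : str
        Unique label within a :class:`ProtonSet`, e.g. ``"A/LIG 1/H2"``.
    atom_name : str
        PDB atom name.
    residue : tuple
        ``(chain_id, residue_name, residue_number)``.
    coords : numpy.ndarray
        Cartesian coordinates in Å.
    role : str
        ``"ligand"`` (observed, receives saturation) or ``"protein"``
        (saturation source).
    exchangeable : bool
        True iff the hydrogen is covalently bonded to N, O or S.
    shift : float or None
        Chemical shift in ppm, if known.
    """

    id: str
    atom_name: str
    residue: tuple
    coords: np.ndarray
    role: str
    exchangeable: bool
    shift: Optional[float] = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"proton {self.id!r}: coords must be 3 finite reals")
        object.__setattr__(self, "coords", coords)
        if self.role not in ("ligand", "protein"):
            raise ValueError(f"proton {self.id!r}: role must be 'ligand' or 'protein'")


@dataclass
class ProtonSet:
    """Ordered, duplicate-free collection of :class:`ProtonSite`.

    Ordering is stable (file order) so that downstream matrices are
    deterministic.
    """

    protons: list = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [p.id for p in self.protons]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate proton ids: {dupes}")

    def __len__(self):
        return len(self.protons)

    def __iter__(self):
        return iter(self.protons)

    def __getitem__(self, i):
        return self.protons[i]

    @property
    def ids(self) -> list:
        return [p.id for p in self.protons]

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in file order."""
        if not self.protons:
            return np.zeros((0, 3))
        return np.stack([p.coords for p in self.protons])

    def subset(self, roles: Iterable[str]) -> "ProtonSet":
        roles = set(roles)
        return ProtonSet(
            [p for p in self.protons if p.role in roles],
            provenance=self.provenance + f" | subset roles={sorted(roles)}",
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": p.id,
                "atom": p.atom_name,
                "chain": p.residue[0],
                "res_name": p.residue[1],
                "res_num": p.residue[2],
                "x": p.coords[0],
                "y": p.coords[1],
                "z": p.coords[2],
                "role": p.role,
                "exchangeable": p.exchangeable,
                "shift": p.shift if p.shift is not None else np.nan,
            }
            for p in self.protons
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "ProtonSet":
        df = pd.read_csv(path_or_buf, sep="\t")
        protons = [
            ProtonSite(
                id=str(r["id"]),
                atom_name=str(r["atom"]),
                residue=(str(r["chain"]), str(r["res_name"]), int(r["res_num"])),
                coords=np.array([r["x"], r["y"], r["z"]], float),
                role=str(r["role"]),
                exchangeable=bool(r["exchangeable"]),
                shift=None if pd.isna(r.get("shift", np.nan)) else float(r["shift"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(protons, provenance="from_tsv")


def _infer_element(atom_name: str) -> str:
    """Element from a PDB atom name when the element column is absent."""
    name = atom_name.strip()
    if not name:
        return ""
    # PDB names like "1HB2" start with a digit for hydrogens
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in ("H", "D"):
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN"):
        return stripped[:2].capitalize().upper()
    return stripped[0].upper()


def _parse_ligand_selector(selector: str):
    """Selector is either a residue name (e.g. ``"NAP"``) or
    ``chain/resnum`` (e.g. ``"B/401"``)."""
    if "/" in selector:
        chain, resnum = selector.split("/", 1)
        return ("chain_resnum", chain.strip(), int(resnum))
    return ("resname", selector.strip().upper(), None)


def parse_protonated_pdb(pdb_text: str, ligand_selector: str) -> ProtonSet:
    """Extract every hydrogen of a pre-protonated PDB as a :class:`ProtonSet`.

    Hydrogens matched by ``ligand_selector`` get ``role="ligand"``, all
    others ``role="protein"``.  Exchangeability is assigned from the
    nearest heavy atom within 1.2 Å: H bonded to N, O or S is
    exchangeable.  Only the first MODEL is read and alternate locations
    other than blank/'A' are dropped.

    Raises
    ------
    ValueError
        If the structure contains no hydrogen atoms (the input must be
        protonated beforehand) or the selector matches nothing.
    """
    pdb = PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb.get_structure(model=1, altloc="first")

    elements = np.array(
        [
            el if el else _infer_element(nm)
            for el, nm in zip(atoms.element, atoms.atom_name)
        ]
    )
    is_h = np.isin(elements, ("H", "D"))
    if not np.any(is_h):
        raise ValueError(
            "no hydrogen atoms found in the PDB input; STD prediction needs an "
            "explicitly protonated structure — add hydrogens first (e.g. with "
            "reduce, openbabel or a modelling suite) and retry"
        )

    kind, a, b = _parse_ligand_selector(ligand_selector)
    if kind == "resname":
        is_ligand = np.char.upper(atoms.res_name.astype(str)) == a
    else:
        is_ligand = (atoms.chain_id == a) & (atoms.res_id == b)
    if not np.any(is_ligand):
        raise ValueError(
            f"ligand selector {ligand_selector!r} matches no residue in the structure"
        )

    heavy_coords = atoms.coord[~is_h]
    heavy_elements = elements[~is_h]

    protons = []
    for idx in np.flatnonzero(is_h):
        coord = atoms.coord[idx]
        exchangeable = False
        if len(heavy_coords):
            d = np.linalg.norm(heavy_coords - coord, axis=1)
            j = int(np.argmin(d))
            if d[j] <= BOND_CUTOFF_A:
                exchangeable = heavy_elements[j] in EXCHANGEABLE_PARTNERS
        chain = str(atoms.chain_id[idx])
        res_name = str(atoms.res_name[idx])
        res_num = int(atoms.res_id[idx])
        name = str(atoms.atom_name[idx])
        protons.append(
            ProtonSite(
                id=f"{chain}/{res_name}{res_num}/{name}",
                atom_name=name,
                residue=(chain, res_name, res_num),
                coords=coord,
                role="ligand" if is_ligand[idx] else "protein",
                exchangeable=exchangeable,
            )
        )
    return ProtonSet(protons, provenance=f"parse_protonated_pdb(ligand={ligand_selector!r})")


def filter_exchangeable(ps: ProtonSet) -> ProtonSet:
    """Drop exchangeable (N/O/S-bonded) hydrogens.

    STD experiments run in D2O replace labile hydrogens with deuterium,
    so they carry no observable magnetization and are excluded from the
    relaxation matrix.  Idempotent; preserves order.
    """
    return ProtonSet(
        [p for p in ps if not p.exchangeable],
        provenance=ps.provenance + " | filter_exchangeable",
    )


def select_binding_site(ps: ProtonSet, cutoff: float) -> ProtonSet:
    """Reduce the basis to the ligand plus binding-site protein protons.

    Keeps all ligand protons and every protein proton whose minimum
    distance to any ligand proton is ≤ ``cutoff`` (inclusive boundary),
    measured proton-to-proton.  An 8 Å cutoff is the conventional choice
    for keeping relaxation matrices tractable while retaining all
    significant dipolar contacts.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = [p for p in ps if p.role == "ligand"]
    if not lig:
        raise ValueError("no ligand protons in set; cannot define a binding site")
    lig_coords = np.stack([p.coords for p in lig])
    kept = []
    for p in ps:
        if p.role == "ligand":
            kept.append(p)
        else:
            dmin = np.min(np.linalg.norm(lig_coords - p.coords, axis=1))
            if dmin <= cutoff:
                kept.append(p)
    return ProtonSet(kept, provenance=ps.provenance + f" | cutoff<={cutoff}A")


def assign_saturated_set(
    ps: ProtonSet, on_resonance: float = 0.75, bandwidth: float = math.inf
) -> set:
    """Ids of protein protons treated as instantaneously saturated.

    Protein protons with ``|shift − on_resonance| ≤ bandwidth/2`` are
    saturated; with ``bandwidth=inf`` (the default, the conventional
    complete-saturation limit) every protein proton is saturated
    regardless of shift.  Ligand protons are never saturated.
    """
    protein = [p for p in ps if p.role == "protein"]
    if math.isinf(bandwidth):
        return {p.id for p in protein}
    missing = [p.id for p in protein if p.shift is None]
    if missing:
        raise ValueError(
            "finite saturation bandwidth requires chemical shifts for all protein "
            f"protons; missing for: {missing}"
        )
    half = bandwidth / 2.0
    return {p.id for p in protein if abs(p.shift - on_resonance) <= half}


def distance_matrix(ps: ProtonSet) -> np.ndarray:
    """Symmetric matrix of interproton Euclidean distances in Å."""
    if len(ps) < 1:
        raise ValueError("distance_matrix needs at least one proton")
    xyz = ps.coords
    diff = xyz[:, None, :] - xyz[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))
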