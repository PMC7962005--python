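"""Protein structure container with PDB and PQR input/output.

A deliberately small structure model: a flat list of atoms with name,
residue identity, chain, coordinates and (for PQR) per-atom charge and
radius.  PDB files are parsed through gemmi; the whitespace-delimited
PQR dialect (ATOM name resname chain resnum x y z charge radius) is
read and written directly since no mainstream parser covers it.

Tryptophan residues missing any of the nine indole heavy atoms are
flagged incomplete and excluded from descriptor calculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

INDOLE_ATOMS = ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2")
BENZENE_ATOMS = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")
PYRROLE_ATOMS = ("CG", "CD1", "NE1", "CE2", "CD2")

# Bondi-style vdW radii used when a PDB carries no per-atom radii.
DEFAULT_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
FALLBACK_RADIUS = 1.70


@dataclass
class Atom:
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    pos: np.ndarray  # (3,) Angstrom
    charge: float | None = None  # e, from PQR
    radius: float | None = None  # Angstrom, from PQR

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float).reshape(3)
        self.element = self.element.strip().upper() or _element_from_name(self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


def _element_from_name(name: str) -> str:
    for ch in name.strip():
        if ch.isalpha():
            el = ch.upper()
            # two-letter halogens in common naming (CL1, BR2)
            two = name.strip()[:2].upper()
            if two in ("CL", "BR") and len(name.strip()) >= 2:
                return two
            return el
    return "C"


@dataclass
class Structure:
    """A list of atoms plus convenience views used by the descriptors."""

    atoms: list[Atom] = field(default_factory=list)
    source_format: str = "PDB"

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms]).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge if a.charge is not None else 0.0 for a in self.atoms])

    @property
    def has_charges(self) -> bool:
        return any(a.charge is not None for a in self.atoms)

    def radii(self) -> np.ndarray:
        return np.array(
            [
                a.radius
                if a.radius is not None
                else DEFAULT_RADII.get(a.element, FALLBACK_RADIUS)
                for a in self.atoms
            ]
        )

    def residue_atoms(self, chain: str, residue_number: int) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain == chain and a.residue_number == residue_number
        ]

    def tryptophans(self) -> list[tuple[str, int]]:
        """Sorted (chain, residue_number) ids of all TRP residues."""
        seen = {}
        for a in self.atoms:
            if a.residue_name.strip().upper() == "TRP":
                seen[(a.chain, a.residue_number)] = True
        return sorted(seen)

    def incomplete_tryptophans(self) -> list[tuple[str, int]]:
        out = []
        for trp_id in self.tryptophans():
            names = {a.name.strip().upper() for a in self.residue_atoms(*trp_id)}
            if not set(INDOLE_ATOMS) <= names:
                out.append(trp_id)
        return out


# ---------------------------------------------------------------------------
# PQR


def read_pqr(path) -> Structure:
    atoms: list[Atom] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            try:
                if len(rec) == 11:  # with chain id
                    (_, _, name, resname, chain, resnum) = rec[:6]
                    x, y, z, q, r = map(float, rec[6:11])
                elif len(rec) == 10:  # chain omitted (PDB2PQR default)
                    (_, _, name, resname, resnum) = rec[:5]
                    chain = "A"
                    x, y, z, q, r = map(float, rec[5:10])
                else:
                    raise ValueError("unexpected field count")
                atoms.append(
                    Atom(name, "", resname, int(resnum), chain, (x, y, z), q, r)
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed PQR record at line {ln}") from exc
    return Structure(atoms, source_format="PQR")


def write_pqr(structure: Structure, path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms, start=1):
            q = a.charge if a.charge is not None else 0.0
            r = a.radius if a.radius is not None else DEFAULT_RADII.get(
                a.element, FALLBACK_RADIUS
            )
            fh.write(
                f"ATOM {i:6d} {a.name:<4s} {a.residue_name:<4s} {a.chain:1s} "
                f"{a.residue_number:4d} {a.pos[0]:10.3f} {a.pos[1]:10.3f} "
                f"{a.pos[2]:10.3f} {q:8.4f} {r:7.4f}\n"
            )


# ---------------------------------------------------------------------------
# PDB (via gemmi)


def read_pdb(path) -> Structure:
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(
                    Atom(
                        at.name,
                        at.element.name.upper(),
                        res.name,
                        res.seqid.num,
                        chain.name,
                        (at.pos.x, at.pos.y, at.pos.z),
                    )
                )
    return Structure(atoms, source_format="PDB")


def write_pdb(structure: Structure, path) -> None:
    import gemmi

    st = gemmi.Structure()
    st.name = "trpscope"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        ch = chains.setdefault(a.chain, gemmi.Chain(a.chain))
        if len(ch) == 0 or ch[-1].seqid.num != a.residue_number or ch[-1].name != a.residue_name:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            ch.add_residue(res)
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.pos)
        ch[-1].add_atom(at)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.write_pdb(str(path))


def read_structure(path, format: str | None = None) -> Structure:
    """Read a structure, inferring PDB vs PQR from the extension if needed."""
    fmt = (format or str(path).rsplit(".", 1)[-1]).upper()
    if fmt == "PQR":
        return read_pqr(path)
    if fmt in ("PDB", "ENT"):
        return read_pdb(path)
    raise ValueError(f"unknown structure format: {fmt}")
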