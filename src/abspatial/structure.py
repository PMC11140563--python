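"""Antibody Fv structure model.

Parses Fv structures from (multi-MODEL) PDB files, assigns partial charges
and van der Waals radii from the bundled plain-text tables, and maps every
residue to the ten scoring regions (six CDRs, their union, Hv, Lv, Fv).

The structure model is deliberately small: atoms carry exactly the state the
spatial scores need (coordinates, charge, radius, side-chain flag), residues
are keyed by ``(chain_role, number, insertion_code)``, and a structure is an
ordered list of snapshots (MD frames or MODEL blocks) with identical atom
composition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger("abspatial")

# The ten scoring regions, in canonical order.
CDR_REGIONS = ("CDRH1", "CDRH2", "CDRH3", "CDRL1", "CDRL2", "CDRL3")
REGIONS = CDR_REGIONS + ("CDR", "Hv", "Lv", "Fv")
HEAVY = "heavy"
LIGHT = "light"

# The three spatial properties, in canonical (descriptor-table) order.
DESCRIPTOR_PROPERTIES = ("SAP_pos", "SCM_neg", "SCM_pos")


def canonical_descriptor_names() -> list[str]:
    """The 30 descriptor names: <property>_<region>, property-major."""
    return [f"{prop}_{region}" for prop in DESCRIPTOR_PROPERTIES
            for region in REGIONS]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Formal charges at the fixed protonation state used throughout:
# His protonated (+1), Asp/Glu deprotonated (-1), everything else neutral.
FORMAL_CHARGE = {name: 0.0 for name in THREE_TO_ONE}
FORMAL_CHARGE.update({"ARG": 1.0, "LYS": 1.0, "HIS": 1.0, "ASP": -1.0, "GLU": -1.0})


class PdbParseError(ValueError):
    """Raised for malformed or inconsistent PDB input."""


class StructureError(ValueError):
    """Raised for violated structural invariants (chains, snapshots)."""


class ParameterError(KeyError):
    """Raised when a charge or radius lookup fails in strict mode."""


class DomainError(ValueError):
    """Raised when a residue cannot be placed in the numbering scheme."""


def _data_text(name: str) -> str:
    return (resources.files("abspatial") / "data" / name).read_text()


def _read_rows(name: str) -> list[list[str]]:
    rows = []
    for line in _data_text(name).splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            rows.append(line.split("\t"))
    return rows


BACKBONE_ATOMS = frozenset(
    line.strip()
    for line in _data_text("backbone_atoms.txt").splitlines()
    if line.strip() and not line.startswith("#")
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray          # (3,) Å
    charge: float = 0.0         # elementary charge units
    radius: float = 0.0         # Å; 0 means "not yet assigned"
    is_side_chain: bool = False


@dataclass
class Residue:
    chain_id: str               # chain role: "heavy" or "light"
    number: int
    icode: str                  # insertion code, "" if none
    aa: str                     # one-letter code
    atoms: list[Atom] = field(default_factory=list)
    chain_label: str = ""       # original PDB chain identifier

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def resname(self) -> str:
        return ONE_TO_THREE[self.aa]

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_side_chain]


@dataclass
class FvSnapshot:
    residues: list[Residue]
    snapshot_index: int = 0

    def __post_init__(self) -> None:
        roles = {r.chain_id for r in self.residues}
        if roles - {HEAVY, LIGHT}:
            raise StructureError(f"unknown chain roles: {sorted(roles - {HEAVY, LIGHT})}")

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def atom_residue_index(self) -> np.ndarray:
        """Index of the parent residue for every atom, in atom order."""
        idx = np.empty(self.n_atoms, dtype=int)
        pos = 0
        for i, res in enumerate(self.residues):
            idx[pos:pos + len(res.atoms)] = i
            pos += len(res.atoms)
        return idx

    def side_chain_mask(self) -> np.ndarray:
        return np.array([a.is_side_chain for a in self.atoms], dtype=bool)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        return [r.key for r in self.residues]


@dataclass
class FvStructure:
    name: str
    snapshots: list[FvSnapshot]

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise StructureError("an FvStructure needs at least one snapshot")


@dataclass(frozen=True)
class DomainMap:
    """Residue-key -> set of region labels over the ten scoring regions."""

    assignment: dict[tuple[str, int, str], frozenset[str]]

    def regions_of(self, key: tuple[str, int, str]) -> frozenset[str]:
        return self.assignment[key]

    def residues_in(self, region: str) -> list[tuple[str, int, str]]:
        return [k for k, regs in self.assignment.items() if region in regs]

    def atom_indices(self, snapshot: FvSnapshot) -> dict[str, np.ndarray]:
        """Atom indices per region; an atom belongs wherever its residue does."""
        res_idx = snapshot.atom_residue_index()
        keys = snapshot.residue_keys()
        out: dict[str, np.ndarray] = {}
        for region in REGIONS:
            members = np.array(
                [region in self.assignment[keys[i]] for i in res_idx], dtype=bool
            )
            out[region] = np.nonzero(members)[0]
        return out


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChargeTable:
    charges: dict[tuple[str, str], float]
    # Terminal patches are charge deltas applied on request (off by default so
    # the per-residue formal-charge invariant holds everywhere).
    nter_patch: dict[str, float]
    cter_patch: dict[str, float]

    @classmethod
    def bundled(cls) -> "ChargeTable":
        charges = {(res, atom): float(q) for res, atom, q in _read_rows("charges.tsv")}
        return cls(
            charges=charges,
            nter_patch={"N": 1.00},
            cter_patch={"C": -0.17, "O": -0.16, "OXT": -0.67},
        )

    def charge(self, resname: str, atom_name: str) -> float:
        return self.charges[(resname, atom_name)]

    def expected_atoms(self, resname: str) -> frozenset[str]:
        return frozenset(a for (r, a) in self.charges if r == resname)

    def formal_charge(self, resname: str) -> float:
        return FORMAL_CHARGE[resname]


@dataclass(frozen=True)
class RadiusTable:
    radii: dict[str, float]

    @classmethod
    def bundled(cls) -> "RadiusTable":
        return cls({el: float(r) for el, r in _read_rows("radii.tsv")})

    def radius(self, element: str) -> float:
        return self.radii[element.upper()]


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

DEFAULT_CHAIN_ROLES = {"H": HEAVY, "L": LIGHT}


def _check_atom_lines(path: Path) -> None:
    """Cheap pre-scan so malformed ATOM records fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and line[:6].strip() in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PdbParseError(f"{path}, line {lineno}: truncated ATOM record")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    raise PdbParseError(
                        f"{path}, line {lineno}: unparseable coordinates"
                    ) from None


def parse_pdb(
    path: str | Path,
    chain_roles: dict[str, str] | None = None,
) -> FvStructure:
    """Read an Fv structure from a PDB file.

    MODEL/ENDMDL blocks become snapshots (a single snapshot if absent).
    ``chain_roles`` maps PDB chain identifiers to ``"heavy"``/``"light"``
    (default H/L). HETATM records are ignored. Charges and radii are left at
    zero until :func:`assign_parameters`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    roles = dict(DEFAULT_CHAIN_ROLES if chain_roles is None else chain_roles)
    _check_atom_lines(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PdbParseError(f"{path}: no models found")

    snapshots = []
    for imodel, model in enumerate(st):
        residues: list[Residue] = []
        for chain in model:
            if chain.name not in roles:
                raise PdbParseError(
                    f"{path}: chain {chain.name!r} has no declared role "
                    f"(declared: {sorted(roles)})"
                )
            role = roles[chain.name]
            for res in chain:
                if res.name not in THREE_TO_ONE:
                    if res.het_flag == "A":
                        raise PdbParseError(
                            f"{path}: non-canonical residue {res.name} "
                            f"{chain.name}{res.seqid.num}"
                        )
                    continue  # waters/ligands
                residue = Residue(
                    chain_id=role,
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    aa=THREE_TO_ONE[res.name],
                    chain_label=chain.name,
                )
                for atom in res:
                    if atom.altloc not in ("", "\0", "A"):
                        continue
                    name = atom.name.strip()
                    residue.atoms.append(Atom(
                        serial=atom.serial,
                        name=name,
                        element=atom.element.name.upper(),
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        is_side_chain=name not in BACKBONE_ATOMS,
                    ))
                residues.append(residue)
        snapshots.append(FvSnapshot(residues=residues, snapshot_index=imodel))

    _check_snapshot_consistency(path, snapshots)
    return FvStructure(name=path.stem, snapshots=snapshots)


def _check_snapshot_consistency(path: Path, snapshots: list[FvSnapshot]) -> None:
    ref = [(r.key, r.aa, tuple(a.name for a in r.atoms)) for r in snapshots[0].residues]
    for snap in snapshots[1:]:
        cur = [(r.key, r.aa, tuple(a.name for a in r.atoms)) for r in snap.residues]
        if cur != ref:
            for a, b in zip(ref, cur):
                if a != b:
                    raise PdbParseError(
                        f"{path}: snapshot {snap.snapshot_index} differs from "
                        f"snapshot 0 at residue {a[0]}: atoms {a[2]} vs {b[2]}"
                    )
            raise PdbParseError(
                f"{path}: snapshot {snap.snapshot_index} has "
                f"{len(cur)} residues, snapshot 0 has {len(ref)}"
            )


def write_pdb(structure: FvStructure, path: str | Path) -> None:
    """Write the structure as a (multi-MODEL) PDB file via gemmi."""
    st = gemmi.Structure()
    st.name = structure.name
    for snap in structure.snapshots:
        model = gemmi.Model(snap.snapshot_index + 1)
        chains: dict[str, gemmi.Chain] = {}
        for res in snap.residues:
            label = res.chain_label or ("H" if res.chain_id == HEAVY else "L")
            if label not in chains:
                chains[label] = gemmi.Chain(label)
            gres = gemmi.Residue()
            gres.name = res.resname
            gres.het_flag = "A"
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.serial = atom.serial
                ga.element = gemmi.Element(atom.element.capitalize())
                ga.pos = gemmi.Position(*atom.coords)
                gres.add_atom(ga)
            chains[label].add_residue(gres)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

def assign_parameters(
    structure: FvStructure,
    charges: ChargeTable | None = None,
    radii: RadiusTable | None = None,
    mode: str = "strict",
    terminal_patches: bool = False,
) -> FvStructure:
    """Assign partial charges and vdW radii to every atom, in place.

    Histidines are looked up as the protonated (+1) tautomer unconditionally
    (fixed protonation at formulation pH). In ``strict`` mode an unknown
    (residue, atom) pair raises :class:`ParameterError`; ``permissive`` mode
    leaves the atom at charge 0 (radius from its element) and logs it.
    """
    if mode not in ("strict", "permissive"):
        raise ValueError(f"unknown mode {mode!r}")
    charges = charges or ChargeTable.bundled()
    radii = radii or RadiusTable.bundled()

    skipped = 0
    total = 0
    for snap in structure.snapshots:
        by_label: dict[str, list[Residue]] = {}
        for res in snap.residues:
            by_label.setdefault(res.chain_label or res.chain_id, []).append(res)
        for res in snap.residues:
            for atom in res.atoms:
                total += 1
                try:
                    atom.charge = charges.charge(res.resname, atom.name)
                except KeyError:
                    if mode == "strict":
                        raise ParameterError(
                            f"no charge for atom {atom.name!r} of residue "
                            f"{res.resname} {res.key}"
                        ) from None
                    skipped += 1
                    atom.charge = 0.0
                    logger.info("skipping unparameterised atom %s of %s %s",
                                atom.name, res.resname, res.key)
                try:
                    atom.radius = radii.radius(atom.element)
                except KeyError:
                    if mode == "strict":
                        raise ParameterError(
                            f"no radius for element {atom.element!r} "
                            f"(atom {atom.name!r} of {res.resname} {res.key})"
                        ) from None
                    atom.radius = 1.70
        if terminal_patches:
            for chain_res in by_label.values():
                _apply_patch(chain_res[0], charges.nter_patch)
                _apply_patch(chain_res[-1], charges.cter_patch)
    if skipped:
        logger.warning("assign_parameters: %d/%d atoms had no charge entry",
                       skipped, total)
    return structure


def _apply_patch(res: Residue, patch: dict[str, float]) -> None:
    for atom in res.atoms:
        if atom.name in patch:
            if atom.name == "OXT":
                atom.charge = patch[atom.name]
            else:
                atom.charge += patch[atom.name]


def sequence_formal_charge(snapshot: FvSnapshot) -> float:
    """Total formal charge implied by composition + fixed protonation rules."""
    return sum(FORMAL_CHARGE[r.resname] for r in snapshot.residues)


# ---------------------------------------------------------------------------
# Domain assignment
# ---------------------------------------------------------------------------

def _load_scheme(scheme: str):
    try:
        rows = _read_rows(f"cdr_{scheme}.tsv")
    except FileNotFoundError:
        raise ValueError(f"unknown numbering scheme {scheme!r}") from None
    cdr = {}
    ranges = {}
    for region, chain, start, end in rows:
        if region in ("Hv", "Lv"):
            ranges[chain] = (int(start), int(end))
        else:
            cdr[region] = (chain, int(start), int(end))
    return cdr, ranges


def assign_domains(snapshot: FvSnapshot, scheme: str = "chothia") -> DomainMap:
    """Map every residue to its scoring regions under a numbering scheme.

    A residue belongs to a CDR iff the numeric part of its position falls in
    the scheme's (inclusive) interval; insertion-coded residues follow their
    numeric parent. CDR is the union of the six CDRs; Fv = Hv ∪ Lv.
    """
    cdr, ranges = _load_scheme(scheme)
    assignment = {}
    for res in snapshot.residues:
        lo, hi = ranges[res.chain_id]
        if not (lo <= res.number <= hi):
            raise DomainError(
                f"residue {res.key} outside the {scheme} {res.chain_id} "
                f"variable-region range {lo}-{hi}"
            )
        regions = {"Fv", "Hv" if res.chain_id == HEAVY else "Lv"}
        for region, (chain, start, end) in cdr.items():
            if chain == res.chain_id and start <= res.number <= end:
                regions.add(region)
                regions.add("CDR")
        assignment[res.key] = frozenset(regions)
    return DomainMap(assignment=assignment)
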