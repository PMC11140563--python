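"""Synthetic fixtures with known ground truth.

Four generators back the test and validation suites:

* toy atomic structures (few single-atom "residues" at hand-picked
  separations) whose SCM/SASA/SAP values follow from closed forms, emitted
  both as in-memory structures and as multi-MODEL PDB files, with an analytic
  score sheet computed by direct summation — never by the scoring engines;
* canonical-length paired Fv sequences compatible with the bundled Chothia
  slot templates, with optional deliberate filter violations;
* sequence -> 10-descriptor datasets where the labels are a fixed sparse
  linear map of the one-hot encoding plus Gaussian noise (surrogate-recovery
  ground truth);
* a 21-antibody descriptor/aggregation-rate table with a known sparse linear
  signal (the small-data regression emulator).

All randomness flows from one seed per call.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import DEFAULT_TARGET, FeatureTable
from .sequences import AA_ALPHABET, FvSequencePair, one_hot_encode, preprocess
from .structure import (
    Atom, FvSnapshot, FvStructure, Residue, HEAVY, LIGHT, ONE_TO_THREE,
    REGIONS, THREE_TO_ONE, canonical_descriptor_names, write_pdb,
)

DEFAULT_PROBE = 1.4


# ---------------------------------------------------------------------------
# Toy structures with analytic score sheets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyAtomSpec:
    name: str
    element: str
    coords: tuple[float, float, float]
    charge: float
    radius: float


@dataclass(frozen=True)
class ToyResidueSpec:
    chain: str          # "heavy" or "light"
    number: int
    resname: str        # three-letter code
    atoms: tuple[ToyAtomSpec, ...]


@dataclass(frozen=True)
class ToyStructureSpec:
    name: str
    residues: tuple[ToyResidueSpec, ...]
    n_snapshots: int = 1
    frame_shift: float = 0.0   # rigid z-translation per extra frame
    scm_radius: float = 10.0
    sap_radius: float = 10.0

    def validate(self) -> None:
        coords = [a.coords for r in self.residues for a in r.atoms]
        if len(set(coords)) != len(coords):
            raise ValueError(f"{self.name}: duplicate atom coordinates")
        chains = {r.chain for r in self.residues}
        if not chains <= {HEAVY, LIGHT}:
            raise ValueError(f"{self.name}: unknown chain roles {chains}")


def structure_from_spec(spec: ToyStructureSpec) -> FvStructure:
    """Build the structure (charges/radii pre-assigned from the spec)."""
    spec.validate()
    snapshots = []
    serial = 1
    for frame in range(spec.n_snapshots):
        shift = np.array([0.0, 0.0, frame * spec.frame_shift])
        residues = []
        serial = 1
        for rspec in spec.residues:
            res = Residue(chain_id=rspec.chain, number=rspec.number, icode="",
                          aa=THREE_TO_ONE[rspec.resname])
            for aspec in rspec.atoms:
                res.atoms.append(Atom(
                    serial=serial, name=aspec.name, element=aspec.element,
                    coords=np.array(aspec.coords) + shift,
                    charge=aspec.charge, radius=aspec.radius,
                    is_side_chain=aspec.name not in ("N", "CA", "C", "O"),
                ))
                serial += 1
            residues.append(res)
        snapshots.append(FvSnapshot(residues=residues, snapshot_index=frame))
    return FvStructure(name=spec.name, snapshots=snapshots)


def analytic_sheet(spec: ToyStructureSpec, probe_radius: float = DEFAULT_PROBE) -> dict:
    """Direct-summation expected values for one frame of a toy spec.

    SCM is exact (O(n²) all-pairs sum over exposed residues; every toy
    residue is exposed by construction). SASA and SAP closed forms are
    emitted only when every atom is isolated (no expanded spheres overlap);
    otherwise those entries are None and the engines are compared against the
    dense-lattice oracle instead.
    """
    from .sap import HydrophobicityScale, ReferenceSasa

    atoms = [(r, a) for r in spec.residues for a in r.atoms]
    n = len(atoms)
    coords = np.array([a.coords for _, a in atoms], dtype=float)
    charges = np.array([a.charge for _, a in atoms])
    radii = np.array([a.radius for _, a in atoms])
    dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)

    # atomic SCM: sum of charges of other atoms within the cutoff
    scm = np.array([
        sum(charges[j] for j in range(n)
            if j != i and dist[i, j] <= spec.scm_radius)
        for i in range(n)
    ])

    isolated = all(dist[i, j] > radii[i] + radii[j] + 2 * probe_radius
                   for i in range(n) for j in range(n) if i != j)
    sasa = sap = None
    if isolated:
        sasa = 4.0 * np.pi * (radii + probe_radius) ** 2
        scale, ref = HydrophobicityScale.bundled(), ReferenceSasa.bundled()
        side = np.array([a.name not in ("N", "CA", "C", "O") for _, a in atoms])
        res_of = [r for r, _ in atoms]
        sap = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if side[j] and dist[i, j] <= spec.sap_radius:
                    rj = res_of[j]
                    sap[i] += sasa[j] / ref(rj.resname) * scale(rj.resname)

    def domain_sums(values: np.ndarray, positive: bool) -> dict[str, float]:
        out = {}
        for region in REGIONS:
            total = 0.0
            for i, (r, _) in enumerate(atoms):
                if _in_region(r, region):
                    v = values[i]
                    total += max(v, 0.0) if positive else max(-v, 0.0)
            out[region] = total
        return out

    sheet = {
        "scm_per_atom": scm,
        "scm_pos": domain_sums(scm, True),
        "scm_neg": domain_sums(scm, False),
        "sasa_per_atom": sasa,
        "sap_per_atom": sap,
        "sap_pos": domain_sums(sap, True) if sap is not None else None,
        "ensemble_std_zero": spec.n_snapshots > 1,  # frames are rigid shifts
    }
    return sheet


_CHOTHIA_CDR = {
    "CDRH1": (HEAVY, 26, 32), "CDRH2": (HEAVY, 52, 56), "CDRH3": (HEAVY, 95, 102),
    "CDRL1": (LIGHT, 24, 34), "CDRL2": (LIGHT, 50, 56), "CDRL3": (LIGHT, 89, 97),
}


def _in_region(res: ToyResidueSpec, region: str) -> bool:
    if region == "Fv":
        return True
    if region == "Hv":
        return res.chain == HEAVY
    if region == "Lv":
        return res.chain == LIGHT
    if region == "CDR":
        return any(_in_region(res, r) for r in _CHOTHIA_CDR)
    chain, lo, hi = _CHOTHIA_CDR[region]
    return res.chain == chain and lo <= res.number <= hi


def _single_atom_residue(chain, number, resname, xyz, charge, radius=1.7):
    return ToyResidueSpec(chain, number, resname, (
        ToyAtomSpec("CB", "C", xyz, charge, radius),
    ))


def toy_catalogue() -> dict[str, ToyStructureSpec]:
    """Named analytic toy specs (every pair unambiguously in/out of radius)."""
    return {
        # two exposed residues 5 Å apart: inside the 10 Å cutoff, SCM = -/+0.5
        "pair_5A": ToyStructureSpec("pair_5A", (
            _single_atom_residue(HEAVY, 30, "LEU", (0.0, 0.0, 0.0), 0.5),
            _single_atom_residue(LIGHT, 50, "SER", (5.0, 0.0, 0.0), -0.5),
        )),
        # 20 Å apart: outside the cutoff, SCM = 0, atoms isolated (closed-form
        # SASA and SAP)
        "pair_20A": ToyStructureSpec("pair_20A", (
            _single_atom_residue(HEAVY, 30, "LEU", (0.0, 0.0, 0.0), 0.5),
            _single_atom_residue(LIGHT, 50, "SER", (20.0, 0.0, 0.0), -0.5),
        )),
        # three rigidly shifted frames: ensemble std must be exactly 0
        "pair_5A_x3": ToyStructureSpec("pair_5A_x3", (
            _single_atom_residue(HEAVY, 30, "LEU", (0.0, 0.0, 0.0), 0.5),
            _single_atom_residue(LIGHT, 50, "SER", (5.0, 0.0, 0.0), -0.5),
        ), n_snapshots=3, frame_shift=25.0),
        # four residues spanning CDR and framework regions, mixed charges
        "quartet": ToyStructureSpec("quartet", (
            _single_atom_residue(HEAVY, 30, "PHE", (0.0, 0.0, 0.0), 0.4),
            _single_atom_residue(HEAVY, 70, "LYS", (6.0, 0.0, 0.0), 1.0),
            _single_atom_residue(LIGHT, 91, "ASP", (0.0, 7.0, 0.0), -1.0),
            _single_atom_residue(LIGHT, 40, "THR", (30.0, 0.0, 0.0), -0.2),
        )),
    }


def make_toy_structure(
    spec: ToyStructureSpec,
    pdb_path=None,
    probe_radius: float = DEFAULT_PROBE,
) -> tuple[FvStructure, dict]:
    """Materialise a toy spec: structure (+ optional PDB file) and its sheet."""
    structure = structure_from_spec(spec)
    if pdb_path is not None:
        write_pdb(structure, pdb_path)
    return structure, analytic_sheet(spec, probe_radius)


# ---------------------------------------------------------------------------
# Synthetic Fv sequence pairs
# ---------------------------------------------------------------------------

_HEAVY_BASE = 113   # numeric Chothia slots; extras go to the CDRH3 loop
_LIGHT_BASE = 107
_HEAVY_CYS = (21, 91)   # 0-based indices of Chothia H22 / H92
_LIGHT_CYS = (22, 87)   # Chothia L23 / L88
_NO_CYS = AA_ALPHABET.replace("C", "")

# Base-slot indices (0-based) inside the Chothia CDR intervals: the positions
# that vary between synthetic antibodies. Framework positions are held at a
# fixed consensus, mirroring the germline conservation of real repertoires.
_HEAVY_VARIABLE = tuple(
    i for i in range(_HEAVY_BASE)
    if (26 <= i + 1 <= 32) or (52 <= i + 1 <= 56) or (95 <= i + 1 <= 102)
)
_LIGHT_VARIABLE = tuple(
    i for i in range(_LIGHT_BASE)
    if (24 <= i + 1 <= 34) or (50 <= i + 1 <= 56) or (89 <= i + 1 <= 97)
)


def _consensus(length: int, cys_idx: tuple[int, ...], tag: int) -> str:
    """Fixed framework consensus for one chain (deterministic)."""
    rng = np.random.default_rng(990001 + tag)
    seq = list(rng.choice(list(_NO_CYS), size=length))
    for idx in cys_idx:
        seq[idx] = "C"
    return "".join(seq)


_HEAVY_CONSENSUS = _consensus(_HEAVY_BASE, _HEAVY_CYS, 0)
_LIGHT_CONSENSUS = _consensus(_LIGHT_BASE, _LIGHT_CYS, 1)


def make_synthetic_sequences(
    n: int,
    seed: int = 0,
    violation: str | None = None,
) -> list[FvSequencePair]:
    """Template-compatible paired Fv sequences.

    Framework positions carry a fixed consensus; the Chothia CDR positions
    are drawn at random per antibody and the CDR3 loops additionally vary in
    length (0-10 heavy / 0-8 light insertions), so sequence diversity is
    concentrated in the loops, as in a real paired repertoire.

    ``violation`` switches every pair to a deliberate filter failure:
    ``"cdrh3_31"`` (CDRH3 length 31) or ``"cys_missing"`` (conserved heavy
    cysteines replaced).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if violation not in (None, "cdrh3_31", "cys_missing"):
        raise ValueError(f"unknown violation mode {violation!r}")
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        extra_h = 23 if violation == "cdrh3_31" else int(rng.integers(0, 11))
        extra_l = int(rng.integers(0, 9))
        heavy = list(_HEAVY_CONSENSUS)
        light = list(_LIGHT_CONSENSUS)
        for idx in _HEAVY_VARIABLE:
            heavy[idx] = str(rng.choice(list(_NO_CYS)))
        for idx in _LIGHT_VARIABLE:
            light[idx] = str(rng.choice(list(_NO_CYS)))
        # CDR3 loop insertions (placed after slot 100 heavy / 95 light)
        heavy[100:100] = [str(rng.choice(list(_NO_CYS))) for _ in range(extra_h)]
        light[95:95] = [str(rng.choice(list(_NO_CYS))) for _ in range(extra_l)]
        if violation == "cys_missing":
            for idx in _HEAVY_CYS:
                heavy[idx] = "A"
        pairs.append(FvSequencePair(
            name=f"synth-{seed}-{i:04d}",
            heavy="".join(heavy), light="".join(light),
        ))
    return pairs


# ---------------------------------------------------------------------------
# Surrogate-recovery dataset
# ---------------------------------------------------------------------------

def _slot_regions() -> list[set[str]]:
    """Region memberships of each of the 272 encoding slots (Chothia)."""
    from .sequences import HEAVY_TEMPLATE, LIGHT_TEMPLATE, slot_numeric

    regions = []
    for chain, template in ((HEAVY, HEAVY_TEMPLATE), (LIGHT, LIGHT_TEMPLATE)):
        for label in template:
            num = slot_numeric(label)
            member = {"Fv", "Hv" if chain == HEAVY else "Lv"}
            for cdr, (cchain, lo, hi) in _CHOTHIA_CDR.items():
                if cchain == chain and lo <= num <= hi:
                    member |= {cdr, "CDR"}
            regions.append(member)
    return regions


def make_surrogate_dataset(
    n: int,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[FvSequencePair]]:
    """Encoded sequences with labels from a fixed sparse linear map.

    The ten outputs mirror the ten scoring regions: output *k* sums a random
    per-amino-acid contribution over the slots of region *k* (gap channel 0),
    which reproduces the additive residue-type structure of the real region
    descriptors (a region score is a sum of per-residue terms; composite
    regions overlap their parts). Each output is rescaled to unit signal
    standard deviation and Gaussian noise of ``noise_sd`` is added, so the
    default signal-to-noise ratio is 10:1.

    Returns ``(X, y, coefficients, pairs)`` with coefficients of shape
    ``(272*21, 10)`` — ``y == X_flat @ coefficients + noise`` exactly when
    ``noise_sd = 0``.
    """
    pairs = make_synthetic_sequences(n, seed=seed)
    encoded = [one_hot_encode(aligned).matrix
               for _, report, aligned in preprocess(pairs) if report.passed]
    X = np.stack(encoded).astype(np.float32)
    flat = X.reshape(len(X), -1).astype(float)

    rng = np.random.default_rng(seed + 1)
    slot_regions = _slot_regions()
    n_channels = X.shape[2]
    W = np.zeros((flat.shape[1], len(REGIONS)))
    for k, region in enumerate(REGIONS):
        channel_w = rng.normal(0.0, 1.0, size=n_channels)
        channel_w[-1] = 0.0  # gaps contribute nothing
        for s, member in enumerate(slot_regions):
            if region in member:
                W[s * n_channels:(s + 1) * n_channels, k] = channel_w
    signal = flat @ W
    sd = signal.std(axis=0)
    sd[sd == 0] = 1.0
    W /= sd
    signal = signal / sd
    y = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return X, y, W, pairs


# ---------------------------------------------------------------------------
# Aggregation-rate table emulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticAggSpec:
    """The 21-antibody descriptor/aggregation-rate study conditions."""

    n: int = 21
    support: tuple[str, str, str] = (
        "SAP_pos_CDRH3", "SCM_pos_CDRL3", "SCM_neg_Fv",
    )
    coefficients: tuple[float, ...] = (1.0, -0.8, 0.6)
    noise_sd: float = 0.3
    column_correlation: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        vocab = set(canonical_descriptor_names())
        if not set(self.support) <= vocab:
            raise ValueError("support must be canonical descriptor names")
        if len(self.coefficients) != len(self.support):
            raise ValueError("one coefficient per support feature")


def make_agg_dataset(spec: SyntheticAggSpec | None = None) -> FeatureTable:
    """n x 30 descriptor matrix + target = linear(support) + noise.

    Descriptor columns are unit-variance Gaussians sharing a common factor
    (pairwise correlation ``column_correlation``), which mimics the strong
    region-overlap correlations of real descriptor tables without making the
    support unidentifiable.
    """
    spec = spec or SyntheticAggSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = canonical_descriptor_names()
    rho = spec.column_correlation
    factor = rng.normal(size=(spec.n, 1))
    Z = rng.normal(size=(spec.n, len(names)))
    X = math.sqrt(1 - rho) * Z + math.sqrt(rho) * factor
    frame = pd.DataFrame(X, columns=names)
    y = sum(c * frame[f].to_numpy() for c, f in
            zip(spec.coefficients, spec.support))
    frame[DEFAULT_TARGET] = y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return FeatureTable(frame=frame, target=DEFAULT_TARGET)
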