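"""Spatial aggregation propensity (SAP) scoring.

The atomic SAP value of atom *i* sums, over every residue *r* with at least
one side-chain atom within radius R of *i*, the residue's solvent-exposure
ratio times its hydrophobicity:

    SAP_i = Σ_r [ SAA(side-chain atoms of r within R of i) / SAA_ref(r) ] · φ(r)

where SAA_ref is the fully-exposed side-chain reference area and φ the
residue hydrophobicity (glycine-anchored scale: Gly = 0, hydrophilic < 0).
Because each in-range side-chain atom contributes its own SASA scaled by its
residue's φ/SAA_ref, the residue-grouped sum equals an atom-level weighted
sum, which is how the engine vectorises it.

Region scores keep the positive part only: SAP_pos(D) = Σ_{i∈D} SAP_i·H(SAP_i).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .sasa import SasaResult
from .scm import AtomicScoreField, positive_part_sums
from .structure import DomainMap, FvSnapshot, _read_rows

DEFAULT_SAP_RADIUS = 10.0  # Å; 5 Å is the common small-patch alternative


@dataclass(frozen=True)
class HydrophobicityScale:
    values: dict[str, float]  # residue name -> dimensionless hydrophobicity

    @classmethod
    def bundled(cls) -> "HydrophobicityScale":
        return cls({res: float(v) for res, v in _read_rows("hydrophobicity.tsv")})

    def __call__(self, resname: str) -> float:
        return self.values[resname]


@dataclass(frozen=True)
class ReferenceSasa:
    values: dict[str, float]  # residue name -> fully exposed side-chain Å²

    @classmethod
    def bundled(cls) -> "ReferenceSasa":
        table = cls({res: float(v) for res, v in _read_rows("ref_sasa.tsv")})
        if any(v <= 0 for v in table.values.values()):
            raise ValueError("reference SASA values must be positive")
        return table

    def __call__(self, resname: str) -> float:
        return self.values[resname]


def atomic_sap(
    snapshot: FvSnapshot,
    sasa: SasaResult,
    radius: float = DEFAULT_SAP_RADIUS,
    scale: HydrophobicityScale | None = None,
    ref: ReferenceSasa | None = None,
) -> AtomicScoreField:
    """Atomic SAP field for one snapshot (SASA must be from the same one)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if len(sasa.per_atom) != snapshot.n_atoms:
        raise ValueError("SASA result does not match the snapshot's atom count")
    scale = scale or HydrophobicityScale.bundled()
    ref = ref or ReferenceSasa.bundled()

    coords = snapshot.coords()
    side = snapshot.side_chain_mask()
    res_idx = snapshot.atom_residue_index()
    resnames = [r.resname for r in snapshot.residues]
    for name in set(resnames):
        if name not in scale.values or name not in ref.values:
            raise KeyError(f"residue {name} missing from hydrophobicity or "
                           "reference-SASA table")

    weight_of_res = np.array(
        [scale(name) / ref(name) for name in resnames], dtype=float
    )
    src = np.nonzero(side)[0]
    values = np.zeros(snapshot.n_atoms)
    if len(src) == 0:
        return AtomicScoreField(values, "SAP")
    # per side-chain atom: its SASA scaled by its residue's hydrophobicity/ref
    w = sasa.per_atom[src] * weight_of_res[res_idx[src]]
    tree = cKDTree(coords[src])
    for i in range(snapshot.n_atoms):
        hits = tree.query_ball_point(coords[i], radius)  # dist <= radius
        if hits:
            values[i] = w[hits].sum()
    return AtomicScoreField(values, "SAP")


def domain_sap_pos(
    field: AtomicScoreField, snapshot: FvSnapshot, domains: DomainMap
) -> dict[str, float]:
    """SAP_pos per region for one snapshot."""
    return positive_part_sums(field, snapshot, domains)
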