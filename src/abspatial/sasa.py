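"""Shrake–Rupley solvent-accessible surface area and residue exposure.

Each atom is wrapped in a solvent-expanded sphere of radius ``r + w`` (vdW
radius plus probe radius) carrying a deterministic golden-section spiral
lattice of test points; a point is accessible iff it lies strictly outside
every other atom's expanded sphere (a point exactly on another sphere's
surface counts as buried). SASA is then the accessible fraction times the
expanded-sphere area, so an isolated atom scores exactly 4π(r+w)².

Residue "exposure" — the gate for spatial charge-map scoring — is the sum of
side-chain atom SASA meeting a threshold (default 10 Å², inclusive).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import FvSnapshot

DEFAULT_PROBE_RADIUS = 1.4   # Å, water probe
DEFAULT_N_POINTS = 960
DEFAULT_EXPOSURE_THRESHOLD = 10.0  # Å², side-chain SASA


@dataclass(frozen=True)
class SasaResult:
    """Per-atom SASA (Å²) aligned to the snapshot's atom order."""

    per_atom: np.ndarray
    probe_radius: float
    n_points: int

    def total(self) -> float:
        return float(self.per_atom.sum())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral lattice on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack((
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ))


def shrake_rupley(
    snapshot: FvSnapshot,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Per-atom SASA of one snapshot."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    coords = snapshot.coords()
    radii = snapshot.radii()
    if coords.shape[0] == 0:
        return SasaResult(np.zeros(0), probe_radius, n_points)
    if np.any(radii <= 0):
        raise ValueError("all atom radii must be assigned (> 0) before SASA")

    expanded = radii + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    per_atom = np.empty(len(coords))

    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach)
                      if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2  # boundary counts as buried
            if not accessible.any():
                break
        frac = accessible.sum() / n_points
        per_atom[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return SasaResult(per_atom, probe_radius, n_points)


def side_chain_sasa(
    sasa: SasaResult, snapshot: FvSnapshot
) -> dict[tuple[str, int, str], float]:
    """Sum of side-chain atom SASA per residue key."""
    if len(sasa.per_atom) != snapshot.n_atoms:
        raise ValueError("SASA result does not match the snapshot's atom count")
    out: dict[tuple[str, int, str], float] = {}
    pos = 0
    for res in snapshot.residues:
        n = len(res.atoms)
        mask = np.array([a.is_side_chain for a in res.atoms], dtype=bool)
        out[res.key] = float(sasa.per_atom[pos:pos + n][mask].sum())
        pos += n
    return out


def exposed_residues(
    sc_sasa: dict[tuple[str, int, str], float],
    threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
) -> set[tuple[str, int, str]]:
    """Residues whose side-chain SASA meets the threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return {key for key, value in sc_sasa.items() if value >= threshold}


def sasa_table(sasa: SasaResult, snapshot: FvSnapshot):
    """Per-atom SASA as a tabular frame keyed by atom serial (for export)."""
    import pandas as pd

    if len(sasa.per_atom) != snapshot.n_atoms:
        raise ValueError("SASA result does not match the snapshot's atom count")
    atoms = snapshot.atoms
    return pd.DataFrame({
        "serial": [a.serial for a in atoms],
        "atom": [a.name for a in atoms],
        "sasa": sasa.per_atom,
    })


def mean_side_chain_sasa(
    per_snapshot: list[dict[tuple[str, int, str], float]],
) -> dict[tuple[str, int, str], float]:
    """Ensemble-mean side-chain SASA (for the mean-structure exposure mode)."""
    keys = per_snapshot[0].keys()
    return {k: float(np.mean([d[k] for d in per_snapshot])) for k in keys}
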