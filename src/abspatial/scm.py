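"""Spatial charge map (SCM) scoring.

The atomic SCM value of atom *i* is the sum of partial charges q_j over all
atoms *j* of exposed residues within a cutoff (default 10 Å) of *i*, with
*i* itself excluded. Region scores split the atomic field by sign:

    SCM_pos(D) = Σ_{i ∈ D} SCM_i · H(SCM_i)
    SCM_neg(D) = Σ_{i ∈ D} |SCM_i| · H(−SCM_i)

with H the Heaviside step (H(0) = 0), so both region scores are ≥ 0.
Ensemble statistics (mean, population std, relative std) summarise the
per-snapshot region scores over an MD ensemble or multi-MODEL file.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import REGIONS, DomainMap, FvSnapshot

logger = logging.getLogger("abspatial")

DEFAULT_SCM_RADIUS = 10.0  # Å


@dataclass(frozen=True)
class AtomicScoreField:
    """Per-atom score values aligned to snapshot atom order (one snapshot)."""

    values: np.ndarray
    property_name: str


@dataclass(frozen=True)
class DomainScore:
    region: str
    property_name: str
    mean: float
    std: float
    rel_std: float  # std / |mean|; NaN sentinel when mean == 0 with spread


def atomic_scm(
    snapshot: FvSnapshot,
    exposed: set[tuple[str, int, str]],
    radius: float = DEFAULT_SCM_RADIUS,
    include_self: bool = False,
    restrict_to_exposed: bool = False,
) -> AtomicScoreField:
    """Atomic SCM field for one snapshot.

    ``exposed`` is the set of exposed residue keys; all atoms (backbone and
    side chain) of an exposed residue contribute their charge. By default the
    field is computed for every atom *i*; ``restrict_to_exposed`` limits it to
    atoms of exposed residues (non-exposed atoms score 0).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    n = snapshot.n_atoms
    values = np.zeros(n)
    if not exposed:
        logger.warning("atomic_scm: empty exposed-residue set; all scores are 0")
        return AtomicScoreField(values, "SCM")

    coords = snapshot.coords()
    charges = snapshot.charges()
    res_idx = snapshot.atom_residue_index()
    keys = snapshot.residue_keys()
    exposed_atom = np.array([keys[i] in exposed for i in res_idx], dtype=bool)
    src = np.nonzero(exposed_atom)[0]

    tree = cKDTree(coords[src])
    for i in range(n):
        if restrict_to_exposed and not exposed_atom[i]:
            continue
        hits = tree.query_ball_point(coords[i], radius)  # dist <= radius
        total = charges[src[hits]].sum() if hits else 0.0
        if not include_self and exposed_atom[i]:
            total -= charges[i]
        values[i] = total
    return AtomicScoreField(values, "SCM")


def positive_part_sums(
    field: AtomicScoreField, snapshot: FvSnapshot, domains: DomainMap
) -> dict[str, float]:
    """Σ of positive atomic values per region (shared by SCM_pos / SAP_pos)."""
    region_atoms = domains.atom_indices(snapshot)
    v = field.values
    return {
        region: float(np.maximum(v[idx], 0.0).sum())
        for region, idx in region_atoms.items()
    }


def domain_scm(
    field: AtomicScoreField, snapshot: FvSnapshot, domains: DomainMap
) -> dict[str, tuple[float, float]]:
    """(SCM_pos, SCM_neg) per region for one snapshot."""
    region_atoms = domains.atom_indices(snapshot)
    v = field.values
    out = {}
    for region in REGIONS:
        idx = region_atoms[region]
        out[region] = (
            float(np.maximum(v[idx], 0.0).sum()),
            float(np.maximum(-v[idx], 0.0).sum()),
        )
    return out


def ensemble_stats(
    per_snapshot_scores: list[dict[str, float]],
    property_name: str,
) -> list[DomainScore]:
    """Mean, population std (denominator N) and relative std per region."""
    if not per_snapshot_scores:
        raise ValueError("need at least one snapshot of scores")
    regions = list(per_snapshot_scores[0].keys())
    out = []
    for region in regions:
        series = np.array([s[region] for s in per_snapshot_scores], dtype=float)
        mean = float(series.mean())
        std = float(series.std(ddof=0))
        if std == 0.0:
            rel = 0.0
        elif mean == 0.0:
            rel = math.nan  # undefined, not infinite
        else:
            rel = std / abs(mean)
        out.append(DomainScore(region, property_name, mean, std, rel))
    return out
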