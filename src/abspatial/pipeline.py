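"""End-to-end workflows: structure -> descriptors and sequence -> descriptors.

``score_structure`` runs the full per-snapshot chain (SASA -> exposure ->
atomic SCM/SAP -> region sums) and reduces over the ensemble, producing the
30 canonical descriptors with their standard deviations and relative
standard deviations. The CLI in :mod:`abspatial.cli` is a thin shell over
these functions.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import sap as sap_mod
from . import sasa as sasa_mod
from . import scm as scm_mod
from .structure import (
    DESCRIPTOR_PROPERTIES, REGIONS, FvStructure, assign_domains,
    canonical_descriptor_names,
)


@dataclass(frozen=True)
class RunConfig:
    """Scoring parameters (Å and Å² defaults: 10, 10, 10, 1.4, 960 points)."""

    scm_radius: float = 10.0
    sap_radius: float = 10.0
    exposure_threshold: float = 10.0
    probe_radius: float = 1.4
    n_points: int = 960
    scheme: str = "chothia"
    exposure_mode: str = "per_frame"   # or "ensemble_mean"
    mode: str = "strict"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scm_radius", "sap_radius", "probe_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.exposure_threshold < 0:
            raise ValueError("exposure_threshold must be >= 0")
        if self.exposure_mode not in ("per_frame", "ensemble_mean"):
            raise ValueError("exposure_mode must be per_frame or ensemble_mean")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def score_structure(structure: FvStructure, config: RunConfig | None = None) -> dict:
    """Ensemble descriptor set for one Fv structure.

    Returns ``{"name", "scores": {descriptor: DomainScore}, "config"}`` with
    one :class:`~abspatial.scm.DomainScore` (mean, std, rel. std) per
    canonical descriptor.
    """
    config = config or RunConfig()
    per_prop: dict[str, list[dict[str, float]]] = {p: [] for p in DESCRIPTOR_PROPERTIES}

    sc_maps = []
    sasa_results = []
    for snap in structure.snapshots:
        res = sasa_mod.shrake_rupley(snap, config.probe_radius, config.n_points)
        sasa_results.append(res)
        sc_maps.append(sasa_mod.side_chain_sasa(res, snap))
    if config.exposure_mode == "ensemble_mean":
        mean_map = sasa_mod.mean_side_chain_sasa(sc_maps)
        exposed_sets = [sasa_mod.exposed_residues(mean_map, config.exposure_threshold)
                        for _ in structure.snapshots]
    else:
        exposed_sets = [sasa_mod.exposed_residues(m, config.exposure_threshold)
                        for m in sc_maps]

    for snap, sasa_res, exposed in zip(structure.snapshots, sasa_results, exposed_sets):
        domains = assign_domains(snap, config.scheme)
        scm_field = scm_mod.atomic_scm(snap, exposed, config.scm_radius)
        pos_neg = scm_mod.domain_scm(scm_field, snap, domains)
        per_prop["SCM_pos"].append({r: pn[0] for r, pn in pos_neg.items()})
        per_prop["SCM_neg"].append({r: pn[1] for r, pn in pos_neg.items()})
        sap_field = sap_mod.atomic_sap(snap, sasa_res, config.sap_radius)
        per_prop["SAP_pos"].append(sap_mod.domain_sap_pos(sap_field, snap, domains))

    scores = {}
    for prop in DESCRIPTOR_PROPERTIES:
        for ds in scm_mod.ensemble_stats(per_prop[prop], prop):
            scores[f"{prop}_{ds.region}"] = ds
    return {"name": structure.name, "scores": scores, "config": config}


def scores_to_frame(results: list[dict]) -> pd.DataFrame:
    """Tabulate score_structure results: value, _std and _rel_std columns."""
    names = canonical_descriptor_names()
    rows = []
    for result in results:
        row = {"Name": result["name"]}
        for name in names:
            ds = result["scores"][name]
            row[name] = ds.mean
            row[f"{name}_std"] = ds.std
            row[f"{name}_rel_std"] = ds.rel_std
        rows.append(row)
    cols = ["Name"] + names + [f"{n}_std" for n in names] + [f"{n}_rel_std" for n in names]
    return pd.DataFrame(rows, columns=cols)


def write_csv(frame: pd.DataFrame, path: str | Path, config: RunConfig | None = None) -> None:
    """CSV writer that embeds the run-config digest as a comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_digest={config.digest()}\n")
        frame.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
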