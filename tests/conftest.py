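"""Shared fixtures: toy structures and random atomic clusters."""
from __future__ import annotations

import numpy as np
import pytest

from abspatial import (
    Atom, FvSnapshot, Residue, HEAVY, LIGHT,
    make_toy_structure, toy_catalogue,
)


@pytest.fixture(scope="session")
def catalogue():
    return toy_catalogue()


@pytest.fixture(scope="session")
def toy_structures(catalogue):
    """name -> (structure, analytic sheet) for every catalogued toy spec."""
    return {name: make_toy_structure(spec) for name, spec in catalogue.items()}


def random_cluster(
    n_atoms: int,
    seed: int,
    box: float = 8.0,
    charged: bool = True,
) -> FvSnapshot:
    """A compact random cluster of single-atom residues on two chains.

    Residue numbers are chosen inside the Chothia variable-region ranges so
    the cluster is domain-mappable; roughly half the residues sit in CDRs.
    """
    rng = np.random.default_rng(seed)
    residues = []
    # alternate framework/CDR numbers on both chains
    heavy_numbers = [30, 40, 53, 70, 96, 10, 99, 60]
    light_numbers = [25, 45, 51, 70, 90, 12, 93, 65]
    names = ["LEU", "SER", "LYS", "ASP", "PHE", "THR", "ARG", "GLU"]
    for i in range(n_atoms):
        chain = HEAVY if i % 2 == 0 else LIGHT
        numbers = heavy_numbers if chain == HEAVY else light_numbers
        res = Residue(
            chain_id=chain,
            number=numbers[(i // 2) % len(numbers)],
            icode="" if i < 2 * len(numbers) else chr(ord("A") + i // (2 * len(numbers)) - 1),
            aa="L" if names[i % len(names)] == "LEU" else
               {"SER": "S", "LYS": "K", "ASP": "D", "PHE": "F",
                "THR": "T", "ARG": "R", "GLU": "E"}[names[i % len(names)]],
        )
        res.atoms.append(Atom(
            serial=i + 1,
            name="CB",
            element="C",
            coords=rng.uniform(0, box, 3),
            charge=float(rng.normal(0, 0.5)) if charged else 0.0,
            radius=float(rng.uniform(1.4, 1.9)),
            is_side_chain=True,
        ))
        residues.append(res)
    return FvSnapshot(residues=residues)
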