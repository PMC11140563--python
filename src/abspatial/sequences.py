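"""Paired Fv sequence preprocessing: numbering, filtering, one-hot encoding.

Variable-length heavy/light chains are placed into fixed Chothia slot
templates (145 heavy + 127 light positions, unoccupied slots padded with
dashes), screened by the dataset-hygiene filters (duplicates, unpaired
chains, CDR3 length cap of 30, insertions outside CDR3, conserved
cysteines), and concatenated heavy-then-light into a 272 x 21 one-hot
matrix (channels: the 20 amino acids alphabetically, gap last).

Numbering is a pluggable interface; production pipelines may wire in an
external annotator, while the bundled :class:`ChothiaTemplateNumberer` is a
deterministic template filler for canonical-length chains (all length
variation carried by the CDR3 loop), which is what the synthetic sequence
generator emits.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .structure import _data_text

logger = logging.getLogger("abspatial")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
CHANNELS = AA_ALPHABET + GAP          # 21 one-hot channels, gap last
HEAVY_LENGTH = 145
LIGHT_LENGTH = 127

# Scheme-relative filter coordinates: conserved cysteine slots and the CDR3
# window (numeric part, inclusive) per chain.
SCHEME_RULES = {
    "chothia": {
        "cys": {"heavy": ("22", "92"), "light": ("23", "88")},
        "cdr3": {"heavy": (95, 102), "light": (89, 97)},
    },
    "imgt": {
        "cys": {"heavy": ("23", "104"), "light": ("23", "104")},
        "cdr3": {"heavy": (105, 117), "light": (105, 117)},
    },
}
MAX_CDR3_LENGTH = 30

_SLOT_RE = re.compile(r"^(\d+)([A-Z]?)$")


class NumberingError(ValueError):
    """Raised when a chain cannot be numbered or placed in the template."""


def _load_template(which: str) -> list[str]:
    text = _data_text(f"template_{which}.txt")
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


HEAVY_TEMPLATE = _load_template("heavy")
LIGHT_TEMPLATE = _load_template("light")
assert len(HEAVY_TEMPLATE) == HEAVY_LENGTH and len(LIGHT_TEMPLATE) == LIGHT_LENGTH


def slot_numeric(label: str) -> int:
    return int(_SLOT_RE.match(label).group(1))


def slot_is_insertion(label: str) -> bool:
    return bool(_SLOT_RE.match(label).group(2))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FvSequencePair:
    name: str
    heavy: str
    light: str

    def __post_init__(self) -> None:
        for chain in (self.heavy, self.light):
            bad = set(chain) - set(AA_ALPHABET)
            if bad:
                raise ValueError(f"{self.name}: non-canonical letters {sorted(bad)}")


@dataclass(frozen=True)
class AlignedFv:
    heavy_aligned: str
    light_aligned: str

    def __post_init__(self) -> None:
        if len(self.heavy_aligned) != HEAVY_LENGTH:
            raise ValueError(f"heavy alignment must be {HEAVY_LENGTH} slots")
        if len(self.light_aligned) != LIGHT_LENGTH:
            raise ValueError(f"light alignment must be {LIGHT_LENGTH} slots")

    @property
    def concatenated(self) -> str:
        return self.heavy_aligned + self.light_aligned

    def stripped(self) -> tuple[str, str]:
        return (self.heavy_aligned.replace(GAP, ""),
                self.light_aligned.replace(GAP, ""))


@dataclass(frozen=True)
class EncodedFv:
    """272 x 21 one-hot matrix (heavy then light; gap is the last channel)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (HEAVY_LENGTH + LIGHT_LENGTH, len(CHANNELS)):
            raise ValueError(f"encoded shape must be (272, 21), got {m.shape}")
        if not np.all(m.sum(axis=1) == 1):
            raise ValueError("each position must have exactly one active channel")


@dataclass(frozen=True)
class FilterReport:
    reasons: frozenset[str] = frozenset()

    REASON_CODES = frozenset({
        "DUPLICATE", "UNPAIRED", "CDRH3_TOO_LONG",
        "INSERTION", "CYS_MISSING", "NUMBERING_FAIL",
    })

    def __post_init__(self) -> None:
        if self.reasons - self.REASON_CODES:
            raise ValueError(f"unknown reason codes {self.reasons - self.REASON_CODES}")

    @property
    def passed(self) -> bool:
        return not self.reasons


# ---------------------------------------------------------------------------
# Numbering
# ---------------------------------------------------------------------------

class ChothiaTemplateNumberer:
    """Deterministic slot assignment for canonical-length chains.

    The first ``base`` residues (113 heavy / 107 light) occupy the numeric
    template slots in order; any extra length is assigned to CDR3 insertion
    slots (100A… heavy, 95A… light). Beyond the template's insertion
    capacity, synthetic overflow labels continue the letter series so
    downstream filters can still measure the CDR3 length; such labels have no
    template slot and therefore cannot be aligned.
    """

    scheme = "chothia"

    def __init__(self) -> None:
        self._templates = {"heavy": HEAVY_TEMPLATE, "light": LIGHT_TEMPLATE}
        self._insert_anchor = {"heavy": "100", "light": "95"}

    def number(self, sequence: str, chain: str) -> list[str]:
        """Per-residue scheme slot labels for one chain."""
        template = self._templates[chain]
        base = [s for s in template if not slot_is_insertion(s)]
        anchor = self._insert_anchor[chain]
        inserts = [s for s in template
                   if slot_is_insertion(s) and s.startswith(anchor)]
        if not sequence:
            raise NumberingError("empty sequence")
        extra = len(sequence) - len(base)
        if extra < 0:
            raise NumberingError(
                f"{chain} chain of length {len(sequence)} is shorter than the "
                f"template base ({len(base)} positions)"
            )
        used_inserts = list(inserts)
        next_letter = ord(used_inserts[-1][-1]) + 1 if used_inserts else ord("A")
        while len(used_inserts) < extra:
            if next_letter > ord("Z"):
                raise NumberingError(f"{chain} CDR3 overflow beyond label Z")
            used_inserts.append(anchor + chr(next_letter))
            next_letter += 1
        used_inserts = used_inserts[:extra]
        anchor_pos = base.index(anchor)
        return base[:anchor_pos + 1] + used_inserts + base[anchor_pos + 1:]


def number_and_align(
    pair: FvSequencePair,
    numberer: ChothiaTemplateNumberer | None = None,
) -> AlignedFv:
    """Place both chains at their scheme slots in the fixed templates.

    Raises :class:`NumberingError` if a chain cannot be numbered or a
    numbered position has no template slot.
    """
    numberer = numberer or ChothiaTemplateNumberer()
    aligned = {}
    for chain, seq, template in (
        ("heavy", pair.heavy, HEAVY_TEMPLATE),
        ("light", pair.light, LIGHT_TEMPLATE),
    ):
        labels = numberer.number(seq, chain)
        slot_index = {s: k for k, s in enumerate(template)}
        row = [GAP] * len(template)
        for aa, label in zip(seq, labels):
            if label not in slot_index:
                raise NumberingError(
                    f"{pair.name}: {chain} position {label} has no template slot"
                )
            row[slot_index[label]] = aa
        aligned[chain] = "".join(row)
    return AlignedFv(aligned["heavy"], aligned["light"])


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_filters(
    pair: FvSequencePair,
    numberer: ChothiaTemplateNumberer | None = None,
    seen: set[tuple[str, str]] | None = None,
    scheme: str = "chothia",
    strict_cys: bool = False,
) -> FilterReport:
    """Dataset-hygiene screen; all failures accumulate as reason codes.

    Checks: exact duplicate of a previously seen (heavy, light) pair; missing
    chain; numbering failure; CDR3 longer than 30; insertion-coded positions
    outside the CDR3 window; missing conserved cysteines (scheme-relative
    positions). Extra cysteines elsewhere are logged; ``strict_cys`` makes
    them fatal (reported as CYS_MISSING).
    """
    rules = SCHEME_RULES[scheme]
    reasons: set[str] = set()
    if seen is not None and (pair.heavy, pair.light) in seen:
        reasons.add("DUPLICATE")
    if not pair.heavy or not pair.light:
        reasons.add("UNPAIRED")
        return FilterReport(frozenset(reasons))

    numberer = numberer or ChothiaTemplateNumberer()
    numberings = {}
    for chain, seq in (("heavy", pair.heavy), ("light", pair.light)):
        try:
            numberings[chain] = numberer.number(seq, chain)
        except NumberingError:
            reasons.add("NUMBERING_FAIL")
    if "NUMBERING_FAIL" in reasons:
        return FilterReport(frozenset(reasons))

    for chain, labels in numberings.items():
        lo, hi = rules["cdr3"][chain]
        in_cdr3 = [lab for lab in labels if lo <= slot_numeric(lab) <= hi]
        if chain == "heavy" and len(in_cdr3) > MAX_CDR3_LENGTH:
            reasons.add("CDRH3_TOO_LONG")
        for lab in labels:
            if slot_is_insertion(lab) and not (lo <= slot_numeric(lab) <= hi):
                reasons.add("INSERTION")
        seq = pair.heavy if chain == "heavy" else pair.light
        by_label = dict(zip(labels, seq))
        for pos in rules["cys"][chain]:
            if by_label.get(pos) != "C":
                reasons.add("CYS_MISSING")
        extra_cys = sum(1 for lab, aa in by_label.items()
                        if aa == "C" and lab not in rules["cys"][chain])
        if extra_cys:
            logger.info("%s: %d extra cysteine(s) in %s chain",
                        pair.name, extra_cys, chain)
            if strict_cys:
                reasons.add("CYS_MISSING")
    return FilterReport(frozenset(reasons))


def preprocess(
    pairs: list[FvSequencePair],
    numberer: ChothiaTemplateNumberer | None = None,
    scheme: str = "chothia",
) -> list[tuple[FvSequencePair, FilterReport, AlignedFv | None]]:
    """Filter and align a batch; duplicates are keyed on the running set."""
    numberer = numberer or ChothiaTemplateNumberer()
    seen: set[tuple[str, str]] = set()
    out = []
    for pair in pairs:
        report = apply_filters(pair, numberer, seen=seen, scheme=scheme)
        seen.add((pair.heavy, pair.light))
        aligned = None
        if report.passed:
            try:
                aligned = number_and_align(pair, numberer)
            except NumberingError:
                report = FilterReport(report.reasons | {"NUMBERING_FAIL"})
        out.append((pair, report, aligned))
    return out


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def one_hot_encode(aligned: AlignedFv) -> EncodedFv:
    """Concatenate heavy-then-light and one-hot encode over 21 channels."""
    seq = aligned.concatenated
    matrix = np.zeros((len(seq), len(CHANNELS)), dtype=np.uint8)
    for i, ch in enumerate(seq):
        try:
            matrix[i, _CHANNEL_INDEX[ch]] = 1
        except KeyError:
            raise ValueError(f"character {ch!r} at position {i} is not encodable")
    return EncodedFv(matrix)


def decode(encoded: EncodedFv) -> AlignedFv:
    """Inverse of :func:`one_hot_encode` (exact)."""
    idx = encoded.matrix.argmax(axis=1)
    seq = "".join(CHANNELS[i] for i in idx)
    return AlignedFv(seq[:HEAVY_LENGTH], seq[HEAVY_LENGTH:])
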