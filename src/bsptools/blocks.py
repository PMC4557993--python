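"""Degenerate consensus blocks of the tandem-FN2 core and a scanner for them.

The BSP (Binder of Sperm) superfamily shares an 87-residue core built from
two fibronectin type II (FN2) domains joined by a short linker.  Nine short
degenerate consensus blocks tile this core: Blocks I-IV form the N-terminal
FN2 domain (1FN2), Block V is the linker, and Blocks VI-IX form the
C-terminal domain (2FN2).  Each block is written in a compact notation:

* an uppercase residue letter  -> that residue is required,
* ``[XYZ]``                    -> any one of the bracketed residues,
* ``x``                        -> any residue (wildcard),
* ``h``                        -> any member of the hydrophobic class.

This module parses that notation, scans protein sequences for block hits
within a configurable per-block mismatch tolerance, and ships the canonical
nine block definitions as a versioned JSON resource.

Coordinates are 1-based inclusive throughout; the core frame is anchored at
the Block I cysteine (core position 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default hydrophobic class backing the 'h' symbol.  Configurable because
#: the consensus notation only promises "hydrophobic".
DEFAULT_HYDROPHOBIC = frozenset("AVLIMFWY")


class BlockId(str, Enum):
    """Roman-numeral identifiers of the nine conserved blocks."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"
    IX = "IX"

    @property
    def index(self) -> int:
        return _BLOCK_ORDER.index(self)


_BLOCK_ORDER = [
    BlockId.I,
    BlockId.II,
    BlockId.III,
    BlockId.IV,
    BlockId.V,
    BlockId.VI,
    BlockId.VII,
    BlockId.VIII,
    BlockId.IX,
]


class Domain(str, Enum):
    FN2_1 = "FN2_1"
    LINKER = "linker"
    FN2_2 = "FN2_2"


class PatternError(ValueError):
    """Raised for malformed consensus strings."""


class SequenceError(ValueError):
    """Raised for sequences containing non-amino-acid symbols."""


@dataclass(frozen=True)
class PositionSpec:
    """One position of a degenerate pattern.

    ``kind`` is one of ``fixed``, ``alt``, ``wildcard``, ``hydrophobic``;
    ``residues`` holds the allowed residues for fixed/alt positions.
    """

    kind: str
    residues: frozenset = frozenset()

    def matches(self, residue: str, hydrophobic: frozenset = DEFAULT_HYDROPHOBIC) -> bool:
        if self.kind == "wildcard":
            return True
        if self.kind == "hydrophobic":
            return residue in hydrophobic
        return residue in self.residues


@dataclass(frozen=True)
class DegeneratePattern:
    """An ordered list of position specs parsed from consensus notation."""

    positions: tuple[PositionSpec, ...]

    def __len__(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:
        return format_pattern(self)


@dataclass(frozen=True)
class BlockDefinition:
    """A conserved block: pattern plus canonical placement in the core frame."""

    block_id: BlockId
    pattern: DegeneratePattern
    domain: Domain
    canonical_start: int
    canonical_length: int

    def __post_init__(self) -> None:
        if len(self.pattern) != self.canonical_length:
            raise ValueError(
                f"block {self.block_id.value}: pattern length {len(self.pattern)} "
                f"!= canonical length {self.canonical_length}"
            )

    @property
    def canonical_end(self) -> int:
        return self.canonical_start + self.canonical_length - 1


@dataclass(frozen=True)
class BlockMatch:
    """A placement of one block on a query sequence (1-based inclusive)."""

    block_id: BlockId
    start: int
    matched_subsequence: str
    mismatches: int
    exact: bool = field(default=False)

    @property
    def end(self) -> int:
        return self.start + len(self.matched_subsequence) - 1


def parse_pattern(text: str) -> DegeneratePattern:
    """Parse consensus notation (e.g. ``"C[VA]FPFxY"``) into a pattern.

    Raises :class:`PatternError` naming the offending 1-based character
    position for empty input, unknown symbols, or unbalanced brackets.
    """
    if not text:
        raise PatternError("empty consensus string")
    positions: list[PositionSpec] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.find("]", i)
            if j == -1:
                raise PatternError(f"unclosed '[' at position {i + 1}")
            alts = text[i + 1 : j]
            if not alts:
                raise PatternError(f"empty alternative set at position {i + 1}")
            bad = [a for a in alts if a not in AMINO_ACIDS]
            if bad:
                raise PatternError(
                    f"non-residue symbol {bad[0]!r} in alternative set at position {i + 1}"
                )
            positions.append(PositionSpec("alt", frozenset(alts)))
            i = j + 1
        elif ch == "x":
            positions.append(PositionSpec("wildcard"))
            i += 1
        elif ch == "h":
            positions.append(PositionSpec("hydrophobic"))
            i += 1
        elif ch in AMINO_ACIDS:
            positions.append(PositionSpec("fixed", frozenset(ch)))
            i += 1
        else:
            raise PatternError(f"unknown character {ch!r} at position {i + 1}")
    return DegeneratePattern(tuple(positions))


def format_pattern(pattern: DegeneratePattern) -> str:
    """Render a pattern back to normalized consensus notation.

    Alternative sets are emitted in alphabetical order, so
    ``format_pattern(parse_pattern(t))`` is a normal form of ``t``.
    """
    out = []
    for spec in pattern.positions:
        if spec.kind == "wildcard":
            out.append("x")
        elif spec.kind == "hydrophobic":
            out.append("h")
        elif spec.kind == "fixed":
            out.append(next(iter(spec.residues)))
        else:
            out.append("[" + "".join(sorted(spec.residues)) + "]")
    return "".join(out)


def match_at(
    pattern: DegeneratePattern,
    sequence: str,
    pos: int,
    tolerance: int = 0,
    hydrophobic: frozenset = DEFAULT_HYDROPHOBIC,
) -> tuple[bool, int]:
    """Count pattern violations for the window starting at 1-based ``pos``.

    Returns ``(matched, mismatches)`` where ``matched`` means the mismatch
    count does not exceed ``tolerance``.  Raises ``IndexError`` if the
    window overruns either sequence end.
    """
    if pos < 1 or pos + len(pattern) - 1 > len(sequence):
        raise IndexError(
            f"window [{pos}, {pos + len(pattern) - 1}] outside sequence of length {len(sequence)}"
        )
    window = sequence[pos - 1 : pos - 1 + len(pattern)]
    mismatches = sum(
        0 if spec.matches(res, hydrophobic) else 1
        for spec, res in zip(pattern.positions, window)
    )
    return mismatches <= tolerance, mismatches


def validate_sequence(sequence: str) -> None:
    """Reject sequences containing non-amino-acid symbols."""
    bad = sorted({c for c in sequence if c not in AMINO_ACIDS})
    if bad:
        raise SequenceError(f"non-amino-acid symbols in sequence: {''.join(bad)}")


def load_block_definitions(
    resource: str | None = None, bsph1_mode: bool = False
) -> list[BlockDefinition]:
    """Load the nine canonical block definitions from the bundled JSON.

    ``bsph1_mode`` swaps in the relaxed Block II variant whose terminal
    serine generalizes to any small residue {S, A, G, T} — the BSPH1 clade
    replaces the otherwise-conserved serine, typically with alanine.
    """
    if resource is None:
        text = resources.files("bsptools.data").joinpath("blocks.json").read_text()
    else:
        with open(resource) as fh:
            text = fh.read()
    raw = json.loads(text)
    defs = []
    for entry in raw["blocks"]:
        consensus = entry["consensus"]
        if bsph1_mode and "consensus_bsph1" in entry:
            consensus = entry["consensus_bsph1"]
        defs.append(
            BlockDefinition(
                block_id=BlockId(entry["block_id"]),
                pattern=parse_pattern(consensus),
                domain=Domain(entry["domain"]),
                canonical_start=entry["canonical_start"],
                canonical_length=entry["canonical_length"],
            )
        )
    return defs


def scan_blocks(
    sequence: str,
    tolerance_per_block: int = 1,
    blocks: Sequence[BlockDefinition] | None = None,
    hydrophobic: frozenset = DEFAULT_HYDROPHOBIC,
    best_only: bool = False,
) -> list[BlockMatch]:
    """Scan a protein sequence for all nine conserved blocks.

    Every position of the sequence is tested against every block pattern
    (a brute-force sliding window — the sequences involved are short), and
    every within-tolerance placement is returned, so the output is exactly
    the brute-force match set.  ``best_only`` reduces overlapping
    candidate hits of the same block to the lowest-mismatch, then
    leftmost, candidate per overlap cluster — a report-friendly view; keep
    the full set when feeding :func:`bsptools.architecture.assemble`,
    which needs all candidates to chain.  Output is sorted by start, then
    block order, and is deterministic.
    """
    validate_sequence(sequence)
    if blocks is None:
        blocks = load_block_definitions()
    all_matches: list[BlockMatch] = []
    for block in blocks:
        width = len(block.pattern)
        candidates: list[BlockMatch] = []
        for pos in range(1, len(sequence) - width + 2):
            ok, mm = match_at(block.pattern, sequence, pos, tolerance_per_block, hydrophobic)
            if ok:
                candidates.append(
                    BlockMatch(
                        block_id=block.block_id,
                        start=pos,
                        matched_subsequence=sequence[pos - 1 : pos - 1 + width],
                        mismatches=mm,
                        exact=(mm == 0),
                    )
                )
        if best_only:
            candidates = prune_overlapping_matches(candidates)
        all_matches.extend(candidates)
    all_matches.sort(key=lambda m: (m.start, m.block_id.index))
    return all_matches


def prune_overlapping_matches(candidates: list[BlockMatch]) -> list[BlockMatch]:
    """Collapse clusters of overlapping same-block hits.

    Within each maximal run of mutually overlapping candidates (one block,
    sorted by start), keep the lowest-mismatch candidate, breaking ties
    leftmost.
    """
    if not candidates:
        return []
    kept: list[BlockMatch] = []
    cluster: list[BlockMatch] = [candidates[0]]
    for cand in candidates[1:]:
        if cand.start <= cluster[-1].end:
            cluster.append(cand)
        else:
            kept.append(min(cluster, key=lambda m: (m.mismatches, m.start)))
            cluster = [cand]
    kept.append(min(cluster, key=lambda m: (m.mismatches, m.start)))
    return kept


def matches_to_rows(seq_id: str, matches: Iterable[BlockMatch]) -> list[dict]:
    """Flatten matches for TSV reporting."""
    return [
        {
            "seq_id": seq_id,
            "block_id": m.block_id.value,
            "start": m.start,
            "end": m.end,
            "subsequence": m.matched_subsequence,
            "mismatches": m.mismatches,
        }
        for m in matches
    ]
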