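"""Assembly of block hits into a validated tandem-FN2 architecture.

A bona fide BSP-superfamily protein carries the nine conserved blocks in
order, spaced by near-canonical gaps: Blocks I-IV (N-terminal FN2 domain),
Block V (linker), Blocks VI-IX (C-terminal FN2 domain).  ``assemble`` picks
the best mutually consistent chain of block hits; ``check_disulfides``
verifies the two conserved disulfide bridges of each FN2 domain (1-3 / 2-4
cysteine connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .blocks import BlockDefinition, BlockId, BlockMatch, load_block_definitions

#: Canonical inter-block gaps (residues between consecutive blocks) in the
#: 87-position core frame: I->II 7, II->III 1, III->IV 2, IV->V 1, V->VI 3,
#: VI->VII 7, VII->VIII 1, VIII->IX 2.
CANONICAL_GAPS = (7, 1, 2, 1, 3, 7, 1, 2)

_FN2_1_BLOCKS = (BlockId.I, BlockId.II, BlockId.III, BlockId.IV)
_FN2_2_BLOCKS = (BlockId.VI, BlockId.VII, BlockId.VIII, BlockId.IX)

#: Offset (0-based within the block) of the conserved cysteine used by each
#: disulfide bridge: Block I pos 1, Block II pos 1, Block III pos 4 (the
#: core C25), Block IV pos 8 (core C38), Block VI pos 1, Block VIII pos 6
#: (core C72), Block IX pos 10 (core C87).
_CYS_OFFSETS = {
    BlockId.I: 0,
    BlockId.II: 0,
    BlockId.III: 3,
    BlockId.IV: 7,
    BlockId.VI: 0,
    BlockId.VIII: 5,
    BlockId.IX: 9,
}


@dataclass(frozen=True)
class DisulfidePair:
    """One inferred disulfide bridge (1-based cysteine positions)."""

    domain: str
    pos1: int | None
    pos2: int
    status: str  # confirmed | invalid | incomplete


@dataclass
class FN2Architecture:
    """A chained, spacing-validated tandem-FN2 hit on one sequence."""

    seq_id: str
    block_matches: dict[BlockId, BlockMatch] = field(default_factory=dict)
    fn2_1_span: tuple[int, int] | None = None
    linker_span: tuple[int, int] | None = None
    fn2_2_span: tuple[int, int] | None = None
    cys_topology: list[DisulfidePair] = field(default_factory=list)
    cter_extension: str = ""
    complete: bool = False
    total_mismatches: int = 0

    @property
    def fn2_1_complete(self) -> bool:
        return all(b in self.block_matches for b in _FN2_1_BLOCKS)

    @property
    def fn2_2_complete(self) -> bool:
        return all(b in self.block_matches for b in _FN2_2_BLOCKS)


def _best_chain(
    candidates: dict[BlockId, list[BlockMatch]],
    blocks: list[BlockDefinition],
    gap_slack: int,
) -> list[BlockMatch]:
    """Dynamic program over block order for the best consistent chain.

    Chain quality is lexicographic: most blocks, then fewest total
    mismatches, then smallest total deviation from canonical inter-block
    spacing, then leftmost start tuple — fully deterministic.  A link
    between chained blocks a < b requires their start offset to sit within
    the canonical core-frame offset +/- gap_slack.
    """
    canon_start = {d.block_id: d.canonical_start for d in blocks}
    order = [d.block_id for d in blocks]
    # nodes: (block_index, match); DP over best chain ending at each node
    nodes: list[tuple[int, BlockMatch]] = []
    for bi, bid in enumerate(order):
        for m in candidates.get(bid, []):
            nodes.append((bi, m))

    best_ending: list[tuple[tuple, list[BlockMatch]]] = []
    for i, (bi, m) in enumerate(nodes):
        best = ((-1, m.mismatches, 0, (m.start,)), [m])
        for j in range(i):
            bj, mj = nodes[j]
            if bj >= bi:
                continue
            offset = canon_start[order[bi]] - canon_start[order[bj]]
            actual = m.start - mj.start
            deviation = abs(actual - offset)
            if deviation > gap_slack or mj.start + len(mj.matched_subsequence) > m.start:
                continue
            neg_n, mm, dev, starts = best_ending[j][0]
            cand_key = (neg_n - 1, mm + m.mismatches, dev + deviation, starts + (m.start,))
            if cand_key < best[0]:
                best = (cand_key, best_ending[j][1] + [m])
        best_ending.append(best)

    if not best_ending:
        return []
    _, chain = min(best_ending, key=lambda kv: kv[0])
    return chain


def assemble(
    matches: list[BlockMatch],
    sequence: str,
    gap_slack: int = 2,
    seq_id: str = "",
    blocks: list[BlockDefinition] | None = None,
) -> FN2Architecture:
    """Chain block hits into an architecture.

    Selects the highest-scoring mutually consistent chain of blocks
    (ordered I..IX, inter-block spacing within canonical +/- ``gap_slack``).
    ``complete`` is true iff all nine blocks are chained.  Input order is
    irrelevant; an empty match list yields an empty, incomplete
    architecture.
    """
    if blocks is None:
        blocks = load_block_definitions()
    candidates: dict[BlockId, list[BlockMatch]] = {}
    for m in sorted(matches, key=lambda m: (m.start, m.block_id.index)):
        candidates.setdefault(m.block_id, []).append(m)

    chain = _best_chain(candidates, blocks, gap_slack)
    arch = FN2Architecture(seq_id=seq_id)
    for m in chain:
        arch.block_matches[m.block_id] = m
    arch.total_mismatches = sum(m.mismatches for m in chain)
    arch.complete = len(arch.block_matches) == len(blocks)

    bm = arch.block_matches
    if arch.fn2_1_complete:
        arch.fn2_1_span = (bm[BlockId.I].start, bm[BlockId.IV].end)
    if BlockId.V in bm:
        arch.linker_span = (bm[BlockId.V].start, bm[BlockId.V].end)
    if arch.fn2_2_complete:
        arch.fn2_2_span = (bm[BlockId.VI].start, bm[BlockId.IX].end)
        arch.cter_extension = sequence[bm[BlockId.IX].end :]
    if arch.fn2_1_complete or arch.fn2_2_complete:
        arch.cys_topology, _ = check_disulfides(arch, sequence)
    return arch


def check_disulfides(
    arch: FN2Architecture, sequence: str
) -> tuple[list[DisulfidePair], bool]:
    """Infer and validate the conserved disulfide bridges.

    Each complete FN2 domain carries two bridges with 1-3 / 2-4
    connectivity.  In the N-terminal domain both partners live inside
    blocks (Block I C - Block III C, Block II C - Block IV C).  In the
    C-terminal domain the first bridge is Block VI C - Block VIII C; the
    second pairs the Block IX terminal cysteine with a cysteine expected in
    the VI->VII inter-block gap.  That gap cysteine is not housed by any
    block, so its absence downgrades the pair to ``incomplete`` (a warning)
    rather than invalidating the architecture.

    Returns the pair list and a validity flag (no ``invalid`` pair).
    """
    if not (arch.fn2_1_complete or arch.fn2_2_complete):
        raise ValueError("disulfide check requires at least one complete FN2 domain")

    def cys_at(pos: int) -> bool:
        return 1 <= pos <= len(sequence) and sequence[pos - 1] == "C"

    bm = arch.block_matches
    pairs: list[DisulfidePair] = []
    if arch.fn2_1_complete:
        for a, b in ((BlockId.I, BlockId.III), (BlockId.II, BlockId.IV)):
            p1 = bm[a].start + _CYS_OFFSETS[a]
            p2 = bm[b].start + _CYS_OFFSETS[b]
            status = "confirmed" if cys_at(p1) and cys_at(p2) else "invalid"
            pairs.append(DisulfidePair("FN2_1", p1, p2, status))
    if arch.fn2_2_complete:
        p1 = bm[BlockId.VI].start + _CYS_OFFSETS[BlockId.VI]
        p2 = bm[BlockId.VIII].start + _CYS_OFFSETS[BlockId.VIII]
        pairs.append(
            DisulfidePair(
                "FN2_2", p1, p2, "confirmed" if cys_at(p1) and cys_at(p2) else "invalid"
            )
        )
        # second bridge: gap cysteine between Block VI end and Block VII start
        gap_cys = None
        for pos in range(bm[BlockId.VI].end + 1, bm[BlockId.VII].start):
            if cys_at(pos):
                gap_cys = pos
                break
        p4 = bm[BlockId.IX].start + _CYS_OFFSETS[BlockId.IX]
        if gap_cys is None:
            pairs.append(
                DisulfidePair("FN2_2", None, p4, "incomplete" if cys_at(p4) else "invalid")
            )
        else:
            pairs.append(
                DisulfidePair("FN2_2", gap_cys, p4, "confirmed" if cys_at(p4) else "invalid")
            )
    valid = all(p.status != "invalid" for p in pairs)
    return pairs, valid


def architecture_row(arch: FN2Architecture) -> dict:
    """Flatten an architecture for TSV reporting."""

    def fmt(span):
        return f"{span[0]}-{span[1]}" if span else ""

    return {
        "seq_id": arch.seq_id,
        "complete": arch.complete,
        "fn2_1_span": fmt(arch.fn2_1_span),
        "linker_span": fmt(arch.linker_span),
        "fn2_2_span": fmt(arch.fn2_2_span),
        "n_disulfides_valid": sum(1 for p in arch.cys_topology if p.status == "confirmed"),
        "cter_extension": arch.cter_extension,
    }
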