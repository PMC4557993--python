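"""Family and subfamily assignment for BSP-superfamily sequences.

Three families make up the superfamily: BSP, BSPH1 and BSPH2.  BSPH1 and
BSPH2 carry diagnostic *fingerprints* — exact (or near-exact) versions of
particular conserved blocks:

* BSPH1: Block III ``HKWCSLN``, Block VI ``ChFPFWY`` (h = hydrophobic),
  Block VIII ``FGKKWCSLT``;
* BSPH2: Block IX ``YNxDxKWKQC``, Block V ``DPP``, Block IV ``FxGRWRYC``,
  plus a strictly conserved ``SP`` dipeptide immediately after Block IX.

BSP proteins carry no family fingerprint; a sequence with a complete
tandem-FN2 architecture but neither fingerprint set is called BSP.  The
BSP family further splits into subfamilies (BSP1, BSP2, BSP3, BSP5) that
are defined by tree clades rather than motifs, so subfamily assignment is
nearest labelled reference by core-identity.

The module also reconciles sequence-based calls against database gene
symbols, flagging misannotations (e.g. a BSPH2 deposited as "BSPH1").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .architecture import FN2Architecture
from .blocks import (
    DEFAULT_HYDROPHOBIC,
    BlockId,
    DegeneratePattern,
    parse_pattern,
)

FAMILIES = ("BSP", "BSPH1", "BSPH2")
BSP_SUBFAMILIES = ("BSP1", "BSP2", "BSP3", "BSP5")

#: Family fingerprints: (component key, consensus text).  'CTER' denotes the
#: dipeptide immediately following Block IX.
FINGERPRINTS: dict[str, tuple[tuple[str, str], ...]] = {
    "BSPH1": (
        (BlockId.III.value, "HKWCSLN"),
        (BlockId.VI.value, "ChFPFWY"),
        (BlockId.VIII.value, "FGKKWCSLT"),
    ),
    "BSPH2": (
        (BlockId.IX.value, "YNxDxKWKQC"),
        (BlockId.V.value, "DPP"),
        (BlockId.IV.value, "FxGRWRYC"),
        ("CTER", "SP"),
    ),
}


@dataclass
class FamilyCall:
    seq_id: str
    family: str  # BSP | BSPH1 | BSPH2 | unclassified | not_BSP_superfamily
    subfamily: str = "none"
    evidence: list[tuple[str, str, bool]] = field(default_factory=list)
    score_bsph1: float = 0.0
    score_bsph2: float = 0.0
    subfamily_identity: float | None = None
    subfamily_ambiguous: bool = False
    arch: FN2Architecture | None = None


def _component_window(
    component: str, arch: FN2Architecture, sequence: str
) -> str | None:
    if component == "CTER":
        ext = arch.cter_extension
        return ext[:2] if len(ext) >= 2 else None
    bid = BlockId(component)
    match = arch.block_matches.get(bid)
    return match.matched_subsequence if match else None


def _component_matches(
    pattern: DegeneratePattern,
    window: str | None,
    tolerance: int,
    hydrophobic: frozenset,
) -> bool:
    if window is None or len(window) != len(pattern):
        return False
    mism = sum(
        0 if spec.matches(res, hydrophobic) else 1
        for spec, res in zip(pattern.positions, window)
    )
    return mism <= tolerance


def classify_family(
    arch: FN2Architecture,
    sequence: str,
    theta: float = 2 / 3,
    component_tolerance: int = 1,
    hydrophobic: frozenset = DEFAULT_HYDROPHOBIC,
) -> FamilyCall:
    """Assign the family from fingerprint evidence on an assembled architecture.

    Scores are the fraction of each family's fingerprint components matched
    (allowing ``component_tolerance`` residue deviations inside a
    component).  Decision rule: incomplete architecture ->
    ``not_BSP_superfamily``; BSPH1 if its score reaches ``theta`` and
    exceeds the BSPH2 score (and symmetrically); both below ``theta`` ->
    BSP; a tie at/above ``theta`` -> ``unclassified``.
    """
    call = FamilyCall(seq_id=arch.seq_id, family="not_BSP_superfamily", arch=arch)
    if not arch.complete:
        return call
    scores = {}
    for family, components in FINGERPRINTS.items():
        hits = 0
        for key, consensus in components:
            window = _component_window(key, arch, sequence)
            ok = _component_matches(
                parse_pattern(consensus), window, component_tolerance, hydrophobic
            )
            call.evidence.append((family, key, ok))
            hits += ok
        scores[family] = hits / len(components)
    call.score_bsph1 = scores["BSPH1"]
    call.score_bsph2 = scores["BSPH2"]
    s1, s2 = call.score_bsph1, call.score_bsph2
    if s1 >= theta and s1 > s2:
        call.family = "BSPH1"
    elif s2 >= theta and s2 > s1:
        call.family = "BSPH2"
    elif s1 < theta and s2 < theta:
        call.family = "BSP"
    else:
        call.family = "unclassified"
    return call


def core_identity(a: str, b: str) -> tuple[float, int]:
    """Fractional identity with pairwise deletion of gap columns.

    Sequences are compared over their overlapping prefix; columns where
    either side is ``-`` are excluded.  Returns (identity, n_sites).
    """
    n = min(len(a), len(b))
    used = matches = 0
    for x, y in zip(a[:n], b[:n]):
        if x == "-" or y == "-":
            continue
        used += 1
        matches += x == y
    return (matches / used if used else 0.0), used


def assign_subfamily(
    call: FamilyCall,
    sequence: str,
    references: dict[str, str],
    identity_floor: float = 0.40,
) -> FamilyCall:
    """Nearest-reference BSP subfamily assignment over the tandem-FN2 core.

    ``references`` maps subfamily labels (or labelled reference ids ending
    in the subfamily token) to core sequences.  The subfamily of the
    highest-identity reference wins; ties go to the alphabetically lower
    subfamily with an ambiguity flag; a best identity below
    ``identity_floor`` yields ``none``.
    """
    if call.family != "BSP":
        raise ValueError("subfamily assignment applies to BSP-family calls only")
    if not references:
        raise ValueError("empty reference panel")
    arch = call.arch
    if arch is None or not arch.complete:
        raise ValueError("call carries no complete architecture")
    core = sequence[
        arch.block_matches[BlockId.I].start - 1 : arch.block_matches[BlockId.IX].end
    ]
    scored: list[tuple[float, str]] = []
    for label, ref_core in references.items():
        ident, _ = core_identity(core, ref_core)
        scored.append((ident, label))
    best = max(s for s, _ in scored)
    if best < identity_floor:
        call.subfamily = "none"
        call.subfamily_identity = best
        return call
    winners = sorted(label for s, label in scored if s == best)
    call.subfamily = winners[0]
    call.subfamily_identity = best
    call.subfamily_ambiguous = len(winners) > 1
    return call


# --- annotation reconciliation -------------------------------------------

_TOKEN_RULES: tuple[tuple[str, str], ...] = (
    ("BSP-30", "BSPH2"),  # "BSP-30 kDa like" deposits are BSPH2
    ("RSVP", "BSP"),  # ram seminal vesicle proteins 14/20/22 are BSPs
    ("BSPH1", "BSPH1"),
    ("BSPH2", "BSPH2"),
    ("BSP1", "BSP"),
    ("BSP2", "BSP"),
    ("BSP3", "BSP"),
    ("BSP5", "BSP"),
    ("BSP", "BSP"),
)


def family_token(symbol: str) -> str | None:
    """Extract the family implied by a free-text gene symbol, or None."""
    s = symbol.upper()
    for needle, fam in _TOKEN_RULES:
        if needle in s:
            return fam
    return None


def subfamily_token(symbol: str) -> str | None:
    """Extract a BSP subfamily token (BSP1/2/3/5) if the symbol names one."""
    m = re.search(r"BSP([1235])", symbol.upper())
    return f"BSP{m.group(1)}" if m else None


def reconcile_annotation(existing_symbol: str, call: FamilyCall | str) -> str:
    """Compare a database symbol against a sequence-based family call.

    Returns ``consistent``, ``misannotated``, ``novel`` (no existing
    symbol) or ``unresolved`` (unclassifiable call, or a symbol carrying
    no recognizable family token).
    """
    call_family = call if isinstance(call, str) else call.family
    if call_family in ("unclassified", "not_BSP_superfamily"):
        return "unresolved"
    existing = (existing_symbol or "").strip()
    if not existing:
        return "novel"
    token = family_token(existing)
    if token is None:
        return "unresolved"
    return "consistent" if token == call_family else "misannotated"


def load_nomenclature() -> pd.DataFrame:
    """Load the bundled curated-nomenclature table (accession, species,
    existing_symbol, proposed_symbol)."""
    path = resources.files("bsptools.data").joinpath("nomenclature.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", keep_default_na=False)


def reconcile_table(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reconcile every row of a nomenclature table.

    The proposed symbol stands in for the sequence-based call (the curated
    assignment); the returned frame adds ``existing_family``,
    ``proposed_family`` and ``status`` columns.
    """
    if table is None:
        table = load_nomenclature()
    out = table.copy()
    out["existing_family"] = [
        family_token(s) or "" for s in out["existing_symbol"]
    ]
    out["proposed_family"] = [
        family_token(s) or "" for s in out["proposed_symbol"]
    ]
    out["status"] = [
        reconcile_annotation(row.existing_symbol, row.proposed_family or "unclassified")
        for row in out.itertuples()
    ]
    return out
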