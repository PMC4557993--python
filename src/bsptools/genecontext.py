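"""Gene-neighborhood (synteny) pattern matching for BSP-superfamily loci.

Across mammalian genomes the superfamily occupies three recurrent
neighborhood patterns:

``BSP``             BSP-family genes flanked by the CD177/TEX101 cluster on
                    one side and LYPD3, PHLDB3, ETHE1, ZNF575 on the other;
``BSPH_ELSPBP1``    a BSPH1 core flanked by C19orf68, LIG1, CABP5 and
                    ELSPBP1 on one side and BSPH2, SULT2A1, CRX on the
                    other;
``BSPH_noELSPBP1``  a BSPH1/BSPH2 core where ELSPBP1 is absent and
                    PLA2G4C appears instead.

Matching is orientation-agnostic (gene order may be reversed) and
window-based, because databases disagree on exactly which filler genes sit
between anchors.  The module also cross-checks database gene symbols
against sequence-based family calls, reporting discrepancies such as a
"BSPH1"-labelled gene whose sequence fingerprint says BSPH2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .classify import FamilyCall, family_token


@dataclass
class NeighborhoodGene:
    symbol: str
    strand: str | None = None
    call: FamilyCall | None = None


@dataclass
class NeighborhoodRecord:
    scaffold_id: str
    species: str = ""
    source: str = ""
    genes: list[NeighborhoodGene] = field(default_factory=list)

    @classmethod
    def from_symbols(cls, scaffold_id: str, symbols: list[str], **kw) -> "NeighborhoodRecord":
        return cls(scaffold_id=scaffold_id, genes=[NeighborhoodGene(s) for s in symbols], **kw)


@dataclass(frozen=True)
class SyntenyPattern:
    pattern_id: str
    flank_a: frozenset
    core_families: frozenset  # families acceptable as core genes
    flank_b: frozenset
    required: frozenset = frozenset()
    forbidden: frozenset = frozenset()

    @property
    def anchors(self) -> frozenset:
        return self.flank_a | self.flank_b


PATTERNS: tuple[SyntenyPattern, ...] = (
    SyntenyPattern(
        pattern_id="BSP",
        flank_a=frozenset({"CD177", "TEX101"}),
        core_families=frozenset({"BSP"}),
        flank_b=frozenset({"LYPD3", "PHLDB3", "ETHE1", "ZNF575"}),
    ),
    SyntenyPattern(
        pattern_id="BSPH_ELSPBP1",
        flank_a=frozenset({"C19ORF68", "LIG1", "CABP5", "ELSPBP1"}),
        core_families=frozenset({"BSPH1", "BSPH2"}),
        flank_b=frozenset({"SULT2A1", "CRX"}),
        required=frozenset({"ELSPBP1"}),
    ),
    SyntenyPattern(
        pattern_id="BSPH_noELSPBP1",
        flank_a=frozenset({"PLA2G4C"}),
        core_families=frozenset({"BSPH1", "BSPH2"}),
        flank_b=frozenset({"SULT2A1", "CRX"}),
        required=frozenset({"PLA2G4C"}),
        forbidden=frozenset({"ELSPBP1"}),
    ),
)


@dataclass
class PatternMatch:
    pattern_id: str | None
    score: float
    anchor_hits: list[str]
    reason: str = ""


_DEFAULT_SYNONYMS = {
    "LOC101107624": "BSP5",  # seminal plasma BSP-30 kDa-like deposit = RSVP22
    "BSP5L": "BSP5",
    "BSP-30 KDA LIKE": "BSPH2",
    "RSVP14": "BSP1",
    "RSVP20": "BSP5",
    "RSVP22": "BSP5",
}


def load_synonyms(path: str | None = None) -> dict[str, str]:
    """Symbol synonym table (editable TSV: symbol, canonical)."""
    if path is None:
        res = resources.files("bsptools.data").joinpath("gene_synonyms.tsv")
        with resources.as_file(res) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return {str(r.symbol).upper(): str(r.canonical).upper() for r in df.itertuples()}


def canonical_symbol(symbol: str, synonyms: dict[str, str] | None = None) -> str:
    s = symbol.strip().upper()
    table = _DEFAULT_SYNONYMS if synonyms is None else synonyms
    return table.get(s, s)


def _core_indices(symbols: list[str], pattern: SyntenyPattern) -> list[int]:
    out = []
    for i, s in enumerate(symbols):
        fam = family_token(s)
        if fam in pattern.core_families:
            out.append(i)
    return out


def match_pattern(
    rec: NeighborhoodRecord,
    patterns: tuple[SyntenyPattern, ...] = PATTERNS,
    window: int = 10,
    score_threshold: float = 0.5,
    synonyms: dict[str, str] | None = None,
) -> PatternMatch:
    """Match a neighborhood against the three synteny patterns.

    The score for a pattern is the fraction of its flank anchors found
    within ``window`` genes of the outermost core genes, in either
    direction (reversing the record changes nothing).  The best-scoring
    pattern wins if its score reaches ``score_threshold``, all its
    required anchors are present and no forbidden anchor occurs.
    """
    symbols = [canonical_symbol(g.symbol, synonyms) for g in rec.genes]
    best: PatternMatch | None = None
    any_core = False
    for pattern in patterns:
        cores = _core_indices(symbols, pattern)
        if not cores:
            continue
        any_core = True
        lo = max(0, min(cores) - window)
        hi = min(len(symbols), max(cores) + window + 1)
        neighborhood = set(symbols[lo:hi])
        if pattern.forbidden & neighborhood:
            continue
        if pattern.required - neighborhood:
            continue
        hits = sorted(pattern.anchors & neighborhood)
        score = len(hits) / len(pattern.anchors)
        cand = PatternMatch(pattern.pattern_id, score, hits)
        if best is None or (cand.score, -_pattern_rank(cand)) > (best.score, -_pattern_rank(best)):
            best = cand
    if not any_core:
        return PatternMatch(None, 0.0, [], reason="no core")
    if best is None or best.score < score_threshold:
        return PatternMatch(None, best.score if best else 0.0, best.anchor_hits if best else [],
                            reason="score below threshold")
    return best


def _pattern_rank(match: PatternMatch) -> int:
    for i, p in enumerate(PATTERNS):
        if p.pattern_id == match.pattern_id:
            return i
    return len(PATTERNS)


@dataclass
class Discrepancy:
    scaffold_id: str
    symbol: str
    symbol_family: str | None
    call_family: str
    note: str


def cross_check(
    rec: NeighborhoodRecord, synonyms: dict[str, str] | None = None
) -> list[Discrepancy]:
    """Report genes whose symbol-derived family conflicts with their
    sequence-based call, annotated with the neighborhood's pattern context."""
    context = match_pattern(rec, synonyms=synonyms)
    out: list[Discrepancy] = []
    for gene in rec.genes:
        if gene.call is None:
            continue
        call_family = gene.call.family
        if call_family not in ("BSP", "BSPH1", "BSPH2"):
            continue
        sym_family = family_token(canonical_symbol(gene.symbol, synonyms))
        if sym_family is not None and sym_family != call_family:
            ctx = context.pattern_id or "unmatched"
            out.append(
                Discrepancy(
                    scaffold_id=rec.scaffold_id,
                    symbol=gene.symbol,
                    symbol_family=sym_family,
                    call_family=call_family,
                    note=f"labelled {gene.symbol} in a {ctx} context, sequence says {call_family}",
                )
            )
    return out


def read_neighborhoods(path: str) -> list[NeighborhoodRecord]:
    """Read neighborhood TSV (scaffold_id, species, source, rank, symbol[, strand])."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for (scaffold, species, source), grp in df.groupby(
        ["scaffold_id", "species", "source"], sort=False
    ):
        grp = grp.sort_values("rank")
        genes = [
            NeighborhoodGene(symbol=row.symbol, strand=getattr(row, "strand", None) or None)
            for row in grp.itertuples()
        ]
        records.append(
            NeighborhoodRecord(
                scaffold_id=scaffold, species=species, source=source, genes=genes
            )
        )
    return records
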