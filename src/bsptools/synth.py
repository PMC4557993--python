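"""Synthetic, fully-labelled test data for the whole pipeline.

The generator emulates BSP-superfamily precursors: a signal-peptide-like
N-terminal stretch, the 87-residue tandem-FN2 core instantiated from the
nine conserved block consensi, family fingerprints overwritten for BSPH1 /
BSPH2 (including the BSPH2 ``SP`` C-terminal extension), and controlled
per-position substitution noise.  Free consensus choices (alternative
sets, wildcards, hydrophobic positions, inter-block gap residues) are
drawn once per (family, subfamily) *lineage prototype*; panel members are
noisy copies of their prototype.  This gives panels genuine group
structure — members of a subfamily are mutually closer than to any other
group — which is what makes nearest-reference subfamily assignment and
clade-recovery checks meaningful.

Decoy sequences (single-FN2 truncations and residue-shuffled cores) probe
the specificity of the scanner and classifier.  Everything is
deterministic per seed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import DEFAULT_HYDROPHOBIC, BlockId, load_block_definitions
from .classify import FINGERPRINTS, FamilyCall

AA = "ACDEFGHIKLMNPQRSTVWY"
CORE_LENGTH = 87
#: Core position given the unhoused second cysteine of the C-terminal FN2
#: domain (it must fall in the Block VI -> Block VII gap, positions 53-59).
GAP_CYSTEINE_POSITION = 55

_DISULFIDE_CORE_POSITIONS = (1, 15, 25, 38, 46, GAP_CYSTEINE_POSITION, 72, 87)


@dataclass
class PanelSpec:
    """Recipe for one synthetic panel.  ``counts`` maps (family, subfamily)
    to the number of members; BSPH families use subfamily ``"none"``."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    epsilon: float = 0.0
    prefix_range: tuple[int, int] = (15, 25)
    suffix_range: tuple[int, int] = (5, 15)
    gap_jitter: int = 0
    decoy_single_fn2: int = 0
    decoy_shuffled: int = 0
    architecture_safe: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.epsilon > 0.5:
            warnings.warn("epsilon > 0.5: truth labels may be unrecoverable")


def default_panel_spec(seed: int, epsilon: float = 0.0, per_group: int = 4) -> PanelSpec:
    """The standard study panel: all four BSP subfamilies plus BSPH1/BSPH2."""
    counts = {("BSP", sub): per_group for sub in ("BSP1", "BSP2", "BSP3", "BSP5")}
    counts[("BSPH1", "none")] = per_group
    counts[("BSPH2", "none")] = per_group
    return PanelSpec(counts=counts, epsilon=epsilon, seed=seed)


def _lineage_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode()) & 0x7FFFFFFF])


def _sample_spec(spec_kind, residues, rng, hydrophobic) -> str:
    if spec_kind == "wildcard":
        return AA[rng.integers(len(AA))]
    if spec_kind == "hydrophobic":
        hs = sorted(hydrophobic)
        return hs[rng.integers(len(hs))]
    opts = sorted(residues)
    return opts[0] if len(opts) == 1 else opts[rng.integers(len(opts))]


def _carries_fingerprint(core: list[str], blocks, hydrophobic) -> bool:
    """True if any family fingerprint component sits within one residue
    mismatch of its canonical window in this core."""
    from .blocks import parse_pattern

    starts = {b.block_id.value: b.canonical_start for b in blocks}
    for components in FINGERPRINTS.values():
        for key, consensus in components:
            if key == "CTER":
                continue
            pat = parse_pattern(consensus)
            s = starts[key] - 1
            window = core[s : s + len(pat)]
            mism = sum(
                0 if spec.matches(res, hydrophobic) else 1
                for spec, res in zip(pat.positions, window)
            )
            if mism <= 1:
                return True
    return False


def prototype_core(
    family: str,
    subfamily: str,
    seed: int,
    hydrophobic: frozenset = DEFAULT_HYDROPHOBIC,
) -> str:
    """Instantiate the 87-residue core prototype of one lineage.

    Fixed consensus positions are kept; alternatives / wildcards /
    hydrophobic positions and inter-block gap residues are sampled
    deterministically from the lineage rng; family fingerprints are then
    overwritten (BSPH1: Blocks III, VI, VIII plus the small-residue Block
    II terminus; BSPH2: Blocks IX, V, IV).  All lineages carry the gap
    cysteine completing the second disulfide of the C-terminal domain.
    """
    rng = _lineage_rng(seed, f"{family}/{subfamily}")
    blocks = load_block_definitions()
    for _ in range(100):
        core = [None] * CORE_LENGTH
        for block in blocks:
            for off, pos_spec in enumerate(block.pattern.positions):
                core[block.canonical_start - 1 + off] = _sample_spec(
                    pos_spec.kind, pos_spec.residues, rng, hydrophobic
                )
        for i in range(CORE_LENGTH):
            if core[i] is None:
                core[i] = AA[rng.integers(len(AA))]
        core[GAP_CYSTEINE_POSITION - 1] = "C"
        # BSP lineages are fingerprint-free by definition: resample any
        # draw that lands near a BSPH1/BSPH2 diagnostic component
        if family in FINGERPRINTS or not _carries_fingerprint(core, blocks, hydrophobic):
            break

    if family in FINGERPRINTS:
        from .blocks import parse_pattern

        starts = {b.block_id.value: b.canonical_start for b in blocks}
        for key, consensus in FINGERPRINTS[family]:
            if key == "CTER":
                continue  # handled by the caller as the suffix start
            pat = parse_pattern(consensus)
            s = starts[key] - 1
            for off, pos_spec in enumerate(pat.positions):
                core[s + off] = _sample_spec(pos_spec.kind, pos_spec.residues, rng, hydrophobic)
        if family == "BSPH1":
            # Block II terminal serine is replaced by another small residue
            core[starts["II"] - 1 + 5] = "A"
    return "".join(core)


def _signal_prefix(rng: np.random.Generator, lo: int, hi: int, hydrophobic) -> str:
    length = int(rng.integers(lo, hi + 1))
    hs = sorted(hydrophobic)
    out = ["M"]
    for _ in range(length - 1):
        if rng.random() < 0.6:
            out.append(hs[rng.integers(len(hs))])
        else:
            out.append(AA[rng.integers(len(AA))])
    return "".join(out)


def _random_tail(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AA[rng.integers(len(AA))] for _ in range(length))


def _mutate(seq: str, epsilon: float, rng: np.random.Generator,
            protected: frozenset = frozenset()) -> str:
    if epsilon == 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < epsilon:
            repl = AA[rng.integers(len(AA))]
            while repl == out[i]:
                repl = AA[rng.integers(len(AA))]
            out[i] = repl
    return "".join(out)


def generate_panel(spec: PanelSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate a labelled panel.

    Returns ``(records, truth)`` where records are (seq_id, sequence)
    pairs and truth is a DataFrame with columns seq_id, family, subfamily,
    is_decoy, core_start, core_end (1-based core placement; -1 for
    decoys without a planted core).  Byte-identical for identical specs.
    """
    records: list[tuple[str, str]] = []
    truth_rows = []
    for (family, subfamily), count in sorted(spec.counts.items()):
        proto = prototype_core(family, subfamily, spec.seed)
        lineage = f"{family}.{subfamily}" if subfamily != "none" else family
        rng = _lineage_rng(spec.seed, f"members/{family}/{subfamily}")
        for k in range(count):
            seq_id = f"{lineage}_{k + 1:03d}"
            prefix = _signal_prefix(rng, *spec.prefix_range, DEFAULT_HYDROPHOBIC)
            tail = _random_tail(rng, *spec.suffix_range)
            suffix = ("SP" + tail) if family == "BSPH2" else tail
            core_start = len(prefix) + 1
            protected = frozenset(
                core_start - 1 + p - 1 for p in _DISULFIDE_CORE_POSITIONS
            ) if spec.architecture_safe else frozenset()
            seq = _mutate(prefix + proto + suffix, spec.epsilon, rng, protected)
            records.append((seq_id, seq))
            truth_rows.append(
                dict(seq_id=seq_id, family=family, subfamily=subfamily,
                     is_decoy=False, core_start=core_start,
                     core_end=core_start + CORE_LENGTH - 1)
            )

    rng = _lineage_rng(spec.seed, "decoys")
    base = prototype_core("BSP", "BSP1", spec.seed)
    for k in range(spec.decoy_single_fn2):
        seq_id = f"decoy.single_{k + 1:03d}"
        prefix = _signal_prefix(rng, *spec.prefix_range, DEFAULT_HYDROPHOBIC)
        seq = prefix + base[:38] + _random_tail(rng, 20, 30)
        records.append((seq_id, seq))
        truth_rows.append(dict(seq_id=seq_id, family="none", subfamily="none",
                               is_decoy=True, core_start=-1, core_end=-1))
    for k in range(spec.decoy_shuffled):
        seq_id = f"decoy.shuffled_{k + 1:03d}"
        shuffled = "".join(rng.permutation(list(base)))
        prefix = _signal_prefix(rng, *spec.prefix_range, DEFAULT_HYDROPHOBIC)
        records.append((seq_id, prefix + shuffled))
        truth_rows.append(dict(seq_id=seq_id, family="none", subfamily="none",
                               is_decoy=True, core_start=-1, core_end=-1))

    return records, pd.DataFrame(truth_rows)


def reference_cores(seed: int) -> dict[str, str]:
    """Prototype cores of the four BSP subfamilies, keyed by subfamily."""
    return {sub: prototype_core("BSP", sub, seed) for sub in ("BSP1", "BSP2", "BSP3", "BSP5")}


def rsvp20_like_precursor(seed: int = 0) -> tuple[str, int]:
    """A synthetic stand-in for the RSVP20 (ovine BSP5b) precursor.

    The real precursor places the core frame at offset 62: the Block I
    cysteine is residue 63, so the conserved Block III tryptophan falls at
    precursor position 86 and the Block VIII tryptophan at 133.  Returns
    (sequence, core_offset).  Synthetic — built from the consensus
    prototype, not the database entry.
    """
    proto = prototype_core("BSP", "BSP5", seed)
    rng = _lineage_rng(seed, "rsvp20-like")
    prefix = "M" + "".join(
        sorted(DEFAULT_HYDROPHOBIC)[rng.integers(8)] for _ in range(61)
    )
    return prefix + proto + _random_tail(rng, 8, 8), 62


# --- neighborhoods --------------------------------------------------------

NEIGHBORHOOD_TEMPLATES: dict[str, list[str]] = {
    "BSP": ["CD177", "TEX101", "BSP5", "BSP3", "BSP1",
            "LYPD3", "PHLDB3", "ETHE1", "ZNF575"],
    "BSPH_ELSPBP1": ["C19ORF68", "LIG1", "CABP5", "ELSPBP1",
                     "BSPH1", "BSPH2", "SULT2A1", "CRX"],
    "BSPH_noELSPBP1": ["PLA2G4C", "BSPH2", "BSPH1", "SULT2A1", "CRX"],
}


def generate_neighborhoods(
    patterns: list[str] | None = None,
    seed: int = 0,
    n_filler: int = 0,
) -> tuple[list, list[str]]:
    """Generate one neighborhood record per requested pattern.

    Filler genes (inert symbols) are inserted at random interior positions
    to emulate the variable gene counts seen between genome databases.
    Returns (records, truth_pattern_ids).
    """
    from .genecontext import NeighborhoodRecord

    if patterns is None:
        patterns = list(NEIGHBORHOOD_TEMPLATES)
    unknown = set(patterns) - set(NEIGHBORHOOD_TEMPLATES)
    if unknown:
        raise ValueError(f"unknown pattern ids: {sorted(unknown)}")
    rng = np.random.default_rng([seed, zlib.crc32(b"neighborhoods") & 0x7FFFFFFF])
    records, labels = [], []
    for i, pid in enumerate(patterns):
        symbols = list(NEIGHBORHOOD_TEMPLATES[pid])
        for k in range(n_filler):
            pos = int(rng.integers(1, len(symbols)))
            symbols.insert(pos, f"ZZFILL{k + 1}")
        records.append(
            NeighborhoodRecord.from_symbols(
                scaffold_id=f"synthetic_scaffold_{i + 1}", symbols=symbols,
                species="synthetic", source="synth",
            )
        )
        labels.append(pid)
    return records, labels


def ferret_style_record():
    """A misannotated-neighborhood fixture: a gene deposited as BSPH1 whose
    sequence-based call is BSPH2, sitting in a PLA2G4C (no-ELSPBP1) context."""
    from .genecontext import NeighborhoodGene, NeighborhoodRecord

    rec = NeighborhoodRecord(
        scaffold_id="synthetic_ferret_scaffold", species="synthetic", source="synth"
    )
    rec.genes = [
        NeighborhoodGene("PLA2G4C"),
        NeighborhoodGene("BSPH1", call=FamilyCall(seq_id="mis1", family="BSPH2")),
        NeighborhoodGene("SULT2A1"),
        NeighborhoodGene("CRX"),
    ]
    return rec
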