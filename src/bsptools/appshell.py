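"""Pipeline orchestration, configuration and the lab quantitation formula.

``run_pipeline`` drives the full analysis over a FASTA input: block
scanning, architecture assembly, family/subfamily classification,
annotation reconciliation, NJ tree with bootstrap supports, and synteny
pattern matching — each stage writing a TSV (or Newick) report stamped
with the tool version, seed and a configuration hash so reruns are
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .architecture import architecture_row, assemble
from .blocks import load_block_definitions, matches_to_rows, scan_blocks
from .classify import (
    assign_subfamily,
    classify_family,
    family_token,
    reconcile_annotation,
)
from .genecontext import cross_check, match_pattern, read_neighborhoods
from .io import InputError, read_fasta, read_tsv, write_tsv
from .phylo import Alignment, annotate_supports, bootstrap, distance_matrix, nj_tree, write_newick
from .synth import reference_cores


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    input_fasta: str = ""
    annotations_tsv: str | None = None  # accession/seq_id, existing_symbol
    neighborhoods_tsv: str | None = None
    out_dir: str = "bsptools_out"
    run_scan: bool = True
    run_classify: bool = True
    run_phylo: bool = True
    run_genecontext: bool = True
    tolerance_per_block: int = 1
    gap_slack: int = 2
    theta: float = 2 / 3
    identity_floor: float = 0.40
    distance_model: str = "dayhoff"
    bootstrap_replicates: int = 100
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.tolerance_per_block <= 5:
            raise ValueError("tolerance_per_block outside [0, 5]")
        if not 0 <= self.gap_slack <= 10:
            raise ValueError("gap_slack outside [0, 10]")
        if not 0 < self.theta <= 1:
            raise ValueError("theta outside (0, 1]")
        if not 0 <= self.identity_floor <= 1:
            raise ValueError("identity_floor outside [0, 1]")
        if self.distance_model not in ("p", "poisson", "dayhoff"):
            raise ValueError(f"unknown distance model {self.distance_model!r}")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded,
        so reruns into different directories produce identical reports)."""
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def header_note(self) -> str:
        return f"bsptools {__version__} seed={self.seed} config={self.config_hash()}"


def protein_concentration(
    a280: float,
    a494: float,
    dilution: float = 1.0,
    epsilon: float = 45380.0,
    fluorophore_correction: float = 0.11,
) -> float:
    """Molar concentration of a fluorophore-conjugated protein.

    ``(A280 - correction * A494) * dilution / epsilon``: the A494 term
    removes the dye's own contribution to the 280 nm absorbance.  Defaults
    are the RSVP20 values (theoretical molar extinction coefficient
    45,380 /M/cm; Alexa Fluor 488 correction factor 0.11).  A negative
    corrected absorbance is returned as-is with a warning.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if a280 < 0 or a494 < 0:
        raise ValueError("absorbances must be non-negative")
    corrected = a280 - fluorophore_correction * a494
    if corrected < 0:
        warnings.warn("corrected absorbance is negative; check the dye correction")
    return corrected * dilution / epsilon


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all enabled stages; returns a map of report name -> path."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    note = config.header_note()
    outputs: dict[str, Path] = {}

    try:
        records = read_fasta(config.input_fasta)
    except (OSError, InputError) as exc:
        raise PipelineError(f"cannot read input FASTA: {exc}") from exc
    if not records:
        raise PipelineError(f"input FASTA {config.input_fasta} contains no sequences")

    blocks = load_block_definitions()
    scan_rows, arch_rows, class_rows = [], [], []
    archs, calls = {}, {}
    for seq_id, seq in records:
        matches = scan_blocks(seq, config.tolerance_per_block, blocks)
        scan_rows.extend(matches_to_rows(seq_id, matches))
        arch = assemble(matches, seq, config.gap_slack, seq_id=seq_id, blocks=blocks)
        archs[seq_id] = (arch, seq)
        arch_rows.append(architecture_row(arch))
        call = classify_family(arch, seq, theta=config.theta)
        if call.family == "BSP":
            assign_subfamily(call, seq, reference_cores(config.seed), config.identity_floor)
        calls[seq_id] = call
        class_rows.append(
            dict(
                seq_id=seq_id,
                family=call.family,
                subfamily=call.subfamily,
                score_bsph1=round(call.score_bsph1, 4),
                score_bsph2=round(call.score_bsph2, 4),
                subfamily_identity="" if call.subfamily_identity is None
                else round(call.subfamily_identity, 4),
            )
        )

    if config.run_scan:
        outputs["scan"] = out_dir / "scan.tsv"
        write_tsv(outputs["scan"], scan_rows, note)
        outputs["architecture"] = out_dir / "architecture.tsv"
        write_tsv(outputs["architecture"], arch_rows, note)
    if config.run_classify:
        outputs["classification"] = out_dir / "classification.tsv"
        write_tsv(outputs["classification"], class_rows, note)

    if config.run_classify and config.annotations_tsv:
        ann = read_tsv(config.annotations_tsv)
        rec_rows = []
        for row in ann.itertuples():
            seq_id = getattr(row, "seq_id", getattr(row, "accession", ""))
            existing = getattr(row, "existing_symbol", "")
            call = calls.get(seq_id)
            status = reconcile_annotation(existing, call) if call else "unresolved"
            rec_rows.append(
                dict(
                    seq_id=seq_id,
                    existing_symbol=existing,
                    existing_family=family_token(existing) or "",
                    called_family=call.family if call else "",
                    status=status,
                )
            )
        outputs["reconciliation"] = out_dir / "reconciliation.tsv"
        write_tsv(outputs["reconciliation"], rec_rows, note)

    if config.run_phylo:
        cores = {
            seq_id: seq[arch.fn2_1_span[0] - 1 : arch.fn2_2_span[1]]
            for seq_id, (arch, seq) in archs.items()
            if arch.complete
        }
        if len(cores) >= 3:
            width = min(len(c) for c in cores.values())
            aln = Alignment(list(cores), [c[:width] for c in cores.values()])
            tree = nj_tree(distance_matrix(aln, config.distance_model))
            supports = bootstrap(
                aln, config.distance_model, config.bootstrap_replicates, config.seed
            )
            annotate_supports(tree, supports)
            outputs["tree"] = out_dir / "tree.nwk"
            outputs["tree"].write_text(f"[{note}]\n" + write_newick(tree))

    if config.run_genecontext and config.neighborhoods_tsv:
        pattern_rows, disc_rows = [], []
        for rec in read_neighborhoods(config.neighborhoods_tsv):
            for gene in rec.genes:
                if gene.symbol in calls:
                    gene.call = calls[gene.symbol]
            pm = match_pattern(rec)
            pattern_rows.append(
                dict(
                    scaffold_id=rec.scaffold_id,
                    pattern=pm.pattern_id or "none",
                    score=round(pm.score, 3),
                    anchors=",".join(pm.anchor_hits),
                    reason=pm.reason,
                )
            )
            for disc in cross_check(rec):
                disc_rows.append(
                    dict(
                        scaffold_id=disc.scaffold_id,
                        symbol=disc.symbol,
                        symbol_family=disc.symbol_family,
                        call_family=disc.call_family,
                        note=disc.note,
                    )
                )
        outputs["patterns"] = out_dir / "patterns.tsv"
        write_tsv(outputs["patterns"], pattern_rows, note)
        outputs["discrepancies"] = out_dir / "discrepancies.tsv"
        write_tsv(outputs["discrepancies"], disc_rows, note)

    return outputs
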