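"""Entropy/gap-filtered scan for mitochondrial codon reassignments.

Given the coding sequences of a focal mitochondrial genome and, per gene, an
amino-acid alignment of reference taxa that includes the focal translation
(with the scanned codon rendered as 'X' so an unknown code cannot bias the
alignment), each focal codon is mapped to its alignment column.  Columns
containing the target codon that are highly conserved among the references
(Shannon entropy below a threshold, gap fraction below a threshold) vote for
the amino acid the codon "corresponds to" via their plurality reference
residue; the aggregated column fractions support or refute a reassignment
call, e.g. TGA read as serine rather than tryptophan.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .core_io import Alignment, GeneticCode, SequenceRecord, GAP_CHARS

DEFAULT_ENTROPY_MAX = 1.0   # nats
DEFAULT_GAP_MAX = 0.20


def shannon_entropy(counts: dict[str, float], base: str = "nats") -> float:
    """Shannon entropy of a residue count distribution (gaps excluded)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("entropy of empty counts is undefined")
    h = 0.0
    for c in counts.values():
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    if base == "bits":
        h /= math.log(2.0)
    elif base != "nats":
        raise ValueError("base must be 'nats' or 'bits'")
    return h


@dataclass
class CodonColumn:
    gene_id: str
    column_index: int          # 0-based in the reference alignment
    focal_codon: str
    ref_counts: dict[str, int]
    gap_fraction: float
    entropy: float

    def plurality(self) -> list[str]:
        """Residue(s) with the maximal reference count (ties all returned)."""
        if not self.ref_counts:
            return []
        top = max(self.ref_counts.values())
        return sorted(a for a, c in self.ref_counts.items() if c == top)


@dataclass
class ReassignmentReport:
    target_codon: str
    n_candidate_columns: int
    n_retained: int
    modal_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def call(self) -> tuple[str | None, float]:
        if not self.modal_fractions:
            return None, 0.0
        aa = max(self.modal_fractions, key=lambda a: (self.modal_fractions[a], a))
        return aa, self.modal_fractions[aa]


def map_codons_to_columns(focal_cds: SequenceRecord, ref_alignment: Alignment,
                          code: GeneticCode, target_codon: str | None = None,
                          entropy_base: str = "nats") -> list[CodonColumn]:
    """Map each focal codon to its reference-alignment column.

    The focal CDS is translated codon by codon (the ``target_codon``, if
    given, renders as 'X'); the row of ``ref_alignment`` whose ungapped
    residues equal this translation anchors the codon-to-column map through
    its gaps.  Reference counts at each column come from all other rows.
    """
    cds = focal_cds.residues.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} of {focal_cds.id!r} is not a "
                         "multiple of 3")
    target = target_codon.upper().replace("U", "T") if target_codon else None
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    translation = "".join(
        "X" if (target and c == target) else code.translate_codon(c) for c in codons)
    translation = translation.rstrip("*")
    codons = codons[:len(translation)]

    focal_row = None
    for rec in ref_alignment.records:
        if rec.ungapped() == translation:
            focal_row = rec
            break
    if focal_row is None:
        raise ValueError(f"focal translation of {focal_cds.id!r} not found as a "
                         "row of the reference alignment")

    # codon index -> alignment column through the focal row's gaps
    col_of_codon = [j for j, ch in enumerate(focal_row.residues) if ch not in GAP_CHARS]
    if len(col_of_codon) != len(codons):
        raise ValueError("focal row length does not match CDS after gap removal")

    others = [r for r in ref_alignment.records if r.id != focal_row.id]
    out = []
    for i, codon in enumerate(codons):
        j = col_of_codon[i]
        residues = [r.residues[j] for r in others]
        gaps = sum(ch in GAP_CHARS for ch in residues)
        counts = Counter(ch for ch in residues if ch not in GAP_CHARS and ch != "X")
        gap_fraction = gaps / len(residues) if residues else 1.0
        entropy = shannon_entropy(counts, entropy_base) if counts else 0.0
        out.append(CodonColumn(focal_cds.id, j, codon, dict(counts),
                               gap_fraction, entropy))
    return out


def scan_codon_reassignment(columns: list[CodonColumn], target_codon: str,
                            entropy_max: float = DEFAULT_ENTROPY_MAX,
                            gap_max: float = DEFAULT_GAP_MAX) -> ReassignmentReport:
    """Aggregate plurality votes over conserved columns of the target codon.

    Retains columns with the target codon, entropy < ``entropy_max`` and
    gap fraction < ``gap_max``; each retained column votes for its plurality
    reference residue (ties split fractionally).
    """
    if entropy_max <= 0 or gap_max <= 0:
        raise ValueError("thresholds must be positive")
    target = target_codon.upper().replace("U", "T")
    candidates = [c for c in columns if c.focal_codon == target]
    retained = [c for c in candidates
                if c.entropy < entropy_max and c.gap_fraction < gap_max
                and c.ref_counts]
    votes: dict[str, float] = {}
    for col in retained:
        top = col.plurality()
        for aa in top:
            votes[aa] = votes.get(aa, 0.0) + 1.0 / len(top)
    n = len(retained)
    fractions = {aa: v / n for aa, v in votes.items()} if n else {}
    return ReassignmentReport(target, len(candidates), n, fractions)


def report_to_tsv(report: ReassignmentReport) -> str:
    lines = [f"target_codon\t{report.target_codon}",
             f"n_candidate_columns\t{report.n_candidate_columns}",
             f"n_retained\t{report.n_retained}",
             "amino_acid\tmodal_fraction"]
    for aa in sorted(report.modal_fractions, key=lambda a: -report.modal_fractions[a]):
        lines.append(f"{aa}\t{report.modal_fractions[aa]:.4f}")
    return "\n".join(lines)
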