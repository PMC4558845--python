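"""Core value types and readers/writers for sequences, alignments and trees.

Sequences and alignments are read with Biopython (FASTA, Stockholm, relaxed
PHYLIP); trees are read with dendropy and converted into a light-weight
:class:`Phylogeny` suited to edge-indexed likelihood work.  All interval
coordinates in this package are 0-based half-open; reading frames are named
``+1, +2, +3, -1, -2, -3``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino-acid"

GAP_CHARS = "-."

# Unambiguous symbols; ambiguity codes are tolerated and treated as missing
# data downstream.
NT_SYMBOLS = set("ACGTU")
NT_AMBIG = set("RYSWKMBDHVN")
AA_SYMBOLS = set("ACDEFGHIKLMNPQRSTVWY")
AA_AMBIG = set("XBZJUO*")

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
NT_ORDER = "ACGT"
NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


class SequenceFormatError(ValueError):
    """Raised on malformed sequence/alignment/tree input."""


@dataclass
class SequenceRecord:
    """A named sequence with a declared alphabet.

    Gap characters are only legal inside alignments; free-standing records
    reject them unless ``allow_gaps`` is set at validation time.
    """

    id: str
    residues: str
    alphabet: str = AMINO_ACID

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence id must be non-empty")
        self.residues = self.residues.upper()

    def validate(self, allow_gaps: bool = False) -> "SequenceRecord":
        legal = (NT_SYMBOLS | NT_AMBIG) if self.alphabet == NUCLEOTIDE else (AA_SYMBOLS | AA_AMBIG)
        if allow_gaps:
            legal = legal | set(GAP_CHARS)
        for pos, ch in enumerate(self.residues):
            if ch not in legal:
                raise SequenceFormatError(
                    f"illegal residue {ch!r} at position {pos} in sequence {self.id!r}"
                )
        return self

    def ungapped(self) -> str:
        return "".join(c for c in self.residues if c not in GAP_CHARS)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Gapped records over a shared column coordinate system."""

    records: list[SequenceRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceFormatError("alignment must contain at least one record")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            bad = sorted({r.id for r in self.records})
            raise SequenceFormatError(f"ragged alignment rows: {bad}")
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise SequenceFormatError(f"duplicate sequence id {r.id!r}")
            seen.add(r.id)
            # normalize '.' gaps to '-'
            r.residues = r.residues.replace(".", "-")
            if not r.ungapped():
                raise SequenceFormatError(f"all-gap row {r.id!r}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return sum(c == "-" for c in col) / len(col)

    def subset(self, ids: list[str]) -> "Alignment":
        keep = set(ids)
        return Alignment([r for r in self.records if r.id in keep], dict(self.metadata))


@dataclass
class GeneticCode:
    """A 64-entry codon table; '*' marks stop codons."""

    table_id: int
    codon_map: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise SequenceFormatError("genetic code must define all 64 codons")

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        tab = CodonTable.unambiguous_dna_by_id[table_id]
        cmap = dict(tab.forward_table)
        for stop in tab.stop_codons:
            cmap[stop] = "*"
        return cls(table_id, cmap)

    def translate_codon(self, codon: str) -> str:
        codon = codon.upper().replace("U", "T")
        return self.codon_map.get(codon, "X")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

EUKARYOTE = "eukaryote"
PROKARYOTE = "prokaryote"
MITOCHONDRIAL = "mitochondrial"
CYTOSOLIC = "cytosolic"
UNKNOWN = "unknown"


class Phylogeny:
    """Rooted tree with branch lengths and optional tip annotations.

    Nodes are integer-indexed; node 0 is the root.  Every non-root node
    defines the edge to its parent, so edge ids are simply non-root node
    indices.  ``domain`` maps tip labels to eukaryote/prokaryote and
    ``lineage`` maps tips to mitochondrial/cytosolic/unknown; both are used
    by placement classification.
    """

    def __init__(self) -> None:
        self.parent: list[int | None] = []
        self.children: list[list[int]] = []
        self.length: list[float] = []
        self.label: list[str | None] = []
        self.domain: dict[str, str] = {}
        self.lineage: dict[str, str] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, parent: int | None, length: float, label: str | None) -> int:
        idx = len(self.parent)
        self.parent.append(parent)
        self.children.append([])
        self.length.append(length)
        self.label.append(label)
        if parent is not None:
            self.children[parent].append(idx)
        return idx

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, default_length: float | None = None) -> "Phylogeny":
        phy = cls()
        seen_tips: set[str] = set()

        def visit(node: dendropy.Node, parent_idx: int | None) -> None:
            label = node.taxon.label.replace(" ", "_") if node.taxon else None
            if label is not None:
                if label in seen_tips and node.is_leaf():
                    raise SequenceFormatError(f"duplicate tip label {label!r}")
                if node.is_leaf():
                    seen_tips.add(label)
            length = node.edge.length
            if length is None:
                if parent_idx is None:
                    length = 0.0
                elif default_length is not None:
                    length = default_length
                else:
                    raise SequenceFormatError(
                        f"missing branch length on edge above {label or 'internal node'}"
                    )
            if length < 0:
                raise SequenceFormatError("negative branch length")
            idx = phy.add_node(parent_idx, float(length), label if node.is_leaf() else None)
            for child in node.child_nodes():
                visit(child, idx)

        visit(tree.seed_node, None)
        return phy

    @classmethod
    def from_newick(cls, text: str, default_length: float | None = None) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise SequenceFormatError(f"newick parse error: {exc}") from exc
        return cls.from_dendropy(tree, default_length)

    # -- queries ----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    def is_tip(self, idx: int) -> bool:
        return not self.children[idx]

    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_tip(i)]

    def tip_labels(self) -> list[str]:
        return [self.label[i] for i in self.tip_indices()]

    def edges(self) -> list[int]:
        """Edge ids: every non-root node indexes the edge to its parent."""
        return [i for i in range(self.n_nodes) if self.parent[i] is not None]

    def postorder(self) -> list[int]:
        order: list[int] = []

        def rec(i: int) -> None:
            for c in self.children[i]:
                rec(c)
            order.append(i)

        rec(self.root)
        return order

    def subtended_tips(self, edge: int) -> list[str]:
        """Tip labels on the child side of an edge (away from the root)."""
        out: list[str] = []
        stack = [edge]
        while stack:
            i = stack.pop()
            if self.is_tip(i):
                out.append(self.label[i])
            stack.extend(self.children[i])
        return sorted(out)

    def annotate_domains(self, domain: dict[str, str]) -> None:
        missing = set(self.tip_labels()) - set(domain)
        if missing:
            raise SequenceFormatError(f"tips without domain annotation: {sorted(missing)}")
        self.domain = dict(domain)

    def annotate_lineages(self, lineage: dict[str, str]) -> None:
        self.lineage = dict(lineage)

    # -- serialization ----------------------------------------------------
    def to_newick(self, edge_numbers: bool = False) -> str:
        """Newick string; with ``edge_numbers`` appends ``{id}`` per jplace v3."""

        def rec(i: int) -> str:
            if self.is_tip(i):
                s = self.label[i]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if self.parent[i] is not None:
                s += f":{self.length[i]:.10g}"
                if edge_numbers:
                    s += "{%d}" % i
            return s

        return rec(self.root) + ";"


# ---------------------------------------------------------------------------
# Parsing operations
# ---------------------------------------------------------------------------

_ALN_FORMATS = {"fasta": "fasta", "stockholm": "stockholm", "phylip": "phylip-relaxed"}


def _guess_alphabet(residues: str) -> str:
    bare = set(residues.upper()) - set(GAP_CHARS)
    if bare and bare <= (NT_SYMBOLS | NT_AMBIG):
        return NUCLEOTIDE
    return AMINO_ACID


def parse_sequences(path: str | os.PathLike, format: str = "fasta",
                    alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a sequence file into a list of validated records.

    Ids are the first whitespace-delimited token of each header; order is
    preserved.  Duplicate ids, empty files and illegal residues are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), format):
        if rec.id in seen:
            raise SequenceFormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        alpha = alphabet or _guess_alphabet(residues)
        records.append(SequenceRecord(rec.id, residues, alpha).validate())
    if not records:
        raise SequenceFormatError(f"no sequences found in {path}")
    return records


def parse_alignment(path: str | os.PathLike, format: str = "fasta",
                    alphabet: str | None = None) -> Alignment:
    """Read a FASTA/Stockholm/relaxed-PHYLIP alignment.

    ``'.'`` and ``'-'`` are both accepted as gaps and normalized to ``'-'``.
    """
    if format not in _ALN_FORMATS:
        raise ValueError(f"unsupported alignment format {format!r}")
    msa = AlignIO.read(str(path), _ALN_FORMATS[format])
    records = []
    for rec in msa:
        residues = str(rec.seq).upper().replace(".", "-")
        alpha = alphabet or _guess_alphabet(residues)
        records.append(SequenceRecord(rec.id, residues, alpha).validate(allow_gaps=True))
    return Alignment(records)


def write_sequences(records: list[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.residues}\n")


def write_alignment(aln: Alignment, path: str | os.PathLike) -> None:
    write_sequences(aln.records, path)


def parse_tree(path: str | os.PathLike, default_length: float | None = None) -> Phylogeny:
    """Read a Newick tree; all edges must carry branch lengths.

    Round-trips through :meth:`Phylogeny.to_newick` preserve topology and
    branch lengths to 10 significant digits.
    """
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read(), default_length)


def write_tree(phy: Phylogeny, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(phy.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


def translate_six_frames(record: SequenceRecord, code: GeneticCode,
                         min_len: int = 30) -> list[SequenceRecord]:
    """Extract stop-to-stop open reading frames from all six frames.

    Returns amino-acid records of length >= ``min_len``; ids encode the
    parent id, frame name and the 0-based half-open nucleotide interval on
    the forward strand.  Ambiguous codons translate as 'X'.
    """
    if record.alphabet != NUCLEOTIDE:
        raise ValueError("translate_six_frames requires a nucleotide record")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = record.residues.replace("U", "T")
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    out: list[SequenceRecord] = []
    for frame in FRAMES:
        strand, off = frame[0], int(frame[1]) - 1
        s = seq if strand == "+" else rc
        peptide = []
        for i in range(off, len(s) - 2, 3):
            peptide.append(code.translate_codon(s[i:i + 3]))
        # split at stops, keep coordinates
        start = 0
        pep = "".join(peptide)
        for segment in pep.split("*"):
            if len(segment) >= min_len and set(segment) != {"X"}:
                aa_start = start
                nt_a = off + 3 * aa_start
                nt_b = off + 3 * (aa_start + len(segment))
                if strand == "-":
                    nt_a, nt_b = n - nt_b, n - nt_a
                out.append(SequenceRecord(
                    f"{record.id}|{frame}|{nt_a}-{nt_b}", segment, AMINO_ACID))
            start += len(segment) + 1
    return out
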