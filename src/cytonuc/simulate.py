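"""Synthetic-data generators with known ground truth for every pipeline stage.

These generators emulate the statistical structure of the study system:
ortholog families with annotated eukaryote/prokaryote clades and paralogous
mitochondrial/cytosolic lineages, transcriptome-like fragmentary search
databases with prokaryotic contaminants, per-specificity rate tables obeying
the compensatory linear model, and mitochondrial coding sequences with
planted codon reassignments.  All generators are deterministic under a seed;
a global seed expands to per-component child seeds through
``numpy.random.SeedSequence(seed).spawn``.

Alignments are simulated gap-free (no indel process); fragmentation creates
terminal truncation only, as in assembled transcript fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (AA_ORDER, AMINO_ACID, CYTOSOLIC, EUKARYOTE,
                      MITOCHONDRIAL, NUCLEOTIDE, Alignment, GeneticCode,
                      Phylogeny, PROKARYOTE, SequenceRecord)
from .substitution import AminoAcidModel, K80Model

NT_ORDER = "ACGT"

DEFAULT_N_EUK = 8          # split 4 mitochondrial / 4 cytosolic paralogs
DEFAULT_N_PROK = 6
DEFAULT_BRANCH_MEAN = 0.15
FRAGMENT_FLOOR = 30        # aa; transcript fragments shorter than this are
                           # below the search length floor
FRAGMENT_MEAN_EXTRA = 50   # geometric mean length above the floor


def child_seed(seed: int, index: int) -> int:
    """Deterministic per-component seed below 2**31."""
    ss = np.random.SeedSequence([seed, index])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def random_clade(labels: list[str], rng: np.random.Generator,
                 phy: Phylogeny, parent: int, mean_bl: float) -> None:
    """Random binary subtree over ``labels`` by recursive random splits."""
    if len(labels) == 1:
        phy.add_node(parent, float(rng.exponential(mean_bl)), labels[0])
        return
    node = phy.add_node(parent, float(rng.exponential(mean_bl)), None)
    k = int(rng.integers(1, len(labels)))
    order = list(rng.permutation(len(labels)))
    left = [labels[i] for i in order[:k]]
    right = [labels[i] for i in order[k:]]
    random_clade(left, rng, phy, node, mean_bl)
    random_clade(right, rng, phy, node, mean_bl)


def simulate_family_tree(n_euk: int = DEFAULT_N_EUK, n_prok: int = DEFAULT_N_PROK,
                         mean_bl: float = DEFAULT_BRANCH_MEAN, seed: int = 0,
                         split_lineages: bool = True) -> Phylogeny:
    """Annotated family tree: a eukaryote clade (optionally split into
    mitochondrial and cytosolic paralog subclades) sister to a prokaryote
    clade."""
    rng = np.random.default_rng(seed)
    phy = Phylogeny()
    root = phy.add_node(None, 0.0, None)
    euk_labels = [f"euk{i+1}" for i in range(n_euk)]
    prok_labels = [f"prok{i+1}" for i in range(n_prok)]
    if split_lineages and n_euk >= 2:
        euk_node = phy.add_node(root, float(rng.exponential(mean_bl)), None)
        half = n_euk // 2
        mt = [f"euk_mt{i+1}" for i in range(half)]
        cy = [f"euk_cy{i+1}" for i in range(n_euk - half)]
        euk_labels = mt + cy
        random_clade(mt, rng, phy, euk_node, mean_bl)
        random_clade(cy, rng, phy, euk_node, mean_bl)
        lineage = {t: MITOCHONDRIAL for t in mt} | {t: CYTOSOLIC for t in cy}
    else:
        random_clade(euk_labels, rng, phy, root, mean_bl)
        lineage = {}
    random_clade(prok_labels, rng, phy, root, mean_bl)
    phy.annotate_domains({t: EUKARYOTE for t in euk_labels}
                         | {t: PROKARYOTE for t in prok_labels})
    phy.annotate_lineages(lineage)
    return phy


# ---------------------------------------------------------------------------
# Sequence evolution along a tree
# ---------------------------------------------------------------------------

def _evolve_states(parent_states: np.ndarray, P: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample child states site-wise from transition rows of P."""
    u = rng.random(len(parent_states))
    cum = np.cumsum(P, axis=1)
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def simulate_alignment(tree: Phylogeny, model: AminoAcidModel | K80Model,
                       n_sites: int, seed: int = 0) -> Alignment:
    """Evolve a gap-free alignment along the tree under the model.

    Root states are drawn from the equilibrium distribution; when the model
    carries discrete-gamma heterogeneity each site keeps one category rate
    along the whole tree.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    is_aa = isinstance(model, AminoAcidModel)
    if is_aa:
        pi = model.equilibrium_freqs
        alphabet, letters = AMINO_ACID, AA_ORDER
        rates = model.category_rates()
    else:
        pi = np.full(4, 0.25)
        alphabet, letters = NUCLEOTIDE, NT_ORDER
        rates = np.ones(1)
    site_rates = rates[rng.integers(0, len(rates), size=n_sites)]
    unique_rates = np.unique(site_rates)

    states = {tree.root: rng.choice(len(pi), size=n_sites, p=pi)}
    order = tree.postorder()[::-1]
    for v in order:
        if tree.parent[v] is None:
            continue
        t = tree.length[v]
        child = np.empty(n_sites, dtype=np.int64)
        for r in unique_rates:
            mask = site_rates == r
            P = model.transition_probabilities(r * t)
            child[mask] = _evolve_states(states[tree.parent[v]][mask], P, rng)
        states[v] = child
    records = [SequenceRecord(tree.label[v], "".join(letters[s] for s in states[v]),
                              alphabet)
               for v in tree.tip_indices()]
    return Alignment(records)


# ---------------------------------------------------------------------------
# Profiling databases
# ---------------------------------------------------------------------------

@dataclass
class ProfilingTruth:
    labels: dict[str, str] = field(default_factory=dict)    # id -> euk/prok
    source_tip: dict[str, str] = field(default_factory=dict)

    def score(self, retained: list[str]) -> tuple[float, float]:
        """(recall over eukaryote fragments, leakage of contaminants)."""
        euk = [i for i, lab in self.labels.items() if lab == EUKARYOTE]
        prok = [i for i, lab in self.labels.items() if lab == PROKARYOTE]
        kept = set(retained)
        recall = sum(i in kept for i in euk) / len(euk) if euk else 0.0
        leakage = sum(i in kept for i in prok) / len(prok) if prok else 0.0
        return recall, leakage


def _fragment(seq: str, rng: np.random.Generator, floor: int = FRAGMENT_FLOOR,
              mean_extra: int = FRAGMENT_MEAN_EXTRA) -> str:
    """Truncated-geometric fragment with a length floor, random offset."""
    n = len(seq)
    length = min(n, floor + int(rng.geometric(1.0 / mean_extra)) - 1)
    start = int(rng.integers(0, n - length + 1))
    return seq[start:start + length]


def simulate_profiling_db(ref_msa: Alignment, tree: Phylogeny,
                          n_orthologs: int = 100, n_contaminants: int = 100,
                          divergence: float = 0.1, fragment: bool = True,
                          seed: int = 0,
                          model: AminoAcidModel | None = None
                          ) -> tuple[list[SequenceRecord], ProfilingTruth]:
    """Simulate a contaminated transcript database for one family.

    Orthologs evolve from random eukaryote tips and contaminants from random
    prokaryote tips of the reference alignment, each by ``divergence``
    expected substitutions/site, optionally truncated to transcript-like
    fragments.  Truth labels allow recall/leakage scoring of any retention
    set.
    """
    if model is None:
        model = AminoAcidModel.wag()
    rng = np.random.default_rng(seed)
    euk = [t for t in tree.tip_labels() if tree.domain.get(t) == EUKARYOTE]
    prok = [t for t in tree.tip_labels() if tree.domain.get(t) == PROKARYOTE]
    if not euk or not prok:
        raise ValueError("tree must have annotated eukaryote and prokaryote clades")
    P = model.transition_probabilities(divergence)
    records: list[SequenceRecord] = []
    truth = ProfilingTruth()

    def emit(tip: str, label: str, idx: int) -> None:
        src = ref_msa.row(tip).ungapped()
        states = np.array([AA_ORDER.index(c) for c in src if c in AA_ORDER])
        child = _evolve_states(states, P, rng)
        seq = "".join(AA_ORDER[s] for s in child)
        if fragment:
            seq = _fragment(seq, rng)
        name = f"{label[:3]}_frag{idx}"
        records.append(SequenceRecord(name, seq, AMINO_ACID))
        truth.labels[name] = label
        truth.source_tip[name] = tip

    for i in range(n_orthologs):
        emit(euk[int(rng.integers(len(euk)))], EUKARYOTE, i)
    for i in range(n_contaminants):
        emit(prok[int(rng.integers(len(prok)))], PROKARYOTE, i)
    return records, truth


# ---------------------------------------------------------------------------
# Rate tables under the compensatory model
# ---------------------------------------------------------------------------

def simulate_rate_table(betas: tuple[float, float, float, float] = (0.10, 0.39, 0.38, 0.07),
                        n_specificities: int = 20, sigma: float = 0.05,
                        x_range: tuple[float, float] = (0.05, 0.8),
                        seed: int = 0):
    """Rate table generated exactly under the compensatory linear model.

    One mt and one cy row per specificity share the same mt-tRNA rate X,
    drawn uniformly on ``x_range``; Y adds Normal(0, sigma^2) noise to the
    model plane.  Noise can take a synthetic Y slightly below zero; rows
    are not truncated, so OLS recovery stays unbiased.
    """
    import pandas as pd

    if n_specificities < 2:
        raise ValueError("need at least 2 specificities")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    b0, b1, b2, b3 = betas
    rng = np.random.default_rng(seed)
    specs = [AA_ORDER[i % 20] + ("" if i < 20 else str(i // 20)) for i in range(n_specificities)]
    X = rng.uniform(*x_range, size=n_specificities)
    rows = []
    for i, spec in enumerate(specs):
        for delta in (0, 1):
            mean = b0 + b1 * delta + b2 * X[i] + b3 * X[i] * delta
            y = mean + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            rows.append({"specificity": spec, "delta_mt": delta,
                         "X": float(X[i]), "Y": float(y)})
    return pd.DataFrame(rows, columns=["specificity", "delta_mt", "X", "Y"])


# ---------------------------------------------------------------------------
# Mitochondrial genomes with planted codon reassignments
# ---------------------------------------------------------------------------

@dataclass
class ReassignmentTruth:
    planted_fraction: float
    per_gene_targets: dict[str, list[int]] = field(default_factory=dict)
    planted_columns: dict[str, list[int]] = field(default_factory=dict)


def _codon_for(residue: str, code: GeneticCode, exclude: str,
               rng: np.random.Generator) -> str:
    options = [c for c, aa in code.codon_map.items()
               if aa == residue and c != exclude]
    if not options:
        raise ValueError(f"no codon other than {exclude} encodes {residue}")
    return options[int(rng.integers(len(options)))]


def simulate_reassigned_genome(n_genes: int = 6, gene_length_codons: int = 100,
                               target_codon: str = "TGA", planted_residue: str = "S",
                               planted_fraction: float = 0.8, n_refs: int = 10,
                               conservation: float = 0.9, gap_rate: float = 0.05,
                               target_density: float = 0.1,
                               code: GeneticCode | None = None, seed: int = 0
                               ) -> tuple[list[SequenceRecord], dict[str, Alignment],
                                          ReassignmentTruth]:
    """Plant a codon reassignment into a synthetic mitochondrial genome.

    Each gene gets per-column consensus residues; reference rows copy the
    consensus with probability ``conservation`` (else a random residue) and
    are gapped at ``gap_rate``.  A ``target_density`` fraction of columns
    carry the target codon in the focal genome; of those, exactly
    ``planted_fraction`` (rounded) have consensus equal to
    ``planted_residue``, the rest a different residue.  Elsewhere the focal
    codon is a synonymous non-target codon for the consensus.
    """
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must lie in [0, 1]")
    if n_refs < 2:
        raise ValueError("need at least 2 reference taxa")
    if code is None:
        code = GeneticCode.from_ncbi(4)
    target = target_codon.upper().replace("U", "T")
    rng = np.random.default_rng(seed)
    aa_pool = [a for a in AA_ORDER]
    cds_records: list[SequenceRecord] = []
    alignments: dict[str, Alignment] = {}
    truth = ReassignmentTruth(planted_fraction)

    for g in range(n_genes):
        gene = f"gene{g+1}"
        n_target = max(1, round(gene_length_codons * target_density))
        tpos = sorted(rng.choice(gene_length_codons, size=n_target, replace=False))
        n_planted = round(planted_fraction * n_target)
        planted_set = set(int(p) for p in rng.permutation(tpos)[:n_planted])
        consensus = [aa_pool[int(i)] for i in rng.integers(0, 20, gene_length_codons)]
        codons = []
        for j in range(gene_length_codons):
            if j in set(tpos):
                if j in planted_set:
                    consensus[j] = planted_residue
                else:
                    others = [a for a in aa_pool if a != planted_residue]
                    consensus[j] = others[int(rng.integers(len(others)))]
                codons.append(target)
            else:
                codons.append(_codon_for(consensus[j], code, target, rng))
        cds = "".join(codons)
        cds_records.append(SequenceRecord(gene, cds, NUCLEOTIDE))

        focal_trans = "".join("X" if c == target else code.translate_codon(c)
                              for c in codons)
        rows = [SequenceRecord(f"{gene}_focal", focal_trans, AMINO_ACID)]
        for r in range(n_refs):
            chars = []
            for j in range(gene_length_codons):
                if rng.random() < gap_rate:
                    chars.append("-")
                elif rng.random() < conservation:
                    chars.append(consensus[j])
                else:
                    chars.append(aa_pool[int(rng.integers(20))])
            rows.append(SequenceRecord(f"ref{r+1}", "".join(chars), AMINO_ACID))
        alignments[gene] = Alignment(rows)
        truth.per_gene_targets[gene] = [int(p) for p in tpos]
        truth.planted_columns[gene] = sorted(planted_set)
    return cds_records, alignments, truth
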