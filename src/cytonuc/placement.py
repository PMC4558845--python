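"""Maximum-likelihood phylogenetic placement on a fixed reference tree.

A query row (in reference-alignment coordinates) is attached at the midpoint
of every edge of the reference tree by a new node with a pendant branch; only
the pendant length is optimized (bounded scalar search), with branch lengths,
topology and the WAG+gamma model held fixed.  The edge maximizing the
attachment log-likelihood is reported together with normalized likelihood
weight ratios, in the spirit of evolutionary placement tools, and the
placement is classified against the tree's eukaryote/prokaryote (and
mitochondrial/cytosolic) tip annotations.

The engine precomputes, per edge and per gamma category, the conditional
likelihoods of the reference data below and above the edge midpoint, so that
per-query work is a single 20-state message per likelihood evaluation.
Gapped or ambiguous query sites are treated as missing data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .core_io import (AA_INDEX, Alignment, EUKARYOTE, MITOCHONDRIAL, CYTOSOLIC,
                      PROKARYOTE, Phylogeny, SequenceRecord, UNKNOWN)
from .substitution import AminoAcidModel

PENDANT_BOUNDS = (1e-8, 5.0)
PENDANT_TOL = 1e-6


@dataclass
class PlacementResult:
    query_id: str
    best_edge: int
    pendant_length: float
    log_likelihood: float
    like_weight_ratio: float
    classification: str = ""          # eukaryote / prokaryote
    lineage: str = ""                 # mitochondrial / cytosolic / ambiguous / ""
    low_confidence: bool = False
    edge_log_likelihoods: dict[int, float] = field(default_factory=dict)
    edge_pendants: dict[int, float] = field(default_factory=dict)


def _row_partial(row: str) -> np.ndarray:
    """Tip conditional likelihoods: indicator rows, ones for gaps/ambiguity."""
    n = len(row)
    L = np.ones((n, 20))
    for i, ch in enumerate(row):
        j = AA_INDEX.get(ch)
        if j is not None:
            L[i] = 0.0
            L[i, j] = 1.0
    return L


class PlacementEngine:
    """Caches reference-tree partials for repeated query placement."""

    def __init__(self, tree: Phylogeny, ref_msa: Alignment, model: AminoAcidModel):
        tips = set(tree.tip_labels())
        if not tips <= set(ref_msa.ids):
            missing = sorted(tips - set(ref_msa.ids))
            raise ValueError(f"tree tips missing from reference alignment: {missing}")
        self.tree = tree
        self.model = model
        self.ref_msa = ref_msa
        self.n_sites = ref_msa.n_columns
        self.rates = model.category_rates()
        k = len(self.rates)
        n = tree.n_nodes

        # down[v][c]: conditional likelihood of data below v given state at v
        # scaled per site; log-scale factors accumulated per (v, c)
        down = [[None] * k for _ in range(n)]
        down_scale = [[None] * k for _ in range(n)]
        down_msg = [[None] * k for _ in range(n)]  # message v -> parent through edge v
        self._P_half = [[None] * k for _ in range(n)]
        P_full = [[None] * k for _ in range(n)]

        for v in tree.postorder():
            for c, r in enumerate(self.rates):
                if tree.parent[v] is not None:
                    t = tree.length[v]
                    P_full[v][c] = model.transition_probabilities(r * t)
                    self._P_half[v][c] = model.transition_probabilities(r * t / 2.0)
                if tree.is_tip(v):
                    down[v][c] = _row_partial(ref_msa.row(tree.label[v]).residues)
                    down_scale[v][c] = np.zeros(self.n_sites)
                else:
                    L = np.ones((self.n_sites, 20))
                    sc = np.zeros(self.n_sites)
                    for ch in tree.children[v]:
                        L = L * down_msg[ch][c]
                        sc = sc + down_scale[ch][c]
                    mx = L.max(axis=1)
                    mx[mx == 0] = 1.0
                    L /= mx[:, None]
                    down[v][c] = L
                    down_scale[v][c] = sc + np.log(mx)
                if tree.parent[v] is not None:
                    down_msg[v][c] = down[v][c] @ P_full[v][c].T

        # H[v][c]: likelihood of all data outside subtree(v) as a function of
        # the state at v, with the stationary prior folded in at the root.
        pi = model.equilibrium_freqs
        H = [[None] * k for _ in range(n)]
        H_scale = [[None] * k for _ in range(n)]
        order = tree.postorder()[::-1]  # preorder
        for v in order:
            for c in range(k):
                if tree.parent[v] is None:
                    H[v][c] = np.tile(pi, (self.n_sites, 1))
                    H_scale[v][c] = np.zeros(self.n_sites)
                else:
                    p = tree.parent[v]
                    G = H[p][c].copy()
                    sc = H_scale[p][c].copy()
                    for s in tree.children[p]:
                        if s != v:
                            G = G * down_msg[s][c]
                            sc = sc + down_scale[s][c]
                    mx = G.max(axis=1)
                    mx[mx == 0] = 1.0
                    G /= mx[:, None]
                    H[v][c] = G @ self._tp(v, c, full=True)
                    H_scale[v][c] = sc + np.log(mx)

        # Per-edge midpoint partials: (above through t/2) * (below through t/2)
        self.edges = tree.edges()
        self.edge_partial = {}
        self.edge_scale = {}
        for e in self.edges:
            parts = []
            scales = []
            for c in range(k):
                # above message to midpoint: outside-data partial at the
                # parent, propagated through the upper half edge
                p = tree.parent[e]
                G = H[p][c].copy()
                sc = H_scale[p][c].copy()
                for s in tree.children[p]:
                    if s != e:
                        G = G * down_msg[s][c]
                        sc = sc + down_scale[s][c]
                mx = G.max(axis=1)
                mx[mx == 0] = 1.0
                G /= mx[:, None]
                sc = sc + np.log(mx)
                above = G @ self._P_half[e][c]
                below = down[e][c] @ self._P_half[e][c].T
                parts.append(above * below)
                scales.append(sc + down_scale[e][c])
            self.edge_partial[e] = parts
            self.edge_scale[e] = scales
        self._ref_ll = self._reference_log_likelihood(down, down_scale)

    def _tp(self, v: int, c: int, full: bool) -> np.ndarray:
        r = self.rates[c]
        t = self.tree.length[v] * (1.0 if full else 0.5)
        return self.model.transition_probabilities(r * t)

    def _reference_log_likelihood(self, down, down_scale) -> float:
        pi = self.model.equilibrium_freqs
        k = len(self.rates)
        site = np.zeros((k, self.n_sites))
        for c in range(k):
            site[c] = (down[self.tree.root][c] * pi[None, :]).sum(axis=1)
            site[c] = np.log(site[c]) + down_scale[self.tree.root][c]
        m = site.max(axis=0)
        return float((m + np.log(np.exp(site - m[None, :]).mean(axis=0))).sum())

    # -- query placement --------------------------------------------------
    def attachment_log_likelihood(self, edge: int, query_partial: np.ndarray,
                                  pendant: float) -> float:
        """Log-likelihood of reference + query with query attached at the
        midpoint of ``edge`` with the given pendant branch length."""
        k = len(self.rates)
        site = np.empty((k, self.n_sites))
        for c in range(k):
            Pq = self.model.transition_probabilities(self.rates[c] * pendant)
            qmsg = query_partial @ Pq.T
            lik = (self.edge_partial[edge][c] * qmsg).sum(axis=1)
            with np.errstate(divide="ignore"):
                site[c] = np.log(lik) + self.edge_scale[edge][c]
        m = site.max(axis=0)
        return float((m + np.log(np.exp(site - m[None, :]).mean(axis=0))).sum())

    def place(self, query_row: SequenceRecord | str, query_id: str = "query"
              ) -> PlacementResult:
        row = query_row.residues if isinstance(query_row, SequenceRecord) else query_row
        if isinstance(query_row, SequenceRecord):
            query_id = query_row.id
        if len(row) != self.n_sites:
            raise ValueError("query row must be in reference-alignment coordinates")
        if not any(ch in AA_INDEX for ch in row):
            raise ValueError("query has zero ungapped sites")
        Lq = _row_partial(row)
        edge_ll: dict[int, float] = {}
        edge_pen: dict[int, float] = {}
        for e in self.edges:
            res = minimize_scalar(
                lambda t: -self.attachment_log_likelihood(e, Lq, t),
                bounds=PENDANT_BOUNDS, method="bounded",
                options={"xatol": PENDANT_TOL})
            edge_ll[e] = -float(res.fun)
            edge_pen[e] = float(res.x)
        best = max(edge_ll, key=lambda e: (edge_ll[e], -e))
        mx = edge_ll[best]
        weights = {e: math.exp(ll - mx) for e, ll in edge_ll.items()}
        Z = sum(weights.values())
        return PlacementResult(
            query_id=query_id, best_edge=best, pendant_length=edge_pen[best],
            log_likelihood=edge_ll[best], like_weight_ratio=weights[best] / Z,
            edge_log_likelihoods=edge_ll, edge_pendants=edge_pen)


def place_query(tree: Phylogeny, ref_msa: Alignment, model: AminoAcidModel,
                query_row: SequenceRecord | str, query_id: str = "query") -> PlacementResult:
    """One-shot placement (builds the engine; use PlacementEngine for batches)."""
    engine = PlacementEngine(tree, ref_msa, model)
    result = engine.place(query_row, query_id)
    if tree.domain:
        classify_placement(result, tree)
    return result


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_placement(placement: PlacementResult, tree: Phylogeny) -> PlacementResult:
    """Domain (eukaryote/prokaryote) and lineage call for a placement.

    A placement is eukaryote iff the tip set subtended by its edge (child
    side, away from the root) is purely eukaryote-annotated; the stem edge
    of a maximal eukaryote-only clade qualifies but is flagged
    low-confidence.  Mixed subtrees are not retained.  The analogous rule on
    mitochondrial/cytosolic tip labels yields the lineage call.
    """
    if not tree.domain:
        raise ValueError("tree tips lack domain annotations")
    missing = set(tree.tip_labels()) - set(tree.domain)
    if missing:
        raise ValueError(f"unannotated tips: {sorted(missing)}")
    below = tree.subtended_tips(placement.best_edge)
    domains = {tree.domain[t] for t in below}
    if domains == {EUKARYOTE}:
        placement.classification = EUKARYOTE
        all_euk = {t for t, d in tree.domain.items() if d == EUKARYOTE}
        # stem of the maximal eukaryote clade: subtends every eukaryote tip
        placement.low_confidence = set(below) == all_euk
        if tree.lineage:
            lin = {tree.lineage.get(t, UNKNOWN) for t in below} - {UNKNOWN}
            if lin == {MITOCHONDRIAL}:
                placement.lineage = MITOCHONDRIAL
            elif lin == {CYTOSOLIC}:
                placement.lineage = CYTOSOLIC
            else:
                placement.lineage = "ambiguous"
    else:
        placement.classification = PROKARYOTE
        placement.lineage = ""
    return placement


# ---------------------------------------------------------------------------
# jplace output
# ---------------------------------------------------------------------------

def write_jplace(tree: Phylogeny, placements: list[PlacementResult], path: str,
                 metadata: dict | None = None) -> None:
    """Write placements in jplace version 3."""
    records = []
    for p in placements:
        mx = p.log_likelihood
        Z = sum(math.exp(ll - mx) for ll in p.edge_log_likelihoods.values()) or 1.0
        rows = []
        for e in sorted(p.edge_log_likelihoods,
                        key=lambda e: -p.edge_log_likelihoods[e])[:7]:
            ll = p.edge_log_likelihoods[e]
            rows.append([e, ll, math.exp(ll - mx) / Z, p.edge_pendants.get(e, 0.0)])
        records.append({"p": rows, "n": [p.query_id]})
    doc = {
        "version": 3,
        "tree": tree.to_newick(edge_numbers=True),
        "placements": records,
        "fields": ["edge_num", "likelihood", "like_weight_ratio", "pendant_length"],
        "metadata": metadata or {"software": "cytonuc"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
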