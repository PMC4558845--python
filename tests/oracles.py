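"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's optimized code paths: the placement
oracle rebuilds the grafted tree and runs a plain recursive pruning pass;
the distance oracles maximize the likelihood on dense grids; the regression
oracle solves least squares through the pseudo-inverse.
"""

from __future__ import annotations

import numpy as np

from cytonuc.core_io import AA_INDEX, Alignment, Phylogeny
from cytonuc.substitution import AminoAcidModel, K80Model


# ---------------------------------------------------------------------------
# Naive pruning likelihood for a query grafted onto an edge midpoint
# ---------------------------------------------------------------------------

def _tip_partial(row: str) -> np.ndarray:
    L = np.ones((len(row), 20))
    for i, ch in enumerate(row):
        j = AA_INDEX.get(ch)
        if j is not None:
            L[i] = 0.0
            L[i, j] = 1.0
    return L


def grafted_log_likelihood(tree: Phylogeny, aln: Alignment, model: AminoAcidModel,
                           edge: int, query_row: str, pendant: float) -> float:
    """Full-tree pruning likelihood with the query attached at the midpoint
    of ``edge`` by a pendant branch; plain recursion, no caching."""
    n_sites = aln.n_columns
    parts = {tree.label[i]: _tip_partial(aln.row(tree.label[i]).residues)
             for i in tree.tip_indices()}
    parts["__QUERY__"] = _tip_partial(query_row)

    def below(node, rate):
        if isinstance(node, str):
            return parts[node]
        out = np.ones((n_sites, 20))
        for child, t in node:
            P = model.transition_probabilities(rate * t)
            out = out * (below(child, rate) @ P.T)
        return out

    def plain(i):
        if tree.is_tip(i):
            return tree.label[i]
        return [(plain(c), tree.length[c]) for c in tree.children[i]]

    def build(i):
        if tree.is_tip(i):
            return tree.label[i]
        children = []
        for c in tree.children[i]:
            if c == edge:
                mid = [(plain(c), tree.length[c] / 2.0), ("__QUERY__", pendant)]
                children.append((mid, tree.length[c] / 2.0))
            else:
                children.append((build(c), tree.length[c]))
        return children

    root = build(tree.root)
    pi = model.equilibrium_freqs
    rates = model.category_rates()
    site = np.array([(below(root, r) * pi[None, :]).sum(axis=1) for r in rates])
    return float(np.log(site.mean(axis=0)).sum())


def best_edge_exhaustive(tree: Phylogeny, aln: Alignment, model: AminoAcidModel,
                         query_row: str, pendant_grid: np.ndarray) -> tuple[int, float]:
    """Best edge by brute force over a pendant grid, naive pruning per point."""
    best = (None, -np.inf)
    for e in tree.edges():
        for p in pendant_grid:
            ll = grafted_log_likelihood(tree, aln, model, e, query_row, float(p))
            if ll > best[1]:
                best = (e, ll)
    return best


# ---------------------------------------------------------------------------
# Grid-search distance oracles
# ---------------------------------------------------------------------------

def k80_grid_ml(a: str, b: str, t_max: float = 3.0) -> float:
    """Joint (t, kappa) grid maximization of the K80 pairwise likelihood,
    with two zoom stages so the final t resolution is well below 1e-4."""
    from cytonuc.core_io import NT_INDEX
    ia = np.array([NT_INDEX.get(c, -1) for c in a.upper()])
    ib = np.array([NT_INDEX.get(c, -1) for c in b.upper()])
    keep = (ia >= 0) & (ib >= 0)
    ia, ib = ia[keep], ib[keep]
    diff = ia != ib
    ts = int((diff & ((ia % 2) == (ib % 2))).sum())
    tv = int((diff & ((ia % 2) != (ib % 2))).sum())
    same = int(len(ia) - ts - tv)

    def scan(t_grid, kappas):
        best = (-np.inf, 0.0, 1.0)
        for k in kappas:
            beta = 1.0 / (k + 2.0)
            alpha = k * beta
            e4 = np.exp(-4.0 * beta * t_grid)
            e2 = np.exp(-2.0 * (alpha + beta) * t_grid)
            P = 0.25 + 0.25 * e4 - 0.5 * e2
            Q = 0.5 - 0.5 * e4
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = same * np.log(1.0 - P - Q)
                if ts:
                    ll = ll + ts * np.log(P)
                if tv:
                    ll = ll + tv * np.log(Q / 2.0)
            i = int(np.nanargmax(ll))
            if ll[i] > best[0]:
                best = (float(ll[i]), float(t_grid[i]), float(k))
        return best

    _, t0, k0 = scan(np.linspace(1e-4, t_max, 2000),
                     np.exp(np.linspace(np.log(0.05), np.log(100.0), 120)))
    for width, kfac, n in ((0.05, 1.3, 400), (0.002, 1.02, 400)):
        t_grid = np.linspace(max(t0 - width, 1e-8), t0 + width, n)
        kappas = np.linspace(k0 / kfac, k0 * kfac, 80)
        _, t0, k0 = scan(t_grid, kappas)
    return t0


def wag_grid_ml(a: str, b: str, model: AminoAcidModel,
                t_max: float = 3.0, t_step: float = 1e-4) -> float:
    """Dense-grid maximization of the WAG pairwise likelihood."""
    ia = np.array([AA_INDEX.get(c, -1) for c in a.upper()])
    ib = np.array([AA_INDEX.get(c, -1) for c in b.upper()])
    keep = (ia >= 0) & (ib >= 0)
    ia, ib = ia[keep], ib[keep]
    counts = np.zeros((20, 20))
    np.add.at(counts, (ia, ib), 1.0)
    logpi = np.log(model.equilibrium_freqs)
    best_ll, best_t = -np.inf, 0.0
    for t in np.arange(t_step, t_max, t_step):
        P = model.transition_probabilities(float(t))
        with np.errstate(divide="ignore"):
            ll = float((counts * (logpi[:, None] + np.log(P))).sum())
        if ll > best_ll:
            best_ll, best_t = ll, float(t)
    return best_t


# ---------------------------------------------------------------------------
# Least-squares oracle
# ---------------------------------------------------------------------------

def pinv_ols(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(D) @ y
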