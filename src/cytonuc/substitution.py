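"""Substitution models and pairwise maximum-likelihood distances.

Implements the WAG empirical amino-acid model (constants bundled in PAML
rate-matrix layout), the Kimura two-parameter (K80) nucleotide model with
its closed-form ML distance, discrete-gamma rate categories, and the
mean-to-outgroup rate summaries that feed the compensatory-substitution
regression.

Pairwise distances are computed rate-homogeneous (no gamma); gamma
categories are used only in placement likelihoods.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .core_io import AA_INDEX, AA_ORDER, Alignment, NT_INDEX

log = logging.getLogger(__name__)

#: Transition pairs under K80 (purine<->purine, pyrimidine<->pyrimidine).
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

DISTANCE_OPT_BOUNDS = (1e-8, 50.0)
DISTANCE_OPT_TOL = 1e-6


class SaturationError(ValueError):
    """All pairs saturated where at least one finite distance is required."""


@dataclass
class DistanceEstimate:
    """A pairwise ML distance in expected substitutions/site.

    ``saturated`` flags pairs whose divergence exceeds the model's
    identifiable range (distance reported as ``inf``).
    """

    distance: float
    n_sites: int
    saturated: bool = False
    se: float | None = None


# ---------------------------------------------------------------------------
# WAG amino-acid model
# ---------------------------------------------------------------------------

def _load_paml_matrix(name: str = "wag.dat") -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("cytonuc.data").joinpath(name).read_text()
    rows: list[list[float]] = []
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        try:
            rows.append([float(x) for x in parts])
        except ValueError:
            break  # trailing commentary
    tri, freqs = rows[:19], np.array(rows[19])
    S = np.zeros((20, 20))
    for i, row in enumerate(tri, start=1):
        S[i, : len(row)] = row
    S = S + S.T
    return S, freqs / freqs.sum()


class AminoAcidModel:
    """Reversible amino-acid model from exchangeabilities and frequencies.

    The generator Q is scaled so the expected substitution rate at
    equilibrium is one per site.  Transition probabilities are computed by
    symmetric eigendecomposition of pi^{1/2} Q pi^{-1/2}, which is exact for
    reversible generators and cheap to reuse across branch lengths.
    """

    def __init__(self, exchangeabilities: np.ndarray, equilibrium_freqs: np.ndarray,
                 gamma_shape: float | None = None, n_categories: int = 1):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(equilibrium_freqs, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric 20x20")
        if pi.shape != (20,) or abs(pi.sum() - 1) > 1e-8 or (pi <= 0).any():
            raise ValueError("equilibrium frequencies must be 20 positive values summing to 1")
        if gamma_shape is not None and gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        Q /= scale
        self.exchangeabilities = S
        self.equilibrium_freqs = pi
        self.rate_matrix = Q
        self.gamma_shape = gamma_shape
        self.n_categories = n_categories
        # symmetric eigendecomposition for fast expm
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        self._left = U / sq[:, None]      # pi^{-1/2} U
        self._right = U.T * sq[None, :]   # U^T pi^{1/2}

    @classmethod
    def wag(cls, gamma_shape: float | None = None, n_categories: int = 1) -> "AminoAcidModel":
        S, pi = _load_paml_matrix("wag.dat")
        return cls(S, pi, gamma_shape, n_categories)

    def transition_probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, P(0) = I."""
        if t < 0 or not math.isfinite(t):
            raise ValueError("branch length must be finite and non-negative")
        P = (self._left * np.exp(self._eigvals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None or self.n_categories == 1:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


def wag_transition_probabilities(model: AminoAcidModel, t: float) -> np.ndarray:
    return model.transition_probabilities(t)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-of-quantile discrete-gamma category rates (equal weights, mean 1)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.ones(1)
    # category boundaries at equal-probability quantiles; category mean via
    # the incomplete-gamma identity E[X; a<X<b] = P(alpha+1 scale cut)
    bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    upper = gamma_dist.cdf(bounds, alpha + 1, scale=1.0 / alpha)
    rates = (upper[1:] - upper[:-1]) * k
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# K80
# ---------------------------------------------------------------------------

@dataclass
class K80Model:
    """Kimura two-parameter model; kappa = transition/transversion rate ratio."""

    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    def pq_at(self, t: float) -> tuple[float, float]:
        """Closed-form expected transition (P) and transversion (Q) proportions."""
        k = self.kappa
        beta = 1.0 / (k + 2.0)   # Q scaled to one substitution/site at t=1
        alpha = k * beta
        e4 = math.exp(-4.0 * beta * t)
        e2 = math.exp(-2.0 * (alpha + beta) * t)
        P = 0.25 + 0.25 * e4 - 0.5 * e2
        Q = 0.5 - 0.5 * e4
        return P, Q

    def transition_probabilities(self, t: float) -> np.ndarray:
        P, Q = self.pq_at(t)
        M = np.full((4, 4), Q / 2.0)
        # order A C G T; transitions A<->G, C<->T
        M[0, 2] = M[2, 0] = P
        M[1, 3] = M[3, 1] = P
        np.fill_diagonal(M, 1.0 - P - Q)
        return M


def _pair_columns(a: str, b: str, index: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    ia = np.array([index.get(c, -1) for c in a.upper()])
    ib = np.array([index.get(c, -1) for c in b.upper()])
    keep = (ia >= 0) & (ib >= 0)
    return ia[keep], ib[keep]


def k80_distance(a: str, b: str) -> DistanceEstimate:
    """Closed-form ML K80 distance between two equal-length gapped sequences.

    With P the transition and Q the transversion proportion over columns
    ungapped/unambiguous in both sequences,
    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).  A non-positive log argument
    is reported as saturation (infinite distance), not an exception.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    ia, ib = _pair_columns(a, b, NT_INDEX)
    n = len(ia)
    if n == 0:
        raise ValueError("no comparable (both-ungapped) columns")
    diff = ia != ib
    # transitions: A(0)<->G(2), C(1)<->T(3): same parity classes
    ts = diff & ((ia % 2) == (ib % 2))
    P = ts.sum() / n
    Q = (diff & ~ts).sum() / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return DistanceEstimate(math.inf, n, saturated=True)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistanceEstimate(max(d, 0.0), n)


def wag_ml_distance(a: str, b: str, model: AminoAcidModel | None = None) -> DistanceEstimate:
    """Pairwise ML distance under plain WAG by bounded scalar optimization.

    Maximizes sum over both-ungapped sites of ln[pi_a P(t)_{ab}] for
    t in [1e-8, 50] with Brent's bounded method (tol 1e-6).
    """
    if model is None:
        model = AminoAcidModel.wag()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    ia, ib = _pair_columns(a, b, AA_INDEX)
    if len(ia) == 0:
        raise ValueError("no comparable (both-ungapped) columns")
    counts = np.zeros((20, 20))
    np.add.at(counts, (ia, ib), 1.0)
    logpi = np.log(model.equilibrium_freqs)

    def nll(t: float) -> float:
        P = model.transition_probabilities(t)
        with np.errstate(divide="ignore"):
            L = logpi[:, None] + np.log(P)
        L[P <= 0] = -1e10
        return -float((counts * L).sum())

    res = minimize_scalar(nll, bounds=DISTANCE_OPT_BOUNDS, method="bounded",
                          options={"xatol": DISTANCE_OPT_TOL})
    t_hat = float(res.x)
    saturated = t_hat > DISTANCE_OPT_BOUNDS[1] * 0.99
    if (ia == ib).all():
        t_hat = 0.0
    return DistanceEstimate(math.inf if saturated else t_hat, int(len(ia)),
                            saturated=saturated)


def mean_outgroup_distance(family: Alignment, outgroup_id: str,
                           ingroup_ids: set[str] | list[str], kind: str = "WAG",
                           model: AminoAcidModel | None = None) -> float:
    """Mean pairwise distance from one outgroup row to each ingroup row.

    Saturated pairs are excluded from the mean with a logged warning; if
    every pair is saturated a :class:`SaturationError` is raised.
    """
    out_row = family.row(outgroup_id).residues
    ingroup = [i for i in ingroup_ids if i != outgroup_id]
    if not ingroup:
        raise ValueError("need at least one ingroup id")
    dists = []
    n_saturated = 0
    for gid in ingroup:
        row = family.row(gid).residues
        est = (wag_ml_distance(out_row, row, model) if kind.upper() == "WAG"
               else k80_distance(out_row, row))
        if est.saturated:
            n_saturated += 1
        else:
            dists.append(est.distance)
    if n_saturated:
        warnings.warn(f"excluded {n_saturated} saturated pair(s) from mean "
                      f"outgroup distance for {outgroup_id}")
    if not dists:
        raise SaturationError("all outgroup/ingroup pairs saturated")
    return float(np.mean(dists))


def distance_matrix_to_tsv(ids: list[str], D: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(ids) + "\n")
        for i, name in enumerate(ids):
            fh.write(name + "\t" + "\t".join(f"{x:.6f}" for x in D[i]) + "\n")
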