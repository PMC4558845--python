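"""Lean Plan7-style profile HMMs for local protein search.

A profile is built from a curated alignment: match columns are those below a
gap-fraction threshold, emissions are Henikoff-weighted counts with
background-proportional pseudocounts, and transitions come from weighted
path counts with Laplace smoothing.  Scoring is log-odds against the
background, with uniform local entry/exit over match states; the forward
algorithm gives the bit score and the Viterbi traceback gives the
residue-to-column match path.  E-values are calibrated per profile by
maximum-likelihood Gumbel fits to the scores of seeded background decoys.

This is a self-contained search instrument, not a byte-compatible
re-implementation of any particular external search tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gumbel_r

from .core_io import AA_INDEX, AA_ORDER, Alignment, SequenceRecord

LOG0 = -1e30


@dataclass
class ProfileModel:
    """Position-specific emission/transition parameters built from an alignment."""

    match_emissions: np.ndarray         # (n_match, 20), rows sum to 1
    transitions: dict[str, np.ndarray]  # keys MM MI MD IM II DM DD, each (n_match,)
    background: np.ndarray              # (20,)
    match_columns: np.ndarray           # ref-alignment column index per match state
    source_alignment_id: str = ""
    calibration: tuple[float, float] | None = None  # Gumbel (mu, beta)

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def insert_emissions(self) -> np.ndarray:
        return self.background

    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.match_emissions.argmax(axis=1))


@dataclass
class SearchHit:
    profile_id: str
    target_id: str
    bit_score: float
    e_value: float
    target_interval: tuple[int, int]   # 0-based half-open on the target
    match_path: list[tuple[int, int]]  # (target residue pos, match state idx)


def henikoff_weights(aln: Alignment) -> np.ndarray:
    """Position-based sequence weights, normalized to sum to n_sequences."""
    rows = [r.residues for r in aln.records]
    n = len(rows)
    w = np.zeros(n)
    for j in range(aln.n_columns):
        col = [row[j] for row in rows]
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        if r <= 1:
            continue
        for i, c in enumerate(col):
            w[i] += 1.0 / (r * counts[c])
    if w.sum() == 0:  # all columns identical across sequences
        w[:] = 1.0
    return w * n / w.sum()


def build_profile(msa: Alignment, background: np.ndarray | None = None,
                  gap_threshold: float = 0.5) -> ProfileModel:
    """Build a profile from an alignment.

    Match columns are those with gap fraction strictly below
    ``gap_threshold``; emission pseudocount mass is 1 per column,
    distributed proportionally to the background.
    """
    if not 0 < gap_threshold < 1:
        raise ValueError("gap_threshold must lie in (0, 1)")
    if background is None:
        from .substitution import AminoAcidModel
        background = AminoAcidModel.wag().equilibrium_freqs
    background = np.asarray(background, dtype=float)
    weights = henikoff_weights(msa)
    rows = [r.residues for r in msa.records]

    match_cols = [j for j in range(msa.n_columns) if msa.gap_fraction(j) < gap_threshold]
    if not match_cols:
        raise ValueError("no match columns at this gap threshold")
    M = len(match_cols)

    emissions = np.tile(background, (M, 1)).copy()  # pseudocount mass 1 per column
    for k, j in enumerate(match_cols):
        for i, row in enumerate(rows):
            c = row[j]
            if c in AA_INDEX:
                emissions[k, AA_INDEX[c]] += weights[i]
    emissions /= emissions.sum(axis=1, keepdims=True)

    # weighted transition path counts with Laplace smoothing (+1 per arc)
    match_set = set(match_cols)
    c = {k: np.ones(M) for k in ("MM", "MI", "MD", "IM", "II", "DM", "DD")}
    for i, row in enumerate(rows):
        wt = weights[i]
        prev: tuple[str, int] | None = None
        k = -1
        for j in range(msa.n_columns):
            ch = row[j]
            if j in match_set:
                k += 1
                state = "M" if ch != "-" else "D"
            else:
                if ch == "-":
                    continue
                state = "I"
            if prev is not None:
                key = prev[0] + state
                if key in c:
                    c[key][prev[1]] += wt
            prev = (state, k)
    trans = {
        "MM": c["MM"] / (c["MM"] + c["MI"] + c["MD"]),
        "MI": c["MI"] / (c["MM"] + c["MI"] + c["MD"]),
        "MD": c["MD"] / (c["MM"] + c["MI"] + c["MD"]),
        "IM": c["IM"] / (c["IM"] + c["II"]),
        "II": c["II"] / (c["IM"] + c["II"]),
        "DM": c["DM"] / (c["DM"] + c["DD"]),
        "DD": c["DD"] / (c["DM"] + c["DD"]),
    }
    return ProfileModel(emissions, trans, background,
                        np.array(match_cols), msa.metadata.get("id", ""))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(ch, -1) for ch in seq.upper()], dtype=np.int64)


class _ScoringArrays:
    """Log-odds emission and log transition vectors, shifted for the DP."""

    def __init__(self, profile: ProfileModel):
        M = profile.n_match
        self.M = M
        self.lo_emit = np.log(profile.match_emissions) - np.log(profile.background)[None, :]
        self.t = {k: np.log(v) for k, v in profile.transitions.items()}
        self.entry = -math.log(M)
        self.exit = -math.log(M)
        neg = LOG0
        # previous-column transition vectors aligned to destination index k
        self.tMM = np.concatenate([[neg], self.t["MM"][:-1]])
        self.tIM = np.concatenate([[neg], self.t["IM"][:-1]])
        self.tDM = np.concatenate([[neg], self.t["DM"][:-1]])
        # cumulative DD chain: cDD[k] = sum_{l<k} log t(DD)_l
        self.cDD = np.concatenate([[0.0], np.cumsum(self.t["DD"][:-1])])

    def emit_rows(self, x: np.ndarray) -> np.ndarray:
        # ambiguity (index -1) emits at background: log-odds 0
        safe = np.clip(x, 0, None)
        rows = self.lo_emit[:, safe].T
        rows[x < 0] = 0.0
        return rows

    def delete_chain(self, nM: np.ndarray, reduce: str):
        """D_k = op_{j<k}(M_j + t(MD)_j + sum of DD arcs between), vectorized."""
        seed = nM + self.t["MD"] - self.cDD - self.t["DD"]
        if reduce == "sum":
            acc = np.logaddexp.accumulate(seed)
            src = None
        else:
            acc = np.maximum.accumulate(seed)
            prev = np.concatenate([[-np.inf], acc[:-1]])
            is_new = seed >= prev
            src = np.maximum.accumulate(np.where(is_new, np.arange(self.M), -1))
        # seed folds in -cDD[j+1]; restore the chain prefix with +cDD[k]
        nD = np.concatenate([[LOG0], acc[:-1] + self.cDD[1:]])
        return nD, src


def forward_bits(profile: ProfileModel, seq: str) -> float:
    """Forward log-odds bit score over all local alignments."""
    x = _encode(seq)
    if len(x) == 0:
        raise ValueError("empty target")
    A = _ScoringArrays(profile)
    M = A.M
    emit = A.emit_rows(x)
    fM = np.full(M, LOG0)
    fI = np.full(M, LOG0)
    fD = np.full(M, LOG0)
    total = LOG0
    for i in range(len(x)):
        pM = np.concatenate([[LOG0], fM[:-1]])
        pI = np.concatenate([[LOG0], fI[:-1]])
        pD = np.concatenate([[LOG0], fD[:-1]])
        cand = np.stack([pM + A.tMM, pI + A.tIM, pD + A.tDM,
                         np.full(M, A.entry)])
        m = cand.max(axis=0)
        nM = emit[i] + m + np.log(np.exp(cand - m[None, :]).sum(axis=0))
        nI = np.logaddexp(fM + A.t["MI"], fI + A.t["II"])
        nD, _ = A.delete_chain(nM, "sum")
        row_end = nM + A.exit
        rm = row_end.max()
        total = np.logaddexp(total, rm + math.log(np.exp(row_end - rm).sum()))
        fM, fI, fD = nM, nI, nD
    return total / math.log(2.0)


def viterbi_bits(profile: ProfileModel, seq: str) -> tuple[float, list[tuple[int, int]]]:
    """Best local alignment bit score and its (residue, match state) path."""
    x = _encode(seq)
    if len(x) == 0:
        raise ValueError("empty target")
    A = _ScoringArrays(profile)
    L, M = len(x), A.M
    emit = A.emit_rows(x)
    vM = np.full(M, LOG0)
    vI = np.full(M, LOG0)
    vD = np.full(M, LOG0)
    bpM = np.zeros((L, M), dtype=np.int8)    # 0=M,1=I,2=D,3=begin (at k-1, row i-1)
    bpI = np.zeros((L, M), dtype=np.int8)    # 0=from M, 1=from I (same k, row i-1)
    dsrc = np.zeros((L, M), dtype=np.int32)  # D at (i,k) seeded by M at (i, dsrc)
    allM = np.empty((L, M))
    for i in range(L):
        pM = np.concatenate([[LOG0], vM[:-1]])
        pI = np.concatenate([[LOG0], vI[:-1]])
        pD = np.concatenate([[LOG0], vD[:-1]])
        cand = np.stack([pM + A.tMM, pI + A.tIM, pD + A.tDM,
                         np.full(M, A.entry)])
        bpM[i] = cand.argmax(axis=0)
        nM = emit[i] + cand.max(axis=0)
        ic = np.stack([vM + A.t["MI"], vI + A.t["II"]])
        bpI[i] = ic.argmax(axis=0)
        nI = ic.max(axis=0)
        nD, src = A.delete_chain(nM, "max")
        dsrc[i, 1:] = src[:-1]
        allM[i] = nM
        vM, vI, vD = nM, nI, nD
    i, k = np.unravel_index(int(np.argmax(allM)), allM.shape)
    score = (allM[i, k] + A.exit) / math.log(2.0)
    path: list[tuple[int, int]] = []
    while True:
        path.append((int(i), int(k)))
        move = bpM[i, k]
        if move == 3 or i == 0 or k == 0:
            break
        if move == 0:       # M(i-1, k-1)
            i, k = i - 1, k - 1
        elif move == 1:     # insert run at column k-1
            i, k = i - 1, k - 1          # now at I(i, k)
            while i > 0 and bpI[i, k] == 1:
                i -= 1                   # I(i-1, k)
            i -= 1                       # the M(i, k) that opened the run
            if i < 0:
                break
        else:               # delete chain back to its seeding match, same row i-1
            i, k = i - 1, int(dsrc[i - 1, k - 1])
    path.reverse()
    return float(score), path


def score_sequence(profile: ProfileModel, target: SequenceRecord | str
                   ) -> tuple[float, list[tuple[int, int]]]:
    """Forward bit score plus Viterbi match path for a target sequence."""
    seq = target.residues if isinstance(target, SequenceRecord) else target
    return forward_bits(profile, seq), viterbi_bits(profile, seq)[1]


# ---------------------------------------------------------------------------
# E-value calibration and search
# ---------------------------------------------------------------------------

def calibrate_evalues(profile: ProfileModel, n_decoys: int = 200,
                      decoy_length: int = 150, seed: int = 0) -> tuple[float, float]:
    """ML Gumbel fit (mu, beta) to forward bit scores of background decoys."""
    if n_decoys < 100:
        raise ValueError("need at least 100 decoys for a stable fit")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    for i in range(n_decoys):
        idx = rng.choice(20, size=decoy_length, p=profile.background)
        scores[i] = forward_bits(profile, "".join(AA_ORDER[j] for j in idx))
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate decoy score variance")
    mu, beta = gumbel_r.fit(scores)
    profile.calibration = (float(mu), float(beta))
    return profile.calibration


def e_value(profile: ProfileModel, bit_score: float, n_db: int) -> float:
    if profile.calibration is None:
        raise ValueError("profile is not calibrated")
    mu, beta = profile.calibration
    return float(n_db * gumbel_r.sf(bit_score, loc=mu, scale=beta))


def search_database(profile: ProfileModel, db: list[SequenceRecord],
                    e_cutoff: float = 1e-5) -> list[SearchHit]:
    """Score every db sequence; keep hits with e-value <= cutoff.

    Sorted by ascending e-value, ties broken by descending bit score then
    lexicographic target id.  One hit (the best-scoring) per target id.
    """
    if profile.calibration is None:
        raise ValueError("calibrate the profile before searching")
    n_db = len(db)
    hits: list[SearchHit] = []
    for rec in db:
        score = forward_bits(profile, rec.residues)
        ev = e_value(profile, score, n_db)
        if ev <= e_cutoff:
            _, path = viterbi_bits(profile, rec.residues)
            interval = (path[0][0], path[-1][0] + 1) if path else (0, 0)
            hits.append(SearchHit(profile.source_alignment_id, rec.id, score,
                                  ev, interval, path))
    hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.target_id))
    return hits


def align_hit_to_reference(hit: SearchHit, profile: ProfileModel,
                           ref_msa: Alignment, target: SequenceRecord) -> SequenceRecord:
    """Project a hit into reference-alignment coordinates via its match path.

    Match-state residues land in the corresponding reference columns;
    insert-state residues are dropped; uncovered columns become gaps.
    """
    if profile.match_columns.max() >= ref_msa.n_columns:
        raise ValueError("profile/reference alignment provenance mismatch")
    row = ["-"] * ref_msa.n_columns
    for tpos, k in hit.match_path:
        row[int(profile.match_columns[k])] = target.residues[tpos]
    return SequenceRecord(hit.target_id, "".join(row), "amino-acid")


# ---------------------------------------------------------------------------
# Plain-text profile serialization
# ---------------------------------------------------------------------------

_TKEYS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")


def write_profile(profile: ProfileModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cytonuc profile v1\nn_match\t{profile.n_match}\n")
        fh.write("source\t" + (profile.source_alignment_id or "-") + "\n")
        fh.write("background\t" + " ".join(f"{x:.10g}" for x in profile.background) + "\n")
        fh.write("match_columns\t" + " ".join(map(str, profile.match_columns)) + "\n")
        if profile.calibration:
            fh.write("calibration\t%.10g %.10g\n" % profile.calibration)
        for k in range(profile.n_match):
            fh.write(f"M{k}\t" + " ".join(f"{x:.10g}" for x in profile.match_emissions[k]))
            fh.write("\t" + " ".join(f"{profile.transitions[key][k]:.10g}"
                                     for key in _TKEYS) + "\n")


def read_profile(path: str) -> ProfileModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    head = {}
    body = []
    for ln in lines:
        tag = ln.split("\t", 1)[0]
        if tag[0] == "M" and tag != "match_columns":
            body.append(ln)
        else:
            head[tag] = ln.split("\t", 1)[1]
    n = int(head["n_match"])
    background = np.array([float(x) for x in head["background"].split()])
    cols = np.array([int(x) for x in head["match_columns"].split()])
    emissions = np.zeros((n, 20))
    trans = {k: np.zeros(n) for k in _TKEYS}
    for ln in body:
        tag, em, tr = ln.split("\t")
        k = int(tag[1:])
        emissions[k] = [float(x) for x in em.split()]
        for key, val in zip(_TKEYS, tr.split()):
            trans[key][k] = float(val)
    src = head.get("source", "")
    prof = ProfileModel(emissions, trans, background, cols,
                        "" if src == "-" else src)
    if "calibration" in head:
        mu, beta = (float(x) for x in head["calibration"].split())
        prof.calibration = (mu, beta)
    return prof
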