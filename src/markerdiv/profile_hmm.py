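"""Profile models for marker families: build, calibrate, screen, align.

A light profile-HMM ("Plan7-lite"): match/insert/delete states with
position-specific emissions and transitions, local alignment by Viterbi in
log-odds space, and E-values from a Gumbel fit to Viterbi scores of random
background sequences.  This preserves the semantics of an HMMER-style screen
(bit scores, E-value thresholding, fragment length gate, alignment of
accepted fragments onto reference columns) at desk scale, without forward
scores or HMMER file formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._model import AA_INDEX, GAP, N_STATES

__all__ = [
    "Profile",
    "SearchHit",
    "AlignedFragment",
    "trim_gap_columns",
    "build_profile",
    "calibrate",
    "search",
    "align_to_profile",
]

_NEG = -1.0e30
_EULER_GAMMA = 0.5772156649015329
_LN2 = float(np.log(2.0))


@dataclass
class Calibration:
    mu: float  # Gumbel location, in bits
    lam: float  # Gumbel scale, per bit
    n_null: int
    null_len: int
    seed: int

    def evalue(self, bit_score, n_eff: float):
        """E(S) = n_eff * exp(-lam * (S - mu)); n_eff = sequences scanned."""
        return n_eff * np.exp(-self.lam * (np.asarray(bit_score, dtype=float) - self.mu))


@dataclass
class Profile:
    """Position-specific model of one group's reference family.

    ``match_columns`` maps match states back to source alignment columns.
    Emission and transition parameters are stored as probabilities
    (each distribution sums to 1); log-odds/log forms are derived.
    """

    source_group: str
    match_columns: np.ndarray  # (K,) int, strictly increasing
    match_emissions: np.ndarray  # (K, 20) probabilities
    background: np.ndarray  # (20,)
    trans: dict[str, np.ndarray]  # keys mm, mi, md, im, ii, dm, dd; each (K,)
    calibration: Calibration | None = None
    _log_odds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not np.all(np.diff(self.match_columns) > 0):
            raise ValueError("match_columns must be strictly increasing")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emissions must sum to 1")

    @property
    def length(self) -> int:
        return self.match_columns.shape[0]

    def log_odds(self) -> np.ndarray:
        """(K, 21) match emission log-odds; column 20 is a padding sentinel."""
        if self._log_odds is None:
            lo = np.log(self.match_emissions) - np.log(self.background)[None, :]
            self._log_odds = np.concatenate(
                [lo, np.full((self.length, 1), _NEG)], axis=1
            )
        return self._log_odds


@dataclass(frozen=True)
class SearchHit:
    fragment_id: str
    best_profile: str  # group label of the winning profile
    bit_score: float
    evalue: float
    aligned_length: int


@dataclass(frozen=True)
class AlignedFragment:
    """A fragment mapped onto reference alignment columns.

    ``column_map[i]`` is the reference column occupied by fragment residue i,
    or None for residues emitted by insert/flank states.
    """

    fragment_id: str
    group: str
    residues: str
    column_map: tuple[int | None, ...]
    span: tuple[int, int]  # (first_col, last_col), inclusive

    def __post_init__(self):
        cols = [c for c in self.column_map if c is not None]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("mapped columns must be strictly increasing")


# ---------------------------------------------------------------------------


def trim_gap_columns(alignment: dict[str, str]) -> dict[str, str]:
    """Restrict an alignment to columns containing no gap character."""
    if not alignment:
        raise ValueError("empty alignment")
    rows = list(alignment.values())
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows must have equal length")
    keep = [j for j in range(width) if all(r[j] != GAP for r in rows)]
    return {k: "".join(v[j] for j in keep) for k, v in alignment.items()}


def _encode_aligned(rows: list[str]) -> np.ndarray:
    out = np.empty((len(rows), len(rows[0])), dtype=np.int8)
    for i, r in enumerate(rows):
        for j, c in enumerate(r):
            out[i, j] = -1 if c == GAP else AA_INDEX[c]
    return out


def build_profile(
    alignment: dict[str, str],
    source_group: str = "",
    match_gap_frac: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> Profile:
    """Estimate a profile from an aligned family.

    Columns whose gap fraction is below ``match_gap_frac`` become match
    states.  Emissions are Dirichlet-smoothed counts,
    (counts + pseudocount*background) / (n_residues + pseudocount); state
    transitions are counted from each row's match/insert/delete path with
    Laplace (+1) smoothing.
    """
    if len(alignment) < 2:
        raise ValueError("at least 2 rows are required to build a profile")
    rows = list(alignment.values())
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows must have equal length")
    enc = _encode_aligned(rows)
    n = enc.shape[0]
    gap_frac = (enc < 0).mean(axis=0)
    match_cols = np.flatnonzero(gap_frac < match_gap_frac)
    if match_cols.size == 0:
        raise ValueError("no match columns at this gap threshold")
    bg = (np.full(N_STATES, 1.0 / N_STATES) if background is None
          else np.asarray(background, dtype=float))

    k = match_cols.size
    emis = np.zeros((k, N_STATES))
    for s, col in enumerate(match_cols):
        residues = enc[:, col]
        residues = residues[residues >= 0]
        counts = np.bincount(residues, minlength=N_STATES).astype(float)
        emis[s] = (counts + pseudocount * bg) / (residues.size + pseudocount)

    # transition counts from observed state paths; rare D->I / I->D steps are
    # folded into D->M / I->M (the DP does not use them)
    cnt = {key: np.zeros(k) for key in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    is_match = np.zeros(width, dtype=bool)
    is_match[match_cols] = True
    state_of_col = np.full(width, -1)
    state_of_col[match_cols] = np.arange(k)
    for row in enc:
        prev = None  # ("M"|"D"|"I", state index)
        for col in range(width):
            if is_match[col]:
                cur = ("M" if row[col] >= 0 else "D", state_of_col[col])
            elif row[col] >= 0:
                cur = ("I", prev[1] if prev is not None else -1)
            else:
                continue
            if prev is not None and prev[1] >= 0:
                a, b = prev[0], cur[0]
                key = {"MM": "mm", "MI": "mi", "MD": "md", "IM": "im",
                       "II": "ii", "DM": "dm", "DD": "dd",
                       "DI": "dm", "ID": "im"}[a + b]
                cnt[key][prev[1]] += 1
            if cur[1] >= 0 or cur[0] == "I":
                prev = cur
        # row end: no explicit end-state bookkeeping (local exit is free)

    trans = {}
    m_tot = cnt["mm"] + cnt["mi"] + cnt["md"] + 3.0
    trans["mm"] = (cnt["mm"] + 1.0) / m_tot
    trans["mi"] = (cnt["mi"] + 1.0) / m_tot
    trans["md"] = (cnt["md"] + 1.0) / m_tot
    i_tot = cnt["im"] + cnt["ii"] + 2.0
    trans["im"] = (cnt["im"] + 1.0) / i_tot
    trans["ii"] = (cnt["ii"] + 1.0) / i_tot
    d_tot = cnt["dm"] + cnt["dd"] + 2.0
    trans["dm"] = (cnt["dm"] + 1.0) / d_tot
    trans["dd"] = (cnt["dd"] + 1.0) / d_tot

    return Profile(
        source_group=source_group,
        match_columns=match_cols,
        match_emissions=emis,
        background=bg,
        trans=trans,
    )


# ---------------------------------------------------------------------------
# Viterbi scoring


def _log_trans(profile: Profile) -> dict[str, np.ndarray]:
    lt = {key: np.log(v) for key, v in profile.trans.items()}
    # transitions out of the last match state lead nowhere
    for key in ("mm", "md"):
        lt[key] = lt[key].copy()
        lt[key][-1] = _NEG
    lt["im"] = lt["im"].copy()
    lt["im"][-1] = _NEG
    lt["dd"] = lt["dd"].copy()
    lt["dd"][-1] = _NEG
    lt["dm"] = lt["dm"].copy()
    lt["dm"][-1] = _NEG
    return lt


def encode_fragment(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        idx = AA_INDEX.get(c)
        if idx is None:
            raise ValueError(f"illegal residue {c!r} at position {i}")
        out[i] = idx
    return out


def _batch_viterbi_scores(profile: Profile, seqs: np.ndarray) -> np.ndarray:
    """Local Viterbi bit scores for a batch of padded sequences.

    ``seqs`` is (B, L) int with residue indices 0..19 and padding value 20
    (padding emissions are -inf, so padded rows never contribute).
    """
    lo = profile.log_odds()
    lt = _log_trans(profile)
    k = profile.length
    b, l = seqs.shape
    c_dd = np.concatenate([[0.0], np.cumsum(lt["dd"])])  # C[j] = sum_{m<j} dd[m]

    m_prev = np.full((b, k), _NEG)
    i_prev = np.full((b, k), _NEG)
    d_prev = np.full((b, k), _NEG)
    best = np.full(b, _NEG)
    shift = np.full((b, 1), _NEG)
    for pos in range(l):
        ev = lo[:, seqs[:, pos]].T  # (B, K)
        from_m = np.concatenate([shift, m_prev[:, :-1] + lt["mm"][:-1]], axis=1)
        from_i = np.concatenate([shift, i_prev[:, :-1] + lt["im"][:-1]], axis=1)
        from_d = np.concatenate([shift, d_prev[:, :-1] + lt["dm"][:-1]], axis=1)
        entry = np.maximum(np.maximum(from_m, from_i), np.maximum(from_d, 0.0))
        m_cur = ev + entry
        i_cur = np.maximum(m_prev + lt["mi"], i_prev + lt["ii"])
        # delete runs: D[j] = C[j] + max_{jj<j} (M[jj] + md[jj] - C[jj+1])
        g = m_cur + lt["md"] - c_dd[1:]
        run = np.maximum.accumulate(g, axis=1)
        d_cur = np.full((b, k), _NEG)
        d_cur[:, 1:] = run[:, :-1] + c_dd[1:k]
        best = np.maximum(best, m_cur.max(axis=1))
        m_prev, i_prev, d_prev = m_cur, i_cur, d_cur
    return best / _LN2


def _viterbi_traceback(profile: Profile, seq: np.ndarray):
    """Full Viterbi with pointers; returns (bit_score, path).

    The path is a list of (residue_index, match_state) for match emissions;
    residues not covered are flank/insert emissions.
    """
    lo = profile.log_odds()
    lt = _log_trans(profile)
    k = profile.length
    l = seq.shape[0]
    c_dd = np.concatenate([[0.0], np.cumsum(lt["dd"])])

    m_all = np.full((l, k), _NEG)
    i_all = np.full((l, k), _NEG)
    d_all = np.full((l, k), _NEG)
    mptr = np.zeros((l, k), dtype=np.int8)  # 0 start, 1 M, 2 I, 3 D
    iptr = np.zeros((l, k), dtype=np.int8)  # 0 M, 1 I
    dstart = np.zeros((l, k), dtype=np.int32)  # feeding match state of the delete run

    m_prev = np.full(k, _NEG)
    i_prev = np.full(k, _NEG)
    d_prev = np.full(k, _NEG)
    for pos in range(l):
        ev = lo[:, seq[pos]]
        from_m = np.concatenate([[_NEG], m_prev[:-1] + lt["mm"][:-1]])
        from_i = np.concatenate([[_NEG], i_prev[:-1] + lt["im"][:-1]])
        from_d = np.concatenate([[_NEG], d_prev[:-1] + lt["dm"][:-1]])
        stacked = np.stack([np.zeros(k), from_m, from_i, from_d])
        choice = stacked.argmax(axis=0)
        m_cur = ev + stacked.max(axis=0)
        mptr[pos] = choice
        i_from_m = m_prev + lt["mi"]
        i_from_i = i_prev + lt["ii"]
        i_cur = np.maximum(i_from_m, i_from_i)
        iptr[pos] = (i_from_i > i_from_m).astype(np.int8)
        g = m_cur + lt["md"] - c_dd[1:]
        run = np.maximum.accumulate(g)
        arg = np.maximum.accumulate(
            np.where(g == run, np.arange(k), 0)
        )
        d_cur = np.full(k, _NEG)
        d_cur[1:] = run[:-1] + c_dd[1:k]
        dstart[pos, 1:] = arg[:-1]
        m_all[pos], i_all[pos], d_all[pos] = m_cur, i_cur, d_cur
        m_prev, i_prev, d_prev = m_cur, i_cur, d_cur

    pos, st = np.unravel_index(np.argmax(m_all), m_all.shape)
    score = m_all[pos, st] / _LN2
    path: list[tuple[int, int]] = []
    state = "M"
    while True:
        if state == "M":
            path.append((int(pos), int(st)))
            c = mptr[pos, st]
            if c == 0:
                break
            if c == 1:
                pos, st, state = pos - 1, st - 1, "M"
            elif c == 2:
                pos, st, state = pos - 1, st - 1, "I"
            else:
                pos, st, state = pos - 1, st - 1, "D"
        elif state == "I":
            c = iptr[pos, st]
            pos, state = pos - 1, ("I" if c == 1 else "M")
            if state == "M":
                # I_st follows M_st
                pass
        else:  # D: jump to the match state that started the delete run
            st = int(dstart[pos, st])
            state = "M"
    path.reverse()
    return score, path


# ---------------------------------------------------------------------------


def calibrate(
    profile: Profile,
    n_null: int = 1000,
    null_len: int | None = None,
    seed: int = 0,
) -> Profile:
    """Fit a Gumbel null score distribution by the method of moments.

    Scores ``n_null`` i.i.d. background-random sequences of ``null_len``
    residues (default: the profile length) with local Viterbi and fits
    (mu, lambda) so that E(S) = n_eff * exp(-lambda * (S - mu)).
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100 for a stable Gumbel fit")
    nl = null_len if null_len is not None else profile.length
    rng = np.random.default_rng(seed)
    seqs = rng.choice(N_STATES, size=(n_null, nl), p=profile.background)
    scores = _batch_viterbi_scores(profile, seqs.astype(np.int64))
    sd = float(np.std(scores, ddof=1))
    lam = np.pi / (sd * np.sqrt(6.0))
    mu = float(np.mean(scores)) - _EULER_GAMMA / lam
    cal = Calibration(mu=mu, lam=float(lam), n_null=n_null, null_len=nl, seed=seed)
    return replace(profile, calibration=cal, _log_odds=None)


def search(
    profiles: list[Profile],
    fragments: list[tuple[str, str]] | dict[str, str],
    evalue_max: float = 1e-5,
    min_len: int = 150,
) -> list[SearchHit]:
    """Screen fragments against calibrated profiles.

    Fragments shorter than ``min_len`` residues are skipped outright.  Each
    surviving fragment is scored against every profile by local Viterbi; the
    hit with the smallest E-value is reported if it clears ``evalue_max``.
    The effective database size for E-values is the number of fragments
    scanned.  Results are sorted by fragment id (input-order invariant).
    """
    for p in profiles:
        if p.calibration is None:
            raise ValueError(f"profile {p.source_group!r} is not calibrated")
    items = list(fragments.items()) if isinstance(fragments, dict) else list(fragments)
    kept = [(fid, seq) for fid, seq in items if len(seq) >= min_len]
    if not kept:
        return []
    n_eff = len(kept)
    maxlen = max(len(s) for _, s in kept)
    mat = np.full((len(kept), maxlen), N_STATES, dtype=np.int64)
    for i, (_, seq) in enumerate(kept):
        mat[i, : len(seq)] = encode_fragment(seq)

    best_e = np.full(len(kept), np.inf)
    best_s = np.full(len(kept), -np.inf)
    best_p = np.full(len(kept), -1)
    for pi, prof in enumerate(profiles):
        scores = _batch_viterbi_scores(prof, mat)
        ev = prof.calibration.evalue(scores, n_eff)
        better = ev < best_e
        best_e[better] = ev[better]
        best_s[better] = scores[better]
        best_p[better] = pi
    hits = []
    for i, (fid, seq) in enumerate(kept):
        if best_p[i] >= 0 and best_e[i] < evalue_max:
            hits.append(
                SearchHit(
                    fragment_id=fid,
                    best_profile=profiles[best_p[i]].source_group,
                    bit_score=float(best_s[i]),
                    evalue=float(best_e[i]),
                    aligned_length=len(seq),
                )
            )
    hits.sort(key=lambda h: h.fragment_id)
    return hits


def align_to_profile(profile: Profile, fragment_id: str, seq: str) -> AlignedFragment:
    """Map a fragment onto reference columns via its Viterbi path.

    The matched core maps to the profile's ``match_columns``; residues
    consumed by flank or insert states get a None marker.
    """
    enc = encode_fragment(seq)
    _, path = _viterbi_traceback(profile, enc)
    colmap: list[int | None] = [None] * len(seq)
    for pos, st in path:
        colmap[pos] = int(profile.match_columns[st])
    mapped = [c for c in colmap if c is not None]
    if not mapped:
        raise ValueError("fragment could not be aligned to any match state")
    return AlignedFragment(
        fragment_id=fragment_id,
        group=profile.source_group,
        residues=seq,
        column_map=tuple(colmap),
        span=(mapped[0], mapped[-1]),
    )
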