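"""Pairwise Ka/Ks (omega) estimation and group comparison.

Nei-Gojobori (1986) counting: synonymous and non-synonymous sites are
counted per codon position as the fraction of possible single-nucleotide
changes that are synonymous (changes to stop codons are excluded from the
denominator); observed differences are averaged over all minimal-length
substitution pathways that avoid stop codons; proportions are Jukes-Cantor
corrected.  The percent standard error of omega comes from a seeded codon
bootstrap.  Estimates can be filtered with the standard inclusion criteria
(Ka above a floor, Ks below a saturation ceiling, percent SE of omega below
a cap) and group omega distributions compared with a Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import CODON_AA, SENSE_CODONS, STOP_CODONS

__all__ = [
    "KaKsEstimate",
    "PairFilter",
    "SaturatedError",
    "count_sites",
    "kaks",
    "filter_pairs",
    "mann_whitney",
]

_BASES = "ACGT"


class SaturatedError(ValueError):
    """Raised when a substitution class has p >= 3/4 (JC correction undefined)."""


@dataclass(frozen=True)
class KaKsEstimate:
    pair_id: str
    ka: float
    ks: float
    omega: float | None  # None when Ks == 0
    se_pct: float | None  # percent standard error of omega (bootstrap)

    def __post_init__(self):
        if self.ka < 0 or self.ks < 0:
            raise ValueError("Ka and Ks must be non-negative")


@dataclass(frozen=True)
class PairFilter:
    """Inclusion criteria for omega estimates.

    Defaults are the virus-style thresholds (Ka > 0.01, Ks < 5.0, SE% < 25);
    a bacteria-style filter uses ks_max = 10.0.
    """

    ka_min: float = 0.01
    ks_max: float = 5.0
    se_pct_max: float = 25.0

    def __post_init__(self):
        if self.ka_min <= 0 or self.ks_max <= 0 or self.se_pct_max <= 0:
            raise ValueError("all thresholds must be positive")

    def passes(self, est: KaKsEstimate) -> bool:
        return (
            est.omega is not None
            and est.se_pct is not None
            and est.ka > self.ka_min
            and est.ks < self.ks_max
            and est.se_pct < self.se_pct_max
        )


# ---------------------------------------------------------------------------
# site and difference counting


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) sites of one sense codon."""
    s = 0.0
    n = 0.0
    aa = CODON_AA[codon]
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_AA[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
            n += 1.0 - syn / valid
        # a position whose every change leads to a stop contributes no sites
    return s, n


_SITE_CACHE = {c: _codon_site_counts(c) for c in SENSE_CODONS}


def _split_codons(seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {i}")
        if c not in CODON_AA:
            raise ValueError(f"invalid codon {c!r} at codon {i}")
    return codons


def count_sites(codon_seq: str) -> tuple[float, float]:
    """Total (synonymous, non-synonymous) sites of a coding sequence."""
    s_tot = n_tot = 0.0
    for c in _split_codons(codon_seq):
        s, n = _SITE_CACHE[c]
        s_tot += s
        n_tot += n
    return s_tot, n_tot


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over minimal pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all pathways are used (extremely rare with real code tables).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if a in STOP_CODONS or b in STOP_CODONS:
                nd += 1.0  # only reachable in the all-blocked fallback
            elif CODON_AA[a] == CODON_AA[b]:
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return sd / k, nd / k


_PAIR_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    hit = _PAIR_CACHE.get(key)
    if hit is None:
        hit = _pathway_differences(c1, c2)
        _PAIR_CACHE[key] = hit
    return hit


def _jc_correct(p: float, label: str) -> float:
    if p >= 0.75:
        raise SaturatedError(f"{label} proportion {p:.3f} is saturated (>= 3/4)")
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def _estimate(
    s_sites: np.ndarray, n_sites: np.ndarray, sd: np.ndarray, nd: np.ndarray
) -> tuple[float, float]:
    s_bar = float(s_sites.sum())
    n_bar = float(n_sites.sum())
    ps = float(sd.sum()) / s_bar if s_bar > 0 else 0.0
    pn = float(nd.sum()) / n_bar if n_bar > 0 else 0.0
    return _jc_correct(pn, "non-synonymous"), _jc_correct(ps, "synonymous")


def kaks(
    seq1: str,
    seq2: str,
    pair_id: str = "pair",
    n_bootstrap: int = 500,
    seed: int = 0,
) -> KaKsEstimate:
    """NG86 Ka/Ks estimate for one pair of aligned coding sequences.

    Site counts are averaged over the two sequences; omega = Ka/Ks is
    undefined (None) when Ks = 0.  ``se_pct`` is the percent standard error
    of omega over ``n_bootstrap`` codon-bootstrap replicates (None when
    omega is undefined).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    cod1 = _split_codons(seq1)
    cod2 = _split_codons(seq2)
    n_cod = len(cod1)
    s_sites = np.empty(n_cod)
    n_sites = np.empty(n_cod)
    sd = np.empty(n_cod)
    nd = np.empty(n_cod)
    for i, (a, b) in enumerate(zip(cod1, cod2)):
        sa, na = _SITE_CACHE[a]
        sb, nb = _SITE_CACHE[b]
        s_sites[i] = (sa + sb) / 2.0
        n_sites[i] = (na + nb) / 2.0
        sd[i], nd[i] = _pair_diffs(a, b)

    ka, ks = _estimate(s_sites, n_sites, sd, nd)
    omega = ka / ks if ks > 0 else None

    se_pct = None
    if omega is not None and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_cod, size=(n_bootstrap, n_cod))
        omegas = []
        for rep in idx:
            try:
                ka_r, ks_r = _estimate(s_sites[rep], n_sites[rep], sd[rep], nd[rep])
            except SaturatedError:
                continue
            if ks_r > 0:
                omegas.append(ka_r / ks_r)
        if len(omegas) >= 2 and omega > 0:
            se_pct = float(np.std(omegas, ddof=1) / omega * 100.0)
    return KaKsEstimate(pair_id=pair_id, ka=ka, ks=ks, omega=omega, se_pct=se_pct)


def filter_pairs(
    estimates: list[KaKsEstimate], pair_filter: PairFilter
) -> list[KaKsEstimate]:
    """Retain estimates passing the inclusion criteria (idempotent)."""
    return [e for e in estimates if pair_filter.passes(e)]


def mann_whitney(
    omegas_a: list[float], omegas_b: list[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on two omega samples.

    Exact p by enumeration when n_a + n_b <= 12 with no ties, otherwise the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(omegas_a, dtype=float)
    b = np.asarray(omegas_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))
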