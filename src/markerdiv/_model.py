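"""Shared 20-state Poisson amino-acid substitution model.

The simulator, the distance correction and the placement likelihood all use
the same exchangeable model: uniform stationary frequencies (1/20) and
uniform exchangeabilities, scaled so that branch lengths are expected
substitutions per site.  Under this model the transition probability has the
closed form

    P(x -> y | t) = e(t) * delta(x, y) + (1 - e(t)) / 20,
    e(t) = exp(-(20/19) * t),

so the expected proportion of differing sites between two sequences at total
path length t is p(t) = (19/20) * (1 - exp(-(20/19) * t)), with inverse
d(p) = -(19/20) * ln(1 - (20/19) * p).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_STATES = 20
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

# rate scaling constant: with uniform frequencies the fraction of events that
# change the state is 19/20, so the per-site event rate is 20/19 when the
# substitution rate is 1.
BETA = N_STATES / (N_STATES - 1)

GAP = "-"


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string as int8 state indices (gap -> -1)."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        if c == GAP:
            out[i] = -1
        else:
            try:
                out[i] = AA_INDEX[c]
            except KeyError:
                raise ValueError(f"illegal residue {c!r} at position {i}") from None
    return out


def decode(states: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[s] if s >= 0 else GAP for s in states)


def expected_p_distance(t: float) -> float:
    """Expected proportion of differing sites at path length t."""
    return (19.0 / 20.0) * (1.0 - np.exp(-BETA * t))


def poisson_distance(p: float, d_max: float = 5.0) -> float:
    """Poisson-corrected distance from an observed p-distance, capped at d_max."""
    p_cap = expected_p_distance(d_max)
    if p >= p_cap:
        return d_max
    return -(19.0 / 20.0) * np.log(1.0 - (20.0 / 19.0) * p)


def evolve_states(states: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a state vector along a branch of length t (substitutions/site).

    Implements the closed-form transition kernel exactly: each site is redrawn
    uniformly from the 20 states with probability 1 - exp(-BETA*t).
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    child = states.copy()
    if t == 0:
        return child
    redraw = rng.random(states.shape[0]) < 1.0 - np.exp(-BETA * t)
    n = int(redraw.sum())
    if n:
        child[redraw] = rng.integers(0, N_STATES, size=n, dtype=np.int8)
    return child


def propagate(partials: np.ndarray, t: float) -> np.ndarray:
    """Apply P(t) to conditional likelihoods of shape (n_sites, 20)."""
    e = np.exp(-BETA * t)
    return e * partials + (1.0 - e) * partials.sum(axis=1, keepdims=True) / N_STATES
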