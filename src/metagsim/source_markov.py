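"""Markov model for the source species of consecutive chimeric segments.

Chimeric nanopore reads join DNA fragments that are not independent draws
from the community: a fragment is more likely to be followed by one from the
same species, presumably because molecules of one species cluster near the
pore.  The model is a first-order chain whose start distribution is the
community abundance profile and whose transitions shrink every other-species
probability by a single factor, the *shrinkage rate* s (0 < s <= 1):

    P(next = i | prev = A) = s * p_i            for i != A
    P(next = A | prev = A) = 1 - s * sum_{i != A} p_i

At s = 1 consecutive sources are independent (homogeneously suspended DNA);
smaller s inflates self-transitions while preserving the relative abundances
of the other species.  The stationary distribution of this chain is the
abundance profile itself for any s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SourceModel",
    "transition_distribution",
    "transition_matrix",
    "learn_shrinkage",
    "sample_species_chain",
    "FALLBACK_SHRINKAGE",
]

FALLBACK_SHRINKAGE = 0.75


@dataclass
class SourceModel:
    """Abundance profile (start probabilities) plus shrinkage rate s."""

    abundance: Mapping[str, float]
    s: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.abundance.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"abundance must sum to 1, got {total}")
        if not 0 < self.s <= 1:
            raise ValueError(f"shrinkage rate must be in (0, 1], got {self.s}")

    @property
    def species(self) -> list[str]:
        return list(self.abundance)


def transition_distribution(prev: str, model: SourceModel) -> dict[str, float]:
    """Distribution of the next segment's source species given the previous one."""
    if prev not in model.abundance:
        raise KeyError(f"unknown species: {prev!r}")
    s = model.s
    out = {sp: s * p for sp, p in model.abundance.items()}
    out[prev] = 1.0 - s * sum(p for sp, p in model.abundance.items() if sp != prev)
    return out


def transition_matrix(model: SourceModel) -> tuple[list[str], np.ndarray]:
    """Explicit row-stochastic transition matrix (for eigen-analysis)."""
    species = model.species
    mat = np.empty((len(species), len(species)))
    for i, sp in enumerate(species):
        dist = transition_distribution(sp, model)
        mat[i] = [dist[t] for t in species]
    return species, mat


def learn_shrinkage(
    pairs: Sequence[tuple[str, str]],
    abundance: Mapping[str, float],
    min_pairs: int = 20,
    weighted: bool = False,
    return_per_species: bool = False,
):
    """Estimate s from overlapping segment pairs of chimeric reads.

    For each first-segment species A with at least *min_pairs* observations,
    the switch probability P(second != A | first = A) is divided by the
    homogeneous expectation sum_{i != A} p_i, giving a per-species reduction
    s_A; s is their (by default unweighted) mean, clamped to (0, 1].
    """
    if not pairs:
        raise ValueError("learn_shrinkage: no segment pairs")
    n_by_first: dict[str, int] = {}
    switches: dict[str, int] = {}
    for a, b in pairs:
        n_by_first[a] = n_by_first.get(a, 0) + 1
        if a != b:
            switches[a] = switches.get(a, 0) + 1
    per_species: dict[str, float] = {}
    weights: dict[str, int] = {}
    for sp, n in n_by_first.items():
        if n < min_pairs:
            continue
        if sp not in abundance or abundance[sp] <= 0:
            raise ValueError(f"species {sp!r} in pairs has no positive abundance")
        other = sum(p for t, p in abundance.items() if t != sp)
        if other <= 0:  # single-species community: switching is undefined
            continue
        per_species[sp] = (switches.get(sp, 0) / n) / other
        weights[sp] = n
    if not per_species:
        raise ValueError(
            f"no species reached min_pairs={min_pairs}; too few chimeric pairs to "
            f"estimate s — fall back to the default shrinkage rate "
            f"{FALLBACK_SHRINKAGE}"
        )
    if weighted:
        total = sum(weights.values())
        s = sum(v * weights[sp] for sp, v in per_species.items()) / total
    else:
        s = float(np.mean(list(per_species.values())))
    s = min(1.0, max(np.finfo(float).tiny, s))
    if return_per_species:
        return s, per_species
    return s


def sample_species_chain(
    k: int, model: SourceModel, rng: np.random.Generator, start: str | None = None
) -> list[str]:
    """Sample the source-species chain for a k-segment read.

    The first segment's species follows the abundance profile (or is forced
    to *start*); each later segment follows the transition distribution given
    its predecessor.
    """
    if k < 1:
        raise ValueError(f"segment count must be >= 1, got {k}")
    species = model.species
    if start is not None:
        if start not in model.abundance:
            raise KeyError(f"unknown species: {start!r}")
        chain = [start]
    else:
        probs = np.array([model.abundance[sp] for sp in species])
        probs = probs / probs.sum()
        chain = [species[rng.choice(len(species), p=probs)]]
    for _ in range(k - 1):
        dist = transition_distribution(chain[-1], model)
        p = np.array([dist[sp] for sp in species])
        chain.append(species[rng.choice(len(species), p=p / p.sum())])
    return chain


def sample_pairs(
    n: int, model: SourceModel, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Vectorized draw of n consecutive segment-source pairs (first ~ abundance,
    second ~ transition row of the first)."""
    species = model.species
    idx = {sp: i for i, sp in enumerate(species)}
    p0 = np.array([model.abundance[sp] for sp in species])
    p0 = p0 / p0.sum()
    firsts = rng.choice(len(species), size=n, p=p0)
    seconds = np.empty(n, dtype=int)
    for i, sp in enumerate(species):
        mask = firsts == i
        m = int(mask.sum())
        if m == 0:
            continue
        dist = transition_distribution(sp, model)
        row = np.array([dist[t] for t in species])
        seconds[mask] = rng.choice(len(species), size=m, p=row / row.sum())
    return [(species[a], species[b]) for a, b in zip(firsts, seconds)]
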