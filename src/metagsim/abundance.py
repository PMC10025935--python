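"""Base-level metagenomic abundance estimation with chimera-aware accounting.

Nanopore read lengths span orders of magnitude, so counting mapped *reads*
biases abundance toward species that happen to receive longer reads; counting
aligned *bases* does not.  Abundances here are fractions of total genomic DNA
weight (they sum to 1); dividing by genome size and renormalizing converts
them to relative genome copy numbers.

Multialigned segments — those with near-equivalent alignments to several
species — are disambiguated by an EM loop: the E-step splits each ambiguous
segment's bases across its candidate species proportionally to the current
abundances, the M-step renormalizes, and the loop stops when the largest
per-species change drops below 1% of the smallest abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chimeric import best_compatible_set, merge_circular_bridge
from .io_formats import SubAlignment

__all__ = [
    "AbundanceProfile",
    "BaseCount",
    "MultiSegment",
    "tally",
    "em_abundance",
    "estimate",
    "copy_numbers",
    "deviation_report",
]

MODES = ("B", "CB", "EB", "ECB", "CR", "ER")


@dataclass
class AbundanceProfile:
    """Species -> relative genomic-DNA-weight fraction; sums to 1."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("negative abundance")
        total = sum(self.entries.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "AbundanceProfile":
        total = sum(counts.values())
        if total <= 0:
            raise ValueError("cannot normalize all-zero counts")
        return cls({sp: v / total for sp, v in counts.items()})

    @classmethod
    def from_tsv(cls, path: str | Path, column: int = 1) -> "AbundanceProfile":
        entries: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                entries[parts[0]] = float(parts[column])
        return cls.from_counts(entries)

    def __getitem__(self, sp: str) -> float:
        return self.entries[sp]

    def __iter__(self):
        return iter(self.entries)

    def items(self):
        return self.entries.items()

    def get(self, sp: str, default: float = 0.0) -> float:
        return self.entries.get(sp, default)


@dataclass
class BaseCount:
    """Species -> aligned-base tally (real-valued once EM fractions accrue)."""

    entries: dict[str, float] = field(default_factory=dict)

    def add(self, species: str, bases: float) -> None:
        if bases < 0:
            raise ValueError("negative base count")
        self.entries[species] = self.entries.get(species, 0.0) + bases

    def total(self) -> float:
        return sum(self.entries.values())


@dataclass
class MultiSegment:
    """An ambiguous segment: its bases and the species it hits equivalently."""

    read_id: str
    bases: float
    candidates: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.candidates) < 2:
            raise ValueError("a multialigned segment needs >= 2 candidate species")
        if self.bases <= 0:
            raise ValueError("bases must be positive")


def _query_overlap_frac(seg: SubAlignment, other: SubAlignment) -> float:
    ov = max(0, min(seg.query_end, other.query_end) - max(seg.query_start, other.query_start))
    return ov / seg.query_span


def tally(
    sets: Sequence,
    all_alignments: Mapping[str, Sequence[SubAlignment]],
    level: str = "base",
    chimera_aware: bool = True,
    score_equiv: float = 0.9,
    mapq_equiv: int = 10,
) -> tuple[BaseCount, list[MultiSegment]]:
    """Tally aligned bases (or reads) per species, splitting off ambiguous segments.

    With *chimera_aware*, every segment of each read's best compatible set
    contributes; otherwise only the primary alignment does.  A counted segment
    becomes a MultiSegment when some other-species alignment of the same read
    overlaps it in query space and comes within *score_equiv* of its aligned
    bases and *mapq_equiv* of its MAPQ.  ``level="read"`` counts 1 per
    segment instead of its bases.
    """
    if level not in ("base", "read"):
        raise ValueError(f"level must be base or read, got {level!r}")
    unique = BaseCount()
    multi: list[MultiSegment] = []
    for cs in sets:
        alns = all_alignments.get(cs.read_id, [])
        if chimera_aware:
            counted = list(cs.segments)
        else:
            primaries = [a for a in alns if a.is_primary]
            counted = [max(primaries, key=lambda a: a.aligned_bases)] if primaries else []
        for seg in counted:
            cands = {seg.ref_species}
            for other in alns:
                if other.ref_species == seg.ref_species:
                    continue
                if _query_overlap_frac(seg, other) < 0.5:
                    continue
                if (
                    other.aligned_bases >= score_equiv * seg.aligned_bases
                    and abs(other.mapq - seg.mapq) <= mapq_equiv
                ):
                    cands.add(other.ref_species)
            weight = float(seg.aligned_bases) if level == "base" else 1.0
            if len(cands) >= 2:
                multi.append(MultiSegment(cs.read_id, weight, frozenset(cands)))
            else:
                unique.add(seg.ref_species, weight)
    return unique, multi


def em_abundance(
    unique: BaseCount,
    multi: Sequence[MultiSegment],
    rel_tol: float = 0.01,
    max_iter: int = 10_000,
) -> AbundanceProfile:
    """EM disambiguation of multialigned bases.

    Starts from the unique-count profile; alternates proportional assignment
    (E) and renormalization (M) until the largest per-species change is below
    ``rel_tol * min(positive abundances)``.  Species with neither unique bases
    nor candidate membership stay at 0 throughout.
    """
    species = sorted(set(unique.entries) | {sp for m in multi for sp in m.candidates})
    if not species or unique.total() <= 0:
        raise ValueError("em_abundance: no uniquely aligned bases to seed the profile")
    uniq = np.array([unique.entries.get(sp, 0.0) for sp in species], dtype=float)
    idx = {sp: i for i, sp in enumerate(species)}
    abun = uniq / uniq.sum()
    if not multi:
        return AbundanceProfile(dict(zip(species, abun)))
    cand_idx = [np.array([idx[sp] for sp in sorted(m.candidates)]) for m in multi]
    bases = np.array([m.bases for m in multi])
    for _ in range(max_iter):
        counts = uniq.copy()
        for ci, b in zip(cand_idx, bases):
            mass = abun[ci].sum()
            if mass > 0:
                counts[ci] += b * abun[ci] / mass
            else:  # degenerate: all candidates at zero abundance
                counts[ci] += b / len(ci)
        new = counts / counts.sum()
        diff = np.abs(new - abun).max()
        positive = new[new > 0]
        abun = new
        if diff < rel_tol * positive.min():
            break
    return AbundanceProfile(dict(zip(species, abun)))


def _split_equally(unique: BaseCount, multi: Sequence[MultiSegment]) -> AbundanceProfile:
    counts = dict(unique.entries)
    for m in multi:
        share = m.bases / len(m.candidates)
        for sp in m.candidates:
            counts[sp] = counts.get(sp, 0.0) + share
    return AbundanceProfile.from_counts(counts)


def estimate(
    alignments: Mapping[str, Sequence[SubAlignment]],
    mode: str = "ECB",
    genomes: Mapping[str, object] | None = None,
    slack: int = 10,
    min_segment: int = 100,
    **tally_kwargs,
) -> AbundanceProfile:
    """Dispatch the six ablation modes of the estimator.

    Mode letters: E = EM fine-tuning, C = chimera-aware accounting,
    B = base level, R = read level.  Non-EM modes split ambiguous segments
    equally among their candidates.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    level = "read" if mode.endswith("R") else "base"
    chimera_aware = "C" in mode
    use_em = mode.startswith("E")
    sets = []
    for read_id, subs in alignments.items():
        cs = best_compatible_set(subs, slack=slack, min_segment=min_segment)
        if genomes is not None:
            cs = merge_circular_bridge(cs, genomes)
        sets.append(cs)
    unique, multi = tally(
        sets, alignments, level=level, chimera_aware=chimera_aware, **tally_kwargs
    )
    if use_em:
        return em_abundance(unique, multi)
    return _split_equally(unique, multi)


def copy_numbers(
    profile: AbundanceProfile, genome_sizes: Mapping[str, int]
) -> dict[str, float]:
    """Relative genome copy numbers: abundance / genome size, renormalized."""
    raw = {}
    for sp, p in profile.items():
        if p > 0 and (sp not in genome_sizes or genome_sizes[sp] <= 0):
            raise ValueError(f"missing or nonpositive genome size for {sp!r}")
        raw[sp] = p / genome_sizes[sp] if p > 0 else 0.0
    total = sum(raw.values())
    return {sp: v / total for sp, v in raw.items()}


def deviation_report(
    estimated: AbundanceProfile,
    expected: AbundanceProfile,
    log_transform_r2: bool = True,
) -> dict:
    """Per-species percent deviation plus summary statistics.

    Returns ``{"per_species": {...}, "sum_abs_percent_error": ...,
    "r_squared": ..., "residual_sd": ..., "log_r_squared": ...}``.  R-squared
    is the squared Pearson correlation between estimated and expected; the
    log variant correlates log10 abundances (species with a zero on either
    side are excluded there).  A species expected at 0 but estimated positive
    is reported as infinite deviation and excluded from the summation.
    """
    if set(estimated.entries) - set(expected.entries):
        raise ValueError("estimated profile contains species absent from expected")
    per: dict[str, float] = {}
    finite = []
    est_v, exp_v = [], []
    for sp, exp_p in expected.items():
        est_p = estimated.get(sp, 0.0)
        est_v.append(est_p)
        exp_v.append(exp_p)
        if exp_p == 0:
            per[sp] = math.inf if est_p > 0 else 0.0
            if est_p == 0:
                finite.append(0.0)
        else:
            dev = (est_p - exp_p) / exp_p * 100.0
            per[sp] = dev
            finite.append(dev)
    est_a, exp_a = np.array(est_v), np.array(exp_v)
    resid = est_a - exp_a
    if len(exp_a) >= 2 and np.std(est_a) > 0 and np.std(exp_a) > 0:
        r2 = float(np.corrcoef(est_a, exp_a)[0, 1] ** 2)
    else:
        r2 = 1.0 if np.allclose(est_a, exp_a) else 0.0
    report = {
        "per_species": per,
        "sum_abs_percent_error": float(sum(abs(d) for d in finite)),
        "r_squared": r2,
        "residual_sd": float(np.std(resid)),
    }
    if log_transform_r2:
        mask = (est_a > 0) & (exp_a > 0)
        if mask.sum() >= 2:
            le, lx = np.log10(est_a[mask]), np.log10(exp_a[mask])
            if np.std(le) > 0 and np.std(lx) > 0:
                report["log_r_squared"] = float(np.corrcoef(le, lx)[0, 1] ** 2)
            else:
                report["log_r_squared"] = 1.0 if np.allclose(le, lx) else 0.0
        else:
            report["log_r_squared"] = float("nan")
    return report
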