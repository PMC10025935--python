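"""Chimeric (split) read detection via best compatible alignment sets.

A read is chimeric when its best explanation comprises two or more
subalignments against distinct reference regions — a library/sequencing
artifact, or an apparent structural difference when the true source genome is
absent from the reference.  Two subalignments are *compatible* when their
query intervals do not overlap and, on the same contig, their reference
intervals do not overlap (a small slack absorbs aligner jitter at junctions).
The best compatible set maximizes total aligned length; reads bridging the
origin of a circular replicon are detected and their flanking subalignments
merged into one, so they are not counted as chimeric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GenomeRecord, SubAlignment

__all__ = [
    "CompatibleSet",
    "ChimericProfile",
    "compatible",
    "best_compatible_set",
    "merge_circular_bridge",
    "profile_chimeras",
]

DEFAULT_SLACK = 10
DEFAULT_MIN_SEGMENT = 100
DEFAULT_MAX_EXACT = 12
DEFAULT_END_TOLERANCE = 50


@dataclass
class CompatibleSet:
    """One read's best explanation: ordered, pairwise-compatible subalignments."""

    read_id: str
    segments: list[SubAlignment]
    gaps: list[int] = field(default_factory=list)
    head_unaligned: int = 0
    tail_unaligned: int = 0

    @property
    def total_aligned(self) -> int:
        return sum(s.aligned_bases for s in self.segments)

    @property
    def min_mapq(self) -> int:
        return min(s.mapq for s in self.segments)

    @property
    def is_chimeric(self) -> bool:
        return len(self.segments) >= 2

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def wrapped(self) -> bool:
        return any(s.wrapped for s in self.segments)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def compatible(a: SubAlignment, b: SubAlignment, slack: int = DEFAULT_SLACK) -> bool:
    """True iff *a* and *b* can coexist in one compatible set.

    Query intervals may overlap by at most *slack* bases; reference intervals
    on the same contig likewise.  Different contigs never conflict in
    reference space.
    """
    if _overlap(a.query_start, a.query_end, b.query_start, b.query_end) > slack:
        return False
    if a.ref_seq == b.ref_seq and _overlap(a.ref_start, a.ref_end, b.ref_start, b.ref_end) > slack:
        return False
    return True


def _finalize(read_id: str, segments: list[SubAlignment], slack: int) -> CompatibleSet:
    segments = sorted(segments, key=lambda s: (s.query_start, s.query_end))
    gaps = [
        max(0, nxt.query_start - prev.query_end)
        for prev, nxt in zip(segments, segments[1:])
    ]
    read_len = segments[0].read_length
    head = segments[0].query_start
    tail = (read_len - segments[-1].query_end) if read_len is not None else 0
    return CompatibleSet(
        read_id=read_id,
        segments=segments,
        gaps=gaps,
        head_unaligned=head,
        tail_unaligned=max(0, tail),
    )


def _set_key(segments: Sequence[SubAlignment]):
    # maximize: total aligned, then mean mapq, then fewer segments, then
    # lexicographically smallest query_start tuple
    total = sum(s.aligned_bases for s in segments)
    mean_mapq = sum(s.mapq for s in segments) / len(segments)
    starts = tuple(sorted(s.query_start for s in segments))
    return (total, mean_mapq, -len(segments), tuple(-x for x in starts))


def _exact_search(subs: list[SubAlignment], slack: int) -> list[SubAlignment]:
    n = len(subs)
    comp = [[compatible(subs[i], subs[j], slack) for j in range(n)] for i in range(n)]
    best: list[SubAlignment] | None = None
    best_key = None
    for mask in range(1, 1 << n):
        idx = [i for i in range(n) if mask >> i & 1]
        ok = all(comp[i][j] for i, j in itertools.combinations(idx, 2))
        if not ok:
            continue
        cand = [subs[i] for i in idx]
        key = _set_key(cand)
        if best_key is None or key > best_key:
            best, best_key = cand, key
    assert best is not None
    return best


def _dp_search(subs: list[SubAlignment], slack: int) -> list[SubAlignment]:
    """Weighted interval scheduling on query space, aligned_bases as weight.

    Reference-space compatibility is enforced greedily on backtrack; exact for
    query-space conflicts, heuristic for rare reference-space ones.
    """
    order = sorted(range(len(subs)), key=lambda i: subs[i].query_end)
    ends = [subs[i].query_end for i in order]
    starts = [subs[i].query_start for i in order]
    n = len(order)
    # p[j]: rightmost i < j whose end <= start_j + slack
    import bisect

    p = [bisect.bisect_right(ends, starts[j] + slack) - 1 for j in range(n)]
    w = [subs[order[j]].aligned_bases for j in range(n)]
    dp = [0] * (n + 1)
    for j in range(1, n + 1):
        dp[j] = max(dp[j - 1], w[j - 1] + dp[p[j - 1] + 1])
    chosen: list[SubAlignment] = []
    j = n
    while j > 0:
        if dp[j] == dp[j - 1]:
            j -= 1
        else:
            cand = subs[order[j - 1]]
            if all(compatible(cand, c, slack) for c in chosen):
                chosen.append(cand)
            j = p[j - 1] + 1
    return chosen


def best_compatible_set(
    subalns: Sequence[SubAlignment],
    slack: int = DEFAULT_SLACK,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    max_exact: int = DEFAULT_MAX_EXACT,
) -> CompatibleSet:
    """Find the compatible set maximizing total aligned length.

    Secondary alignments never seed the search; segments shorter than
    *min_segment* are dropped (falling back to the single best subalignment
    if nothing survives).  Search is exhaustive up to *max_exact*
    subalignments, then switches to dynamic-programming interval scheduling.
    """
    subalns = list(subalns)
    if not subalns:
        raise ValueError("best_compatible_set: empty subalignment list")
    read_ids = {s.read_id for s in subalns}
    if len(read_ids) != 1:
        raise ValueError(f"subalignments from multiple reads: {sorted(read_ids)}")
    pool = [s for s in subalns if not s.is_secondary and s.query_span >= min_segment]
    if not pool:
        pool = [max(subalns, key=lambda s: (s.is_primary, s.aligned_bases))]
    if len(pool) <= max_exact:
        chosen = _exact_search(pool, slack)
    else:
        chosen = _dp_search(pool, slack)
    return _finalize(subalns[0].read_id, chosen, slack)


def _merge_pair(a: SubAlignment, b: SubAlignment, contig_len: int) -> SubAlignment:
    merged = SubAlignment(
        read_id=a.read_id,
        query_start=a.query_start,
        query_end=b.query_end,
        ref_species=a.ref_species,
        ref_seq=a.ref_seq,
        # unwrapped linear coordinate: ref_end may exceed the contig length
        ref_start=a.ref_start if a.strand == "+" else b.ref_start,
        ref_end=(contig_len + b.ref_end) if a.strand == "+" else (contig_len + a.ref_end),
        strand=a.strand,
        aligned_bases=a.aligned_bases + b.aligned_bases,
        mapq=min(a.mapq, b.mapq),
        is_primary=a.is_primary or b.is_primary,
        read_length=a.read_length,
        wrapped=True,
    )
    return merged


def merge_circular_bridge(
    cs: CompatibleSet,
    genomes: Mapping[str, GenomeRecord],
    end_tolerance: int = DEFAULT_END_TOLERANCE,
) -> CompatibleSet:
    """Concatenate adjacent subalignments that bridge a circular origin.

    Two consecutive segments on the same circular contig and strand, the first
    ending within *end_tolerance* of the contig end and the second starting
    within *end_tolerance* of position 0 (mirrored for the minus strand), are
    merged into one wrapped segment.  Applied iteratively; chimera status is
    recomputed afterwards.  Linear genomes pass through unchanged.
    """
    segs = list(cs.segments)
    changed = True
    while changed and len(segs) >= 2:
        changed = False
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            if a.ref_seq != b.ref_seq or a.strand != b.strand or a.wrapped or b.wrapped:
                continue
            genome = genomes.get(a.ref_species)
            if genome is None or genome.topology != "circular":
                continue
            try:
                contig_len = len(genome.contig(a.ref_seq))
            except KeyError:
                continue
            if a.strand == "+":
                bridges = (
                    a.ref_end >= contig_len - end_tolerance and b.ref_start <= end_tolerance
                )
            else:
                bridges = (
                    a.ref_start <= end_tolerance and b.ref_end >= contig_len - end_tolerance
                )
            if bridges:
                segs[i : i + 2] = [_merge_pair(a, b, contig_len)]
                changed = True
                break
    return _finalize(cs.read_id, segs, 0)


@dataclass
class ChimericProfile:
    """Fitted chimeric-read statistics driving simulation.

    ``p_geom`` is the geometric success probability of the per-read segment
    count (mean segments = 1/p); ``shrinkage_rate`` scales other-species
    transition probabilities between consecutive chimeric segments.
    """

    p_geom: float
    chimeric_fraction: float
    shrinkage_rate: float
    gap_model: object | None = None
    segment_length_model: object | None = None
    shrinkage_per_species: dict[str, float] = field(default_factory=dict)
    n_reads: int = 0

    @property
    def mean_segments(self) -> float:
        return 1.0 / self.p_geom

    def to_dict(self) -> dict:
        return {
            "p_geom": self.p_geom,
            "mean_segments": self.mean_segments,
            "chimeric_fraction": self.chimeric_fraction,
            "shrinkage_rate": self.shrinkage_rate,
            "shrinkage_per_species": self.shrinkage_per_species,
            "n_reads": self.n_reads,
        }


def profile_chimeras(
    sets: Sequence[CompatibleSet],
    abundance=None,
    fallback_shrinkage: float = 0.75,
    min_pairs: int = 20,
) -> ChimericProfile:
    """Fit the chimeric profile from per-read best compatible sets.

    The geometric parameter is the maximum-likelihood estimate on support
    {1, 2, ...}: p = N / sum(segment counts).  Gap and segment length models
    are fitted on the observed gaps/segment spans; the shrinkage rate is
    learned from consecutive same-read segment-source pairs when an abundance
    profile is supplied.
    """
    from .length_models import fit_kde
    from .source_markov import learn_shrinkage

    if not sets:
        raise ValueError("profile_chimeras: no compatible sets")
    counts = np.array([cs.n_segments for cs in sets])
    p_geom = len(counts) / counts.sum()
    chimeric_fraction = float((counts >= 2).mean())
    gaps = [g for cs in sets for g in cs.gaps]
    seg_lengths = [s.query_span for cs in sets if cs.is_chimeric for s in cs.segments]
    gap_model = fit_kde(gaps, log_space=True, log1p=True) if len(gaps) >= 2 else None
    seg_model = fit_kde(seg_lengths, log_space=True) if len(seg_lengths) >= 2 else None

    s = fallback_shrinkage
    per_species: dict[str, float] = {}
    if abundance is not None:
        pairs = [
            (a.ref_species, b.ref_species)
            for cs in sets
            if cs.is_chimeric
            for a, b in zip(cs.segments, cs.segments[1:])
        ]
        if pairs:
            try:
                s, per_species = learn_shrinkage(
                    pairs, abundance, min_pairs=min_pairs, return_per_species=True
                )
            except ValueError:
                s = fallback_shrinkage
    return ChimericProfile(
        p_geom=float(p_geom),
        chimeric_fraction=chimeric_fraction,
        shrinkage_rate=float(s),
        gap_model=gap_model,
        segment_length_model=seg_model,
        shrinkage_per_species=per_species,
        n_reads=len(sets),
    )
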