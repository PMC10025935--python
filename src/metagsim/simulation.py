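"""Read simulation: abundance-consistent base allocation, chimeric assembly,
circular wrap-around extraction, error introduction, multi-sample batching.

Abundance is allocated in *bases*, not reads, so the simulated DNA-weight
fractions match the base-level quantification model: each species receives a
base budget proportional to its (optionally perturbed) abundance, and reads
whose first segment belongs to that species are drawn until the budget is
spent.  Chimeric reads are assembled segment by segment — segment count from
the geometric model, source species from the shrinkage-rate Markov chain,
lengths and gaps from the trained KDEs — then each segment is mutated by the
error chain and collated with unaligned junk sequence.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .abundance import AbundanceProfile
from .error_model import ErrorModel, assign_qualities, introduce_errors
from .io_formats import GenomeRecord, reverse_complement, write_reads
from .length_models import AlignRatioModel, LengthKDE, sample_lengths, sample_segment_count
from .source_markov import SourceModel, sample_species_chain

__all__ = [
    "SegmentTruth",
    "SimulatedRead",
    "TrainedModels",
    "SimulationConfig",
    "perturb_abundances",
    "allocate_bases",
    "extract_fragment",
    "simulate_read",
    "simulate_sample",
    "simulate_metagenome",
    "realized_abundance",
]

_BASES = "ACGT"


@dataclass
class SegmentTruth:
    species: str
    seq_id: str
    ref_start: int
    ref_end: int  # may exceed contig length for wrapped circular segments
    strand: str
    wrapped: bool = False

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    segments: list[SegmentTruth]
    gaps: list[int] = field(default_factory=list)
    head_junk: int = 0
    tail_junk: int = 0
    qualities: list[int] | None = None
    error_logs: list[list[tuple]] = field(default_factory=list)

    @property
    def is_chimeric(self) -> bool:
        return len(self.segments) >= 2

    @property
    def pre_error_length(self) -> int:
        return sum(s.length for s in self.segments) + sum(self.gaps) + self.head_junk + self.tail_junk


@dataclass
class TrainedModels:
    """The model bundle produced by characterization and consumed by simulation."""

    aligned_read_kde: LengthKDE
    segment_kde: LengthKDE | None
    gap_kde: LengthKDE | None
    align_ratio: AlignRatioModel
    error_model: ErrorModel
    p_geom: float
    shrinkage_rate: float
    mean_read_length: float

    @property
    def chimeric_enabled(self) -> bool:
        return self.p_geom < 1.0 and self.segment_kde is not None


@dataclass
class SimulationConfig:
    genomes: list[GenomeRecord]
    samples: list[tuple[str, AbundanceProfile, int]]  # (sample_id, profile, n_reads)
    models: TrainedModels
    deviation: tuple[float, float] | None = None  # (lo, hi) relative bounds
    s_override: float | None = None
    seed: int = 0
    output_format: str = "fasta"
    max_segments: int = 10

    def __post_init__(self) -> None:
        if self.deviation is not None and self.deviation[0] > self.deviation[1]:
            raise ValueError("deviation bounds must satisfy lo <= hi")
        for sid, _profile, n in self.samples:
            if n <= 0:
                raise ValueError(f"sample {sid!r}: n_reads must be positive")


def perturb_abundances(
    profile: AbundanceProfile,
    lo: float,
    hi: float,
    genome_sizes: Mapping[str, int],
    rng: np.random.Generator,
    return_errors: bool = False,
):
    """Apply size-ranked uniform relative errors to an abundance profile.

    Relative errors ~ Uniform(lo, hi) are sorted by absolute magnitude and
    assigned to species sorted by genome size (largest |error| to the largest
    genome, ties broken by name); perturbed values are clamped at 0 and
    renormalized to sum to 1.
    """
    if lo > hi:
        raise ValueError("lo must be <= hi")
    species = sorted(profile, key=lambda sp: (-genome_sizes.get(sp, 0), sp))
    errors = rng.uniform(lo, hi, size=len(species))
    ranked = sorted(errors, key=abs, reverse=True)
    assigned = dict(zip(species, ranked))
    raw = {sp: max(0.0, profile[sp] * (1 + assigned[sp])) for sp in profile}
    perturbed = AbundanceProfile.from_counts(raw)
    if return_errors:
        return perturbed, assigned
    return perturbed


def allocate_bases(profile: AbundanceProfile, total_bases: int) -> dict[str, int]:
    """Per-species base budgets: round(p_i * total)."""
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    return {sp: int(round(p * total_bases)) for sp, p in profile.items()}


def extract_fragment(
    genome: GenomeRecord,
    seq_id: str,
    start: int,
    length: int,
    strand: str = "+",
    rng: np.random.Generator | None = None,
) -> tuple[str, int]:
    """Extract a fragment, wrapping past the origin for circular contigs.

    Circular contigs rotate (at most one full wrap); on linear contigs a
    start that would run off the end is resampled (or clamped without an rng)
    into the valid range.  Returns (sequence, actual start); minus strand
    yields the reverse complement.
    """
    contig = genome.contig(seq_id)
    clen = len(contig)
    if length > clen:
        raise ValueError(f"fragment length {length} exceeds contig length {clen}")
    if not 0 <= start < clen:
        raise ValueError(f"start {start} outside contig [0, {clen})")
    if genome.topology == "circular":
        end = start + length
        frag = contig[start:end] if end <= clen else contig[start:] + contig[: end - clen]
    else:
        if start + length > clen:
            hi = clen - length
            start = int(rng.integers(0, hi + 1)) if rng is not None else hi
        frag = contig[start : start + length]
    if strand == "-":
        frag = reverse_complement(frag)
    return frag, start


def _random_seq(n: int, comp: np.ndarray, rng: np.random.Generator) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[i] for i in rng.choice(4, size=n, p=comp))


def _choose_contig(genome: GenomeRecord, rng: np.random.Generator) -> tuple[str, int]:
    lens = np.array([len(s) for _, s in genome.sequences], dtype=float)
    i = int(rng.choice(len(lens), p=lens / lens.sum()))
    sid, seq = genome.sequences[i]
    return sid, len(seq)


def simulate_read(
    models: TrainedModels,
    genomes: Mapping[str, GenomeRecord],
    profile: AbundanceProfile,
    rng: np.random.Generator,
    s: float | None = None,
    first_species: str | None = None,
    read_id: str = "read",
    with_qualities: bool = False,
    max_segments: int = 10,
    perfect: bool = False,
) -> SimulatedRead:
    """Generate one read with full per-segment ground truth."""
    s_eff = models.shrinkage_rate if s is None else s
    source = SourceModel(dict(profile.items()), s=min(1.0, max(1e-12, s_eff)))
    k = sample_segment_count(models.p_geom, rng, max_segments=max_segments)
    if not models.chimeric_enabled:
        k = 1
    chain = sample_species_chain(k, source, rng, start=first_species)
    if k == 1:
        lengths = sample_lengths(models.aligned_read_kde, 1, rng)
    else:
        lengths = sample_lengths(models.segment_kde, k, rng)
    gaps = (
        list(sample_lengths(models.gap_kde, k - 1, rng, min_clip=0))
        if (k > 1 and models.gap_kde is not None)
        else [0] * (k - 1)
    )
    head_frac, unaligned_frac = models.align_ratio.sample(rng)
    aligned_total = int(lengths.sum())
    budget = 0
    if unaligned_frac > 0 and unaligned_frac < 1:
        budget = int(round(unaligned_frac * aligned_total / (1 - unaligned_frac)))
    ht_budget = max(0, budget - sum(gaps))
    head = int(round(head_frac * ht_budget))
    tail = ht_budget - head

    comp = models.error_model.base_composition
    parts: list[str] = [_random_seq(head, comp, rng)]
    quals: list[int] = []
    segments: list[SegmentTruth] = []
    logs: list[list[tuple]] = []
    if with_qualities:
        quals.extend(_junk_quals(models.error_model, head, rng))
    for i, (sp, ln) in enumerate(zip(chain, lengths)):
        genome = genomes[sp]
        ln = int(ln)
        sid, clen = _choose_contig(genome, rng)
        for _ in range(10):  # bounded retries when the contig is too short
            if ln <= clen:
                break
            ln = int(sample_lengths(models.segment_kde or models.aligned_read_kde, 1, rng)[0])
        ln = min(ln, clen)
        start = int(rng.integers(0, clen))
        strand = "+" if rng.random() < 0.5 else "-"
        frag, start = extract_fragment(genome, sid, start, ln, strand, rng)
        wrapped = genome.topology == "circular" and start + ln > clen
        if perfect:
            mutated, log = frag, [("match", 0, len(frag), None)]
        else:
            mutated, log = introduce_errors(frag, models.error_model, rng)
        segments.append(SegmentTruth(sp, sid, start, start + ln, strand, wrapped))
        logs.append(log)
        parts.append(mutated)
        if with_qualities:
            quals.extend(assign_qualities(log, models.error_model, rng))
        if i < k - 1:
            g = int(gaps[i])
            parts.append(_random_seq(g, comp, rng))
            if with_qualities:
                quals.extend(_junk_quals(models.error_model, g, rng))
    parts.append(_random_seq(tail, comp, rng))
    if with_qualities:
        quals.extend(_junk_quals(models.error_model, tail, rng))
    return SimulatedRead(
        read_id=read_id,
        sequence="".join(parts),
        segments=segments,
        gaps=[int(g) for g in gaps],
        head_junk=head,
        tail_junk=tail,
        qualities=quals if with_qualities else None,
        error_logs=logs,
    )


def _junk_quals(model: ErrorModel, n: int, rng: np.random.Generator) -> list[int]:
    if n <= 0:
        return []
    if model.quality_hists is None:
        raise ValueError("quality simulation requested but model has no quality histograms")
    vals, probs = model.quality_hists["match"]
    return [int(q) for q in rng.choice(vals, size=n, p=probs)]


def sample_seed(master_seed: int, sample_id: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{sample_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def simulate_sample(
    config: SimulationConfig,
    sample_id: str,
    profile: AbundanceProfile,
    n_reads: int,
    perfect: bool = False,
) -> tuple[list[SimulatedRead], dict]:
    """Simulate one sample; deterministic given (config.seed, sample_id)."""
    rng = np.random.default_rng(sample_seed(config.seed, sample_id))
    genomes = {g.species: g for g in config.genomes}
    missing = [sp for sp in profile if sp not in genomes and profile[sp] > 0]
    if missing:
        raise ValueError(f"profile species missing a genome: {missing}")
    sizes = {g.species: g.total_size for g in config.genomes}
    errors = None
    target = profile
    if config.deviation is not None:
        lo, hi = config.deviation
        profile, errors = perturb_abundances(profile, lo, hi, sizes, rng, return_errors=True)
    total_bases = int(n_reads * config.models.mean_read_length)
    budgets = allocate_bases(profile, total_bases)
    remaining = {sp: float(b) for sp, b in budgets.items()}
    reads: list[SimulatedRead] = []
    realized: dict[str, float] = {sp: 0.0 for sp in profile}
    idx = 0
    with_q = config.output_format == "fastq"
    for sp in profile:
        while remaining.get(sp, 0.0) > 0:
            read = simulate_read(
                config.models,
                genomes,
                profile,
                rng,
                s=config.s_override,
                first_species=sp,
                read_id=f"{sample_id}_{idx}",
                with_qualities=with_q,
                max_segments=config.max_segments,
                perfect=perfect,
            )
            idx += 1
            for seg in read.segments:
                remaining[seg.species] = remaining.get(seg.species, 0.0) - seg.length
                realized[seg.species] = realized.get(seg.species, 0.0) + seg.length
            reads.append(read)
    total = sum(realized.values())
    report = {
        "sample_id": sample_id,
        "n_reads": len(reads),
        "total_bases": total,
        "species": {
            sp: {
                "target": target[sp],
                "perturbed": profile[sp],
                "relative_error": None if errors is None else errors[sp],
                "realized": realized.get(sp, 0.0) / total if total else 0.0,
            }
            for sp in target
        },
    }
    return reads, report


def simulate_metagenome(config: SimulationConfig, output_prefix: str | Path | None = None):
    """Simulate every sample in the batch; optionally write reads + reports.

    Per-sample seeds are derived from (master seed, sample id), so adding a
    sample never changes another sample's reads.
    """
    results = {}
    for sample_id, profile, n_reads in config.samples:
        reads, report = simulate_sample(config, sample_id, profile, n_reads)
        if output_prefix is not None:
            prefix = Path(f"{output_prefix}_{sample_id}")
            ext = ".fastq" if config.output_format == "fastq" else ".fasta"
            write_reads(reads, prefix.with_suffix(ext), format=config.output_format)
            with open(prefix.with_suffix(".abundance_report.json"), "w") as fh:
                json.dump(report, fh, indent=1)
        results[sample_id] = (reads, report)
    return results


def realized_abundance(reads: Sequence[SimulatedRead]) -> AbundanceProfile:
    """Base-level quantification straight from ground-truth segments."""
    counts: dict[str, float] = {}
    for read in reads:
        for seg in read.segments:
            counts[seg.species] = counts.get(seg.species, 0.0) + seg.length
    return AbundanceProfile.from_counts(counts)
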