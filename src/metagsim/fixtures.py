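"""Deterministic synthetic communities and planted alignments for testing.

Every stage of the tool is testable without downloads or an aligner: random
genomes with copied homologous blocks induce controlled multialignments,
planted chimeric reads carry a known shrinkage rate and segment-count
distribution, and alignment records are emitted directly (or as PAF) with
their ground truth.  All output is byte-reproducible under a fixed seed.

The generated sequences are uniform-random nucleotides: they emulate genome
sizes, homology sharing, chimera structure and abundance skew, not realistic
phylogenetic evolution or nanopore signal artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .abundance import AbundanceProfile
from .error_model import STATES, ErrorModel, _SIDX
from .io_formats import GenomeRecord, SubAlignment
from .length_models import AlignRatioModel, fit_kde
from .simulation import TrainedModels
from .source_markov import SourceModel, sample_species_chain

__all__ = [
    "FixtureSpec",
    "logarithmic_profile",
    "make_community",
    "make_alignment_fixture",
    "planted_error_model",
    "make_trained_models",
    "write_paf",
]

_BASES = np.array(list("ACGT"))


def logarithmic_profile(n_species: int = 10, decades: float = 2.0) -> AbundanceProfile:
    """Logarithmically spaced abundances over *decades* orders of magnitude."""
    weights = np.logspace(0.0, -decades, n_species)
    weights = weights / weights.sum()
    return AbundanceProfile({f"sp{i + 1:02d}": float(w) for i, w in enumerate(weights)})


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic community.

    Defaults emulate a small mock community sequenced on a nanopore platform:
    ten species spanning two abundance decades, 50-kb genomes with a mix of
    linear and circular topologies, ~2-kb median reads, a low-percent
    chimeric-read fraction with sub-independent source switching, and a
    basecall error rate near 9% split across mismatches/insertions/deletions.
    """

    n_species: int = 10
    genome_size: int = 50_000
    circular_species: tuple[str, ...] = ("sp02", "sp05")
    shared_blocks: tuple[tuple[str, str, int], ...] = ()
    abundance: AbundanceProfile | None = None
    chimeric_fraction: float = 0.0217
    shrinkage: float = 0.77
    median_read_length: int = 2000
    read_length_sigma: float = 0.6
    median_segment_length: int = 800
    mismatch_rate: float = 0.04
    insertion_rate: float = 0.02
    deletion_rate: float = 0.03
    seed: int = 42

    def profile(self) -> AbundanceProfile:
        return self.abundance or logarithmic_profile(self.n_species)


def make_community(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[list[GenomeRecord], dict]:
    """Random genomes with planted shared homologous blocks.

    Shared blocks are byte-identical subsequences copied between the named
    species pairs, inducing controlled multialignments.  Optionally writes
    one FASTA per species plus genome/topology/truth TSVs under *out_dir*.
    """
    rng = np.random.default_rng(spec.seed)
    profile = spec.profile()
    genomes: dict[str, GenomeRecord] = {}
    for sp in profile:
        seq = "".join(rng.choice(_BASES, size=spec.genome_size))
        topo = "circular" if sp in spec.circular_species else "linear"
        genomes[sp] = GenomeRecord(species=sp, sequences=[(f"{sp}_c1", seq)], topology=topo)
    truth: dict = {"shared_blocks": []}
    for sp_a, sp_b, block_len in spec.shared_blocks:
        ga, gb = genomes[sp_a], genomes[sp_b]
        if block_len > min(ga.total_size, gb.total_size):
            raise ValueError("shared block longer than a genome")
        sid_a, seq_a = ga.sequences[0]
        sid_b, seq_b = gb.sequences[0]
        start_a = int(rng.integers(0, len(seq_a) - block_len + 1))
        start_b = int(rng.integers(0, len(seq_b) - block_len + 1))
        block = seq_a[start_a : start_a + block_len]
        gb.sequences[0] = (sid_b, seq_b[:start_b] + block + seq_b[start_b + block_len :])
        truth["shared_blocks"].append(
            {"a": (sp_a, sid_a, start_a), "b": (sp_b, sid_b, start_b), "length": block_len}
        )
    records = list(genomes.values())
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "genome_list.tsv", "w") as gl, open(
            out_dir / "topology_list.tsv", "w"
        ) as tl:
            for g in records:
                fasta = out_dir / f"{g.species}.fasta"
                with open(fasta, "w") as fh:
                    for sid, seq in g.sequences:
                        fh.write(f">{sid}\n{seq}\n")
                gl.write(f"{g.species}\t{fasta}\n")
                tl.write(f"{g.species}\t{g.topology}\n")
    return records, truth


def _lognormal_int(rng, median: float, sigma: float, size: int | None = None):
    draw = rng.lognormal(np.log(median), sigma, size=size)
    return np.maximum(50, np.rint(draw).astype(int))


def make_alignment_fixture(
    spec: FixtureSpec,
    genomes: Sequence[GenomeRecord] | None = None,
    truth: dict | None = None,
    n_reads: int = 2000,
    paf_path: str | Path | None = None,
) -> tuple[dict[str, list[SubAlignment]], dict]:
    """Planted per-read alignments with known best compatible sets.

    Each read draws its segment count from Geometric(1 - chimeric_fraction),
    its source chain from the shrinkage-rate Markov model, and perfect
    alignments on the community genomes; segments falling inside a planted
    shared block additionally emit an equivalent secondary alignment to the
    homologous species.  Returns (read_id -> subalignments, ground truth).
    """
    rng = np.random.default_rng(spec.seed + 1)
    if genomes is None:
        genomes, truth = make_community(spec)
    gmap = {g.species: g for g in genomes}
    profile = spec.profile()
    source = SourceModel(dict(profile.items()), s=spec.shrinkage)
    p_geom = 1.0 - spec.chimeric_fraction
    blocks = (truth or {}).get("shared_blocks", [])
    alignments: dict[str, list[SubAlignment]] = {}
    read_truth: dict[str, dict] = {}
    for i in range(n_reads):
        read_id = f"fix{i:06d}"
        k = int(rng.geometric(p_geom))
        k = min(k, 6)
        chain = sample_species_chain(k, source, rng)
        if k == 1:
            seg_lens = _lognormal_int(rng, spec.median_read_length, spec.read_length_sigma, 1)
        else:
            seg_lens = _lognormal_int(rng, spec.median_segment_length, spec.read_length_sigma, k)
        gaps = rng.integers(0, 200, size=k - 1)
        head = int(rng.integers(0, 80))
        tail = int(rng.integers(0, 80))
        qlen = head + int(seg_lens.sum()) + int(gaps.sum()) + tail
        qpos = head
        subs: list[SubAlignment] = []
        used: dict[str, list[tuple[int, int]]] = {}
        for j, (sp, ln) in enumerate(zip(chain, seg_lens)):
            g = gmap[sp]
            sid, seq = g.sequences[0]
            ln = int(min(ln, len(seq) // (len(chain) + 1)))
            # keep same-contig segments reference-disjoint so the planted
            # chain is itself the best compatible set
            taken = used.setdefault(sid, [])
            for _ in range(50):
                start = int(rng.integers(0, len(seq) - ln))
                if all(start + ln <= s or start >= e for s, e in taken):
                    break
            else:
                start = max((e for _s, e in taken), default=0)
                start = min(start, len(seq) - ln)
            taken.append((start, start + ln))
            strand = "+" if rng.random() < 0.5 else "-"
            subs.append(
                SubAlignment(
                    read_id=read_id,
                    query_start=qpos,
                    query_end=qpos + ln,
                    ref_species=sp,
                    ref_seq=sid,
                    ref_start=start,
                    ref_end=start + ln,
                    strand=strand,
                    aligned_bases=ln,
                    mapq=60,
                    is_primary=(j == 0),
                    read_length=qlen,
                )
            )
            for blk in blocks:
                for here, there in ((blk["a"], blk["b"]), (blk["b"], blk["a"])):
                    sp_h, sid_h, st_h = here
                    if sp_h != sp:
                        continue
                    if start >= st_h and start + ln <= st_h + blk["length"]:
                        sp_t, sid_t, st_t = there
                        off = start - st_h
                        subs.append(
                            SubAlignment(
                                read_id=read_id,
                                query_start=qpos,
                                query_end=qpos + ln,
                                ref_species=sp_t,
                                ref_seq=sid_t,
                                ref_start=st_t + off,
                                ref_end=st_t + off + ln,
                                strand=strand,
                                aligned_bases=ln,
                                mapq=60,
                                is_primary=False,
                                is_secondary=True,
                                read_length=qlen,
                            )
                        )
            qpos += ln + (int(gaps[j]) if j < k - 1 else 0)
        alignments[read_id] = subs
        read_truth[read_id] = {"k": k, "chain": chain}
    fixture_truth = {
        "reads": read_truth,
        "p_geom": p_geom,
        "shrinkage": spec.shrinkage,
        "profile": dict(profile.items()),
    }
    if paf_path is not None:
        write_paf(alignments, paf_path)
    return alignments, fixture_truth


def write_paf(alignments: Mapping[str, Sequence[SubAlignment]], path: str | Path) -> Path:
    """Emit SubAlignments as minimap2-style PAF (12 columns + tp:A tag)."""
    path = Path(path)
    with open(path, "w") as fh:
        for subs in alignments.values():
            for s in subs:
                tp = "P" if s.is_primary else ("S" if s.is_secondary else "P")
                if not s.is_primary and not s.is_secondary:
                    tp = "P"  # supplementary: minimap2 marks tp:A:P on SUPP too
                fields = [
                    s.read_id,
                    str(s.read_length or s.query_end),
                    str(s.query_start),
                    str(s.query_end),
                    s.strand,
                    s.ref_seq,
                    str(s.ref_end + 1000),
                    str(s.ref_start),
                    str(s.ref_end),
                    str(s.aligned_bases),
                    str(s.query_end - s.query_start),
                    str(s.mapq),
                    f"tp:A:{tp}",
                ]
                if s.cigar:
                    fields.append(f"cg:Z:{s.cigar}")
                fh.write("\t".join(fields) + "\n")
    return path


def planted_error_model(
    mismatch: float = 0.04,
    insertion: float = 0.02,
    deletion: float = 0.03,
    max_match_run: int = 200,
) -> ErrorModel:
    """An ErrorModel whose stationary per-base rates equal the given targets.

    Error runs have length 1 and always return to a match run whose length is
    geometric with mean (1 - mismatch - deletion) / (mismatch + insertion +
    deletion); from-match transitions are proportional to the target rates.
    """
    rates = {"mismatch": mismatch, "insertion": insertion, "deletion": deletion}
    total = sum(rates.values())
    if not 0 < total < 0.5:
        raise ValueError("combined error rate must be in (0, 0.5)")
    mean_match = (1.0 - mismatch - deletion) / total
    p = 1.0 / mean_match
    vals = np.arange(1, max_match_run + 1)
    probs = (1 - p) ** (vals - 1) * p
    probs = probs / probs.sum()
    trans = np.zeros((4, 4))
    mi = _SIDX["match"]
    for st, r in rates.items():
        trans[mi, _SIDX[st]] = r / total
    for st in rates:
        trans[_SIDX[st], mi] = 1.0
    run_lengths = {st: (np.array([1]), np.array([1.0])) for st in STATES}
    run_lengths["match"] = (vals, probs)
    quality_hists = {
        "match": (np.array([14, 18, 22]), np.array([0.2, 0.5, 0.3])),
        "mismatch": (np.array([5, 8, 11]), np.array([0.4, 0.4, 0.2])),
        "insertion": (np.array([4, 7, 10]), np.array([0.5, 0.3, 0.2])),
    }
    return ErrorModel(
        transitions=trans, run_lengths=run_lengths, quality_hists=quality_hists
    )


def make_trained_models(
    spec: FixtureSpec, rng: np.random.Generator | None = None, perfect: bool = False
) -> TrainedModels:
    """A TrainedModels bundle fitted to synthetic draws of the spec's
    distributions — the simulation-side counterpart of characterization."""
    rng = rng or np.random.default_rng(spec.seed + 2)
    read_lens = _lognormal_int(rng, spec.median_read_length, spec.read_length_sigma, 4000)
    seg_lens = _lognormal_int(rng, spec.median_segment_length, spec.read_length_sigma, 4000)
    gap_lens = rng.integers(0, 300, size=2000)
    err = (
        ErrorModel.error_free()
        if perfect
        else planted_error_model(spec.mismatch_rate, spec.insertion_rate, spec.deletion_rate)
    )
    ratio = AlignRatioModel(
        head_fracs=rng.uniform(0, 1, size=500),
        unaligned_fracs=rng.uniform(0, 0.08, size=500),
    )
    return TrainedModels(
        aligned_read_kde=fit_kde(read_lens, log_space=True),
        segment_kde=fit_kde(seg_lens, log_space=True),
        gap_kde=fit_kde(gap_lens, log_space=True, log1p=True),
        align_ratio=ratio,
        error_model=err,
        p_geom=1.0 - spec.chimeric_fraction,
        shrinkage_rate=spec.shrinkage,
        mean_read_length=float(read_lens.mean()),
    )
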