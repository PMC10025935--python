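"""Readers and writers for the alignment and sequence formats the tool touches.

All internal coordinates are 0-based, half-open.  SAM's 1-based reference
coordinates are converted at the boundary; reverse-strand alignments store
query coordinates on the original read orientation (the PAF convention), so
chimera compatibility checks can operate in read space.

PAF is parsed by hand (12 mandatory tab-separated columns plus optional
``tp:A``/``cg:Z`` tags); SAM goes through pysam, FASTA/FASTQ through Biopython.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "SubAlignment",
    "GenomeRecord",
    "ReadRecord",
    "parse_alignments",
    "load_genomes",
    "write_reads",
    "read_tsv_map",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SubAlignment:
    """One aligned block of a read against one reference interval.

    The atom of chimera detection: primary and supplementary records each
    become one SubAlignment; secondaries are retained but flagged so they can
    feed the EM multialignment pool without seeding compatible-set search.
    """

    read_id: str
    query_start: int
    query_end: int
    ref_species: str
    ref_seq: str
    ref_start: int
    ref_end: int
    strand: str
    aligned_bases: int
    mapq: int
    is_primary: bool = True
    is_secondary: bool = False
    cigar: str | None = None
    read_length: int | None = None
    wrapped: bool = False

    def __post_init__(self) -> None:
        if not self.query_start < self.query_end:
            raise ValueError(
                f"{self.read_id}: query interval empty ({self.query_start}, {self.query_end})"
            )
        if not self.ref_start < self.ref_end:
            raise ValueError(
                f"{self.read_id}: reference interval empty ({self.ref_start}, {self.ref_end})"
            )
        if self.aligned_bases > self.query_end - self.query_start:
            raise ValueError(f"{self.read_id}: aligned_bases exceeds query span")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class GenomeRecord:
    """A species' reference genome: one or more contigs plus a topology."""

    species: str
    sequences: list[tuple[str, str]]
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")

    @property
    def total_size(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    def contig(self, seq_id: str) -> str:
        for sid, seq in self.sequences:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")


def read_tsv_map(path: str | Path) -> dict[str, str]:
    """Two-column, tab-delimited, headerless key->value file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            out[parts[0]] = parts[1]
    return out


def _species_of(ref_name: str, species_map: Mapping[str, str] | None, delimiter: str) -> str:
    if species_map is not None:
        if ref_name not in species_map:
            raise KeyError(f"reference sequence id not in species map: {ref_name!r}")
        return species_map[ref_name]
    return ref_name.split(delimiter, 1)[0]


def _parse_paf_line(line: str, lineno: int, species_map, delimiter: str) -> SubAlignment:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise ValueError(f"malformed PAF line {lineno}: expected >=12 columns, got {len(cols)}")
    try:
        qlen, qstart, qend = int(cols[1]), int(cols[2]), int(cols[3])
        tstart, tend = int(cols[7]), int(cols[8])
        nmatch, mapq = int(cols[9]), int(cols[11])
    except ValueError as exc:
        raise ValueError(f"malformed PAF line {lineno}: {exc}") from None
    strand = cols[4]
    is_primary = True
    is_secondary = False
    cigar = None
    for tag in cols[12:]:
        if tag.startswith("tp:A:"):
            is_primary = tag[5] == "P"
            is_secondary = tag[5] == "S"
        elif tag.startswith("cg:Z:"):
            cigar = tag[5:]
    return SubAlignment(
        read_id=cols[0],
        query_start=qstart,
        query_end=qend,
        ref_species=_species_of(cols[5], species_map, delimiter),
        ref_seq=cols[5],
        ref_start=tstart,
        ref_end=tend,
        strand=strand,
        aligned_bases=min(nmatch, qend - qstart),
        mapq=mapq,
        is_primary=is_primary,
        is_secondary=is_secondary,
        cigar=cigar,
        read_length=qlen,
    )


# CIGAR ops that consume the query / the reference
_Q_OPS = set("MIS=X")
_R_OPS = set("MDN=X")


def _sam_to_subalignment(rec: "pysam.AlignedSegment", species_map, delimiter: str) -> SubAlignment:
    cig = rec.cigartuples
    if cig is None:
        raise ValueError(f"SAM record {rec.query_name} has no CIGAR")
    # leading/trailing clips (hard or soft) position the aligned block on the
    # full-length read as stored; query-consuming middle ops give its span
    lead = 0
    for op, ln in cig:
        if op in (4, 5):  # S, H
            lead += ln
        else:
            break
    consumed = sum(ln for op, ln in cig if op in (0, 1, 7, 8))  # M, I, =, X
    aligned = sum(ln for op, ln in cig if op in (0, 7, 8))  # M, =, X
    total = sum(ln for op, ln in cig if op in (0, 1, 4, 5, 7, 8))
    qstart, qend = lead, lead + consumed
    if rec.is_reverse:  # report on the original read orientation
        qstart, qend = total - qend, total - qstart
    return SubAlignment(
        read_id=rec.query_name,
        query_start=qstart,
        query_end=qend,
        ref_species=_species_of(rec.reference_name, species_map, delimiter),
        ref_seq=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        aligned_bases=aligned,
        mapq=rec.mapping_quality,
        is_primary=not (rec.is_secondary or rec.is_supplementary),
        is_secondary=rec.is_secondary,
        cigar=rec.cigarstring,
        read_length=total,
    )


def parse_alignments(
    path: str | Path,
    format: str = "paf",
    species_map: Mapping[str, str] | None = None,
    delimiter: str = "_",
) -> dict[str, list[SubAlignment]]:
    """Parse a PAF or SAM/BAM file into per-read lists of SubAlignments.

    Every record — primary, supplementary and secondary — becomes one
    SubAlignment, grouped by read id.  Species identity of a reference contig
    comes from *species_map* (seq_id -> species); without a map, the first
    token of the reference name before *delimiter* is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    grouped: dict[str, list[SubAlignment]] = {}
    if format == "paf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                sa = _parse_paf_line(line, lineno, species_map, delimiter)
                grouped.setdefault(sa.read_id, []).append(sa)
    elif format in ("sam", "bam"):
        mode = "rb" if format == "bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for rec in fh.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                grouped.setdefault(rec.query_name, []).append(
                    _sam_to_subalignment(rec, species_map, delimiter)
                )
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    return grouped


def load_genomes(
    genome_list: str | Path | Mapping[str, str],
    topology_list: str | Path | Mapping[str, str] | None = None,
    loader=None,
) -> list[GenomeRecord]:
    """Load per-species genomes from a species->FASTA-path table.

    *topology_list* maps species to ``linear``/``circular``; unspecified
    species default to linear.  *loader* is a hook ``path -> iterable of
    (seq_id, sequence)`` so callers can resolve remote addresses; the default
    reads local FASTA files only.
    """
    genomes = genome_list if isinstance(genome_list, Mapping) else read_tsv_map(genome_list)
    if topology_list is None:
        topologies: Mapping[str, str] = {}
    elif isinstance(topology_list, Mapping):
        topologies = topology_list
    else:
        topologies = read_tsv_map(topology_list)
    for sp, topo in topologies.items():
        if sp not in genomes:
            raise ValueError(f"species {sp!r} in topology list but not in genome list")
        if topo not in ("linear", "circular"):
            raise ValueError(f"topology for {sp!r} must be linear or circular, got {topo!r}")
    if loader is None:
        def loader(p):
            if not Path(p).exists():
                raise FileNotFoundError(p)
            return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(p), "fasta")]
    out = []
    for species, fasta_path in genomes.items():
        out.append(
            GenomeRecord(
                species=species,
                sequences=list(loader(fasta_path)),
                topology=topologies.get(species, "linear"),
            )
        )
    return out


def _phred_string(quals: Sequence[int]) -> str:
    return "".join(chr(min(q, 93) + 33) for q in quals)


def write_reads(reads: Iterable, path: str | Path, format: str = "fasta") -> Path:
    """Write simulated reads as FASTA/FASTQ plus a companion ground-truth TSV.

    Read ids encode per-segment ground truth as
    ``<species>;<seq_id>:<start>-<end>;<strand>;seg<i>of<n>;<readindex>``
    joined with ``|``; the TSV carries one row per segment.
    """
    path = Path(path)
    truth_path = path.parent / (path.stem + "_truth.tsv")
    with open(path, "w") as fh, open(truth_path, "w") as tfh:
        tfh.write(
            "read_id\tsegment_index\tspecies\tseq_id\tref_start\tref_end\tstrand\thead_trim\ttail_trim\n"
        )
        for idx, read in enumerate(reads):
            segs = read.segments
            n = len(segs)
            parts = [
                f"{s.species};{s.seq_id}:{s.ref_start}-{s.ref_end};{s.strand};seg{i + 1}of{n};{idx}"
                for i, s in enumerate(segs)
            ]
            rid = "|".join(parts) if parts else f"unaligned;{idx}"
            if format == "fasta":
                fh.write(f">{rid}\n{read.sequence}\n")
            elif format == "fastq":
                if read.qualities is None:
                    raise ValueError(
                        "fastq output requested but read has no simulated qualities"
                    )
                fh.write(f"@{rid}\n{read.sequence}\n+\n{_phred_string(read.qualities)}\n")
            else:
                raise ValueError(f"unknown read format: {format!r}")
            for i, s in enumerate(segs):
                tfh.write(
                    f"{rid}\t{i}\t{s.species}\t{s.seq_id}\t{s.ref_start}\t{s.ref_end}"
                    f"\t{s.strand}\t{read.head_junk}\t{read.tail_junk}\n"
                )
    return truth_path
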