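"""Model/Results facade over the characterization stage.

``ReadProfileModel`` is built from per-read alignments (plus optional genomes,
raw reads and an expected abundance table); ``fit()`` runs chimera detection,
abundance estimation, length-model and error-model fitting, and returns a
``ReadProfileResults`` carrying the estimates, diagnostics and a ``summary()``
table.  Simulation hangs off the results object, statsmodels-style:

    model = ReadProfileModel.from_files("aln.paf", genome_list="genomes.tsv",
                                        topology_list="topologies.tsv")
    res = model.fit(mode="ECB")
    print(res.summary())
    res.save("model_dir/")
    res.simulate(samples=[("s1", res.abundance, 1000)], seed=7,
                 output_prefix="sim")
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np

from . import abundance as abund
from .abundance import AbundanceProfile, deviation_report, estimate
from .chimeric import (
    ChimericProfile,
    best_compatible_set,
    merge_circular_bridge,
    profile_chimeras,
)
from .error_model import ErrorModel, fit_error_model
from .io_formats import GenomeRecord, SubAlignment, load_genomes, parse_alignments, read_tsv_map
from .length_models import AlignRatioModel, fit_kde
from .simulation import SimulationConfig, TrainedModels, simulate_metagenome

__all__ = ["ReadProfileModel", "ReadProfileResults", "save_models", "load_models"]


class ReadProfileModel:
    """Characterization model for a nanopore (meta)genomic read set."""

    def __init__(
        self,
        alignments: Mapping[str, Sequence[SubAlignment]],
        genomes: Sequence[GenomeRecord] | None = None,
        reads: Mapping[str, object] | None = None,
        expected_abundance: AbundanceProfile | None = None,
        slack: int = 10,
        min_segment: int = 100,
        end_tolerance: int = 50,
    ):
        if not alignments:
            raise ValueError("no alignments supplied")
        self.alignments = dict(alignments)
        self.genomes = {g.species: g for g in genomes} if genomes else {}
        self.reads = reads
        self.expected_abundance = expected_abundance
        self.slack = slack
        self.min_segment = min_segment
        self.end_tolerance = end_tolerance

    @classmethod
    def from_files(
        cls,
        alignment_path: str | Path,
        format: str = "paf",
        genome_list: str | Path | None = None,
        topology_list: str | Path | None = None,
        species_map: str | Path | None = None,
        expected_abundance: str | Path | None = None,
        **kwargs,
    ) -> "ReadProfileModel":
        smap = read_tsv_map(species_map) if species_map else None
        alns = parse_alignments(alignment_path, format=format, species_map=smap)
        genomes = load_genomes(genome_list, topology_list) if genome_list else None
        expected = AbundanceProfile.from_tsv(expected_abundance) if expected_abundance else None
        return cls(alns, genomes=genomes, expected_abundance=expected, **kwargs)

    def fit(self, mode: str = "ECB", detect_chimeras: bool = True) -> "ReadProfileResults":
        sets = []
        for read_id, subs in self.alignments.items():
            cs = best_compatible_set(subs, slack=self.slack, min_segment=self.min_segment)
            if self.genomes:
                cs = merge_circular_bridge(cs, self.genomes, end_tolerance=self.end_tolerance)
            sets.append(cs)
        profile = estimate(
            self.alignments,
            mode=mode if detect_chimeras else mode.replace("C", "") or "B",
            genomes=self.genomes or None,
            slack=self.slack,
            min_segment=self.min_segment,
        )
        chim = profile_chimeras(sets, abundance=profile)
        aligned_spans = [cs.segments[-1].query_end - cs.segments[0].query_start for cs in sets]
        aligned_kde = fit_kde(aligned_spans, log_space=True) if len(aligned_spans) >= 2 else None
        ratio = AlignRatioModel.fit(sets)
        try:
            err = fit_error_model(self.alignments, reads=self.reads)
        except ValueError:
            err = ErrorModel.error_free()
        deviation = None
        if self.expected_abundance is not None:
            deviation = deviation_report(profile, self.expected_abundance)
        return ReadProfileResults(
            model=self,
            sets=sets,
            abundance=profile,
            chimeric_profile=chim,
            aligned_read_kde=aligned_kde,
            align_ratio=ratio,
            error_model=err,
            mode=mode,
            deviation=deviation,
        )


@dataclass
class ReadProfileResults:
    """Fitted characterization: estimates, diagnostics, simulation entry point."""

    model: ReadProfileModel
    sets: list
    abundance: AbundanceProfile
    chimeric_profile: ChimericProfile
    aligned_read_kde: object
    align_ratio: AlignRatioModel
    error_model: ErrorModel
    mode: str = "ECB"
    deviation: dict | None = None

    @property
    def n_reads(self) -> int:
        return len(self.sets)

    @property
    def chimeric_fraction(self) -> float:
        return self.chimeric_profile.chimeric_fraction

    @property
    def shrinkage_rate(self) -> float:
        return self.chimeric_profile.shrinkage_rate

    @property
    def trained_models(self) -> TrainedModels:
        cp = self.chimeric_profile
        mean_len = float(np.mean([cs.segments[-1].query_end - cs.segments[0].query_start
                                  for cs in self.sets]))
        return TrainedModels(
            aligned_read_kde=self.aligned_read_kde,
            segment_kde=cp.segment_length_model,
            gap_kde=cp.gap_model,
            align_ratio=self.align_ratio,
            error_model=self.error_model,
            p_geom=cp.p_geom,
            shrinkage_rate=cp.shrinkage_rate,
            mean_read_length=mean_len,
        )

    def copy_numbers(self) -> dict[str, float]:
        sizes = {sp: g.total_size for sp, g in self.model.genomes.items()}
        return abund.copy_numbers(self.abundance, sizes)

    def simulate(
        self,
        samples: Sequence[tuple[str, AbundanceProfile, int]],
        genomes: Sequence[GenomeRecord] | None = None,
        deviation: tuple[float, float] | None = None,
        s: float | None = None,
        seed: int = 0,
        output_format: str = "fasta",
        output_prefix: str | Path | None = None,
    ):
        """Simulate one or more samples from the fitted models."""
        genome_list = list(genomes) if genomes is not None else list(self.model.genomes.values())
        config = SimulationConfig(
            genomes=genome_list,
            samples=list(samples),
            models=self.trained_models,
            deviation=deviation,
            s_override=s,
            seed=seed,
            output_format=output_format,
        )
        return simulate_metagenome(config, output_prefix=output_prefix)

    def summary(self) -> str:
        cp = self.chimeric_profile
        lines = [
            "Read profile characterization",
            "=" * 46,
            f"{'reads':<30}{self.n_reads:>16}",
            f"{'estimation mode':<30}{self.mode:>16}",
            f"{'chimeric fraction':<30}{cp.chimeric_fraction:>16.4f}",
            f"{'segment-count p (geometric)':<30}{cp.p_geom:>16.4f}",
            f"{'mean segments per read':<30}{cp.mean_segments:>16.4f}",
            f"{'shrinkage rate s':<30}{cp.shrinkage_rate:>16.4f}",
            "-" * 46,
            f"{'species':<24}{'abundance':>12}",
        ]
        for sp, p in sorted(self.abundance.items(), key=lambda kv: -kv[1]):
            lines.append(f"{sp:<24}{p:>12.6f}")
        if self.deviation is not None:
            lines += [
                "-" * 46,
                f"{'sum |percent error|':<30}{self.deviation['sum_abs_percent_error']:>16.4f}",
                f"{'R-squared':<30}{self.deviation['r_squared']:>16.4f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def save(self, model_dir: str | Path) -> Path:
        return save_models(self.trained_models, model_dir, extra=self.chimeric_profile.to_dict())


def save_models(models: TrainedModels, model_dir: str | Path, extra: dict | None = None) -> Path:
    """Persist a model bundle to the directory layout ``simulate`` consumes."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    joblib.dump(models.aligned_read_kde, model_dir / "kde_aligned_reads.model")
    if models.segment_kde is not None:
        joblib.dump(models.segment_kde, model_dir / "kde_segments.model")
    if models.gap_kde is not None:
        joblib.dump(models.gap_kde, model_dir / "kde_gaps.model")
    joblib.dump(models.align_ratio, model_dir / "align_ratio.model")
    em = models.error_model
    err = {
        "transitions": em.transitions.tolist(),
        "run_lengths": {
            st: {"values": v.tolist(), "probs": p.tolist()}
            for st, (v, p) in em.run_lengths.items()
        },
        "base_composition": em.base_composition.tolist(),
        "quality_hists": None
        if em.quality_hists is None
        else {
            st: {"values": v.tolist(), "probs": p.tolist()}
            for st, (v, p) in em.quality_hists.items()
        },
    }
    with open(model_dir / "error_model.json", "w") as fh:
        json.dump(err, fh)
    profile = {
        "p_geom": models.p_geom,
        "shrinkage_rate": models.shrinkage_rate,
        "mean_read_length": models.mean_read_length,
    }
    if extra:
        profile.update(extra)
    with open(model_dir / "chimeric_profile.json", "w") as fh:
        json.dump(profile, fh, indent=1)
    return model_dir


def load_models(model_dir: str | Path) -> TrainedModels:
    model_dir = Path(model_dir)
    with open(model_dir / "chimeric_profile.json") as fh:
        profile = json.load(fh)
    with open(model_dir / "error_model.json") as fh:
        err = json.load(fh)
    error_model = ErrorModel(
        transitions=np.array(err["transitions"]),
        run_lengths={
            st: (np.array(d["values"]), np.array(d["probs"]))
            for st, d in err["run_lengths"].items()
        },
        base_composition=np.array(err["base_composition"]),
        quality_hists=None
        if err["quality_hists"] is None
        else {
            st: (np.array(d["values"]), np.array(d["probs"]))
            for st, d in err["quality_hists"].items()
        },
    )
    seg = model_dir / "kde_segments.model"
    gap = model_dir / "kde_gaps.model"
    return TrainedModels(
        aligned_read_kde=joblib.load(model_dir / "kde_aligned_reads.model"),
        segment_kde=joblib.load(seg) if seg.exists() else None,
        gap_kde=joblib.load(gap) if gap.exists() else None,
        align_ratio=joblib.load(model_dir / "align_ratio.model"),
        error_model=error_model,
        p_geom=profile["p_geom"],
        shrinkage_rate=profile["shrinkage_rate"],
        mean_read_length=profile["mean_read_length"],
    )
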