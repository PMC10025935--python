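"""Simulator: perturbation, allocation, fragment extraction, read assembly,
multi-sample batching and the simulation/quantification closed loop."""

import numpy as np
import pytest

from metagsim.abundance import AbundanceProfile
from metagsim.error_model import replay_log
from metagsim.io_formats import GenomeRecord
from metagsim.simulation import (
    SimulationConfig,
    allocate_bases,
    extract_fragment,
    perturb_abundances,
    realized_abundance,
    sample_seed,
    simulate_metagenome,
    simulate_read,
    simulate_sample,
)


class TestPerturbAbundances:
    def test_identity_bounds(self, rng):
        p = AbundanceProfile({"A": 0.5, "B": 0.3, "C": 0.2})
        out = perturb_abundances(p, 0.0, 0.0, {"A": 5, "B": 4, "C": 2}, rng)
        assert out.entries == pytest.approx(p.entries)

    def test_rank_matching_by_size_and_magnitude(self, rng):
        """Largest |error| goes to the largest genome: with draws
        {+0.08, -0.02, +0.05} and sizes 5/4/2 Mbp the assignment is
        fixed regardless of draw order."""
        p = AbundanceProfile({"big": 0.4, "mid": 0.35, "small": 0.25})
        sizes = {"big": 5_000_000, "mid": 4_000_000, "small": 2_000_000}

        class FakeRng:
            def uniform(self, lo, hi, size):
                return np.array([-0.02, 0.08, 0.05])

        out, errors = perturb_abundances(p, -0.1, 0.1, sizes, FakeRng(), return_errors=True)
        assert errors == {"big": 0.08, "mid": 0.05, "small": -0.02}
        raw = {"big": 0.4 * 1.08, "mid": 0.35 * 1.05, "small": 0.25 * 0.98}
        z = sum(raw.values())
        for sp in raw:
            assert out[sp] == pytest.approx(raw[sp] / z)

    def test_draws_stay_within_bounds(self, rng):
        p = AbundanceProfile({"A": 0.6, "B": 0.4})
        for _ in range(300):
            _out, errors = perturb_abundances(
                p, -0.1, 0.1, {"A": 2, "B": 1}, rng, return_errors=True
            )
            assert all(-0.1 <= e <= 0.1 for e in errors.values())

    def test_invalid_bounds(self, rng):
        p = AbundanceProfile({"A": 1.0})
        with pytest.raises(ValueError):
            perturb_abundances(p, 0.2, -0.2, {"A": 1}, rng)


class TestAllocateBases:
    def test_proportional_split(self):
        p = AbundanceProfile({"A": 0.7, "B": 0.3})
        assert allocate_bases(p, 10_000) == {"A": 7000, "B": 3000}

    def test_single_species_gets_everything(self):
        assert allocate_bases(AbundanceProfile({"A": 1.0}), 999) == {"A": 999}

    def test_positive_total_required(self):
        with pytest.raises(ValueError):
            allocate_bases(AbundanceProfile({"A": 1.0}), 0)


class TestExtractFragment:
    circ = GenomeRecord("A", [("c", "ACGTT")], topology="circular")
    lin = GenomeRecord("A", [("c", "ACGTT")], topology="linear")

    def test_circular_rotation(self):
        frag, start = extract_fragment(self.circ, "c", 3, 4, "+")
        assert frag == "TTAC" and start == 3

    def test_linear_start_clamped_into_range(self, rng):
        frag, start = extract_fragment(self.lin, "c", 3, 4, "+", rng)
        assert start in (0, 1) and len(frag) == 4

    def test_reverse_complement(self):
        frag, _ = extract_fragment(self.lin, "c", 0, 5, "-")
        assert frag == "AACGT"

    def test_fragment_longer_than_contig(self):
        with pytest.raises(ValueError):
            extract_fragment(self.lin, "c", 0, 6, "+")


@pytest.fixture()
def sim_setup(spec, community, trained_models):
    genomes, _ = community
    return genomes, {g.species: g for g in genomes}, trained_models, spec.profile()


class TestSimulateRead:
    def test_single_segment_read(self, sim_setup, rng):
        genomes, gmap, models, profile = sim_setup
        models_single = models.__class__(**{**models.__dict__, "p_geom": 1.0})
        read = simulate_read(models_single, gmap, profile, rng)
        assert len(read.segments) == 1 and not read.is_chimeric
        assert read.pre_error_length == read.segments[0].length + read.head_junk + read.tail_junk

    def test_iid_species_at_s_one(self, sim_setup, rng):
        _genomes, gmap, models, profile = sim_setup
        counts = {sp: 0 for sp in profile}
        n = 4000
        for i in range(n):
            read = simulate_read(models, gmap, profile, rng, s=1.0, perfect=True)
            counts[read.segments[0].species] += 1
        for sp in profile:
            se = max(3 * np.sqrt(profile[sp] * n), 10)
            assert abs(counts[sp] - profile[sp] * n) < se + 25

    def test_ground_truth_replay(self, sim_setup, rng):
        """Re-extracting each segment and replaying its error log rebuilds
        the emitted sequence exactly (junk regions pass through unmutated)."""
        _genomes, gmap, models, profile = sim_setup
        for _ in range(30):
            read = simulate_read(models, gmap, profile, rng)
            pos = read.head_junk
            for i, (seg, log) in enumerate(zip(read.segments, read.error_logs)):
                g = gmap[seg.species]
                frag, _ = extract_fragment(
                    g, seg.seq_id, seg.ref_start % len(g.contig(seg.seq_id)),
                    seg.length, seg.strand,
                )
                mut = replay_log(frag, log)
                assert read.sequence[pos : pos + len(mut)] == mut
                pos += len(mut)
                if i < len(read.segments) - 1:
                    pos += read.gaps[i]
            assert pos + read.tail_junk == len(read.sequence)

    def test_wrapped_segments_only_on_circular_genomes(self, sim_setup, rng):
        _genomes, gmap, models, profile = sim_setup
        for _ in range(300):
            read = simulate_read(models, gmap, profile, rng, perfect=True)
            for seg in read.segments:
                if seg.wrapped:
                    assert gmap[seg.species].topology == "circular"
                clen = len(gmap[seg.species].contig(seg.seq_id))
                if not seg.wrapped:
                    assert 0 <= seg.ref_start < seg.ref_end <= clen


class TestSimulateSample:
    def test_bit_identical_reruns(self, sim_setup, spec):
        genomes, _gmap, models, profile = sim_setup
        cfg = SimulationConfig(genomes=genomes, samples=[], models=models, seed=5)
        r1, rep1 = simulate_sample(cfg, "s1", profile, 200)
        r2, rep2 = simulate_sample(cfg, "s1", profile, 200)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert rep1 == rep2

    def test_sample_seeds_independent_of_batch(self, sim_setup):
        genomes, _gmap, models, profile = sim_setup
        cfg1 = SimulationConfig(
            genomes=genomes, samples=[("a", profile, 50)], models=models, seed=5
        )
        cfg2 = SimulationConfig(
            genomes=genomes,
            samples=[("a", profile, 50), ("b", profile, 50)],
            models=models,
            seed=5,
        )
        out1 = simulate_metagenome(cfg1)
        out2 = simulate_metagenome(cfg2)
        assert [r.sequence for r in out1["a"][0]] == [r.sequence for r in out2["a"][0]]

    def test_seed_derivation_stable_and_in_range(self):
        s = sample_seed(123, "sampleX")
        assert s == sample_seed(123, "sampleX")
        assert 0 <= s < 2**31
        assert s != sample_seed(123, "sampleY")

    def test_realized_base_fractions_track_profile(self, sim_setup):
        genomes, _gmap, models, _ = sim_setup
        profile = AbundanceProfile({"sp01": 0.5, "sp02": 0.3, "sp03": 0.2})
        cfg = SimulationConfig(genomes=genomes, samples=[], models=models, seed=11)
        reads, report = simulate_sample(cfg, "s", profile, 3000, perfect=True)
        realized = realized_abundance(reads)
        for sp in profile:
            assert abs(realized[sp] - profile[sp]) < 0.01
            assert report["species"][sp]["realized"] == pytest.approx(realized[sp])

    def test_deviation_bounds_respected_in_report(self, sim_setup):
        genomes, _gmap, models, profile = sim_setup
        cfg = SimulationConfig(
            genomes=genomes, samples=[], models=models, seed=3, deviation=(-0.1, 0.1)
        )
        _reads, report = simulate_sample(cfg, "s", profile, 100, perfect=True)
        for sp, row in report["species"].items():
            assert -0.1 <= row["relative_error"] <= 0.1
            assert row["perturbed"] == pytest.approx(
                row["target"] * (1 + row["relative_error"]) /
                sum(report["species"][t]["target"] * (1 + report["species"][t]["relative_error"])
                    for t in report["species"]),
                rel=1e-9,
            )

    def test_missing_genome_for_profile_species(self, sim_setup):
        genomes, _gmap, models, _ = sim_setup
        cfg = SimulationConfig(genomes=genomes, samples=[], models=models, seed=1)
        with pytest.raises(ValueError, match="ghost"):
            simulate_sample(cfg, "s", AbundanceProfile({"ghost": 1.0}), 10)

    def test_fasta_output_and_truth_rows(self, sim_setup, tmp_path):
        genomes, _gmap, models, profile = sim_setup
        cfg = SimulationConfig(
            genomes=genomes, samples=[("s1", profile, 50)], models=models, seed=2
        )
        simulate_metagenome(cfg, output_prefix=tmp_path / "sim")
        fasta = tmp_path / "sim_s1.fasta"
        truth = tmp_path / "sim_s1_truth.tsv"
        assert fasta.exists() and truth.exists()
        n_reads = sum(1 for ln in open(fasta) if ln.startswith(">"))
        n_rows = sum(1 for _ in open(truth)) - 1
        assert n_rows >= n_reads > 0
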