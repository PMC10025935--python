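# metagsim

Characterization and simulation of nanopore metagenomic sequencing reads.

Nanopore metagenome datasets carry three platform-specific complications that
standard short-read tooling ignores: read lengths spanning several orders of
magnitude, basecall error rates of 5–15%, and a small but persistent fraction
of **chimeric (split) reads** whose best alignment explanation is two or more
subalignments against distinct reference regions. `metagsim` is for
bioinformaticians who need (a) accurate **species abundance estimates** from
long-read alignments against a reference metagenome and (b) **simulated
metagenomes with known ground truth** — including chimeric artifacts,
circular-genome wrap-around reads and realistic abundance deviation — to
benchmark assemblers, binners and quantification tools.

## The models

**Chimera detection.** For each read, its subalignments (primary +
supplementary, from PAF or SAM) are searched for the *best compatible set*:
a subset pairwise non-overlapping in query and reference coordinates (up to a
small slack) maximizing total aligned length. This is exact (exhaustive) up
to 12 subalignments and falls back to weighted interval scheduling beyond.
A read is chimeric iff the best set has ≥ 2 segments; reads bridging the
origin of a circular replicon are merged back into a single wrapped segment
first. The per-read segment count *k* is modeled as Geometric(*p*) on
{1, 2, …}, so the mean segment count is 1/*p* and the chimeric fraction is
1 − *p*.

**Source-species Markov chain.** Consecutive chimeric segments are not
independent draws from the community. With community abundances
{p_A, …, p_N} and a single *shrinkage rate* s ∈ (0, 1]:

    P(next = i | prev = A) = s·p_i                    (i ≠ A)
    P(next = A | prev = A) = 1 − s·Σ_{i≠A} p_i

s = 1 recovers independent sources; s < 1 inflates self-transitions while
preserving relative abundances of the other species (the chain's stationary
distribution is the abundance profile for every s). s is estimated from
overlapping segment pairs as the mean over species of
P̂(switch | first = A) / Σ_{i≠A} p_i.

**Base-level EM abundance.** Abundance is the fraction of aligned *bases*
(relative genomic DNA weight), not reads, per species; dividing by genome
size gives relative copy numbers. Ambiguous segments aligning equivalently
to several species are resolved by EM: E-step splits their bases across
candidates proportionally to current abundances, M-step renormalizes, and
iteration stops when the largest change is below 1% of the smallest
abundance. Six ablation modes (`B, CB, EB, ECB, CR, ER`) toggle base/read
level, chimera-aware accounting, and EM.

**Simulation.** Read/segment/gap lengths come from log-space Gaussian KDEs
fitted to the characterized data; errors from a first-order event chain over
match/mismatch/insertion/deletion runs; per-species base budgets from the
(optionally size-rank perturbed) abundance profile. Every read records full
per-segment ground truth.

## Worked example

```python
from metagsim.fixtures import FixtureSpec, make_community, make_alignment_fixture
from metagsim.model import ReadProfileModel

spec = FixtureSpec(n_species=6, genome_size=30_000, chimeric_fraction=0.15, seed=21)
genomes, truth = make_community(spec)
alns, _ = make_alignment_fixture(spec, genomes=genomes, truth=truth, n_reads=3000)

res = ReadProfileModel(alns, genomes=genomes).fit(mode="ECB")
print(res.summary())
```

```
Read profile characterization
==============================================
reads                                     3000
estimation mode                            ECB
chimeric fraction                       0.1503
segment-count p (geometric)             0.8491
mean segments per read                  1.1777
shrinkage rate s                        0.8003
----------------------------------------------
species                    abundance
sp01                        0.599328
sp02                        0.240521
sp03                        0.104737
sp04                        0.031320
sp05                        0.015511
sp06                        0.008583
==============================================
```

The fixture planted a 15% chimeric fraction (observed 0.1503), a shrinkage
rate of 0.77 (recovered 0.80 from ~450 segment pairs) and a logarithmic
6-species profile (recovered per species to within a few thousandths).
Simulation then closes the loop — realized base fractions track the target
profile:

```python
out = res.simulate(samples=[("s1", spec.profile(), 300)], seed=17)
reads, report = out["s1"]
```

```
simulated 312 reads, 730109 bases
  sp01: target 0.6043  realized 0.6068
  sp02: target 0.2406  realized 0.2359
  sp03: target 0.0958  realized 0.0974
  ...
```

The same stages are scriptable from a shell: `metagsim characterize`,
`metagsim abundance`, `metagsim simulate`, `metagsim fixtures`.

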