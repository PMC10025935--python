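"""Base-level abundance estimation: tally, EM, ablation modes, reporting."""

import math

import numpy as np
import pytest

from metagsim.abundance import (
    AbundanceProfile,
    BaseCount,
    MultiSegment,
    copy_numbers,
    deviation_report,
    em_abundance,
    estimate,
    tally,
)
from metagsim.chimeric import best_compatible_set

from conftest import make_sub


def _sets_and_alns(alns_by_read):
    sets = [
        best_compatible_set(subs, min_segment=10) for subs in alns_by_read.values()
    ]
    return sets, alns_by_read


class TestTally:
    def test_chimeric_segments_count_toward_their_species(self):
        subs = [
            make_sub(read_id="r1", qs=0, qe=500, species="A", seq="cA", aligned=500),
            make_sub(read_id="r1", qs=520, qe=820, species="B", seq="cB", aligned=300),
        ]
        sets, alns = _sets_and_alns({"r1": subs})
        unique, multi = tally(sets, alns)
        assert unique.entries == {"A": 500.0, "B": 300.0} and multi == []

    def test_equal_score_competitor_becomes_multisegment(self):
        seg = make_sub(read_id="r1", qs=0, qe=400, species="A", seq="cA")
        alt = make_sub(read_id="r1", qs=0, qe=400, species="B", seq="cB",
                       is_primary=False, is_secondary=True)
        sets, alns = _sets_and_alns({"r1": [seg, alt]})
        unique, multi = tally(sets, alns)
        assert unique.entries == {}
        (m,) = multi
        assert m.bases == 400 and m.candidates == frozenset({"A", "B"})

    def test_read_level_without_chimera_awareness_counts_primary_once(self):
        subs = [
            make_sub(read_id="r1", qs=0, qe=500, species="A", seq="cA"),
            make_sub(read_id="r1", qs=520, qe=820, species="B", seq="cB",
                     is_primary=False),
        ]
        sets, alns = _sets_and_alns({"r1": subs})
        unique, multi = tally(sets, alns, level="read", chimera_aware=False)
        assert unique.entries == {"A": 1.0} and multi == []


class TestEMAbundance:
    def test_no_multialignments_is_plain_normalization(self):
        prof = em_abundance(BaseCount({"A": 600, "B": 400}), [])
        assert prof["A"] == pytest.approx(0.6) and prof["B"] == pytest.approx(0.4)

    def test_fixed_point_worked_example(self):
        # E assigns 90/10, M restores 0.9/0.1: converged immediately
        prof = em_abundance(
            BaseCount({"A": 900, "B": 100}),
            [MultiSegment("r", 100, frozenset({"A", "B"}))],
        )
        assert prof["A"] == pytest.approx(0.9, abs=1e-12)
        assert prof["B"] == pytest.approx(0.1, abs=1e-12)

    def test_first_iteration_matches_hand_computation(self):
        """unique {A:500,B:300,C:200}, multi [(100,{A,B}),(100,{B,C})]:
        first E/M gives {A:0.46875, B:0.33125, C:0.2}."""
        unique = BaseCount({"A": 500, "B": 300, "C": 200})
        multi = [
            MultiSegment("r1", 100, frozenset({"A", "B"})),
            MultiSegment("r2", 100, frozenset({"B", "C"})),
        ]
        prof = em_abundance(unique, multi, rel_tol=1e30)  # stop after 1 round
        assert prof["A"] == pytest.approx(0.46875)
        assert prof["B"] == pytest.approx(0.33125)
        assert prof["C"] == pytest.approx(0.2)

    def test_convergence_matches_independent_fixed_point_oracle(self):
        unique = BaseCount({"A": 500, "B": 300, "C": 200})
        multi = [
            MultiSegment("r1", 100, frozenset({"A", "B"})),
            MultiSegment("r2", 100, frozenset({"B", "C"})),
        ]
        prof = em_abundance(unique, multi, rel_tol=1e-12)

        # oracle: dumb dict-based fixed-point iteration, written independently
        abun = {"A": 0.5, "B": 0.3, "C": 0.2}
        for _ in range(10_000):
            counts = {"A": 500.0, "B": 300.0, "C": 200.0}
            for bases, cands in ((100, ("A", "B")), (100, ("B", "C"))):
                tot = sum(abun[c] for c in cands)
                for c in cands:
                    counts[c] += bases * abun[c] / tot
            z = sum(counts.values())
            abun = {k: v / z for k, v in counts.items()}
        for sp in abun:
            assert prof[sp] == pytest.approx(abun[sp], abs=1e-9)

    def test_conservation_and_simplex_invariants(self, rng):
        species = [f"s{i}" for i in range(6)]
        unique = BaseCount({sp: float(rng.integers(50, 2000)) for sp in species})
        multi = [
            MultiSegment(
                f"r{i}",
                float(rng.integers(10, 500)),
                frozenset(rng.choice(species, size=2, replace=False)),
            )
            for i in range(20)
        ]
        prof = em_abundance(unique, multi, rel_tol=1e-9)
        assert sum(prof.entries.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in prof.entries.values())

    def test_equal_candidate_symmetry(self):
        unique = BaseCount({"A": 300, "B": 300, "C": 400})
        multi = [MultiSegment("r", 200, frozenset({"A", "B"}))]
        prof = em_abundance(unique, multi, rel_tol=1e-12)
        assert prof["A"] == pytest.approx(prof["B"], abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            em_abundance(BaseCount({}), [])


def _homolog_fixture():
    """100:1 abundance pair sharing a homologous region.

    Reads from the shared region truly originate from the abundant species A
    but the aligner hands their primary alignment to the rare species B (they
    hit both equally well), grossly inflating B under primary-only counting;
    EM reassigns the ambiguous bases in proportion to the abundances."""
    alns = {}
    for i in range(100):  # unique reads of abundant species A
        alns[f"a{i}"] = [make_sub(read_id=f"a{i}", qs=0, qe=1000, species="A", seq="cA")]
    alns["b_unique"] = [make_sub(read_id="b_unique", qs=0, qe=1000, species="B", seq="cB")]
    for j in range(20):  # shared-region reads, primary misassigned to B
        rid = f"shared{j}"
        alns[rid] = [
            make_sub(read_id=rid, qs=0, qe=1000, species="B", seq="cB"),
            make_sub(read_id=rid, qs=0, qe=1000, species="A", seq="cA",
                     is_primary=False, is_secondary=True),
        ]
    return alns, {"A": 120 / 121, "B": 1 / 121}


class TestEstimateModes:
    def test_em_mode_beats_plain_base_mode_on_rare_species(self):
        alns, truth = _homolog_fixture()
        plain = estimate(alns, mode="B", min_segment=10)
        em = estimate(alns, mode="ECB", min_segment=10)
        err_plain = abs(plain.get("B") - truth["B"])
        err_em = abs(em.get("B") - truth["B"])
        assert err_em < err_plain

    def test_modes_agree_without_multialignments(self):
        alns = {
            "r1": [make_sub(read_id="r1", qs=0, qe=1000, species="A", seq="cA")],
            "r2": [make_sub(read_id="r2", qs=0, qe=1000, species="B", seq="cB")],
            "r3": [make_sub(read_id="r3", qs=0, qe=1000, species="A", seq="cA")],
        }
        base_modes = ["B", "CB", "EB", "ECB"]
        profiles = [estimate(alns, mode=m, min_segment=10) for m in base_modes]
        for prof in profiles[1:]:
            for sp in prof:
                assert prof[sp] == pytest.approx(profiles[0][sp], abs=1e-12)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            estimate({}, mode="XYZ")


class TestCopyNumbers:
    def test_worked_example(self):
        prof = AbundanceProfile({"A": 0.6, "B": 0.4})
        cn = copy_numbers(prof, {"A": 6_000_000, "B": 2_000_000})
        assert cn["A"] == pytest.approx(1 / 3) and cn["B"] == pytest.approx(2 / 3)

    def test_equal_sizes_identity(self):
        prof = AbundanceProfile({"A": 0.7, "B": 0.3})
        cn = copy_numbers(prof, {"A": 10, "B": 10})
        assert cn == pytest.approx(prof.entries)

    def test_single_species_and_missing_size(self):
        assert copy_numbers(AbundanceProfile({"A": 1.0}), {"A": 5}) == {"A": 1.0}
        with pytest.raises(ValueError):
            copy_numbers(AbundanceProfile({"A": 1.0}), {})


class TestDeviationReport:
    def test_identical_profiles(self):
        p = AbundanceProfile({"A": 0.5, "B": 0.5})
        rep = deviation_report(p, p)
        assert all(v == 0 for v in rep["per_species"].values())
        assert rep["r_squared"] == pytest.approx(1.0)
        assert rep["sum_abs_percent_error"] == 0

    def test_signed_percent_deviation(self):
        est = AbundanceProfile({"A": 0.55, "B": 0.45})
        exp = AbundanceProfile({"A": 0.5, "B": 0.5})
        rep = deviation_report(est, exp)
        assert rep["per_species"]["A"] == pytest.approx(10.0)
        assert rep["per_species"]["B"] == pytest.approx(-10.0)

    def test_log_r_squared_uses_log10_values(self):
        exp = AbundanceProfile({"A": 0.9, "B": 0.09, "C": 0.01})
        est = AbundanceProfile({"A": 0.89, "B": 0.1, "C": 0.01})
        rep = deviation_report(est, exp)
        le = np.log10([0.89, 0.1, 0.01])
        lx = np.log10([0.9, 0.09, 0.01])
        assert rep["log_r_squared"] == pytest.approx(float(np.corrcoef(le, lx)[0, 1] ** 2))

    def test_zero_expected_reported_infinite_and_excluded(self):
        est = AbundanceProfile({"A": 0.9, "B": 0.1})
        exp = AbundanceProfile({"A": 1.0, "B": 0.0})
        rep = deviation_report(est, exp)
        assert math.isinf(rep["per_species"]["B"])
        assert math.isfinite(rep["sum_abs_percent_error"])
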