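import numpy as np
import pytest

from mutspec.calling import GermlinePair, call_mutations
from mutspec.classify import SENSE_CODONS, translate_codon
from mutspec.simulate import (
    SimConfig,
    default_burden_pmf,
    draw_survival,
    fixture_small,
    make_germline,
    mutate_sequence,
    simulate_cohort,
)


class TestMakeGermline:
    def test_shape_and_stop_free(self):
        recs = make_germline(5, 300, seed=1)
        assert len(recs) == 5
        for r in recs:
            assert len(r.nt_sequence) == 300
            codons = [r.nt_sequence[i : i + 3] for i in range(0, 300, 3)]
            assert all(translate_codon(c) != "*" for c in codons)

    def test_reproducible(self):
        a = make_germline(3, 90, seed=7)
        b = make_germline(3, 90, seed=7)
        assert [r.nt_sequence for r in a] == [r.nt_sequence for r in b]

    def test_length_not_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            make_germline(1, 299, seed=0)


class TestMutateSequence:
    def test_zero_mutations_identity(self):
        germ = make_germline(1, 300, seed=2)[0].nt_sequence
        seq, sites = mutate_sequence(germ, 0, np.random.default_rng(0))
        assert seq == germ and sites == []

    def test_roundtrip_through_mutation_calling(self):
        """36 simulated substitutions are recovered exactly by the caller."""
        germ = make_germline(1, 300, seed=2)[0].nt_sequence
        seq, sites = mutate_sequence(germ, 36, np.random.default_rng(1))
        pair = GermlinePair(patient_id="t", aligned_patient=seq, aligned_germline=germ)
        called = call_mutations(pair)
        assert [(s.alignment_pos, s.germline_base, s.observed_base) for s in called] == sites

    def test_too_many_mutations(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGTAC", 7, np.random.default_rng(0))

    def test_transition_fraction(self):
        """2:1:1 weighting gives transition probability 1/2 (binomial check)."""
        germ = make_germline(1, 300, seed=3)[0].nt_sequence
        rng = np.random.default_rng(4)
        n = 10_000
        transitions = 0
        pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for _ in range(n):
            _, ((_, ref, alt),) = mutate_sequence(germ, 1, rng)
            transitions += (ref, alt) in pairs
        sd = np.sqrt(0.5 * 0.5 / n)
        assert abs(transitions / n - 0.5) < 3 * sd

    def test_hotspot_multiplier_enriches_motifs(self):
        germ = "TACTAC" * 50  # C at positions 2 mod 3 inside TAC (WRC) motifs
        rng = np.random.default_rng(5)
        hot = sum(
            mutate_sequence(germ, 1, rng, hotspot_multiplier=20.0)[1][0][1] == "C"
            for _ in range(500)
        )
        cold = sum(
            mutate_sequence(germ, 1, rng, hotspot_multiplier=1.0)[1][0][1] == "C"
            for _ in range(500)
        )
        assert hot > cold

    def test_scr_weight_shifts_composition(self):
        from mutspec.simulate import true_profile

        germ = make_germline(1, 300, seed=6)[0].nt_sequence
        rng = np.random.default_rng(7)

        def scr_frac(w):
            s = rc = tot = 0
            for _ in range(300):
                _, sites = mutate_sequence(germ, 5, rng, scr_weight=w)
                p = true_profile("t", germ, sites)
                s, rc, tot = s + p.n_S, rc + p.n_Rc, tot + p.n_total
            return (s + rc) / tot

        # ~1500 sites per arm: 3 sd of the difference is ~0.05
        assert scr_frac(8.0) > scr_frac(1.0) + 0.05


class TestSimulateCohort:
    def test_zero_mutation_fraction(self):
        sim = simulate_cohort(SimConfig(n_patients=10_000, seed=8))
        frac = (sim.truth["n_mut"] == 0).mean()
        tol = 3 * np.sqrt(0.35 * 0.65 / 10_000)
        assert abs(frac - 0.35) < tol

    def test_burden_support_1_to_36(self, sim300):
        mutated = sim300.truth.loc[sim300.truth.n_mut > 0, "n_mut"]
        assert mutated.min() >= 1 and mutated.max() <= 36

    def test_burden_pmf_normalised(self):
        pmf = default_burden_pmf()
        assert pmf[0] == 0 and pmf.sum() == pytest.approx(1.0)

    def test_reproducible_given_seed(self):
        a = simulate_cohort(SimConfig(n_patients=50, seed=9))
        b = simulate_cohort(SimConfig(n_patients=50, seed=9))
        assert a.truth.equals(b.truth)
        assert [r.nt_sequence for r in a.patient_records] == [
            r.nt_sequence for r in b.patient_records
        ]

    def test_hazard_decreases_with_burden(self):
        """beta_mut < 0: heavily mutated clones are treated later."""
        sim = simulate_cohort(SimConfig(n_patients=4000, seed=10))
        t = sim.truth
        lo = t[(t.n_mut >= 1) & (t.n_mut <= 4) & t.event]["ttft_years"].median()
        hi = t[(t.n_mut >= 16) & t.event]["ttft_years"].median()
        assert hi > lo

    def test_censoring_fraction_reasonable(self, sim300):
        frac = 1 - sim300.truth["event"].mean()
        assert 0.2 < frac < 0.6

    def test_files_roundtrip(self, sim300, tmp_path):
        from mutspec import io as mio

        paths = sim300.write(tmp_path)
        germ = mio.read_fasta(paths["germline"])
        pats = mio.read_airr_rearrangements(paths["rearrangements"])
        clin = mio.read_clinical(paths["clinical"])
        assert len(germ) == sim300.config.n_germline_genes
        assert len(pats) == len(clin) == 300
        assert all(p.is_prealigned for p in pats)


class TestFixtureSmall:
    def test_covers_all_categories(self, fixture_cohort):
        t = fixture_cohort.truth
        cats = set()
        for r in t.itertuples():
            if r.n_mut == 0:
                cats.add("0 Mut")
            elif r.n_Rc + r.n_Rnc == 0:
                cats.add("S only")
            elif r.n_S == 0:
                cats.add("R only")
            else:
                cats.add("S+R")
        assert cats == {"0 Mut", "S only", "R only", "S+R"}

    def test_boundary_ratio_patient(self, fixture_cohort):
        t = fixture_cohort.truth.set_index("patient_id")
        assert t.loc["P04", "ratio"] == pytest.approx(1.0)
        assert t.loc["P04", "group"] == "LOW"
        assert (t.loc["P04", ["n_S", "n_Rc", "n_Rnc"]] == [3, 2, 5]).all()

    def test_contains_stop_mutation(self, fixture_cohort):
        # P05 was engineered with one nonsense substitution
        germ = fixture_cohort.germline_records[0].nt_sequence
        p05 = next(r for r in fixture_cohort.patient_records if r.id == "P05")
        stops = 0
        for i in range(0, 300, 3):
            if translate_codon(p05.nt_sequence[i : i + 3]) == "*":
                stops += 1
        assert stops == 1

    def test_byte_identical_reruns(self, tmp_path):
        a = fixture_small().write(tmp_path / "a")
        b = fixture_small().write(tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()
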