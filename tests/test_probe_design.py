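"""Probe selection, Tm thermodynamics and structure scoring oracles."""

import numpy as np
import pytest

from _oracles import nn_tm_hand, revcomp, structure_brute
from conftest import random_seq
from oligochip.fixtures import FixtureSpec, generate_unigenes
from oligochip.probe_design import (
    MissingReason,
    ProbeConstraints,
    design_all,
    enumerate_candidates,
    gc_content,
    melting_temperature,
    rank_score,
    satisfies_hard_constraints,
    secondary_structure_scores,
    select_probe,
)


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATATAT", 0.0), ("GCGC", 100.0), ("ACGTACGTGG", 60.0)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            gc_content("ACGTN")


class TestMeltingTemperature:
    def test_hand_summed_table(self):
        """The 10-mer value equals a direct dH/dS table summation."""
        assert melting_temperature("AGCGTAAGCT") == pytest.approx(
            nn_tm_hand("AGCGTAAGCT"), abs=1e-9
        )

    @pytest.mark.parametrize("length", [12, 30, 65])
    @pytest.mark.parametrize("na", [25.0, 150.0])
    def test_matches_oracle_on_random_sequences(self, rng, length, na):
        for _ in range(5):
            s = random_seq(rng, length)
            assert melting_temperature(s, na_mM=na) == pytest.approx(
                nn_tm_hand(s, na_mM=na), abs=1e-6
            )

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(10):
            s = random_seq(rng, 40)
            assert melting_temperature(s) == pytest.approx(
                melting_temperature(revcomp(s)), abs=1e-9
            )

    def test_gc_monotonicity(self):
        """Replacing AT pairs by GC pairs never lowers Tm."""
        seq = list("ATATATATGCGCATATATAT")
        tms = []
        for i in (0, 2, 4, 6):
            seq[i] = "G"
            seq[i + 1] = "C"
            tms.append(melting_temperature("".join(seq)))
        assert all(b > a for a, b in zip(tms, tms[1:]))

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")


class TestSecondaryStructure:
    def test_homopolymer_scores_zero(self):
        assert secondary_structure_scores("AAAAAAAAAA") == (0, 0)

    def test_constructed_hairpin(self):
        stem = "GCATTCGA"
        seq = stem + "TTTT" + revcomp(stem)
        stem_score, _ = secondary_structure_scores(seq, min_loop=3)
        assert stem_score == 8

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            s = random_seq(rng, int(rng.integers(10, 40)), gc=0.5)
            assert secondary_structure_scores(s, min_loop=3) == structure_brute(s, 3)

    def test_reverse_complement_invariance(self, rng):
        for _ in range(10):
            s = random_seq(rng, 30, gc=0.5)
            assert secondary_structure_scores(s) == secondary_structure_scores(revcomp(s))


class TestEnumerateCandidates:
    def test_short_unigene_empty(self, rng):
        assert enumerate_candidates("u", random_seq(rng, 40), ProbeConstraints()) == []

    def test_exact_length_unigene(self, rng):
        """A 65 nt unigene admits every window of length 60..65; the
        full-length window is the unique length-65 candidate."""
        cands = enumerate_candidates("u", random_seq(rng, 65), ProbeConstraints())
        expected = sum(65 - length + 1 for length in range(60, 66))
        assert len(cands) == expected
        full = [c for c in cands if c.length == 65]
        assert len(full) == 1
        assert (full[0].start, full[0].dist_3prime) == (0, 0)

    def test_count_matches_direct_enumeration(self, rng):
        seq = random_seq(rng, 200)
        cands = enumerate_candidates("u", seq, ProbeConstraints())
        expected = sum(
            1
            for length in range(60, 71)
            for start in range(0, 200 - length + 1)
        )
        assert len(cands) == expected
        # annotations recomputable
        c = cands[37]
        assert c.sequence == seq[c.start : c.start + c.length]
        assert c.dist_3prime == 200 - (c.start + c.length)
        assert c.gc == pytest.approx(gc_content(c.sequence))

    def test_3prime_window_respected(self, rng):
        seq = random_seq(rng, 1200)
        cands = enumerate_candidates("u", seq, ProbeConstraints())
        assert all(c.dist_3prime <= 1000 for c in cands)
        assert any(c.dist_3prime == 1000 for c in cands)


class TestSelectProbe:
    def test_all_at_unigene_is_missing(self):
        out = select_probe("u", "AT" * 100)
        assert out.probe is None
        assert out.missing_reason is MissingReason.no_window_meets_constraints

    def test_too_short_unigene(self):
        out = select_probe("u", "ACGT" * 10)
        assert out.missing_reason is MissingReason.too_short

    def test_feasible_only_when_window_planted(self, rng):
        """An AT-only unigene is missing; planting one GC-balanced
        window makes the design succeed inside the planted region."""
        c = ProbeConstraints()
        for _ in range(30):
            window = random_seq(rng, 65, gc=0.43)
            stem, dimer = secondary_structure_scores(window)
            if not (
                abs(melting_temperature(window) - 67) <= 3
                and abs(gc_content(window) - 43) <= 5
                and stem <= c.max_stem
                and dimer <= c.max_selfdimer
            ):
                continue
            flank = "AT" * 20
            barren = select_probe("u", flank + "AT" * 33 + flank, c)
            assert barren.probe is None
            out = select_probe("u", flank + window + flank, c)
            assert out.probe is not None
            # any feasible window must draw its GC from the planted one
            assert out.probe.start >= 25 and out.probe.start + out.probe.length <= 115
            assert satisfies_hard_constraints(out.probe, c)
            return
        pytest.fail("no feasible planted window found")

    def test_matches_exhaustive_scoring_oracle(self, rng):
        """Selection equals an independent enumerate-filter-argmin."""
        c = ProbeConstraints()
        seq = random_seq(rng, 400)
        out = select_probe("u", seq, c)
        best = None
        for length in range(60, 71):
            for start in range(0, len(seq) - length + 1):
                if len(seq) - (start + length) > 1000:
                    continue
                w = seq[start : start + length]
                gc = 100.0 * (w.count("G") + w.count("C")) / length
                tm = nn_tm_hand(w)
                stem, dimer = structure_brute(w, 3)
                if abs(tm - 67) > 3 or abs(gc - 43) > 5 or stem > 8 or dimer > 12:
                    continue
                score = abs(tm - 67) + abs(gc - 43) + stem + dimer + 0.001 * (
                    len(seq) - start - length
                )
                key = (score, len(seq) - start - length, start)
                if best is None or key < best[0]:
                    best = (key, start, length)
        if best is None:
            assert out.probe is None
        else:
            assert out.probe is not None
            assert (out.probe.start, out.probe.length) == (best[1], best[2])

    def test_permutation_invariance_and_partition(self, small_spec):
        unigenes, _ = generate_unigenes(small_spec)
        fwd = design_all(unigenes)
        rev = design_all(list(reversed(unigenes)))
        assert {o.unigene_id: (o.probe.sequence if o.probe else None) for o in fwd} == {
            o.unigene_id: (o.probe.sequence if o.probe else None) for o in rev
        }
        designed = [o for o in fwd if o.probe]
        missing = [o for o in fwd if o.probe is None]
        assert len(designed) + len(missing) == len(unigenes)
        assert all(o.missing_reason is not MissingReason.none for o in missing)

    def test_designed_probes_satisfy_all_constraints(self, small_spec):
        c = ProbeConstraints()
        unigenes, _ = generate_unigenes(small_spec)
        outcomes = design_all(unigenes, c)
        assert any(o.probe for o in outcomes)
        for o in outcomes:
            if o.probe is None:
                continue
            p = o.probe
            assert abs(p.tm - 67) <= 3
            assert abs(p.gc - 43) <= 5
            assert 60 <= p.length <= 70
            assert p.dist_3prime <= 1000
            assert p.stem_score <= c.max_stem
            assert p.selfdimer_score <= c.max_selfdimer
            # annotations recomputable from the sequence
            assert p.tm == pytest.approx(melting_temperature(p.sequence))
            assert p.gc == pytest.approx(gc_content(p.sequence))


def test_invalid_constraints_rejected():
    with pytest.raises(ValueError):
        ProbeConstraints(length_target=22, length_tol=5)
    with pytest.raises(ValueError):
        ProbeConstraints(tm_tol=-1)
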