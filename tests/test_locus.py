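import itertools

import numpy as np
import pytest

from venomdyn.locus import (
    HaplotypeArray,
    Locus,
    breakpoint_context,
    compare_haplotypes,
    count_copies,
    detect_tandem_units,
    flag_pseudogene,
    scan_nonb_motifs,
)


def make_array(labels, gap=1700, length=300, pseudo=None):
    pseudo = pseudo or set()
    loci = []
    pos = 0
    for i, lbl in enumerate(labels):
        loci.append(Locus(str(lbl), "+", pos, pos + length, i in pseudo))
        pos += length + gap
    return HaplotypeArray("h", loci)


class TestCountCopies:
    def test_zero_copy_haplotype(self):
        assert count_copies(HaplotypeArray("empty", [])) == 0

    def test_seventeen_with_pseudogenes(self):
        h = make_array(range(17), pseudo={3, 9})
        assert count_copies(h, include_pseudogenes=True) == 17
        assert count_copies(h, include_pseudogenes=False) == 15

    def test_difference_equals_pseudogene_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(0, 12))
            pseudo = {int(i) for i in rng.choice(n, rng.integers(0, n + 1), replace=False)} if n else set()
            h = make_array(range(n), pseudo=pseudo)
            assert count_copies(h, True) - count_copies(h, False) == len(pseudo)


class TestFlagPseudogene:
    def test_premature_stop(self):
        cds = "ATG" + "GCT" * 5 + "TAA" + "GCT" * 30 + "TGA"
        flagged, reason = flag_pseudogene(cds, expected_mature_length=30)
        assert flagged and reason == "premature stop"

    def test_intact_cds(self):
        cds = "ATG" + "GCT" * 40 + "TGA"
        flagged, reason = flag_pseudogene(cds, expected_mature_length=30)
        assert not flagged and reason == "intact"

    def test_truncated_peptide(self):
        cds = "ATG" + "GCT" * 18 + "TGA"  # 60% of expected 30
        flagged, reason = flag_pseudogene(cds, expected_mature_length=30)
        assert flagged and reason == "truncated"

    def test_no_start_codon(self):
        flagged, reason = flag_pseudogene("CCC" * 20, expected_mature_length=10)
        assert flagged and reason == "no ORF"


def brute_force_tandem(labels, gaps, rel_tol=0.2, abs_tol=500.0):
    """Enumerate every (period, start, repeats) decomposition; keep maximal
    non-overlapping ones under the same preference order."""
    n = len(labels)
    cands = []
    for u in range(1, n // 2 + 1):
        for start in range(n - 2 * u + 1):
            m = 2
            while True:
                end = start + m * u
                if end > n:
                    break
                ok = all(
                    labels[start + k] == labels[start + k + u]
                    for k in range((m - 1) * u)
                ) and all(
                    abs(gaps[start + k] - gaps[start + k + u])
                    <= max(rel_tol * max(abs(gaps[start + k]), abs(gaps[start + k + u])), abs_tol)
                    for k in range((m - 1) * u)
                    if start + k + u < len(gaps)
                )
                if ok:
                    cands.append((u, start, m))
                    m += 1
                else:
                    break
    # maximal repeats per (u, start); then the same greedy preference
    best = {}
    for u, start, m in cands:
        key = (u, start)
        best[key] = max(best.get(key, 0), m)
    final = [(u, s, m) for (u, s), m in best.items()]
    final.sort(key=lambda t: (t[0], -(t[2] * t[0]), t[1]))
    chosen, covered = [], set()
    for u, s, m in final:
        rng_ = set(range(s, s + u * m))
        if rng_ & covered:
            continue
        chosen.append((u, s, m))
        covered |= rng_
    return sorted((s, u, m) for u, s, m in chosen)


class TestDetectTandemUnits:
    def test_pure_singlet_repeat(self):
        units = detect_tandem_units(make_array([6, 6, 6, 6]))
        assert [(u.unit, u.repeats) for u in units] == [(("6",), 4)]

    def test_quadruplet_duplication(self):
        units = detect_tandem_units(make_array([8, 6, 1, 6, 8, 6, 1, 6]))
        assert [(u.unit, u.repeats) for u in units] == [(("8", "6", "1", "6"), 2)]

    def test_duplet_duplication(self):
        units = detect_tandem_units(make_array([6, 20, 6, 20]))
        assert [(u.unit, u.repeats) for u in units] == [(("6", "20"), 2)]

    def test_no_unit_in_unrepeated_array(self):
        assert detect_tandem_units(make_array([1, 2, 3])) == []

    def test_inconsistent_gaps_break_run(self):
        loci = [
            Locus("6", "+", 0, 300),
            Locus("6", "+", 2000, 2300),       # gap 1700
            Locus("6", "+", 12000, 12300),     # gap 9700: incompatible
        ]
        units = detect_tandem_units(HaplotypeArray("h", loci))
        assert [(u.unit, u.repeats) for u in units] == [(("6",), 2)]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(150):
            n = int(rng.integers(2, 11))
            labels = [str(c) for c in rng.choice(list("abc"), n)]
            h = make_array(labels)
            got = sorted(
                (u.start_index, len(u.unit), u.repeats) for u in detect_tandem_units(h)
            )
            assert got == brute_force_tandem(tuple(labels), h.gaps)


class TestCompareHaplotypes:
    def test_identity_zero_events(self):
        assert compare_haplotypes(("6", "1"), ("6", "1"))[0] == 0

    def test_single_duplication(self):
        count, script = compare_haplotypes(("6",), ("6", "6"))
        assert count == 1 and "duplicate" in script[0]

    def test_quadruplet_duplication_one_event(self):
        count, _ = compare_haplotypes(
            ("8", "6", "1", "6"), ("8", "6", "1", "6", "8", "6", "1", "6")
        )
        assert count == 1

    def test_full_deletion_to_zero_copy(self):
        count, script = compare_haplotypes(("6", "6", "1"), ())
        assert count == 1 and "delete" in script[0]

    def test_single_event_symmetric(self):
        # one tandem duplication is exactly undone by one block deletion
        rng = np.random.default_rng(2)
        for _ in range(60):
            base = tuple(str(c) for c in rng.choice(list("ab"), rng.integers(1, 6)))
            i = int(rng.integers(0, len(base)))
            j = int(rng.integers(i + 1, len(base) + 1))
            other = base[:j] + base[i:j] + base[j:]
            if other == base:
                continue
            assert compare_haplotypes(base, other, max_events=2)[0] == 1
            assert compare_haplotypes(other, base, max_events=2)[0] == 1

    def test_deletion_can_shortcut_nested_duplications(self):
        # expanding ('a',) to ('a','a','a','a') needs two doublings, while
        # one block deletion contracts it back: the event count is
        # direction-dependent under free block deletion
        fwd = compare_haplotypes(("a",), ("a", "a", "a", "a"), max_events=3)[0]
        rev = compare_haplotypes(("a", "a", "a", "a"), ("a",), max_events=3)[0]
        assert fwd == 2 and rev == 1


class TestNonBMotifs:
    def test_worked_inverted_repeat(self):
        hits = scan_nonb_motifs("ACGTACTTTTGTACGT")
        ir = [h for h in hits if h.kind == "inverted_repeat"]
        assert len(ir) == 1
        assert ir[0].interval == (0, 6) and ir[0].partner == (10, 16)

    def test_poly_g_run(self):
        hits = scan_nonb_motifs("AAAA" + "G" * 10 + "AAAA")
        runs = [h for h in hits if h.kind == "polyG"]
        assert len(runs) == 1 and runs[0].interval == (4, 14)

    def test_short_runs_ignored(self):
        assert scan_nonb_motifs("AAAA" + "G" * 7 + "AAAA") == []

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(8)
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 300))
            fwd = scan_nonb_motifs(seq, min_arm=5, max_loop=50, min_g_run=6)
            rev = scan_nonb_motifs(seq.translate(comp)[::-1], min_arm=5, max_loop=50, min_g_run=6)
            n = len(seq)

            def mirror(h):
                spans = [(n - h.end, n - h.start)]
                if h.partner:
                    spans.append((n - h.partner[1], n - h.partner[0]))
                return tuple(sorted(spans))

            fwd_spans = {mirror(h) for h in fwd}
            rev_spans = {
                tuple(sorted([(h.start, h.end)] + ([h.partner] if h.partner else [])))
                for h in rev
            }
            assert fwd_spans == rev_spans


class TestBreakpointContext:
    def test_breakpoint_inside_motif(self):
        hits = scan_nonb_motifs("AAAA" + "G" * 10 + "AAAA")
        ctx = breakpoint_context([8], hits, seq_length=18, window=500)
        assert ctx[8][0][1] == 0

    def test_signed_distance_left_of_breakpoint(self):
        seq = "A" * 100 + "G" * 10 + "A" * 1000
        hits = scan_nonb_motifs(seq)
        bp = 110 - 1 + 356  # motif's last base 356 bp left of the breakpoint
        ctx = breakpoint_context([bp], hits, seq_length=len(seq), window=500)
        assert ctx[bp][0][1] == -356

    def test_empty_when_no_motifs_near(self):
        seq = "A" * 2000 + "G" * 10 + "A" * 100
        hits = scan_nonb_motifs(seq)
        ctx = breakpoint_context([100], hits, seq_length=len(seq), window=500)
        assert ctx[100] == []

    def test_out_of_bounds_raises(self):
        from venomdyn.errors import VenomdynError

        with pytest.raises(VenomdynError):
            breakpoint_context([99], [], seq_length=50)
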