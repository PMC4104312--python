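import random

import pytest

from pin_architect.motifs import (
    MotifDef, ScanThresholds, default_motif_library, detect_repeats,
    motif_matrix, read_motif_library, repeat_unit, scan_loop,
    write_motif_library, _best_assignment, _window_scores,
)
from pin_architect.seqio import CladeMap


def _instantiate(pattern):
    out = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            out.append(pattern[i + 1])
            i = j + 1
        elif pattern[i] == "X":
            out.append("A")
            i += 1
        else:
            out.append(pattern[i])
            i += 1
    return "".join(out)


def brute_force_assignment(loop, library):
    """Exhaustive order-respecting assignment maximizing total identity.

    Enumerates every subset of motifs and every non-overlapping increasing
    window placement; the independent oracle for the scanner's DP.
    """
    n = len(library)
    cols = [m.columns() for m in library]
    lens = [len(c) for c in cols]
    best = 0.0

    def rec(i, pos, score):
        nonlocal best
        best = max(best, score)
        if i == n:
            return
        rec(i + 1, pos, score)  # skip motif i
        for s in range(pos, len(loop) - lens[i] + 1):
            ident, _ = _window_scores(loop, cols[i], s)
            rec(i + 1, s + lens[i], score + ident)

    rec(0, 0, 0.0)
    return best


class TestScanLoop:
    def test_planted_library_all_present_in_order(self):
        library = default_motif_library()
        loop = "GG".join(_instantiate(m.pattern) for m in library)
        hits = scan_loop(loop, library)
        assert all(h.state == "present" for h in hits)
        starts = [h.start for h in hits]
        ends = [h.end for h in hits]
        assert starts == sorted(starts)
        assert all(e <= s for s, e in zip(starts[1:], ends[:-1]))

    def test_wildcard_and_alternative_columns(self):
        lib = [MotifDef("tpr", "TPRXS[SN]", rank=1, phospho=True)]
        hits = scan_loop("GGGGTPRASSGGGG", lib)
        assert hits[0].state == "present"
        assert hits[0].identity == pytest.approx(1.0)  # X column excluded
        # the [SN] alternative accepts N as well
        assert scan_loop("GGGGTPRKSNGGGG", lib)[0].identity == pytest.approx(1.0)

    def test_empty_library_is_error(self):
        with pytest.raises(ValueError):
            scan_loop("GGGG", [])

    def test_unordered_library_is_error(self):
        lib = [MotifDef("a", "AAAA", rank=2), MotifDef("b", "CCCC", rank=1)]
        with pytest.raises(ValueError, match="rank"):
            scan_loop("GGGG", lib)

    def test_missing_loop_gives_no_data(self):
        lib = [MotifDef("a", "AAAA", rank=1)]
        assert scan_loop(None, lib)[0].state == "no_data"

    def test_equals_exhaustive_assignment_oracle(self):
        rng = random.Random(9)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        lib = [MotifDef("a", "DERK", rank=1), MotifDef("b", "KLMN", rank=2),
               MotifDef("c", "QRST", rank=3)]
        for _ in range(25):
            n = rng.randint(12, 60)
            loop = "".join(rng.choice(alphabet) for _ in range(n))
            if rng.random() < 0.5:  # plant fragments
                for m in lib:
                    pos = rng.randint(0, n - 4)
                    loop = loop[:pos] + _instantiate(m.pattern) + loop[pos + 4:]
            score, starts = _best_assignment(loop, lib)
            oracle = brute_force_assignment(loop, lib)
            assert score == pytest.approx(oracle)
            # returned windows are valid and achieve the optimal score
            placed = [(s, s + len(m)) for m, s in zip(lib, starts) if s is not None]
            assert placed == sorted(placed)
            assert all(e1 <= s2 for (_, e1), (s2, _) in zip(placed, placed[1:]))
            total = sum(_window_scores(loop, m.columns(), s)[0]
                        for m, s in zip(lib, starts) if s is not None)
            assert total == pytest.approx(oracle)

    def test_partial_state_at_truncated_edge(self):
        lib = [MotifDef("a", "DDEEKKRR", rank=1), MotifDef("b", "WWYYFFHH", rank=2)]
        # right half of motif a hangs off the (truncated) left edge
        loop = "KKRR" + "G" * 10 + "WWYYFFHH" + "G" * 4
        hits = scan_loop(loop, lib, complete_left=False)
        assert hits[0].state == "partial"
        assert hits[1].state == "present"

    def test_no_data_beyond_truncated_edge(self):
        lib = [MotifDef("a", "DDEEKKRR", rank=1), MotifDef("b", "WWYYFFHH", rank=2)]
        # motif a entirely lost to the left truncation
        loop = "GGG" + "WWYYFFHH" + "GGGG"
        hits = scan_loop(loop, lib, complete_left=False)
        assert hits[0].state == "no_data"
        assert hits[1].state == "present"

    def test_absent_when_loop_fully_observed(self):
        lib = [MotifDef("a", "DDEEKKRR", rank=1), MotifDef("b", "WWYYFFHH", rank=2)]
        loop = "GGG" + "WWYYFFHH" + "GGGG"
        hits = scan_loop(loop, lib)
        assert hits[0].state == "absent"

    def test_shuffling_never_increases_present_count(self):
        """Destroying the signal cannot make motifs more detectable on average."""
        rng = random.Random(4)
        library = default_motif_library()[:5]
        loop = "GG".join(_instantiate(m.pattern) for m in library)
        baseline = sum(h.state == "present" for h in scan_loop(loop, library))
        totals = 0
        n_shuffles = 40
        for _ in range(n_shuffles):
            chars = list(loop)
            rng.shuffle(chars)
            totals += sum(h.state == "present"
                          for h in scan_loop("".join(chars), library))
        assert totals / n_shuffles <= baseline


class TestDetectRepeats:
    def test_four_planted_copies(self):
        library = default_motif_library()
        unit = repeat_unit(library)
        block = "".join(_instantiate(m.pattern) + "GG" for m in unit)
        loop = "DDDD" + block * 4 + "DDDD"
        count, spans, partial = detect_repeats(loop, unit)
        assert count == 4
        assert len(spans) == 4 and partial is None

    def test_no_occurrence(self):
        unit = repeat_unit(default_motif_library())
        count, spans, partial = detect_repeats("G" * 60, unit)
        assert count == 0 and spans == [] and partial is None

    def test_two_full_and_a_half(self):
        library = default_motif_library()
        unit = repeat_unit(library)
        block = "".join(_instantiate(m.pattern) + "GG" for m in unit)
        half = _instantiate(unit[0].pattern)  # only the first unit motif
        loop = block * 2 + half + "DDDDDDDDDDDDDDDDDDDD"
        count, spans, partial = detect_repeats(loop, unit)
        assert count == 2
        assert partial is not None
        assert partial[0] >= spans[-1][1]

    def test_max_copies_cap(self):
        library = default_motif_library()
        unit = repeat_unit(library)
        block = "".join(_instantiate(m.pattern) + "GG" for m in unit)
        count, _, _ = detect_repeats(block * 6, unit, max_copies=4)
        assert count == 4


class TestMotifMatrix:
    def _clade_map(self, assignments):
        return CladeMap(sequence_to_clade=assignments,
                        clade_to_lineage={c: "other" for c in set(assignments.values())})

    def _scan_with_states(self, states):
        from pin_architect.motifs import MotifHit
        return [MotifHit("m", 0, 4, 1.0, 1.0, s) for s in states]

    def test_unanimous_clade(self):
        scans = {f"s{i}": self._scan_with_states(["present"]) for i in range(5)}
        mat = motif_matrix(scans, self._clade_map({f"s{i}": "A" for i in range(5)}))
        assert mat.loc["A", "m"] == "present"

    def test_no_majority_gives_no_consensus(self):
        states = [["present"], ["present"], ["absent"], ["divergent"]]
        scans = {f"s{i}": self._scan_with_states(st) for i, st in enumerate(states)}
        mat = motif_matrix(scans, self._clade_map({f"s{i}": "A" for i in range(4)}))
        assert mat.loc["A", "m"] == "no_consensus"

    def test_no_data_members_excluded_from_majority(self):
        states = [["no_data"], ["no_data"], ["present"], ["present"], ["absent"]]
        scans = {f"s{i}": self._scan_with_states(st) for i, st in enumerate(states)}
        mat = motif_matrix(scans, self._clade_map({f"s{i}": "A" for i in range(5)}))
        assert mat.loc["A", "m"] == "present"

    def test_all_no_data(self):
        scans = {f"s{i}": self._scan_with_states(["no_data"]) for i in range(3)}
        mat = motif_matrix(scans, self._clade_map({f"s{i}": "A" for i in range(3)}))
        assert mat.loc["A", "m"] == "no_data"

    def test_unmapped_sequence_warns_and_is_excluded(self):
        scans = {"s0": self._scan_with_states(["present"]),
                 "orphan": self._scan_with_states(["absent"])}
        cm = self._clade_map({"s0": "A"})
        with pytest.warns(UserWarning, match="orphan"):
            mat = motif_matrix(scans, cm)
        assert mat.loc["A", "m"] == "present"

    def test_planted_retention_recovered(self, family_default, partitions_default):
        """Clade-level matrix matches the planted loss pattern at >= 95% of cells
        (states collapsed to present vs not-present)."""
        fam = family_default
        scans = {}
        for rec in fam.records:
            p = partitions_default[rec.id]
            scans[rec.id] = scan_loop(p.loop, fam.motif_library,
                                      complete_left=p.loop_complete_left,
                                      complete_right=p.loop_complete_right)
        mat = motif_matrix(scans, fam.clade_map)
        agree = total = 0
        for clade in mat.index:
            for m in mat.columns:
                total += 1
                planted = bool(fam.retention.loc[clade, m])
                agree += (mat.loc[clade, m] == "present") == planted
        assert agree / total >= 0.95


def test_library_round_trip(tmp_path):
    lib = default_motif_library()
    path = tmp_path / "lib.tsv"
    write_motif_library(lib, path)
    assert read_motif_library(path) == lib


def test_motif_pattern_validation():
    with pytest.raises(ValueError, match="shorter"):
        MotifDef("x", "AB[CD]", rank=1)
    with pytest.raises(ValueError, match="hc_group"):
        MotifDef("x", "AAAA", rank=1, hc_group="HC9")
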