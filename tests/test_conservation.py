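import numpy as np
import pytest

from pin_architect.conservation import (
    TABLE2_BANDS, TABLE3_BANDS, alignment_stats, band_counts, build_profile,
    consensus, conserved_positions, cross_conservation,
)
from pin_architect.domains import delineate
from pin_architect.seqio import AlignmentMatrix, SequenceRecord


def _partition(seq, **kwargs):
    return delineate(SequenceRecord(id=kwargs.pop("id", "s"), residues=seq, **kwargs))


class TestBuildProfile:
    def test_single_sequence_full_identity(self, family_complete):
        tmpl = family_complete.template
        part = _partition(tmpl["n_domain"] + tmpl["loop"] + tmpl["c_domain"])
        prof = build_profile([part], "n_domain")
        covered = prof.coverage > 0
        assert covered.all()
        assert np.allclose(prof.modal_identity[covered], 1.0)

    def test_two_sequences_one_difference(self, family_complete):
        tmpl = family_complete.template
        seq1 = tmpl["n_domain"] + tmpl["loop"] + tmpl["c_domain"]
        # change N20 (index 19) to a different residue
        n2 = tmpl["n_domain"][:19] + ("G" if tmpl["n_domain"][19] != "G" else "D") \
            + tmpl["n_domain"][20:]
        seq2 = n2 + tmpl["loop"] + tmpl["c_domain"]
        prof = build_profile(
            [_partition(seq1, id="a"), _partition(seq2, id="b")], "n_domain")
        idx = prof.position_index()
        assert prof.modal_identity[idx["N20"]] == pytest.approx(0.5)
        others = [i for lab, i in idx.items() if lab != "N20"]
        assert np.allclose(prof.modal_identity[others], 1.0)

    def test_insertions_excluded_from_canonical_positions(self, family_complete):
        tmpl = family_complete.template
        n_ins = tmpl["n_domain"][:97] + "D" * 5 + tmpl["n_domain"][97:]
        part = _partition(n_ins + tmpl["loop"] + tmpl["c_domain"])
        prof = build_profile([part], "n_domain")
        assert len(prof.labels) == 158
        assert prof.coverage.sum() == 158  # the 5 insertion residues not counted

    def test_absent_region_is_error(self):
        part = _partition("G" * 200)  # no anchors at all
        with pytest.raises(ValueError, match="no observations"):
            build_profile([part], "n_domain")

    def test_frequencies_sum_to_one_where_covered(self, partitions_default):
        prof = build_profile(list(partitions_default.values()), "tm")
        covered = prof.coverage > 0
        assert np.allclose(prof.frequencies[covered].sum(axis=1), 1.0)

    def test_band_mean_identity_recovers_generator_truth(self, family_default,
                                                         partitions_default):
        """Mean modal identity per planted band within +-0.03 of 1 - rate."""
        truth = family_default.members.set_index("id")
        can = [partitions_default[r.id] for r in family_default.records
               if truth.loc[r.id, "label"] == "canonical"]
        prof = build_profile(can, "tm")
        idx = prof.position_index()
        rate = {b.label: b.sub_prob for b in family_default.config.bands}
        for band, r in rate.items():
            labs = [lab for lab, b in family_default.band_of_position.items()
                    if b == band and prof.coverage[idx[lab]] >= 10]
            assert len(labs) > 10
            mean = float(np.mean([prof.modal_identity[idx[lab]] for lab in labs]))
            assert mean == pytest.approx(1.0 - r, abs=0.03)


class TestConsensus:
    def test_identical_family_returns_the_sequence(self, family_complete):
        tmpl = family_complete.template
        parts = [_partition(tmpl["n_domain"] + tmpl["loop"] + tmpl["c_domain"],
                            id=f"s{i}") for i in range(3)]
        prof = build_profile(parts, "c_domain")
        assert consensus(prof, floor=0.5) == tmpl["c_domain"]

    def test_floor_threshold_edge(self):
        # 49 of 100 sequences share the modal residue at one position
        prof_parts = []
        base = "G" * 150 + "FLFEFRAAR"
        for i in range(100):
            res = "A" if i < 49 else ("D" if i % 2 else "E")
            seq = base[:10] + res + base[11:]
            prof_parts.append(_partition(seq, id=f"s{i}"))
        prof = build_profile(prof_parts, "n_domain")
        cons = consensus(prof, floor=0.5)
        assert cons[10] == "."

    def test_generator_consensus_matches_template_at_high_bands(
            self, family_default, partitions_default):
        truth = family_default.members.set_index("id")
        can = [partitions_default[r.id] for r in family_default.records
               if truth.loc[r.id, "label"] == "canonical"]
        prof = build_profile(can, "n_domain")
        cons = consensus(prof, floor=0.5)
        tmpl = family_default.template["n_domain"]
        idx = prof.position_index()
        for lab, band in family_default.band_of_position.items():
            if not lab.startswith("N") or band not in ("100%", ">99%", ">95%"):
                continue
            i = idx[lab]
            if prof.coverage[i] >= 10:
                assert cons[i] == tmpl[i]


class TestBandCounts:
    def test_total_positions_312(self, partitions_default):
        prof = build_profile(list(partitions_default.values()), "tm")
        counts, excluded = band_counts(prof, TABLE3_BANDS)
        assert sum(counts.values()) + excluded == 312

    def test_all_identical_family_in_100_band(self, family_complete):
        tmpl = family_complete.template
        parts = [_partition(tmpl["n_domain"] + tmpl["loop"] + tmpl["c_domain"],
                            id=f"s{i}") for i in range(5)]
        prof = build_profile(parts, "tm")
        counts, excluded = band_counts(prof, TABLE3_BANDS)
        assert counts["100%"] == 312 and excluded == 0

    def test_hand_planted_counts(self, family_complete):
        """10-sequence toy family with hand-planted substitution counts."""
        tmpl = family_complete.template
        base = tmpl["n_domain"] + tmpl["loop"] + tmpl["c_domain"]
        # plant: N10 differs in 1/10 (90%), N20 in 3/10 (70%), N30 in 6/10 (40%)
        plan = {9: 1, 19: 3, 29: 6}
        spares = "GDEKNQRST"
        seqs = []
        for i in range(10):
            s = list(base)
            for pos, k in plan.items():
                if i < k:
                    # distinct replacements so the original stays modal
                    s[pos] = next(x for x in spares if x != base[pos])[0]
                    s[pos] = [x for x in spares if x != base[pos]][i]
            seqs.append("".join(s))
        prof = build_profile([_partition(s, id=f"s{i}") for i, s in enumerate(seqs)],
                             "n_domain")
        counts, excluded = band_counts(prof, TABLE3_BANDS)
        # hand tally with lower-open bands: 0.9 -> 70-90%, 0.7 -> 50-70%,
        # 0.4 -> <50%; everything else invariant
        assert excluded == 0
        assert counts == {"100%": 155, "95-99%": 0, "90-95%": 0,
                          "70-90%": 1, "50-70%": 1, "<50%": 1}

    def test_low_coverage_positions_reported_separately(self, family_complete):
        tmpl = family_complete.template
        # one full sequence plus one N-truncated fragment
        full = _partition(tmpl["n_domain"] + tmpl["loop"] + tmpl["c_domain"], id="a")
        frag = _partition(tmpl["n_domain"][100:] + tmpl["loop"] + tmpl["c_domain"],
                          id="b", n_complete=False)
        prof = build_profile([full, frag], "n_domain")
        counts, excluded = band_counts(prof, TABLE2_BANDS, min_coverage=2)
        assert excluded == 100
        assert sum(counts.values()) == 58


class TestCrossConservation:
    def test_identity_case(self, partitions_default, family_default):
        truth = family_default.members.set_index("id")
        can = [partitions_default[r.id] for r in family_default.records
               if truth.loc[r.id, "label"] == "canonical"]
        prof = build_profile(can, "tm")
        reference = conserved_positions(prof, TABLE2_BANDS, min_coverage=10)
        counts = cross_conservation(reference, prof, min_coverage=10)
        for band, posset in reference.items():
            assert counts[band] == len(posset)

    def test_all_below_threshold_gives_zero(self, family_complete):
        tmpl = family_complete.template
        base = tmpl["n_domain"] + tmpl["loop"] + tmpl["c_domain"]
        ref = {"100%": {"N5", "N6", "C10"}}
        # query family variable at exactly those positions (2 of 4 share residue)
        seqs = []
        for i in range(4):
            s = list(base)
            for pos in (4, 5):
                s[pos] = "DEKG"[i]
            s[158 + len(tmpl["loop"]) + 9] = "DEKG"[i]
            seqs.append("".join(s))
        prof = build_profile([_partition(s, id=f"s{i}") for i, s in enumerate(seqs)],
                             "tm")
        assert cross_conservation(ref, prof, threshold=0.90) == {"100%": 0}

    def test_planted_overlap(self, family_complete):
        tmpl = family_complete.template
        base = tmpl["n_domain"] + tmpl["loop"] + tmpl["c_domain"]
        planted = {"N3", "N7", "C50"}   # stay invariant in the query
        broken = {"N12", "C30"}          # made variable in the query
        pos_of = {f"N{i}": i - 1 for i in range(1, 159)}
        pos_of.update({f"C{i}": 158 + len(tmpl["loop"]) + i - 1 for i in range(1, 155)})
        seqs = []
        for i in range(10):
            s = list(base)
            for lab in broken:
                s[pos_of[lab]] = "DEKGNQRST"[i % 9]
            seqs.append("".join(s))
        prof = build_profile([_partition(s, id=f"s{i}") for i, s in enumerate(seqs)],
                             "tm")
        n = cross_conservation(planted | broken, prof, threshold=0.90)
        assert n == len(planted)

    def test_coordinate_mismatch_is_error(self, family_complete):
        tmpl = family_complete.template
        part = _partition(tmpl["n_domain"] + tmpl["loop"] + tmpl["c_domain"])
        prof = build_profile([part], "n_domain")
        with pytest.raises(ValueError, match="coordinate mismatch"):
            cross_conservation({"C5"}, prof)


class TestAlignmentStats:
    def test_single_state_column_not_informative(self):
        aln = AlignmentMatrix(rows=[(f"s{i}", "A") for i in range(4)])
        assert alignment_stats(aln)["parsimony_informative"] == 0

    def test_matches_per_column_definition_on_random_matrix(self):
        rng = np.random.default_rng(5)
        cells = rng.choice(list("ACD-?"), size=(6, 8), p=[0.3, 0.25, 0.15, 0.15, 0.15])
        aln = AlignmentMatrix(rows=[(f"s{i}", "".join(r)) for i, r in enumerate(cells)])
        stats = alignment_stats(aln)
        informative = 0
        for j in range(8):
            col = [cells[i][j] for i in range(6) if cells[i][j] not in "-?"]
            n_multi = sum(1 for state in set(col) if col.count(state) >= 2)
            informative += n_multi >= 2
        assert stats["parsimony_informative"] == informative
        missing = sum(cells[i][j] in "-?" for i in range(6) for j in range(8))
        assert stats["missing_fraction"] == pytest.approx(missing / 48)

    def test_all_missing(self):
        aln = AlignmentMatrix(rows=[("a", "--??"), ("b", "????")])
        stats = alignment_stats(aln)
        assert stats["missing_fraction"] == 1.0
        assert stats["parsimony_informative"] == 0


def test_planted_invariants_in_100_band(family_default, partitions_default):
    """The planted invariant tyrosine at C123 (and the anchors) land in the
    100% band of the canonical family profile."""
    truth = family_default.members.set_index("id")
    can = [partitions_default[r.id] for r in family_default.records
           if truth.loc[r.id, "label"] == "canonical"]
    prof = build_profile(can, "tm")
    idx = prof.position_index()
    assert prof.modal_residue[idx["C123"]] == "Y"
    for lab in ["C123", "N158", "C1", "C8"]:
        assert prof.modal_identity[idx[lab]] == pytest.approx(1.0)
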