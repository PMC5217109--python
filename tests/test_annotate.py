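"""Microhomology calls, template search, primer identity."""

import numpy as np
import pytest

from dsbfoot.annotate import (
    annotate_all,
    annotate_microhomology,
    find_template,
    primer_identity,
)
from dsbfoot.caller import call_footprint, dedupe
from dsbfoot.locus import revcomp
from dsbfoot.simulate import config_from_preset, generate_dataset


class TestMicrohomology:
    def test_repeat_flanked_deletion(self):
        fp = call_footprint("TTTCAGCAGTTT", "TTTCAGTTT")
        mh = annotate_microhomology(fp, "TTTCAGCAGTTT")
        assert mh.length == 3 and mh.sequence == "CAG"
        assert mh.placements == (3, 6)

    def test_unique_placement_deletion_has_no_microhomology(self):
        fp = call_footprint("AAACCCGGGTTT", "AAAGGGTTT")
        mh = annotate_microhomology(fp, "AAACCCGGGTTT")
        assert mh.length == 0 and mh.sequence == ""

    def test_intact_footprint_reports_zero(self):
        fp = call_footprint("AAACCCGGGTTT", "AAACCCGGGTTT")
        assert annotate_microhomology(fp, "AAACCCGGGTTT").length == 0

    def test_length_equals_placement_count_minus_one_on_random_cases(self):
        from dsbfoot.caller import enumerate_placements

        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            n = int(rng.integers(20, 50))
            ref = "".join(bases[rng.integers(0, 4, n)])
            L = int(rng.integers(1, 8))
            s = int(rng.integers(0, n - L + 1))
            read = ref[:s] + ref[s + L :]
            fp = call_footprint(ref, read, min_anchor=0)
            if fp.event_class != "deletion":
                continue
            mh = annotate_microhomology(fp, ref)
            placements = enumerate_placements(ref, fp.del_len, "", read)
            assert mh.length == len(placements) - 1


class TestFindTemplate:
    def test_planted_direct_copy_is_perfect(self, cru_locus):
        cut = cru_locus.cut_pos
        word = cru_locus.amplicon[cut - 12 : cut - 4]
        tm = find_template(word, cru_locus)
        assert tm.category == "perfect"
        assert tm.coverage == 1.0
        assert len(tm.segments) == 1 and tm.segments[0].orientation == "direct"

    def test_planted_reverse_complement_copy(self, cru_locus):
        cut = cru_locus.cut_pos
        word = cru_locus.amplicon[cut - 12 : cut - 4]
        tm = find_template(revcomp(word), cru_locus)
        # unless the inverted word happens to also occur directly, the
        # category must be reverse with full coverage
        assert tm.category == "reverse" and tm.coverage == 1.0

    def test_short_insertion_not_searched(self, cru_locus):
        tm = find_template("TT", cru_locus, min_search_len=3)
        assert tm.category == "none" and tm.coverage == 0.0 and not tm.searched

    def test_orientation_consistency_on_planted_words(self, cru_locus):
        rng = np.random.default_rng(3)
        cut = cru_locus.cut_pos
        n_checked = 0
        for _ in range(50):
            ln = int(rng.integers(8, 16))
            start = int(rng.integers(cut - 90, cut + 90 - ln))
            word = cru_locus.amplicon[start : start + ln]
            fwd = find_template(word, cru_locus)
            rev = find_template(revcomp(word), cru_locus)
            if fwd.category == "perfect" and rev.category == "reverse":
                n_checked += 1
                assert fwd.segments[0].ref_pos == rev.segments[0].ref_pos
        assert n_checked > 30  # palindromic/double-occurring words are rare

    def test_coverage_monotone_in_min_seed(self, cru_locus):
        rng = np.random.default_rng(5)
        cut = cru_locus.cut_pos
        for _ in range(20):
            # chimeric insertion: two window pieces + random tail
            a = cru_locus.amplicon[cut - 30 : cut - 24]
            b = cru_locus.amplicon[cut + 10 : cut + 15]
            tail = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4)])
            ins = a + tail + b
            covs = [
                find_template(ins, cru_locus, min_seed=ms).coverage for ms in (4, 5, 6, 8)
            ]
            assert all(c1 >= c2 for c1, c2 in zip(covs, covs[1:]))


class TestPrimerIdentity:
    # flank = ref[:7] = AAAGATC; GGGG block at 11-14
    REF = "AAA" + "GATC" + "AAAA" + "GGGG" + "TTTT"

    def _fp(self):
        from dsbfoot.caller import Footprint

        return Footprint("insertion", 7, 7, "GGGG", 7, 7, 0)

    def test_planted_upstream_identity(self):
        from dsbfoot.annotate import Segment, TemplateMatch

        # template at 7: its upstream 4-mer is GATC, identical to the
        # flank 3' end (and the run of As extends the identity further)
        tm = TemplateMatch("x", "perfect", (Segment(0, 4, 7, "direct"),), 1.0)
        n, primed = primer_identity(tm, self._fp(), self.REF)
        assert n >= 4 and primed

    def test_no_upstream_identity(self):
        from dsbfoot.annotate import Segment, TemplateMatch

        # template at 11 (GGGG): upstream AAAA mismatches the flank end ...GATC
        tm = TemplateMatch("x", "perfect", (Segment(0, 4, 11, "direct"),), 1.0)
        n, primed = primer_identity(tm, self._fp(), self.REF)
        assert n == 0 and not primed

    def test_category_none_gives_zero(self):
        from dsbfoot.annotate import TemplateMatch

        tm = TemplateMatch("x", "none", (), 0.0)
        assert primer_identity(tm, self._fp(), self.REF) == (0, False)


class TestAnnotateAll:
    def test_event_set_without_insertions(self, cru_locus):
        cfg = config_from_preset(cru_locus, "WT", "Cas9-CRU", 60, seed=9)
        cfg.class_weights = {
            "intact": 0.0,
            "small_indel": 0.0,
            "mmej_deletion": 1.0,
            "templated_insertion": 0.0,
        }
        reads, _ = generate_dataset(cfg)
        events = dedupe(
            [call_footprint(cru_locus.amplicon, r) for r in reads]
        )
        annotations, summary = annotate_all(events, cru_locus)
        assert summary.n_insertions.sum() == 0
        assert summary.n_templated.sum() == 0

    def test_planted_templated_vs_verified_random_insertions(self, cru_locus):
        ref = cru_locus.amplicon
        cut = cru_locus.cut_pos
        rng = np.random.default_rng(11)
        reads = []
        # 10 templated: copies of window 10-mers; 5 random absent 12-mers
        planted = 0
        while planted < 10:
            start = int(rng.integers(cut - 80, cut + 70))
            word = ref[start : start + 10]
            if word[0] == ref[cut] or word[-1] == ref[cut - 1]:
                continue  # keep the planted junction canonical
            reads.append(ref[:cut] + word + ref[cut:])
            planted += 1
        bases = np.array(list("ACGT"))
        lo, hi = cut - 100, cut + 100
        win = ref[max(0, lo) : hi]

        def truly_absent(word: str) -> bool:
            # no substring of seed length or longer occurs in the window in
            # either orientation, so no partial match can be found either
            for k in range(4, len(word) + 1):
                for off in range(len(word) - k + 1):
                    sub = word[off : off + k]
                    if sub in win or revcomp(sub) in win:
                        return False
            return True

        added = 0
        for _ in range(20000):
            if added == 5:
                break
            word = "".join(bases[rng.integers(0, 4, 5)])
            if not truly_absent(word):
                continue
            if word[0] == ref[cut] or word[-1] == ref[cut - 1]:
                continue
            reads.append(ref[:cut] + word + ref[cut:])
            added += 1
        assert added == 5
        from dsbfoot.caller import CloneRead

        clones = [
            CloneRead(f"c{i}", f"L{i}", "WT", "Cas9-CRU", s) for i, s in enumerate(reads)
        ]
        events = dedupe([call_footprint(ref, c) for c in clones])
        _, summary = annotate_all(events, cru_locus)
        assert int(summary.n_insertions.sum()) == 15
        assert int(summary.n_templated.sum()) == 10
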