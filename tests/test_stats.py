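"""Length binning, Mann-Whitney U behavior, genotype contrasts."""

import itertools

import numpy as np
import pytest

from dsbfoot.caller import EventSet, Footprint
from dsbfoot.stats import (
    bin_deletions,
    compare_genotypes,
    deletion_with_without_insertion,
    mwu_two_tailed,
    resistant_fraction,
)


class TestBinDeletions:
    def test_one_per_bin(self):
        d = bin_deletions([5, 10, 25, 50])
        assert d.counts == (1, 1, 1, 1)
        assert d.fractions == (0.25, 0.25, 0.25, 0.25)

    def test_upper_edges_inclusive(self):
        assert bin_deletions([9, 19, 49]).counts == (1, 1, 1, 0)

    def test_intact_length_rejected(self):
        with pytest.raises(ValueError):
            bin_deletions([5, 0])

    def test_fractions_sum_to_one_and_binning_is_exhaustive(self):
        rng = np.random.default_rng(2)
        lens = rng.integers(1, 200, size=500)
        d = bin_deletions(list(lens))
        assert sum(d.counts) == 500
        assert abs(sum(d.fractions) - 1) < 1e-12

    def test_fractions_reflect_known_composition(self):
        # 1,000 lengths with a fixed composition recover it exactly
        lens = [5] * 570 + [12] * 230 + [30] * 150 + [60] * 50
        d = bin_deletions(lens)
        assert d.fractions == (0.57, 0.23, 0.15, 0.05)


def _enumeration_p(x, y):
    """Independent exact oracle: all C(n1+n2, n1) group labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(a > b for a in x for b in y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in comb]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in set(comb)]
        us.append(sum(a > b for a in g1 for b in g2))
    us = np.asarray(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestMWU:
    def test_extreme_small_sample(self):
        r = mwu_two_tailed([1, 2], [3, 4])
        assert r.U == 0 and r.method == "exact"
        assert abs(r.p_two_tailed - 1 / 3) < 5e-5

    def test_identical_multisets_give_p_one(self):
        r = mwu_two_tailed([5, 5, 5], [5, 5, 5])
        assert r.p_two_tailed == 1.0
        assert r.method == "normal_approx"  # ties route to the approximation

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            while True:
                vals = rng.normal(size=n1 + n2)
                if len(set(vals)) == n1 + n2:
                    break
            x, y = list(vals[:n1]), list(vals[n1:])
            r = mwu_two_tailed(x, y)
            assert r.method == "exact"
            assert abs(r.p_two_tailed - _enumeration_p(x, y)) < 1e-9

    def test_symmetry_and_u_complement(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = list(rng.normal(size=15))
            y = list(rng.normal(size=11))
            r1, r2 = mwu_two_tailed(x, y), mwu_two_tailed(y, x)
            assert abs(r1.p_two_tailed - r2.p_two_tailed) < 1e-12
            assert abs(r1.U + r2.U - len(x) * len(y)) < 1e-9

    def test_exact_and_normal_agree_for_moderate_samples(self):
        from scipy import stats as sps

        rng = np.random.default_rng(17)
        for _ in range(100):
            while True:
                vals = rng.normal(size=40)
                if len(set(vals)) == 40:
                    break
            x, y = list(vals[:20]), list(vals[20:])
            exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            approx = mwu_two_tailed(x, y).p_two_tailed
            assert abs(exact - approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mwu_two_tailed([], [1.0])


def _event(genotype, nuclease, del_len=0, ins="", line="L1", clone="c"):
    cls = (
        "intact"
        if del_len == 0 and not ins
        else "deletion"
        if not ins
        else "insertion"
        if del_len == 0
        else "substitution"
        if del_len == len(ins)
        else "delins"
    )
    return Footprint(cls, 10, 10 + del_len, ins, 10, 10, 0, clone, line, genotype, nuclease)


class TestCompareGenotypes:
    def test_small_group_yields_na_row_with_warning(self):
        events = EventSet(
            [_event("WT", "Cas9-CRU", del_len=5, clone=f"c{i}") for i in range(4)]
            + [_event("ku80", "Cas9-CRU", del_len=30, clone="k0")]
        )
        with pytest.warns(UserWarning):
            out = compare_genotypes(events, "del_len")
        row = out[(out.nuclease == "Cas9-CRU") & (out.group2 == "ku80")].iloc[0]
        assert row.method == "not_tested" and np.isnan(row.p)

    def test_planted_shift_is_detected(self):
        rng = np.random.default_rng(5)
        events = []
        for i in range(30):
            events.append(
                _event("WT", "Cas9-CRU", del_len=int(rng.integers(1, 10)), clone=f"w{i}")
            )
            events.append(
                _event("ku80", "Cas9-CRU", del_len=int(rng.integers(30, 80)), clone=f"k{i}")
            )
        out = compare_genotypes(EventSet(events), "del_len")
        row = out[(out.nuclease == "Cas9-CRU") & (out.group2 == "ku80")].iloc[0]
        assert row.significant and row.median2 > row.median1

    def test_substitutions_excluded_from_lengths(self):
        events = EventSet(
            [_event("WT", "Cas9-CRU", del_len=3, ins="TTT", clone=f"s{i}") for i in range(5)]
            + [_event("WT", "Cas9-CRU", del_len=5, clone=f"d{i}") for i in range(3)]
        )
        out = compare_genotypes(events, "del_len")
        assert int(out[out.nuclease == "Cas9-CRU"].iloc[0].n1) == 3


class TestDeletionWithWithoutInsertion:
    def test_all_without_insertion_gives_na(self):
        events = EventSet([_event("WT", "Cas9-CRU", del_len=5, clone=f"c{i}") for i in range(10)])
        with pytest.warns(UserWarning):
            out = deletion_with_without_insertion(events)
        assert out.iloc[0].method == "not_tested"

    def test_planted_threefold_effect_is_significant(self):
        rng = np.random.default_rng(9)
        events = []
        for i in range(50):
            base = int(rng.integers(2, 20))
            events.append(_event("WT", "Cas9-CRU", del_len=base, clone=f"d{i}"))
            events.append(
                _event("WT", "Cas9-CRU", del_len=3 * base, ins="GATTA", clone=f"x{i}")
            )
        out = deletion_with_without_insertion(EventSet(events))
        assert bool(out.iloc[0].significant)


@pytest.mark.parametrize(
    "resistant,bands,expected",
    [(30, [30, 70], 0.30), (0, [0, 100], 0.0), (50, [50, 25, 25], 0.50)],
)
def test_resistant_fraction(resistant, bands, expected):
    assert resistant_fraction(resistant, bands) == pytest.approx(expected)


def test_resistant_fraction_errors():
    with pytest.raises(ValueError):
        resistant_fraction(10, [0, 0])
    with pytest.raises(ValueError):
        resistant_fraction(120, [50, 50])
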