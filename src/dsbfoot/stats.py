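"""Deletion/insertion length statistics and genotype contrasts.

Deletion lengths are summarized in the four bins <10, 10-19, 20-49 and
>=50 bp and compared between wild type and repair-mutant genotypes with
two-tailed Mann-Whitney U tests.  Exact p-values (full enumeration of rank
assignments) are used for small tie-free samples; larger or tied samples
use the tie-corrected normal approximation with continuity correction.
Substitution events are excluded from all length statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .caller import EventSet, Footprint
from .locus import DELETION_BINS, DELETION_BIN_LABELS

#: exact-test regime: total sample size at or below this, and no ties
EXACT_MAX_N = 12


@dataclass(frozen=True)
class LengthDistribution:
    """Binned deletion-length distribution."""

    bins: tuple[str, ...]
    counts: tuple[int, ...]
    fractions: tuple[float, ...]
    n: int


def bin_deletions(lengths: Sequence[int]) -> LengthDistribution:
    """Bin deletion lengths into <10 / 10-19 / 20-49 / >=50 bp.

    Intact events (length 0) must never reach statistics and raise.
    """
    counts = [0, 0, 0, 0]
    for L in lengths:
        if L < 1:
            raise ValueError(f"deletion length must be >= 1, got {L}")
        for i, (lo, hi) in enumerate(DELETION_BINS):
            if lo <= L <= hi:
                counts[i] += 1
                break
    n = len(lengths)
    fractions = tuple(c / n for c in counts) if n else (0.0,) * 4
    return LengthDistribution(DELETION_BIN_LABELS, tuple(counts), fractions, n)


@dataclass(frozen=True)
class MWUResult:
    """Two-tailed Mann-Whitney U outcome (U reported for group 1)."""

    U: float
    n1: int
    n2: int
    p_two_tailed: float
    method: str  # 'exact' | 'normal_approx'
    medians: tuple[float, float]

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < 0.05


def mwu_two_tailed(x: Sequence[float], y: Sequence[float]) -> MWUResult:
    """Two-tailed Mann-Whitney U test.

    Exact null distribution when ``n1 + n2 <= 12`` and the pooled sample is
    tie-free; otherwise the normal approximation with tie-corrected
    variance and 0.5 continuity correction.  The method actually used is
    recorded in the result.
    """
    x = list(x)
    y = list(y)
    if not x or not y:
        raise ValueError("mwu_two_tailed: both groups must be non-empty")
    pooled = x + y
    tie_free = len(set(pooled)) == len(pooled)
    if len(pooled) <= EXACT_MAX_N and tie_free:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal_approx"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return MWUResult(
        U=float(res.statistic),
        n1=len(x),
        n2=len(y),
        p_two_tailed=min(1.0, float(res.pvalue)),
        method=method,
        medians=(float(np.median(x)), float(np.median(y))),
    )


def _measure_values(events: Iterable[Footprint], measure: str) -> list[int]:
    """Event lengths for one measure, excluding substitutions and intacts."""
    if measure == "del_len":
        return [fp.del_len for fp in events if fp.event_class in ("deletion", "delins")]
    if measure == "ins_len":
        return [fp.ins_len for fp in events if fp.event_class in ("insertion", "delins")]
    raise ValueError(f"unknown measure {measure!r}")


_NA_ROW_FIELDS = dict(
    n1=0, n2=0, median1=np.nan, median2=np.nan, U=np.nan, p=np.nan,
    method="not_tested", significant=False,
)


def _contrast_row(nuclease: str, g1: str, g2: str, v1, v2, alpha: float) -> dict:
    if len(v1) < 2 or len(v2) < 2:
        warnings.warn(
            f"contrast {g1} vs {g2} ({nuclease}): fewer than 2 events per group, "
            "reporting NA"
        )
        return {"nuclease": nuclease, "group1": g1, "group2": g2, **_NA_ROW_FIELDS,
                "n1": len(v1), "n2": len(v2)}
    r = mwu_two_tailed(v1, v2)
    return {
        "nuclease": nuclease,
        "group1": g1,
        "group2": g2,
        "n1": r.n1,
        "n2": r.n2,
        "median1": r.medians[0],
        "median2": r.medians[1],
        "U": r.U,
        "p": r.p_two_tailed,
        "method": r.method,
        "significant": bool(r.p_two_tailed < alpha),
    }


def compare_genotypes(
    events: EventSet, measure: str = "del_len", *, alpha: float = 0.05
) -> pd.DataFrame:
    """Wild type versus each mutant genotype.

    Deletion lengths are contrasted per nuclease (and additionally pooled
    over both targets); insertion lengths are contrasted on the pooled
    targets only, as insertion events are sparse.
    """
    mutants = ("ku80", "parp1parp2", "ku80parp1parp2")
    rows = []

    def values(genotype: str, nuclease: str | None) -> list[int]:
        sel = [
            fp
            for fp in events.events
            if fp.genotype == genotype and (nuclease is None or fp.nuclease == nuclease)
        ]
        return _measure_values(sel, measure)

    nucleases: list[str | None]
    if measure == "del_len":
        nucleases = ["Cas9-CRU", "Cas9-PPO", None]
    else:
        nucleases = [None]
    for nuc in nucleases:
        wt = values("WT", nuc)
        for mut in mutants:
            rows.append(
                _contrast_row(nuc or "pooled", "WT", mut, wt, values(mut, nuc), alpha)
            )
    return pd.DataFrame(rows)


def deletion_with_without_insertion(events: EventSet, *, alpha: float = 0.05) -> pd.DataFrame:
    """Deletion lengths of junctions with versus without an insertion.

    Pooled over all genotypes and both targets; a junction "with insertion"
    is a delins event, "without" a pure deletion.
    """
    with_ins = [fp.del_len for fp in events.events if fp.event_class == "delins"]
    without = [fp.del_len for fp in events.events if fp.event_class == "deletion"]
    row = _contrast_row("pooled", "del+ins", "del-only", with_ins, without, alpha)
    row["group1"], row["group2"] = "with_insertion", "without_insertion"
    return pd.DataFrame([row])


def distributions_table(events: EventSet) -> pd.DataFrame:
    """Deletion-length bin counts/fractions per genotype x nuclease."""
    rows = []
    df = pd.DataFrame(
        [
            {"genotype": fp.genotype, "nuclease": fp.nuclease, "del_len": fp.del_len}
            for fp in events.events
            if fp.event_class in ("deletion", "delins")
        ]
    )
    if len(df) == 0:
        return pd.DataFrame(
            columns=["genotype", "nuclease", "bin", "count", "fraction", "n"]
        )
    for (gt, nuc), grp in df.groupby(["genotype", "nuclease"], sort=True):
        dist = bin_deletions(list(grp["del_len"]))
        for lab, c, f in zip(dist.bins, dist.counts, dist.fractions):
            rows.append(
                {
                    "genotype": gt,
                    "nuclease": nuc,
                    "bin": lab,
                    "count": c,
                    "fraction": f,
                    "n": dist.n,
                }
            )
    return pd.DataFrame(rows)


def resistant_fraction(
    resistant_intensity: float, all_band_intensities: Sequence[float]
) -> float:
    """Relative mutation frequency from gel band intensities.

    The intensity of the digest-resistant band divided by the total
    intensity of all bands in the lane.
    """
    if resistant_intensity < 0 or any(b < 0 for b in all_band_intensities):
        raise ValueError("band intensities must be non-negative")
    total = float(sum(all_band_intensities))
    if total <= 0:
        raise ValueError("total band intensity must be positive")
    if resistant_intensity > total + 1e-9:
        raise ValueError("resistant band intensity exceeds lane total")
    return resistant_intensity / total
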