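"""Junction microhomology and templated-insertion annotation.

Two hallmarks of polymerase-theta-mediated end joining are scored here:
short direct repeats spanning deletion junctions (microhomology, rendering
the junction placement ambiguous) and inserted sequence copied from DNA
near the break — as one perfect match, a reverse-complement match, or a
patchwork of shorter identity stretches — often primed by a short identity
between the junction's 3' end and the bases immediately upstream of the
copied template.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from .caller import EventSet, Footprint, enumerate_placements
from .locus import TargetLocus, revcomp


@dataclass(frozen=True)
class MicrohomologyCall:
    """Direct repeat shared by the two junction flanks of a deletion."""

    length: int
    sequence: str
    placements: tuple[int, int]  # [p_min, p_max] of equivalent start positions


class Segment(NamedTuple):
    """One matched stretch of an insertion on the nearby reference.

    ``ref_pos`` is the start of the matched window on the forward strand of
    the amplicon; for ``orientation == 'reverse'`` the insertion carries the
    reverse complement of that window.
    """

    ins_offset: int
    length: int
    ref_pos: int
    orientation: str  # 'direct' | 'reverse'


@dataclass(frozen=True)
class TemplateMatch:
    """Mapping of an inserted sequence onto the +/-100 bp neighborhood."""

    insertion_id: str
    category: str  # 'perfect' | 'partial' | 'reverse' | 'none'
    segments: tuple[Segment, ...]
    coverage: float
    primer_identity_len: int = 0
    primed: bool = False
    searched: bool = True

    def segments_str(self) -> str:
        return ";".join(
            f"{s.ins_offset}:{s.length}@{s.ref_pos}{'+' if s.orientation == 'direct' else '-'}"
            for s in self.segments
        )


def annotate_microhomology(fp: Footprint, reference: str) -> MicrohomologyCall:
    """Microhomology of a pure deletion junction.

    The length equals the width of the junction's placement range (the
    number of equivalent placements minus one); the sequence is the
    repeated word present at the start of both flanking copies.  Other
    event classes report length 0 — with an insertion present, junction
    ambiguity is attributed to the insertion placement instead.
    """
    if fp.event_class != "deletion":
        return MicrohomologyCall(0, "", (fp.del_start, fp.del_start))
    read = fp.reconstruct(reference)
    placements = enumerate_placements(reference, fp.del_len, "", read)
    if not placements:
        raise ValueError(f"inconsistent footprint for clone {fp.clone_id!r}")
    p_min = placements[0][0]
    p_max = placements[-1][0]
    length = p_max - p_min
    return MicrohomologyCall(length, reference[p_min : p_min + length], (p_min, p_max))


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def find_template(
    ins_seq: str,
    locus: TargetLocus,
    *,
    window_bp: int = 100,
    min_search_len: int = 3,
    min_seed: int = 4,
    insertion_id: str = "",
) -> TemplateMatch:
    """Search the cut-site neighborhood for the origin of an insertion.

    The search space is ``amplicon[cut-window_bp : cut+window_bp]`` (clipped
    at the amplicon ends) and its reverse complement.  A full-length match
    gives category ``perfect`` (direct) or ``reverse``; otherwise the
    insertion is greedily decomposed into maximal matched substrings of at
    least ``min_seed`` bases (longest first; ties broken leftmost on the
    insertion, direct preferred), giving ``partial`` when any base matches
    and ``none`` otherwise.  Insertions shorter than ``min_search_len`` are
    not searched.
    """
    if not ins_seq:
        raise ValueError("find_template: empty insertion")
    if len(ins_seq) < min_search_len:
        return TemplateMatch(insertion_id, "none", (), 0.0, searched=False)

    lo = max(0, locus.cut_pos - window_bp)
    hi = min(len(locus.amplicon), locus.cut_pos + window_bp)
    win = locus.amplicon[lo:hi]

    def nearest(word: str) -> int | None:
        """Occurrence whose midpoint lies closest to the cut (repair
        templates are typically copied from right next to the break)."""
        hits = _find_all(win, word)
        if not hits:
            return None
        mid = locus.cut_pos - lo - len(word) / 2
        return min(hits, key=lambda i: (abs(i - mid), i))

    idx = nearest(ins_seq)
    if idx is not None:
        seg = Segment(0, len(ins_seq), lo + idx, "direct")
        return TemplateMatch(insertion_id, "perfect", (seg,), 1.0)
    idx = nearest(revcomp(ins_seq))
    if idx is not None:
        seg = Segment(0, len(ins_seq), lo + idx, "reverse")
        return TemplateMatch(insertion_id, "reverse", (seg,), 1.0)

    # greedy decomposition over uncovered insertion intervals
    uncovered: list[tuple[int, int]] = [(0, len(ins_seq))]
    segments: list[Segment] = []
    while True:
        best: Segment | None = None
        for a, b in uncovered:
            span = b - a
            if span < min_seed:
                continue
            limit = best.length if best else min_seed - 1
            for length in range(span, limit, -1):
                found = None
                for off in range(a, b - length + 1):
                    sub = ins_seq[off : off + length]
                    i = nearest(sub)
                    if i is not None:
                        found = Segment(off, length, lo + i, "direct")
                        break
                    i = nearest(revcomp(sub))
                    if i is not None:
                        found = Segment(off, length, lo + i, "reverse")
                        break
                if found is not None:
                    if best is None or found.length > best.length or (
                        found.length == best.length
                        and (found.ins_offset, found.orientation == "reverse")
                        < (best.ins_offset, best.orientation == "reverse")
                    ):
                        best = found
                    break  # longer lengths in this interval already exhausted
        if best is None:
            break
        segments.append(best)
        nxt = []
        for a, b in uncovered:
            if b <= best.ins_offset or a >= best.ins_offset + best.length:
                nxt.append((a, b))
            else:
                if a < best.ins_offset:
                    nxt.append((a, best.ins_offset))
                if best.ins_offset + best.length < b:
                    nxt.append((best.ins_offset + best.length, b))
        uncovered = nxt

    segments.sort(key=lambda s: s.ins_offset)
    covered = sum(s.length for s in segments)
    coverage = covered / len(ins_seq)
    category = "partial" if covered else "none"
    return TemplateMatch(insertion_id, category, tuple(segments), coverage)


def primer_identity(
    match: TemplateMatch,
    fp: Footprint,
    reference: str,
    *,
    min_primer: int = 2,
) -> tuple[int, bool]:
    """Identity between the junction's 3' end and the template's upstream.

    Uses the 5'-most matched segment of the insertion.  The primer is the
    3' terminus of the retained left flank (the strand end that initiated
    repair synthesis); it is compared base-by-base with the sequence
    immediately upstream of the template start, read in template
    orientation.  ``primed`` requires at least ``min_primer`` identical
    bases.
    """
    if match.category == "none" or not match.segments:
        return 0, False
    seg = match.segments[0]
    flank = reference[: fp.del_start]
    n = 0
    if seg.orientation == "direct":
        while (
            n < len(flank)
            and seg.ref_pos - 1 - n >= 0
            and flank[-1 - n] == reference[seg.ref_pos - 1 - n]
        ):
            n += 1
    else:
        # template runs right-to-left on the forward strand; its upstream
        # context is the complement of the bases just right of the window
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        end = seg.ref_pos + seg.length
        while (
            n < len(flank)
            and end + n < len(reference)
            and flank[-1 - n] == comp[reference[end + n]]
        ):
            n += 1
    return n, n >= min_primer


def annotate_all(
    events: EventSet,
    locus: TargetLocus,
    *,
    window_bp: int = 100,
    min_search_len: int = 3,
    min_seed: int = 4,
    min_primer: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate every event; summarize templated insertions per genotype.

    Returns ``(annotations, summary)``.  ``annotations`` has one row per
    event (microhomology for deletions, template category / coverage /
    segments / primer identity for insertion-bearing events).  ``summary``
    has one row per genotype x nuclease with insertion counts, templated
    counts (category != none), primed counts and the corresponding
    fractions.
    """
    rows = []
    for fp in events.events:
        mh = annotate_microhomology(fp, locus.amplicon)
        row = {
            "clone_id": fp.clone_id,
            "line_id": fp.line_id,
            "genotype": fp.genotype,
            "nuclease": fp.nuclease,
            "event_class": fp.event_class,
            "del_len": fp.del_len,
            "ins_len": fp.ins_len,
            "mh_len": mh.length,
            "mh_seq": mh.sequence,
            "template_category": "",
            "coverage": float("nan"),
            "segments": "",
            "primer_identity_len": 0,
            "primed": False,
        }
        if fp.ins_seq and fp.event_class in ("insertion", "delins"):
            tm = find_template(
                fp.ins_seq,
                locus,
                window_bp=window_bp,
                min_search_len=min_search_len,
                min_seed=min_seed,
                insertion_id=fp.clone_id,
            )
            plen, primed = primer_identity(tm, fp, locus.amplicon, min_primer=min_primer)
            row.update(
                template_category=tm.category,
                coverage=tm.coverage,
                segments=tm.segments_str(),
                primer_identity_len=plen,
                primed=primed,
            )
        rows.append(row)
    annotations = pd.DataFrame(rows)

    summary_rows = []
    if len(annotations):
        ins_mask = annotations["event_class"].isin(["insertion", "delins"])
        for (gt, nuc), grp in annotations.groupby(["genotype", "nuclease"], sort=True):
            ins = grp[grp["event_class"].isin(["insertion", "delins"])]
            n_ins = len(ins)
            n_templated = int((ins["template_category"].isin(["perfect", "partial", "reverse"])).sum())
            n_primed = int(ins["primed"].sum())
            summary_rows.append(
                {
                    "genotype": gt,
                    "nuclease": nuc,
                    "n_events": len(grp),
                    "n_insertions": n_ins,
                    "n_templated": n_templated,
                    "n_primed": n_primed,
                    "frac_templated": n_templated / n_ins if n_ins else 0.0,
                    "frac_primed": n_primed / n_ins if n_ins else 0.0,
                }
            )
    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "genotype",
            "nuclease",
            "n_events",
            "n_insertions",
            "n_templated",
            "n_primed",
            "frac_templated",
            "frac_primed",
        ],
    )
    return annotations, summary
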