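"""End-anchored footprint calling from clone junction sequences.

Each digest-resistant clone is a Sanger read spanning the whole amplicon, so
a repair footprint can be called by comparing the read to the reference from
both ends: the longest common prefix and suffix delimit one contiguous
deleted/inserted segment at the junction.  Microhomology at the junction
makes the placement ambiguous; the caller canonicalizes to the leftmost
equivalent placement and records the full shift range, whose width is the
microhomology length for pure deletions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

GENOTYPES = ("WT", "ku80", "parp1parp2", "ku80parp1parp2")
NUCLEASES = ("Cas9-CRU", "Cas9-PPO")

EVENT_CLASSES = ("intact", "deletion", "insertion", "delins", "substitution")


class UnalignableCloneError(ValueError):
    """Read shares neither primer anchor with the reference amplicon."""


class ComplexCloneError(ValueError):
    """Called event extends implausibly far from the cut (noise/chimera)."""


@dataclass(frozen=True)
class CloneRead:
    """One sequenced clone with its line/genotype provenance."""

    clone_id: str
    line_id: str
    genotype: str
    nuclease: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"clone {self.clone_id}: empty sequence")
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"clone {self.clone_id}: genotype {self.genotype!r} not in {GENOTYPES}"
            )
        if self.nuclease not in NUCLEASES:
            raise ValueError(
                f"clone {self.clone_id}: nuclease {self.nuclease!r} not in {NUCLEASES}"
            )


@dataclass(frozen=True)
class Footprint:
    """A called repair event in canonical (leftmost) form.

    ``del_interval=[del_start, del_end)`` on the reference, ``ins_seq`` the
    inserted bases at that junction; ``shift_min..shift_max`` are the start
    coordinates of all equivalent placements.  Reassembling
    ``ref[:del_start] + ins_seq + ref[del_end:]`` reproduces the read.
    """

    event_class: str
    del_start: int
    del_end: int
    ins_seq: str
    shift_min: int
    shift_max: int
    mh_len: int
    clone_id: str = ""
    line_id: str = ""
    genotype: str = ""
    nuclease: str = ""

    @property
    def del_len(self) -> int:
        return self.del_end - self.del_start

    @property
    def ins_len(self) -> int:
        return len(self.ins_seq)

    def key(self) -> tuple:
        """Canonical identity of the event (independent of clone id)."""
        return (self.event_class, self.del_start, self.del_end, self.ins_seq)

    def reconstruct(self, reference: str) -> str:
        return reference[: self.del_start] + self.ins_seq + reference[self.del_end :]


def classify_event(del_len: int, ins_seq: str) -> str:
    """Three-way indel taxonomy plus substitutions and intact reads.

    Equal-length replacements are classed ``substitution`` (reported
    separately and excluded from length statistics, since they are likely
    PCR artifacts); unequal replacements are ``delins``.
    """
    ins_len = len(ins_seq)
    if del_len == 0 and ins_len == 0:
        return "intact"
    if ins_len == 0:
        return "deletion"
    if del_len == 0:
        return "insertion"
    if del_len == ins_len:
        return "substitution"
    return "delins"


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _shift_left(ref: str, start: int, end: int, ins: str) -> tuple[int, int, str] | None:
    """One-step leftward equivalent placement, or None if blocked."""
    if start == 0:
        return None
    if ins:
        if ins[-1] != ref[end - 1]:
            return None
        return start - 1, end - 1, ref[start - 1] + ins[:-1]
    if ref[start - 1] != ref[end - 1]:
        return None
    return start - 1, end - 1, ins


def _shift_right(ref: str, start: int, end: int, ins: str) -> tuple[int, int, str] | None:
    if end == len(ref):
        return None
    if ins:
        if ins[0] != ref[start]:
            return None
        return start + 1, end + 1, ins[1:] + ref[end]
    if ref[start] != ref[end]:
        return None
    return start + 1, end + 1, ins


def call_footprint(
    reference: str,
    read: CloneRead | str,
    *,
    min_anchor: int = 1,
    cut_pos: int | None = None,
    max_radius: int = 250,
) -> Footprint:
    """Call the single contiguous repair event of one clone.

    The longest common prefix (length p) and suffix (length s, capped so
    p + s never exceeds either sequence) anchor the event; the deleted
    reference segment is ``ref[p : len(ref)-s]`` and the inserted read
    segment ``read[p : len(read)-s]``.  The result is canonicalized to the
    leftmost equivalent placement.

    Raises :class:`UnalignableCloneError` when both primer anchors are
    shorter than ``min_anchor``, and :class:`ComplexCloneError` when the
    called event reaches further than ``max_radius`` from ``cut_pos``
    (scattered mismatches inflating the event; such clones are excluded
    from statistics by the pipeline).
    """
    if isinstance(read, CloneRead):
        seq = read.sequence
        meta = dict(
            clone_id=read.clone_id,
            line_id=read.line_id,
            genotype=read.genotype,
            nuclease=read.nuclease,
        )
    else:
        seq = read
        meta = {}
    if not seq:
        raise UnalignableCloneError("empty read")

    p = _common_prefix_len(reference, seq)
    s = _common_prefix_len(reference[::-1], seq[::-1])
    if p < min_anchor and s < min_anchor:
        raise UnalignableCloneError(
            f"clone {meta.get('clone_id', '?')}: shares neither end anchor "
            f"with the reference (prefix {p} nt, suffix {s} nt)"
        )
    s = min(s, min(len(reference), len(seq)) - p)

    start, end = p, len(reference) - s
    ins = seq[p : len(seq) - s]

    # canonicalize leftmost; record the whole equivalence range
    left = (start, end, ins)
    while (step := _shift_left(reference, *left)) is not None:
        left = step
    right = (start, end, ins)
    while (step := _shift_right(reference, *right)) is not None:
        right = step
    start, end, ins = left
    shift_min, shift_max = left[0], right[0]

    del_len = end - start
    if del_len == 0 and not ins:
        start = end = shift_min = shift_max = 0

    if cut_pos is not None and (del_len or ins):
        if max(abs(start - cut_pos), abs(end - cut_pos)) > max_radius:
            raise ComplexCloneError(
                f"clone {meta.get('clone_id', '?')}: event [{start},{end}) reaches "
                f"more than {max_radius} bp from the cut at {cut_pos}"
            )

    event_class = classify_event(del_len, ins)
    mh_len = shift_max - shift_min if event_class == "deletion" else 0
    fp = Footprint(
        event_class=event_class,
        del_start=start,
        del_end=end,
        ins_seq=ins,
        shift_min=shift_min,
        shift_max=shift_max,
        mh_len=mh_len,
        **meta,
    )
    assert fp.reconstruct(reference) == seq, "round-trip invariant violated"
    return fp


def enumerate_placements(
    reference: str, del_len: int, ins_seq: str, read: str
) -> list[tuple[int, int]]:
    """All (start, start+del_len) whose excision/insertion yields ``read``.

    Brute-force definition of the junction equivalence class for a fixed
    inserted sequence; ascending order.  The degenerate intact event
    returns the single canonical placement ``[(0, 0)]``.
    """
    if del_len < 0:
        raise ValueError("del_len must be >= 0")
    if del_len == 0 and not ins_seq:
        return [(0, 0)] if read == reference else []
    out = []
    for start in range(len(reference) - del_len + 1):
        if reference[:start] + ins_seq + reference[start + del_len :] == read:
            out.append((start, start + del_len))
    return out


@dataclass
class EventSet:
    """Per-line deduplicated repair events.

    Identical footprints within one plant line are collapsed to a single
    mutagenesis event (they may stem from PCR amplification of one
    molecule); identical footprints in different lines remain distinct.
    """

    events: list[Footprint]
    duplicates_removed: int = 0

    def __len__(self) -> int:
        return len(self.events)

    def by_genotype(self) -> dict[str, list[Footprint]]:
        groups: dict[str, list[Footprint]] = {}
        for fp in self.events:
            groups.setdefault(fp.genotype, []).append(fp)
        return groups

    def subset(self, pred) -> "EventSet":
        return EventSet([fp for fp in self.events if pred(fp)], self.duplicates_removed)


def dedupe(events: Iterable[Footprint]) -> EventSet:
    """Collapse identical footprints within each line to one event."""
    seen: dict[tuple, Footprint] = {}
    removed = 0
    for fp in events:
        k = (fp.line_id, fp.key())
        if k in seen:
            removed += 1
        else:
            seen[k] = fp
    return EventSet(list(seen.values()), duplicates_removed=removed)
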