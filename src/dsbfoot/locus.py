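"""Target-locus model and in-silico restriction digest.

A nuclease target is described by its PCR amplicon, the 20-nt protospacer
with its NGG PAM, the predicted blunt cut position (a between-base junction
coordinate 3 nt 5' of the PAM), and a restriction enzyme whose recognition
site lies near the cut.  Loss of that site after erroneous repair is what
makes a mutant clone digest-resistant and hence sequenceable; the digest
model here predicts which repair footprints are detectable that way.

Coordinates are 0-based and half-open throughout; ``cut_pos`` is a junction
coordinate between bases (0..len(amplicon)).
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA = frozenset("ACGT")

PROTOSPACER_LEN = 20
PAM_LEN = 3
#: distance (nt) of the blunt SpCas9 cut from the PAM-proximal protospacer end
CUT_OFFSET_FROM_PAM = 3


class LocusError(ValueError):
    """Raised when a locus definition violates its invariants."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, label: str = "sequence") -> None:
    bad = set(seq) - _DNA
    if not seq or bad:
        raise ValueError(
            f"{label}: expected non-empty uppercase DNA over ACGT, "
            f"offending characters: {sorted(bad) if bad else 'empty'}"
        )


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme reduced to its exact recognition sequence.

    Matching is exact (no degenerate IUPAC codes) and performed on both
    strands, so non-palindromic sites such as FauI's CCCGC are also found
    as their reverse complement.
    """

    name: str
    recognition: str

    def __post_init__(self) -> None:
        _check_dna(self.recognition, f"enzyme {self.name} recognition")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


#: the two enzymes used for the loss-of-restriction-site assay
PSTI = RestrictionEnzyme("PstI", "CTGCAG")
FAUI = RestrictionEnzyme("FauI", "CCCGC")


def find_recognition_sites(
    seq: str, enzyme: RestrictionEnzyme, label: str = "sequence"
) -> list[tuple[int, str]]:
    """All exact occurrences of the recognition site on either strand.

    Returns ``(position, strand)`` pairs sorted by position, positions
    0-based on ``seq``.  A palindromic window is reported once with
    strand '+'; a reverse-complement-only match is reported with '-'.
    """
    _check_dna(seq, label)
    site = enzyme.recognition
    rc = revcomp(site)
    hits: dict[int, str] = {}
    start = seq.find(site)
    while start != -1:
        hits[start] = "+"
        start = seq.find(site, start + 1)
    if rc != site:
        start = seq.find(rc)
        while start != -1:
            hits.setdefault(start, "-")
            start = seq.find(rc, start + 1)
    return sorted(hits.items())


def is_detectable(mutated_amplicon: str, enzyme: RestrictionEnzyme) -> bool:
    """True iff the amplicon lost every recognition site.

    Such a molecule survives the post-PCR digest and enters the cloned,
    sequenced pool; a footprint that leaves the site intact (e.g. a 1-2 bp
    deletion away from the site) is invisible to the assay.
    """
    return not find_recognition_sites(mutated_amplicon, enzyme)


def expected_cut_position(
    protospacer_interval: tuple[int, int], strand: str
) -> int:
    """Blunt-cut junction coordinate for a protospacer on the amplicon.

    On '+' the PAM is right of the protospacer and the cut falls
    ``CUT_OFFSET_FROM_PAM`` nt left of the protospacer's 3' end; on '-'
    everything mirrors.
    """
    start, end = protospacer_interval
    if strand == "+":
        return end - CUT_OFFSET_FROM_PAM
    if strand == "-":
        return start + CUT_OFFSET_FROM_PAM
    raise LocusError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class TargetLocus:
    """An amplicon-scale description of one nuclease target site."""

    name: str
    amplicon: str
    protospacer_interval: tuple[int, int]
    protospacer_strand: str
    pam_interval: tuple[int, int]
    cut_pos: int
    enzyme: RestrictionEnzyme
    primer_fwd: str
    primer_rev: str
    synthetic: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ---------------------------------------------------
    @property
    def protospacer(self) -> str:
        s, e = self.protospacer_interval
        seq = self.amplicon[s:e]
        return seq if self.protospacer_strand == "+" else revcomp(seq)

    @property
    def pam(self) -> str:
        s, e = self.pam_interval
        seq = self.amplicon[s:e]
        return seq if self.protospacer_strand == "+" else revcomp(seq)

    @property
    def recognition_interval(self) -> tuple[int, int]:
        """Interval of the unique recognition site on the amplicon."""
        (pos, _strand), = find_recognition_sites(self.amplicon, self.enzyme)
        return pos, pos + len(self.enzyme.recognition)

    def validate(self) -> None:
        _check_dna(self.amplicon, f"locus {self.name} amplicon")
        ps, pe = self.protospacer_interval
        if pe - ps != PROTOSPACER_LEN:
            raise LocusError(f"{self.name}: protospacer must be {PROTOSPACER_LEN} nt")
        gs, ge = self.pam_interval
        if ge - gs != PAM_LEN:
            raise LocusError(f"{self.name}: PAM must be {PAM_LEN} nt")
        pam = self.pam
        if not (pam[1:] == "GG"):
            raise LocusError(f"{self.name}: PAM {pam} does not match NGG")
        if self.protospacer_strand == "+":
            if gs != pe:
                raise LocusError(f"{self.name}: PAM not 3'-adjacent to protospacer")
        elif self.protospacer_strand == "-":
            if ge != ps:
                raise LocusError(f"{self.name}: PAM not 3'-adjacent to protospacer")
        else:
            raise LocusError(f"{self.name}: bad strand {self.protospacer_strand!r}")
        expected = expected_cut_position(self.protospacer_interval, self.protospacer_strand)
        if self.cut_pos != expected:
            raise LocusError(
                f"{self.name}: cut_pos {self.cut_pos} inconsistent with "
                f"protospacer/PAM geometry (expected {expected})"
            )
        if not ps <= self.cut_pos <= pe:
            raise LocusError(f"{self.name}: cut_pos outside the protospacer")
        sites = find_recognition_sites(self.amplicon, self.enzyme)
        if len(sites) != 1:
            raise LocusError(
                f"{self.name}: recognition site {self.enzyme.recognition} occurs "
                f"{len(sites)} times in the amplicon; exactly one required"
            )
        _check_dna(self.primer_fwd, f"{self.name} primer_fwd")
        _check_dna(self.primer_rev, f"{self.name} primer_rev")
        if not self.amplicon.startswith(self.primer_fwd):
            raise LocusError(f"{self.name}: amplicon does not start with primer_fwd")
        if not self.amplicon.endswith(revcomp(self.primer_rev)):
            raise LocusError(
                f"{self.name}: amplicon does not end with revcomp(primer_rev)"
            )


def compute_cut_position(locus: TargetLocus) -> int:
    """Junction coordinate of the blunt cut (idempotent with ``cut_pos``)."""
    return expected_cut_position(locus.protospacer_interval, locus.protospacer_strand)


# ---------------------------------------------------------------------------
# detection-bias accounting
# ---------------------------------------------------------------------------

DELETION_BINS: tuple[tuple[int, float], ...] = ((1, 9), (10, 19), (20, 49), (50, float("inf")))
DELETION_BIN_LABELS: tuple[str, ...] = ("<10", "10-19", "20-49", ">=50")


def deletion_bin_label(del_len: int) -> str:
    for (lo, hi), lab in zip(DELETION_BINS, DELETION_BIN_LABELS):
        if lo <= del_len <= hi:
            return lab
    raise ValueError(f"deletion length must be >= 1, got {del_len}")


def detection_bias(truth: Sequence, locus: TargetLocus) -> pd.DataFrame:
    """Fraction of simulated events the digest pre-selection would keep.

    ``truth`` is a sequence of objects with ``event_class``, ``del_len`` and
    ``rendered_read`` attributes (the generator's truth records).  Rows are
    one per event class, plus one per deletion-length bin for deletion-type
    events; detectability is recomputed by re-digesting every rendered read.
    """
    if len(truth) == 0:
        raise ValueError("detection_bias: empty truth set")
    rows = []
    for rec in truth:
        det = is_detectable(rec.rendered_read, locus.enzyme)
        rows.append(
            {
                "event_class": rec.event_class,
                "del_bin": deletion_bin_label(rec.del_len)
                if rec.event_class in ("deletion", "delins") and rec.del_len >= 1
                else "",
                "detectable": det,
            }
        )
    df = pd.DataFrame(rows)
    by_class = (
        df.groupby("event_class")["detectable"]
        .agg(n="size", n_detectable="sum")
        .reset_index()
    )
    by_class.insert(1, "del_bin", "")
    dels = df[df["del_bin"] != ""]
    parts = [by_class]
    if len(dels):
        by_bin = (
            dels.groupby(["event_class", "del_bin"])["detectable"]
            .agg(n="size", n_detectable="sum")
            .reset_index()
        )
        parts.append(by_bin)
    out = pd.concat(parts, ignore_index=True)
    out["fraction_detectable"] = out["n_detectable"] / out["n"]
    return out


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def load_locus(path: str | Path) -> TargetLocus:
    """Read a locus definition from a TOML or JSON config file.

    The amplicon may be given inline (``amplicon``) or as a FASTA path plus
    record id (``amplicon_fasta``/``amplicon_record``, path relative to the
    config file).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        cfg = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    if "amplicon" in cfg:
        amplicon = cfg["amplicon"].upper()
    elif "amplicon_fasta" in cfg:
        from Bio import SeqIO

        want = cfg.get("amplicon_record")
        fasta = path.parent / cfg["amplicon_fasta"]
        for rec in SeqIO.parse(str(fasta), "fasta"):
            if want is None or rec.id == want:
                amplicon = str(rec.seq).upper()
                break
        else:
            raise LocusError(f"record {want!r} not found in {fasta}")
    else:
        raise LocusError(f"{path}: config must provide 'amplicon' or 'amplicon_fasta'")
    enzyme = RestrictionEnzyme(cfg["enzyme"]["name"], cfg["enzyme"]["recognition"].upper())
    proto = tuple(cfg["protospacer_interval"])
    strand = cfg["protospacer_strand"]
    return TargetLocus(
        name=cfg["name"],
        amplicon=amplicon,
        protospacer_interval=proto,  # type: ignore[arg-type]
        protospacer_strand=strand,
        pam_interval=tuple(cfg["pam_interval"]),  # type: ignore[arg-type]
        cut_pos=cfg.get("cut_pos", expected_cut_position(proto, strand)),  # type: ignore[arg-type]
        enzyme=enzyme,
        primer_fwd=cfg["primer_fwd"].upper(),
        primer_rev=cfg["primer_rev"].upper(),
        synthetic=bool(cfg.get("synthetic", False)),
    )


def dump_locus(locus: TargetLocus, path: str | Path) -> None:
    """Write a locus definition as JSON (round-trips with :func:`load_locus`)."""
    cfg = {
        "name": locus.name,
        "amplicon": locus.amplicon,
        "protospacer_interval": list(locus.protospacer_interval),
        "protospacer_strand": locus.protospacer_strand,
        "pam_interval": list(locus.pam_interval),
        "cut_pos": locus.cut_pos,
        "enzyme": {"name": locus.enzyme.name, "recognition": locus.enzyme.recognition},
        "primer_fwd": locus.primer_fwd,
        "primer_rev": locus.primer_rev,
        "synthetic": locus.synthetic,
    }
    Path(path).write_text(json.dumps(cfg, indent=2) + "\n")
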