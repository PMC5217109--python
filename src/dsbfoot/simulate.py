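"""Synthetic clone-read generator with per-event truth records.

Emulates the clone pools the footprint pipeline analyzes: each simulated
clone carries one contiguous repair event at a defined Cas9 cut site —
nothing, a small 1-2 bp indel, a microhomology-flanked deletion, or a
(possibly deletion-accompanied) insertion copied from the cut-site
neighborhood — flanked by exact reference sequence.  Per-genotype presets
calibrate the deletion-length model to the study's reported bin fractions,
so mutant backgrounds deficient in classical end joining draw longer,
resection-like deletions.

Every random draw comes from one explicitly passed seeded generator, so a
given (config, seed) pair reproduces its dataset byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .caller import GENOTYPES, NUCLEASES, CloneRead, classify_event
from .locus import (
    FAUI,
    PSTI,
    RestrictionEnzyme,
    TargetLocus,
    expected_cut_position,
    find_recognition_sites,
    is_detectable,
    revcomp,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

EVENT_CLASS_NAMES = ("intact", "small_indel", "mmej_deletion", "templated_insertion")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# synthetic loci
# ---------------------------------------------------------------------------

def synthetic_locus(
    name: str = "CRU3syn",
    enzyme: RestrictionEnzyme | None = None,
    *,
    seed: int = 7,
    length: int = 360,
    site_gap: int = 2,
) -> TargetLocus:
    """Build a synthetic target locus with the assay's geometry.

    A random amplicon carries a 20-nt protospacer with an AGG PAM near its
    middle; the enzyme recognition site sits inside the protospacer with
    its PAM-proximal edge ``site_gap`` bases 5' of the blunt cut, so the
    site is near but does not overlap the cut — 1-2 bp deletions at the
    junction then leave it intact and escape digest-based detection.  The
    recognition sequence is guaranteed unique in the amplicon (either
    strand).  This is a synthetic stand-in for a real amplicon, not a
    transcription of any genomic target.
    """
    if enzyme is None:
        enzyme = PSTI
    rng = np.random.default_rng(seed)
    proto_start = length // 2 - 20
    proto_end = proto_start + 20
    cut = proto_end - 3
    site_len = len(enzyme.recognition)
    site_start = cut - site_gap - site_len
    if site_start < proto_start:
        raise ValueError("recognition site does not fit inside the protospacer")
    for _ in range(500):
        amp = list(_random_dna(rng, length))
        amp[site_start : site_start + site_len] = enzyme.recognition
        amp[proto_end : proto_end + 3] = ["A", "G", "G"]
        seq = "".join(amp)
        if len(find_recognition_sites(seq, enzyme)) == 1:
            return TargetLocus(
                name=name,
                amplicon=seq,
                protospacer_interval=(proto_start, proto_end),
                protospacer_strand="+",
                pam_interval=(proto_end, proto_end + 3),
                cut_pos=cut,
                enzyme=enzyme,
                primer_fwd=seq[:20],
                primer_rev=revcomp(seq[-20:]),
                synthetic=True,
            )
    raise RuntimeError("could not build a locus with a unique recognition site")


def default_loci(seed: int = 7) -> dict[str, TargetLocus]:
    """Synthetic stand-ins for the two assay targets, keyed by nuclease."""
    return {
        "Cas9-CRU": synthetic_locus("CRU3syn", PSTI, seed=seed),
        "Cas9-PPO": synthetic_locus("PPOsyn", FAUI, seed=seed + 1),
    }


# ---------------------------------------------------------------------------
# deletion-length model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DelLenModel:
    """Mixture of a short geometric and a long-tailed lognormal component.

    The geometric captures minimal end-processing by classical end joining;
    the discretized lognormal captures resection-scale deletions.  Support
    is 1..max_len (renormalized).
    """

    p_short: float
    mu_long: float
    sigma_long: float
    lambda_long: float
    max_len: int = 150

    def pmf(self) -> np.ndarray:
        k = np.arange(1, self.max_len + 1)
        short = self.p_short * (1 - self.p_short) ** (k - 1)
        short = short / short.sum()
        long = np.exp(-((np.log(k) - self.mu_long) ** 2) / (2 * self.sigma_long**2)) / k
        long = long / long.sum()
        p = self.lambda_long * long + (1 - self.lambda_long) * short
        return p / p.sum()

    def bin_probs(self) -> np.ndarray:
        """Analytic probabilities of the <10 / 10-19 / 20-49 / >=50 bins."""
        p = self.pmf()
        edges = [(1, 9), (10, 19), (20, 49), (50, self.max_len)]
        return np.array([p[lo - 1 : hi].sum() for lo, hi in edges])

    def sample(self, rng: np.random.Generator, size: int | None = None):
        p = self.pmf()
        out = rng.choice(np.arange(1, self.max_len + 1), size=size, p=p)
        return int(out) if size is None else out


# ---------------------------------------------------------------------------
# configuration and presets
# ---------------------------------------------------------------------------

def _load_preset_table() -> dict:
    with resources.files("dsbfoot.data").joinpath("presets.json").open() as fh:
        return json.load(fh)


@dataclass
class SimulationConfig:
    """All knobs of the repair-outcome generator.

    ``class_weights`` mix the four generator event classes; the deletion
    model, microhomology-length and insertion-length distributions shape
    the footprints; template parameters control where insertions are
    copied from (within ``template_window`` bp of the cut, reverse
    complement with probability ``p_reverse``) and whether a >=2 bp primer
    identity is planted (probability ``p_primed``).
    """

    locus: TargetLocus
    n_clones: int
    genotype: str = "WT"
    nuclease: str = "Cas9-CRU"
    seed: int = 0
    class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "intact": 0.05,
            "small_indel": 0.10,
            "mmej_deletion": 0.65,
            "templated_insertion": 0.20,
        }
    )
    del_len_model: DelLenModel = field(
        default_factory=lambda: DelLenModel(0.1247, 2.476, 1.2, 0.4823)
    )
    mh_len_dist: tuple[float, ...] = (0.40, 0.25, 0.15, 0.10, 0.05, 0.03, 0.02)
    ins_geom_p: float = 0.12
    ins_max_len: int = 60
    template_window: int = 100
    p_reverse: float = 0.3
    p_primed: float = 0.5
    p_untemplated: float = 0.2
    p_del_with_ins: float = 0.6
    delins_del_multiplier: float = 3.0
    p_pcr_duplicate: float = 0.05
    sub_noise_rate: float = 0.0
    n_lines: int = 8

    def __post_init__(self) -> None:
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        w = np.array([self.class_weights[c] for c in EVENT_CLASS_NAMES], float)
        if w.min() < 0 or abs(w.sum() - 1) > 1e-6:
            raise ValueError("class_weights must be a probability vector over "
                             f"{EVENT_CLASS_NAMES}")
        if abs(sum(self.mh_len_dist) - 1) > 1e-6:
            raise ValueError("mh_len_dist must sum to 1")


def preset_profile(genotype: str, nuclease: str) -> dict:
    """Calibrated generator parameters for one genotype x nuclease.

    The deletion-length model reproduces the reported per-genotype bin
    fractions analytically; KU-deficient presets also carry a higher
    templated-insertion weight (insertion events were more frequent there).
    Raises with the list of valid labels on an unknown key.
    """
    table = _load_preset_table()
    key = f"{genotype}|{nuclease}"
    if key not in table:
        raise KeyError(
            f"no preset {key!r}; valid presets: {sorted(table)} "
            f"(genotypes {GENOTYPES}, nucleases {NUCLEASES})"
        )
    entry = table[key]
    model = DelLenModel(
        p_short=entry["p_short"],
        mu_long=entry["mu_long"],
        sigma_long=entry["sigma_long"],
        lambda_long=entry["lambda_long"],
        max_len=entry["max_len"],
    )
    if "ku80" in genotype:
        weights = {
            "intact": 0.05,
            "small_indel": 0.08,
            "mmej_deletion": 0.59,
            "templated_insertion": 0.28,
        }
    else:
        weights = {
            "intact": 0.05,
            "small_indel": 0.10,
            "mmej_deletion": 0.65,
            "templated_insertion": 0.20,
        }
    return {
        "genotype": genotype,
        "nuclease": nuclease,
        "del_len_model": model,
        "class_weights": weights,
        "bin_targets": tuple(entry["bin_targets"]),
    }


def config_from_preset(
    locus: TargetLocus, genotype: str, nuclease: str, n_clones: int, seed: int, **overrides
) -> SimulationConfig:
    frag = preset_profile(genotype, nuclease)
    frag.pop("bin_targets")
    frag.update(overrides)
    return SimulationConfig(locus=locus, n_clones=n_clones, seed=seed, **frag)


# ---------------------------------------------------------------------------
# truth records and event sampling
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """The generating event behind one simulated clone."""

    clone_id: str
    line_id: str
    genotype: str
    nuclease: str
    event_class: str  # generator class
    footprint_class: str  # intact/deletion/insertion/delins taxonomy
    del_start: int
    del_end: int
    ins_seq: str
    mh_len_planted: int = 0
    mh_fallback: bool = False
    template_pos: int = -1
    template_orientation: str = ""
    template_unique: bool = False
    primer_len_planted: int = -1
    rendered_read: str = ""
    detectable: bool = False
    is_pcr_duplicate: bool = False

    @property
    def del_len(self) -> int:
        return self.del_end - self.del_start


def render_read(truth: TruthRecord, locus: TargetLocus) -> str:
    """Deterministic read assembly: left flank + insertion + right flank."""
    ref = locus.amplicon
    if not (0 <= truth.del_start <= truth.del_end <= len(ref)):
        raise ValueError(
            f"{truth.clone_id}: deletion interval [{truth.del_start},{truth.del_end}) "
            f"outside amplicon of length {len(ref)}"
        )
    return ref[: truth.del_start] + truth.ins_seq + ref[truth.del_end :]


def _occurrences(window: str, word: str) -> int:
    """Overlapping occurrences of ``word`` or its reverse complement."""
    def count(w: str) -> int:
        n, i = 0, window.find(w)
        while i != -1:
            n += 1
            i = window.find(w, i + 1)
        return n

    rc = revcomp(word)
    return count(word) + (count(rc) if rc != word else 0)


def _geom_trunc(rng: np.random.Generator, p: float, max_val: int) -> int:
    while True:
        v = int(rng.geometric(p))
        if v <= max_val:
            return v


def _deletion_split(rng: np.random.Generator, cut: int, L: int, ref_len: int) -> tuple[int, int]:
    """Uniform left/right split of an L-bp deletion straddling/abutting the cut."""
    lo = max(0, cut - L)
    hi = min(cut, ref_len - L)
    s = int(rng.integers(lo, hi + 1))
    return s, s + L


def _truth_primer_len(ref: str, s: int, t_pos: int, t_len: int, orientation: str) -> int:
    """Identity between left-flank 3' end and the template's upstream context."""
    flank = ref[:s]
    n = 0
    if orientation == "direct":
        while n < len(flank) and t_pos - 1 - n >= 0 and flank[-1 - n] == ref[t_pos - 1 - n]:
            n += 1
    else:
        end = t_pos + t_len
        while n < len(flank) and end + n < len(ref) and flank[-1 - n] == _COMP[ref[end + n]]:
            n += 1
    return n


class _FallbackCounter:
    def __init__(self) -> None:
        self.mh_fallbacks = 0
        self.template_fallbacks = 0


def sample_event(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    counter: _FallbackCounter | None = None,
) -> TruthRecord:
    """Draw one repair event (without rendering or ids).

    Deletions straddle or abut the cut with a uniformly drawn left/right
    split.  Microhomology-class deletions search locally for endpoints whose
    flanks share exactly the drawn m-mer, falling back to any shared m-mer
    and finally to m=0 (counted).  Templated insertions copy a window
    substring in the drawn orientation and are placed so that the planted
    primer-identity length is exact; insertion boundaries never extend the
    junction flank matches, so the planted event is the minimal footprint.
    """
    ref = cfg.locus.amplicon
    cut = cfg.locus.cut_pos
    counter = counter or _FallbackCounter()
    cls = rng.choice(EVENT_CLASS_NAMES, p=[cfg.class_weights[c] for c in EVENT_CLASS_NAMES])

    if cls == "intact":
        return TruthRecord("", "", cfg.genotype, cfg.nuclease, cls, "intact", cut, cut, "")

    if cls == "small_indel":
        if rng.random() < 0.7:
            L = int(rng.integers(1, 3))
            s, e = _deletion_split(rng, cut, L, len(ref))
            return TruthRecord("", "", cfg.genotype, cfg.nuclease, cls, "deletion", s, e, "")
        ins = _random_dna(rng, 1)
        return TruthRecord("", "", cfg.genotype, cfg.nuclease, cls, "insertion", cut, cut, ins)

    if cls == "mmej_deletion":
        L = cfg.del_len_model.sample(rng)
        m = int(rng.choice(len(cfg.mh_len_dist), p=cfg.mh_len_dist))

        def candidates(L2: int) -> tuple[list, list]:
            exact, atleast = [], []
            lo, hi = max(0, cut - L2), min(cut, len(ref) - L2)
            for s in range(lo, hi + 1):
                e = s + L2
                if m > 0 and not (e + m <= len(ref) and ref[s : s + m] == ref[e : e + m]):
                    continue
                right_blocked = e + m >= len(ref) or ref[s + m] != ref[e + m]
                left_blocked = s == 0 or ref[s - 1] != ref[e - 1]
                (exact if right_blocked and left_blocked else atleast).append((s, e))
            return exact, atleast

        # prefer the drawn length so planted lengths track the calibrated
        # model; widen to +/-2 bp only when it admits no m-mer placement
        pick = fallback = None
        lengths = [L2 for L2 in (L, L - 1, L + 1, L - 2, L + 2) if 1 <= L2 <= len(ref) - 1]
        for want_exact in (True, False):
            for L2 in lengths:
                cands = candidates(L2)[0 if want_exact else 1]
                if cands:
                    pick = cands[int(rng.integers(len(cands)))]
                    fallback = False
                    break
            if pick is not None:
                break
        if pick is None:
            counter.mh_fallbacks += 1
            pick = _deletion_split(rng, cut, L, len(ref))
            m, fallback = 0, True
        s, e = pick
        return TruthRecord(
            "", "", cfg.genotype, cfg.nuclease, cls, "deletion", s, e, "",
            mh_len_planted=m, mh_fallback=fallback,
        )

    # templated_insertion -----------------------------------------------
    ins_len = _geom_trunc(rng, cfg.ins_geom_p, cfg.ins_max_len)
    if rng.random() < cfg.p_del_with_ins:
        base = cfg.del_len_model.sample(rng)
        L_del = min(int(np.ceil(base * cfg.delins_del_multiplier)), cut, len(ref) - cut)
        L_del = max(L_del, 1)
    else:
        L_del = 0

    lo = max(0, cut - cfg.template_window)
    hi = min(len(ref), cut + cfg.template_window)

    if rng.random() < cfg.p_untemplated:
        # random word; verified absent (both orientations) from the window
        # when long enough that absence is achievable (short words always
        # occur somewhere in a 2*window_bp neighborhood)
        win = ref[lo:hi]
        s, e = _deletion_split(rng, cut, L_del, len(ref)) if L_del else (cut, cut)
        for _ in range(200):
            ins = _random_dna(rng, ins_len)
            if L_del:
                if ins[0] == ref[s] or ins[-1] == ref[e - 1]:
                    continue  # would shrink the minimal footprint
            elif ins[0] == ref[s] or (s > 0 and ins[-1] == ref[s - 1]):
                continue  # junction could shift and rotate the word
            if ins_len >= 8 and (ins in win or revcomp(ins) in win):
                continue
            break
        else:
            raise RuntimeError("could not draw an untemplated insertion")
        return TruthRecord(
            "", "", cfg.genotype, cfg.nuclease, cls,
            classify_event(e - s, ins), s, e, ins, primer_len_planted=-1,
        )

    orientation = "reverse" if rng.random() < cfg.p_reverse else "direct"
    if rng.random() < cfg.p_primed:
        want_k = int(rng.integers(2, 5))
    else:
        want_k = int(rng.integers(0, 2))

    if L_del:
        s_lo, s_hi = max(0, cut - L_del), min(cut, len(ref) - L_del)
        splits = list(range(s_lo, s_hi + 1))
    else:
        splits = [cut]
    t_positions = list(range(lo, hi - ins_len + 1))
    rng.shuffle(splits)
    rng.shuffle(t_positions)

    win = ref[lo:hi]

    def accept(s: int, t: int, exact_k: bool) -> TruthRecord | None:
        e = s + L_del
        word = ref[t : t + ins_len]
        ins = word if orientation == "direct" else revcomp(word)
        # the planted placement must be the unique (hence canonical) one:
        # an insertion boundary matching the adjacent reference base would
        # let the junction shift and rotate the inserted word
        if L_del:
            if ins[0] == ref[s] or ins[-1] == ref[e - 1]:
                return None
        else:
            if (s < len(ref) and ins[0] == ref[s]) or (s > 0 and ins[-1] == ref[s - 1]):
                return None
        k = _truth_primer_len(ref, s, t, ins_len, orientation)
        if exact_k and k != want_k:
            return None
        return TruthRecord(
            "", "", cfg.genotype, cfg.nuclease, cls,
            classify_event(e - s, ins), s, e, ins,
            template_pos=t, template_orientation=orientation,
            template_unique=_occurrences(win, ins) == 1,
            primer_len_planted=k,
        )

    for exact_k in (True, False):
        for s in splits:
            for t in t_positions:
                rec = accept(s, t, exact_k)
                if rec is not None:
                    if not exact_k:
                        counter.template_fallbacks += 1
                    return rec
    raise RuntimeError(
        f"could not place a {ins_len} bp templated insertion on locus "
        f"{cfg.locus.name}; amplicon too short for the requested event"
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_truth(cfg: SimulationConfig) -> list[TruthRecord]:
    """Sample ``n_clones`` truth records (with PCR-duplicate clones)."""
    rng = np.random.default_rng(cfg.seed)
    counter = _FallbackCounter()
    records: list[TruthRecord] = []
    per_line: dict[str, list[int]] = {}
    short = {"WT": "wt", "ku80": "k80", "parp1parp2": "p1p2", "ku80parp1parp2": "k80p1p2"}
    tag = short.get(cfg.genotype, cfg.genotype)
    for i in range(cfg.n_clones):
        line = f"{tag}-L{(i % cfg.n_lines) + 1}"
        clone_id = f"{tag}-{cfg.nuclease.split('-')[-1]}-c{i:05d}"
        prior = per_line.get(line, [])
        if prior and rng.random() < cfg.p_pcr_duplicate:
            src = records[prior[int(rng.integers(len(prior)))]]
            rec = replace(src, clone_id=clone_id, is_pcr_duplicate=True)
        else:
            rec = sample_event(cfg, rng, counter)
            rec.clone_id = clone_id
            rec.line_id = line
        rec.line_id = line
        rec.rendered_read = render_read(rec, cfg.locus)
        rec.detectable = is_detectable(rec.rendered_read, cfg.locus.enzyme)
        per_line.setdefault(line, []).append(len(records))
        records.append(rec)
    if counter.mh_fallbacks or counter.template_fallbacks:
        logger.info(
            "generator fallbacks: %d microhomology placements relaxed to m=0, "
            "%d templated insertions without exact primer identity",
            counter.mh_fallbacks,
            counter.template_fallbacks,
        )
    return records


def reads_from_truth(
    truth: Sequence[TruthRecord], cfg: SimulationConfig
) -> list[CloneRead]:
    """Clone reads for the caller; optional substitution noise on top."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 94]))
    out = []
    for rec in truth:
        seq = rec.rendered_read
        if cfg.sub_noise_rate > 0:
            chars = list(seq)
            for j in range(len(chars)):
                if rng.random() < cfg.sub_noise_rate:
                    chars[j] = str(rng.choice([b for b in "ACGT" if b != chars[j]]))
            seq = "".join(chars)
        out.append(
            CloneRead(rec.clone_id, rec.line_id, rec.genotype, rec.nuclease, seq)
        )
    return out


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in truth])


def generate_dataset(
    cfg: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[CloneRead], list[TruthRecord]]:
    """Generate reads + truth; optionally write FASTA / truth TSV / sample sheet.

    Outputs are byte-identical for identical (config, seed).
    """
    truth = generate_truth(cfg)
    reads = reads_from_truth(truth, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_reads_fasta, write_sample_sheet

        write_reads_fasta(reads, out / "reads.fasta")
        write_sample_sheet(reads, out / "samples.tsv")
        truth_to_frame(truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    return reads, truth
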