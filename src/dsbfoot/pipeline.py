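"""Stage orchestration: call -> dedupe -> digest filter -> annotate -> stats.

The analyze stage mirrors the wet-lab workflow: every clone is footprint-
called against the amplicon, identical footprints within a plant line are
collapsed to one mutagenesis event, the digest pre-selection optionally
removes events whose read retains the recognition site (``predigest``),
and the surviving events are annotated and contrasted between genotypes.
A run manifest records versions, thresholds, seeds and per-stage counts so
that every output is self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .annotate import annotate_all
from .caller import (
    CloneRead,
    ComplexCloneError,
    EventSet,
    Footprint,
    UnalignableCloneError,
    call_footprint,
    dedupe,
)
from .locus import TargetLocus, is_detectable
from .stats import (
    compare_genotypes,
    deletion_with_without_insertion,
    distributions_table,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    footprints: pd.DataFrame
    annotations: pd.DataFrame
    template_summary: pd.DataFrame
    stats_del: pd.DataFrame
    stats_ins: pd.DataFrame
    stats_del_with_ins: pd.DataFrame
    distributions: pd.DataFrame
    events: EventSet
    manifest: dict


def _footprints_frame(
    events: Sequence[Footprint], locus: TargetLocus
) -> pd.DataFrame:
    rows = []
    for fp in events:
        rows.append(
            {
                "clone_id": fp.clone_id,
                "line_id": fp.line_id,
                "genotype": fp.genotype,
                "nuclease": fp.nuclease,
                "event_class": fp.event_class,
                "del_start": fp.del_start,
                "del_end": fp.del_end,
                "del_len": fp.del_len,
                "ins_seq": fp.ins_seq,
                "mh_len": fp.mh_len,
                "shift_min": fp.shift_min,
                "shift_max": fp.shift_max,
                "detectable": is_detectable(fp.reconstruct(locus.amplicon), locus.enzyme),
            }
        )
    return pd.DataFrame(rows)


def analyze(
    locus: TargetLocus,
    reads: Sequence[CloneRead],
    *,
    predigest: bool = True,
    window_bp: int = 100,
    min_seed: int = 4,
    min_primer: int = 2,
    alpha: float = 0.05,
    max_radius: int = 250,
) -> AnalysisResult:
    """Run the full analysis chain on clone reads against one locus.

    With ``predigest`` (the default, mimicking enrichment of mutated
    molecules by digesting before PCR) only events whose reads lost the
    recognition site enter annotation and statistics.
    """
    min_anchor = min(len(locus.primer_fwd), len(locus.primer_rev))
    called: list[Footprint] = []
    unalignable = 0
    for read in reads:
        try:
            called.append(
                call_footprint(
                    locus.amplicon,
                    read,
                    min_anchor=min_anchor,
                    cut_pos=locus.cut_pos,
                    max_radius=max_radius,
                )
            )
        except (UnalignableCloneError, ComplexCloneError) as exc:
            logger.warning("excluding clone: %s", exc)
            unalignable += 1

    events = dedupe(called)
    n_after_dedupe = len(events)

    filtered_by_digest = 0
    if predigest:
        keep = []
        for fp in events.events:
            if is_detectable(fp.reconstruct(locus.amplicon), locus.enzyme):
                keep.append(fp)
            else:
                filtered_by_digest += 1
        events = EventSet(keep, events.duplicates_removed)

    # intact reads never enter annotation/statistics
    mutated = events.subset(lambda fp: fp.event_class != "intact")

    annotations, template_summary = annotate_all(
        mutated, locus, window_bp=window_bp, min_seed=min_seed, min_primer=min_primer
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats_del = compare_genotypes(mutated, "del_len", alpha=alpha)
        stats_ins = compare_genotypes(mutated, "ins_len", alpha=alpha)
        stats_dwi = deletion_with_without_insertion(mutated, alpha=alpha)
    distributions = distributions_table(mutated)

    manifest = {
        "tool": "dsbfoot",
        "version": __version__,
        "locus": locus.name,
        "enzyme": locus.enzyme.name,
        "predigest": predigest,
        "window_bp": window_bp,
        "min_seed": min_seed,
        "min_primer": min_primer,
        "alpha": alpha,
        "max_radius": max_radius,
        "counts": {
            "clones_read": len(reads),
            "unalignable": unalignable,
            "duplicates_removed": events.duplicates_removed,
            "events_after_dedup": n_after_dedupe,
            "filtered_by_digest": filtered_by_digest,
            "events_analyzed": len(events),
            "mutated_events": len(mutated),
        },
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    counts = manifest["counts"]
    assert (
        counts["clones_read"]
        == counts["events_after_dedup"] + counts["duplicates_removed"] + counts["unalignable"]
    ), "manifest count conservation violated"

    return AnalysisResult(
        footprints=_footprints_frame(called, locus),
        annotations=annotations,
        template_summary=template_summary,
        stats_del=stats_del,
        stats_ins=stats_ins,
        stats_del_with_ins=stats_dwi,
        distributions=distributions,
        events=events,
        manifest=manifest,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: AnalysisResult, out_dir: str | Path) -> None:
    """Write all TSV outputs plus JSON mirrors and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "footprints": result.footprints,
        "annotations": result.annotations,
        "template_summary": result.template_summary,
        "stats_del": result.stats_del,
        "stats_ins": result.stats_ins,
        "stats_del_with_ins": result.stats_del_with_ins,
        "distributions": result.distributions,
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
        df.to_json(out / f"{name}.json", orient="records", indent=2)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2) + "\n")


def render_report(out_dir: str | Path) -> str:
    """Human-readable summary assembled from a finished analyze directory.

    Numbers are re-read from the stage TSVs so the report always matches
    them byte for byte; missing stage outputs raise with the file name.
    """
    out = Path(out_dir)
    needed = {
        name: out / f"{name}.tsv"
        for name in ("distributions", "stats_del", "stats_ins",
                     "stats_del_with_ins", "template_summary")
    }
    for name, path in needed.items():
        if not path.exists():
            raise FileNotFoundError(f"missing analyze output: {path}")
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing analyze output: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())

    def table(path: Path) -> str:
        df = pd.read_csv(path, sep="\t")
        return df.to_string(index=False) if len(df) else "  (no data)"

    lines = [
        f"dsbfoot {manifest['version']} report",
        f"locus {manifest['locus']} / {manifest['enzyme']}, "
        f"predigest={manifest['predigest']}, alpha={manifest['alpha']}",
        f"counts: {json.dumps(manifest['counts'])}",
        "",
        "Deletion-length distributions (per genotype x nuclease)",
        table(needed["distributions"]),
        "",
        "Deletion-length contrasts (WT vs mutants, two-tailed Mann-Whitney U)",
        table(needed["stats_del"]),
        "",
        "Insertion-length contrasts (pooled targets)",
        table(needed["stats_ins"]),
        "",
        "Deletions with vs without insertions (pooled)",
        table(needed["stats_del_with_ins"]),
        "",
        "Templated insertions per genotype",
        table(needed["template_summary"]),
        "",
    ]
    text = "\n".join(lines)
    (out / "report.txt").write_text(text)
    return text
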