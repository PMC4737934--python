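"""End-to-end orchestration: simulated or real FASTQ in, linkage out.

``process_reads`` chains the read-processing stages in the standard
order (demultiplex, merge, quality filter, de novo chimera removal,
structure validation, V4 trimming, optional barcode collapsing) and keeps
per-stage accounting. ``run_spikein_experiment`` reproduces the in-silico
spike-in design: one community, positive and negative control beads, a
barcode-16S assay and a targeted assay, processed end to end into a
specificity report and a function-phylotype linkage table.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from epicpcr.construct import FusionConstructSpec, DEFAULT_CONSTRUCT
from epicpcr.otu import build_linkage
from epicpcr.readproc import (
    CollapsedPair,
    MergedRead,
    ParsedFusion,
    Rejection,
    collapse_barcode_pairs,
    demultiplex,
    dereplicate,
    detect_chimeras,
    merge_pairs,
    quality_filter,
    trim_v4,
    validate_structure,
)
from epicpcr.simulate import (
    ControlBead,
    SimConfig,
    SimReadPair,
    SimResult,
    Taxon,
    make_default_community,
    make_default_controls,
    simulate_experiment,
)
from epicpcr.spikein import classify_controls, specificity_report


def _open_maybe_gz(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> list[SimReadPair]:
    """Load a paired FASTQ (optionally gzipped) into read-pair records."""
    pairs = []
    with _open_maybe_gz(r1) as f1, _open_maybe_gz(r2) as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            if rec1.id != rec2.id:
                raise ValueError(f"unpaired reads: {rec1.id} vs {rec2.id}")
            pairs.append(
                SimReadPair(
                    read_id=rec1.id,
                    sample_id="",
                    r1_seq=str(rec1.seq),
                    r1_qual=np.asarray(
                        rec1.letter_annotations["phred_quality"], dtype=np.int16
                    ),
                    r2_seq=str(rec2.seq),
                    r2_qual=np.asarray(
                        rec2.letter_annotations["phred_quality"], dtype=np.int16
                    ),
                )
            )
    return pairs


@dataclass
class SampleResult:
    """Processed output of one sample: surviving reads and accounting."""

    sample_id: str
    parsed: list[ParsedFusion]
    collapsed: list[CollapsedPair] | None
    stats: dict[str, int]
    reject_reasons: Counter
    chimeric_read_ids: set[str]


def process_reads(
    pairs: Sequence[SimReadPair],
    sample_table: dict[str, str],
    construct: FusionConstructSpec = DEFAULT_CONSTRUCT,
    assay: str = "target16s",
    q_threshold: float = 20.0,
    max_mm_per_element: int = 1,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    demux_max_mm: int = 0,
    run_chimera_check: bool = True,
    collapse: bool | None = None,
) -> dict[str, SampleResult]:
    """Run the full read-processing pipeline; one result per sample.

    ``collapse`` defaults to collapsing identical (barcode, 16S) pairs in
    the barcode assay and not in the targeted assay.
    """
    if collapse is None:
        collapse = assay == "barcode16s"
    demuxed = demultiplex(pairs, sample_table, max_mm=demux_max_mm)
    out: dict[str, SampleResult] = {}
    for sample_id, sample_pairs in demuxed.items():
        if sample_id == "unassigned":
            continue
        stats = {"input_pairs": len(sample_pairs)}
        reasons: Counter = Counter()

        merged: list[MergedRead] = []
        for rp in sample_pairs:
            m = merge_pairs(
                rp.r1_seq,
                rp.r1_qual,
                rp.r2_seq,
                rp.r2_qual,
                read_id=rp.read_id,
                sample_id=sample_id,
                min_overlap=min_overlap,
                max_mismatch_frac=max_mismatch_frac,
            )
            if isinstance(m, Rejection):
                reasons[m.reason] += 1
            else:
                merged.append(m)
        stats["merged"] = len(merged)

        kept = [m for m in merged if quality_filter(m, q_threshold)]
        stats["quality_passed"] = len(kept)

        chimeric_ids: set[str] = set()
        if run_chimera_check and kept:
            uniques = dereplicate((m.read_id, m.seq) for m in kept)
            flags = detect_chimeras(uniques)
            flagged_seqs = {
                uniques[i][1]
                for i in range(len(uniques))
                if bool(flags.iloc[i]["flagged"])
            }
            if flagged_seqs:
                chimeric_ids = {m.read_id for m in kept if m.seq in flagged_seqs}
                kept = [m for m in kept if m.read_id not in chimeric_ids]
        stats["chimera_passed"] = len(kept)

        parsed: list[ParsedFusion] = []
        for m in kept:
            res = validate_structure(m, construct, assay, max_mm_per_element)
            if isinstance(res, Rejection):
                reasons[res.reason] += 1
                continue
            res = trim_v4(res, construct, max_mm_per_element)
            if isinstance(res, Rejection):
                reasons[res.reason] += 1
                continue
            parsed.append(res)
        stats["structure_passed"] = len(parsed)

        collapsed = collapse_barcode_pairs(parsed) if (collapse and parsed) else (
            [] if collapse else None
        )
        if collapsed is not None:
            stats["collapsed_pairs"] = len(collapsed)

        out[sample_id] = SampleResult(
            sample_id=sample_id,
            parsed=parsed,
            collapsed=collapsed,
            stats=stats,
            reject_reasons=reasons,
            chimeric_read_ids=chimeric_ids,
        )
    return out


@dataclass
class SpikeinExperiment:
    """Everything produced by one in-silico spike-in experiment."""

    community: list[Taxon]
    controls: list[ControlBead]
    sims: dict[str, SimResult]
    results: dict[str, SampleResult]
    classified: dict[str, pd.DataFrame]
    report: object  # SpecificityReport
    linkage: pd.DataFrame


def run_spikein_experiment(
    seed: int = 0,
    n_droplets: int = 10_000,
    n_taxa: int = 12,
    frac_with_target: float = 0.25,
    construct: FusionConstructSpec = DEFAULT_CONSTRUCT,
    config_overrides: dict | None = None,
) -> SpikeinExperiment:
    """Simulate and process the two-assay spike-in design end to end.

    The same community and control beads are assayed twice: once with the
    random-barcode fusion (untargeted, captures everything that received
    a barcode molecule) and once with the functional-gene fusion
    (targeted, captures only target carriers and positive beads). Both
    read sets run through the full pipeline, reads are classified against
    the control mock-16S segments, and the targeted assay additionally
    yields a function-phylotype linkage table.
    """
    overrides = dict(config_overrides or {})
    community = make_default_community(
        n_taxa=n_taxa,
        frac_with_target=frac_with_target,
        seed=seed,
        construct=construct,
    )
    controls = make_default_controls(construct)

    sims: dict[str, SimResult] = {}
    results: dict[str, SampleResult] = {}
    classified: dict[str, pd.DataFrame] = {}
    for k, assay in enumerate(("barcode16s", "target16s")):
        cfg = SimConfig(
            seed=(seed * 7 + k + 1) % (2**31),
            n_droplets=n_droplets,
            assay=assay,
            **overrides,
        )
        sim = simulate_experiment(community, cfg, controls, construct)
        sims[assay] = sim
        processed = process_reads(
            sim.read_pairs,
            sample_table={cfg.sample_id: cfg.sample_barcode},
            construct=construct,
            assay=assay,
        )
        res = processed.get(cfg.sample_id) or SampleResult(
            cfg.sample_id, [], None, {}, Counter(), set()
        )
        results[assay] = res
        classified[assay] = classify_controls(res.parsed, controls, construct)

    report = specificity_report(classified)

    refs = [(t.taxon_id, t.ssu_seq) for t in community]
    linkage, _, _ = build_linkage(results["target16s"].parsed, references=refs)
    return SpikeinExperiment(
        community=community,
        controls=controls,
        sims=sims,
        results=results,
        classified=classified,
        report=report,
        linkage=linkage,
    )
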