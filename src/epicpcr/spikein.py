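"""Spike-in specificity accounting and epicPCR-vs-bulk recovery comparison.

Synthetic control beads calibrate the central claim of an emulsion fusion
assay: a negative bead carries only a mock-16S, so in a targeted
(functional-gene) assay it must never appear in a fusion product, while
the untargeted barcode assay should capture environmental, positive and
negative sequences alike. This module classifies processed reads against
the control sequences and tabulates the counts, and compares group-level
recovery between bulk 16S surveys and fusion assays run with and without
extra lysis treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from epicpcr.construct import FusionConstructSpec
from epicpcr.otu import nearest_reference, pairwise_identity
from epicpcr.readproc import ParsedFusion, Rejection, trim_v4
from epicpcr.simulate import ControlBead

POSITIVE = "positive_control"
NEGATIVE = "negative_control"
ENVIRONMENTAL = "environmental"


def control_reference_segments(
    controls: Sequence[ControlBead], construct: FusionConstructSpec
) -> list[tuple[str, str]]:
    """Trimmed V4 segments of the control mock-16S sequences.

    Processed reads carry only the anchored ``trim_len`` segment, so the
    classifier compares like with like.
    """
    refs = []
    for c in controls:
        dummy = ParsedFusion(
            read_id=c.control_id,
            sample_id="",
            target_segment="",
            ssu_segment=c.ssu_seq,
            barcode=None,
            bridge_mismatches=0,
        )
        trimmed = trim_v4(dummy, construct)
        if isinstance(trimmed, Rejection):
            raise ValueError(f"control {c.control_id} lacks a trimmable V4 segment")
        refs.append((c.control_id, trimmed.ssu_segment))
    return refs


def classify_controls(
    parsed: Sequence[ParsedFusion],
    controls: Sequence[ControlBead],
    construct: FusionConstructSpec,
    min_identity: float = 0.97,
) -> pd.DataFrame:
    """Assign each read's 16S segment to a control class or environmental.

    A read is classified to the control whose trimmed mock-16S it matches
    at >= ``min_identity``; otherwise it is environmental. The control set
    must be mutually distinct below the cutoff, or classes would overlap.
    """
    refs = control_reference_segments(controls, construct)
    for i, (ida, sa) in enumerate(refs):
        for idb, sb in refs[i + 1 :]:
            if pairwise_identity(sa, sb) >= min_identity:
                raise ValueError(
                    f"controls {ida} and {idb} are not distinct at {min_identity:.2f}"
                )
    kind = {c.control_id: c.kind for c in controls}

    cache: dict[str, str] = {}
    rows = []
    for p in parsed:
        cls = cache.get(p.ssu_segment)
        if cls is None:
            rid, ident = nearest_reference(p.ssu_segment, refs)
            if ident >= min_identity:
                cls = POSITIVE if kind[rid] == "positive" else NEGATIVE
            else:
                cls = ENVIRONMENTAL
            cache[p.ssu_segment] = cls
        rows.append({"read_id": p.read_id, "class": cls})
    return pd.DataFrame(rows, columns=["read_id", "class"])


@dataclass(frozen=True)
class SpecificityReport:
    """Per-assay control/environmental read counts.

    ``negative_in_target_assay`` is the headline specificity number: with
    droplet compartments intact it must be zero, because negative beads
    have no target to fuse from.
    """

    counts: Mapping[str, Mapping[str, int]]  # assay -> class -> reads
    negative_in_target_assay: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"assay": assay, "class": cls, "reads": n}
            for assay, by_cls in self.counts.items()
            for cls, n in by_cls.items()
        ]
        return pd.DataFrame(rows, columns=["assay", "class", "reads"])


def specificity_report(
    classified_by_assay: Mapping[str, pd.DataFrame]
) -> SpecificityReport:
    """Tabulate class counts per assay from ``classify_controls`` outputs."""
    counts: dict[str, dict[str, int]] = {}
    for assay, df in classified_by_assay.items():
        by_cls = {cls: 0 for cls in (POSITIVE, NEGATIVE, ENVIRONMENTAL)}
        if len(df):
            by_cls.update(df["class"].value_counts().to_dict())
        counts[assay] = by_cls
    neg_in_target = counts.get("target16s", {}).get(NEGATIVE, 0)
    return SpecificityReport(counts=counts, negative_in_target_assay=neg_in_target)


def recovery_compare(
    epic_tables: Mapping[str, pd.DataFrame],
    bulk_table: pd.DataFrame,
    min_reads: int = 2,
) -> pd.DataFrame:
    """Group-level presence/absence across bulk 16S and fusion treatments.

    Tables have columns ``group`` (taxon group, e.g. phylum), ``sample``
    and ``count`` (OTUs or reads per group). A group counts as present in
    a fusion assay at >= ``min_reads`` to damp singleton noise; bulk
    presence is any nonzero count. Returns one row per (group, sample,
    treatment).
    """
    for name, df in list(epic_tables.items()) + [("bulk", bulk_table)]:
        missing = {"group", "sample", "count"} - set(df.columns)
        if missing:
            raise ValueError(f"table {name!r} lacks columns {sorted(missing)}")
    bulk_groups = set(bulk_table["group"])
    epic_groups = set().union(*(set(df["group"]) for df in epic_tables.values()))
    if epic_groups and bulk_groups and not (bulk_groups & epic_groups):
        raise ValueError("bulk and fusion tables share no group labels")

    bulk = bulk_table.groupby(["group", "sample"])["count"].sum()
    keys = set(bulk.index)
    for df in epic_tables.values():
        keys |= set(df.groupby(["group", "sample"])["count"].sum().index)

    rows = []
    for treatment, df in epic_tables.items():
        epic = df.groupby(["group", "sample"])["count"].sum()
        for group, sample in sorted(keys):
            b = int(bulk.get((group, sample), 0))
            e = int(epic.get((group, sample), 0))
            rows.append(
                {
                    "group": group,
                    "sample": sample,
                    "treatment": treatment,
                    "present_in_bulk": b > 0,
                    "present_in_epic": e >= min_reads,
                    "epic_otu_count": e,
                    "bulk_otu_count": b,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "sample",
            "treatment",
            "present_in_bulk",
            "present_in_epic",
            "epic_otu_count",
            "bulk_otu_count",
        ],
    )
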