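"""Fusion-read processing: demultiplex, merge, filter, parse, collapse.

The pipeline follows the standard analysis of an emulsion fusion-PCR
library: split reads by sample barcode, stitch the paired ends, drop
low-quality merges, flag de novo chimeras, keep only reads that match the
expected fusion grammar [F1 | target-or-barcode | bridge | 16S | rc(R2)],
trim the 16S side to a fixed-length V4 segment behind a conserved anchor,
and collapse identical (droplet barcode, 16S) pairs so that droplets that
amplified exponentially more than others count once.

Structure matching is ungapped sliding-window comparison with IUPAC-aware
mismatch counting; this matches the substitution-dominated error profile
of short-insert Illumina amplicon reads.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from epicpcr.construct import FusionConstructSpec
from epicpcr.iupac import encode, reverse_complement

# reads are plain ACGTN; N never matches a primer code
_READ_LUT = np.zeros(256, dtype=np.uint8)
for _b, _m in zip(b"ACGT", (1, 2, 4, 8)):
    _READ_LUT[_b] = _m
    _READ_LUT[_b + 32] = _m


def encode_read(seq: str) -> np.ndarray:
    """Encode a read; ambiguous/N bases get mask 0 (mismatch everything)."""
    return _READ_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class MergedRead:
    read_id: str
    seq: str
    quals: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("sequence and quality lengths differ")

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quals))


@dataclass
class ParsedFusion:
    """A validated fusion read split into its segments."""

    read_id: str
    sample_id: str
    target_segment: str
    ssu_segment: str
    barcode: str | None
    bridge_mismatches: int
    mean_quality: float = 0.0


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


@dataclass(frozen=True)
class CollapsedPair:
    barcode: str
    ssu_segment: str
    read_count: int
    representative_read_id: str


# ---------------------------------------------------------------------------
# demultiplexing


def demultiplex(
    pairs: Iterable,
    barcode_table: dict[str, str],
    max_mm: int = 0,
) -> dict[str, list]:
    """Assign read pairs to samples by the R1 prefix barcode.

    ``pairs`` is an iterable of objects with ``r1_seq``/``r1_qual`` (and
    the rest of the pair left untouched); assigned pairs get the barcode
    stripped off R1. Reads matching no barcode within ``max_mm``
    substitutions — or matching two equally well — go to ``"unassigned"``.
    """
    samples = list(barcode_table)
    bcs = [barcode_table[s] for s in samples]
    if len(set(bcs)) != len(bcs):
        raise ValueError("duplicate sample barcodes")
    lens = {len(b) for b in bcs}
    if len(lens) != 1:
        raise ValueError("sample barcodes must share one length")
    blen = lens.pop()
    enc = [encode_read(b) for b in bcs]

    out: dict[str, list] = {s: [] for s in samples}
    out["unassigned"] = []
    for rp in pairs:
        prefix = encode_read(rp.r1_seq[:blen])
        if len(prefix) < blen:
            out["unassigned"].append(rp)
            continue
        mms = [int(((prefix & e) == 0).sum()) for e in enc]
        best = min(mms)
        if best > max_mm or mms.count(best) > 1:
            out["unassigned"].append(rp)
            continue
        s = samples[mms.index(best)]
        stripped = type(rp)(
            read_id=rp.read_id,
            sample_id=s,
            r1_seq=rp.r1_seq[blen:],
            r1_qual=rp.r1_qual[blen:],
            r2_seq=rp.r2_seq,
            r2_qual=rp.r2_qual,
        )
        out[s].append(stripped)
    return out


# ---------------------------------------------------------------------------
# pair merging


def merge_pairs(
    fwd_seq: str,
    fwd_qual: np.ndarray,
    rev_seq: str,
    rev_qual: np.ndarray,
    read_id: str = "",
    sample_id: str = "",
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | Rejection:
    """Stitch a read pair over the longest qualifying ungapped overlap.

    Overlap lengths are scanned from longest to shortest; the first with a
    mismatch fraction <= ``max_mismatch_frac`` wins (random sequence
    disagrees at ~75% of positions, so spurious long overlaps do not
    qualify). Disagreeing overlap bases resolve to the higher-quality
    base, ties to the forward read.
    """
    rc = reverse_complement(rev_seq)
    rcq = rev_qual[::-1]
    a = np.frombuffer(fwd_seq.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(rc.encode("ascii"), dtype=np.uint8)
    max_ov = min(len(a), len(b))
    for ov in range(max_ov, min_overlap - 1, -1):
        mism = a[len(a) - ov :] != b[:ov]
        n_mm = int(mism.sum())
        if n_mm / ov <= max_mismatch_frac:
            head = a[: len(a) - ov]
            tail = b[ov:]
            fq = fwd_qual[len(a) - ov :]
            rq = rcq[:ov]
            take_rev = mism & (rq > fq)
            cons = np.where(take_rev, b[:ov], a[len(a) - ov :])
            cons_q = np.maximum(fq, rq)
            seq = (head.tobytes() + cons.tobytes() + tail.tobytes()).decode("ascii")
            quals = np.concatenate([fwd_qual[: len(a) - ov], cons_q, rcq[ov:]])
            return MergedRead(read_id=read_id, seq=seq, quals=quals, sample_id=sample_id)
    return Rejection(read_id, "no_overlap")


# ---------------------------------------------------------------------------
# quality filter


def quality_filter(
    read: MergedRead, q_threshold: float = 20.0, max_n: int = 0
) -> bool:
    """Keep iff mean Phred strictly exceeds the threshold and N count <= max_n."""
    if read.seq.upper().count("N") > max_n:
        return False
    return read.mean_quality > q_threshold


# ---------------------------------------------------------------------------
# de novo chimera flagging


def _top2_per_column(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (best value, best row, second value, second row) of a 2-D array."""
    a1 = m.argmax(axis=0)
    cols = np.arange(m.shape[1])
    v1 = m[a1, cols]
    masked = m.copy()
    masked[a1, cols] = np.iinfo(m.dtype).min
    a2 = masked.argmax(axis=0)
    v2 = masked[a2, cols]
    return v1, a1, v2, a2


def detect_chimeras(
    uniques: Sequence[tuple[str, str, float]],
    parent_ratio: float = 2.0,
    min_divergence: float = 0.02,
    min_composite_identity: float = 0.99,
    n_chunks: int = 8,
    max_candidates: int = 64,
) -> pd.DataFrame:
    """Flag unique sequences explainable as two-parent single crossovers.

    ``uniques`` are (seq_id, sequence, abundance) records, typically a
    dereplicated read set. A query is flagged when two distinct parents,
    each at >= ``parent_ratio`` times the query abundance and of the same
    length, admit a crossover whose composite identity to the query is
    >= ``min_composite_identity`` and exceeds the best single-parent
    identity by >= ``min_divergence``. Parents amplify earlier and more
    than their chimeric offspring, hence the abundance gate.

    Candidate parents are prescreened by exact shared sequence chunks
    (``n_chunks`` non-overlapping windows), keeping the ``max_candidates``
    best by shared-chunk count then abundance — the usual de novo
    shortcut: a crossover product shares whole chunks with each parent,
    and any same-side lookalike works as a stand-in parent.

    Returns a DataFrame with seq_id, flagged, best composite and best
    single-parent identities (identities are 0 where no pair of eligible
    parents exists or the early single-parent exit fired).
    """
    by_len: dict[int, list[int]] = {}
    for i, (_, seq, _) in enumerate(uniques):
        by_len.setdefault(len(seq), []).append(i)

    mats: dict[int, np.ndarray] = {}
    chunk_index: dict[tuple[int, int, str], list[int]] = {}
    for L, idxs in by_len.items():
        mats[L] = np.stack(
            [np.frombuffer(uniques[i][1].encode("ascii"), dtype=np.uint8) for i in idxs]
        )
        clen = max(L // n_chunks, 1)
        for row, i in enumerate(idxs):
            seq = uniques[i][1]
            for c in range(n_chunks):
                key = (L, c, seq[c * clen : (c + 1) * clen])
                chunk_index.setdefault(key, []).append(row)

    abundances = np.array([u[2] for u in uniques])
    # chunks from constant construct regions index thousands of sequences;
    # keep only the most abundant per posting list — an eligible parent is
    # always at least as abundant as the query it explains
    for key, rows_ in chunk_index.items():
        if len(rows_) > 2 * max_candidates:
            L = key[0]
            ab_group = abundances[by_len[L]]
            rows_.sort(key=lambda r: -ab_group[r])
            del rows_[2 * max_candidates :]

    # lexicographic orders give O(log n) access to the sequences sharing
    # the longest exact prefix/suffix with a query — the natural parent
    # candidates on each side of a crossover
    fwd_sorted: dict[int, list[tuple[str, int]]] = {}
    rev_sorted: dict[int, list[tuple[str, int]]] = {}
    for L, idxs in by_len.items():
        fwd_sorted[L] = sorted((uniques[i][1], r) for r, i in enumerate(idxs))
        rev_sorted[L] = sorted((uniques[i][1][::-1], r) for r, i in enumerate(idxs))

    def _neighbors(order: list[tuple[str, int]], key: str, width: int = 16) -> list[int]:
        pos = bisect.bisect_left(order, (key, -1))
        return [r for _, r in order[max(0, pos - width) : pos + width]]

    # visit in decreasing abundance so that chimeras are unmasked before
    # their own error variants, and never serve as parents themselves
    flagged_ids: set[int] = set()
    order = sorted(range(len(uniques)), key=lambda i: (-uniques[i][2], uniques[i][0]))
    results: dict[int, tuple] = {}
    for qi in order:
        qid, qseq, qab = uniques[qi]
        L = len(qseq)
        idxs = by_len[L]
        ab_group = abundances[idxs]
        clen = max(L // n_chunks, 1)
        shared: dict[int, int] = {}
        for c in range(n_chunks):
            for row in chunk_index.get((L, c, qseq[c * clen : (c + 1) * clen]), ()):
                shared[row] = shared.get(row, 0) + 1
        for row in _neighbors(fwd_sorted[L], qseq):
            shared[row] = shared.get(row, 0) + 1
        for row in _neighbors(rev_sorted[L], qseq[::-1]):
            shared[row] = shared.get(row, 0) + 1
        cand = [
            row
            for row in shared
            if idxs[row] != qi
            and idxs[row] not in flagged_ids
            and ab_group[row] >= parent_ratio * qab
        ]
        if len(cand) < 2:
            results[qi] = (qid, False, 0.0, 0.0)
            continue
        cand.sort(key=lambda r: (-shared[r], -ab_group[r]))
        cand = cand[:max_candidates]

        qarr = np.frombuffer(qseq.encode("ascii"), dtype=np.uint8)
        mat = mats[L][cand]
        match = mat == qarr  # C x L
        totals = match.sum(axis=1)
        best_single = float(totals.max()) / L
        if best_single + min_divergence > 1.0:
            # a near-identical parent explains the query on its own
            results[qi] = (qid, False, 0.0, best_single)
            continue
        pref = np.zeros((match.shape[0], L + 1), dtype=np.int32)
        np.cumsum(match, axis=1, out=pref[:, 1:])
        suf = (totals[:, None] - pref).astype(np.int32)  # matches in [k:]
        ks = np.arange(1, L)
        p1v, p1i, p2v, _ = _top2_per_column(pref[:, ks])
        s1v, s1i, s2v, _ = _top2_per_column(suf[:, ks])
        same = p1i == s1i
        composite = np.where(same, np.maximum(p2v + s1v, p1v + s2v), p1v + s1v)
        best_comp = float(composite.max()) / L
        flagged = (
            best_comp >= min_composite_identity
            and best_comp >= best_single + min_divergence
        )
        if flagged:
            flagged_ids.add(qi)
        results[qi] = (qid, bool(flagged), best_comp, best_single)
    rows = [results[i] for i in range(len(uniques))]
    return pd.DataFrame(
        rows, columns=["seq_id", "flagged", "composite_identity", "single_identity"]
    )


# ---------------------------------------------------------------------------
# structure validation and trimming


def _scan_windows(read_masks: np.ndarray, elem_masks: np.ndarray) -> np.ndarray:
    """Mismatch count of an element at every window start of the read."""
    le = len(elem_masks)
    if len(read_masks) < le:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(read_masks, le)
    return ((win & elem_masks) == 0).sum(axis=1)


def validate_structure(
    read: MergedRead,
    construct: FusionConstructSpec,
    assay: str = "target16s",
    max_mm_per_element: int = 1,
) -> ParsedFusion | Rejection:
    """Split a merged read by the fusion grammar, or reject with a reason.

    Checks, in order: the F1 prefix, a unique internal bridge hit, room
    for a 16S segment, and the rc(R2) suffix. In the barcode assay the
    span between F1 and the bridge must be exactly the barcode length.
    Reason codes: ``f1``, ``bridge``, ``bridge_ambiguous``,
    ``missing_ssu``, ``r2``, ``barcode_len``.
    """
    if assay not in ("target16s", "barcode16s"):
        raise ValueError("assay must be 'target16s' or 'barcode16s'")
    r = encode_read(read.seq)
    f1 = encode(construct.f1)
    bridge = encode(construct.bridge)
    r2rc = encode(reverse_complement(construct.r2))

    if len(r) < len(f1) + len(bridge) + len(r2rc):
        return Rejection(read.read_id, "missing_ssu")

    if int(((r[: len(f1)] & f1) == 0).sum()) > max_mm_per_element:
        return Rejection(read.read_id, "f1")

    interior = r[len(f1) :]
    mms = _scan_windows(interior, bridge)
    hits = np.flatnonzero(mms <= max_mm_per_element)
    if hits.size == 0:
        return Rejection(read.read_id, "bridge")
    if hits.size > 1:
        return Rejection(read.read_id, "bridge_ambiguous")
    bstart = len(construct.f1) + int(hits[0])
    bend = bstart + len(construct.bridge)

    ssu_end = len(r) - len(r2rc)
    if ssu_end <= bend:
        return Rejection(read.read_id, "missing_ssu")
    if int(((r[ssu_end:] & r2rc) == 0).sum()) > max_mm_per_element:
        return Rejection(read.read_id, "r2")

    target = read.seq[len(construct.f1) : bstart]
    barcode: str | None = None
    if assay == "barcode16s":
        if len(target) != construct.barcode_len:
            return Rejection(read.read_id, "barcode_len")
        barcode = target
    return ParsedFusion(
        read_id=read.read_id,
        sample_id=read.sample_id,
        target_segment=target,
        ssu_segment=read.seq[bend:ssu_end],
        barcode=barcode,
        bridge_mismatches=int(mms[hits[0]]),
        mean_quality=read.mean_quality,
    )


def trim_v4(
    parsed: ParsedFusion,
    construct: FusionConstructSpec,
    max_mm_per_element: int = 1,
) -> ParsedFusion | Rejection:
    """Trim the 16S segment to ``trim_len`` bases after the V4 anchor.

    The anchor is located by IUPAC-aware ungapped scan (best hit, then
    leftmost); reads whose post-anchor span is shorter than ``trim_len``
    are rejected. Reason codes: ``anchor``, ``short_ssu``.
    """
    seg = encode_read(parsed.ssu_segment)
    anchor = encode(construct.anchor_motif)
    mms = _scan_windows(seg, anchor)
    if mms.size == 0:
        return Rejection(parsed.read_id, "anchor")
    best = int(mms.min())
    if best > max_mm_per_element:
        return Rejection(parsed.read_id, "anchor")
    start = int(np.flatnonzero(mms == best)[0]) + len(construct.anchor_motif)
    if len(parsed.ssu_segment) - start < construct.trim_len:
        return Rejection(parsed.read_id, "short_ssu")
    return ParsedFusion(
        read_id=parsed.read_id,
        sample_id=parsed.sample_id,
        target_segment=parsed.target_segment,
        ssu_segment=parsed.ssu_segment[start : start + construct.trim_len],
        barcode=parsed.barcode,
        bridge_mismatches=parsed.bridge_mismatches,
        mean_quality=parsed.mean_quality,
    )


# ---------------------------------------------------------------------------
# barcode collapsing


def collapse_barcode_pairs(parsed: Iterable[ParsedFusion]) -> list[CollapsedPair]:
    """One record per exact (droplet barcode, 16S segment) pair.

    The representative is the member read with the highest mean quality
    (ties to the lexicographically smallest read id), so collapsing is
    independent of input order. Idempotent by construction.
    """
    groups: dict[tuple[str, str], list[ParsedFusion]] = {}
    for p in parsed:
        if p.barcode is None:
            raise ValueError(f"{p.read_id}: no barcode; collapse applies to barcode-16S reads")
        groups.setdefault((p.barcode, p.ssu_segment), []).append(p)
    out = []
    for (bc, ssu), members in sorted(groups.items()):
        rep = min(members, key=lambda p: (-p.mean_quality, p.read_id))
        out.append(
            CollapsedPair(
                barcode=bc,
                ssu_segment=ssu,
                read_count=len(members),
                representative_read_id=rep.read_id,
            )
        )
    return out


def dereplicate(seqs: Iterable[tuple[str, str]]) -> list[tuple[str, str, float]]:
    """Collapse identical sequences: (id, seq) -> (first_id, seq, count)."""
    counts: dict[str, list] = {}
    for sid, seq in seqs:
        if seq in counts:
            counts[seq][1] += 1
            if sid < counts[seq][0]:
                counts[seq][0] = sid
        else:
            counts[seq] = [sid, 1]
    return [(v[0], seq, float(v[1])) for seq, v in counts.items()]
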