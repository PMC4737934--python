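"""Pairwise identity, greedy centroid OTU clustering and linkage tables.

Identity is computed from a glocal alignment: the shorter sequence (an
anchored, fixed-length amplicon segment) aligns end to end, terminal
gaps are free only in the longer sequence (e.g. a full-length reference
gene), and internal gaps count as mismatch columns. Clustering is the
classic abundance-sorted greedy
centroid rule: sequences are visited in decreasing abundance and join the
first centroid within the identity threshold, otherwise found a new
cluster — the exact rule, with no word-length heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from epicpcr.readproc import ParsedFusion

_GAP = 2  # linear gap penalty; match +1, mismatch -1


def _score_matrix(a: str, b: str) -> np.ndarray:
    """Glocal DP matrix: ``a`` aligns globally, end gaps free in ``b`` only.

    H is (len(a)+1) x (len(b)+1); row vectorized with the running-maximum
    trick for the linear gap penalty.
    """
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    n, m = len(aa), len(bb)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    jj = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        s = np.where(bb == aa[i - 1], 1, -1).astype(np.int32)
        c = np.empty(m + 1, dtype=np.int32)
        c[0] = H[i - 1, 0] - _GAP  # consuming `a` always costs
        c[1:] = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] - _GAP)
        t = c + _GAP * jj
        H[i] = np.maximum.accumulate(t) - _GAP * jj
    return H


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching columns in the best glocal alignment.

    The shorter sequence must align end to end (anchored amplicon
    segments carry signal along their whole length); terminal gaps are
    free in the longer sequence only and excluded from the column count,
    while internal gaps count as mismatch columns. Match +1, mismatch -1,
    gap -2; traceback prefers diagonal, then gap-in-longer, then
    gap-in-shorter; the end column maximizes (score, coverage). Symmetric
    in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    if len(a) == len(b):
        # one substitution apart: the ungapped alignment is strictly
        # optimal (any gapped or end-trimmed path scores lower), so skip
        # the DP
        aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
        bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
        d = int((aa != bb).sum())
        if d <= 1:
            return (len(a) - d) / len(a)
        if a > b:
            a, b = b, a  # canonical order keeps ties symmetric
    elif len(a) > len(b):
        a, b = b, a
    H = _score_matrix(a, b)
    n, m = len(a), len(b)
    j = 0
    for jj in range(m + 1):
        if H[n, jj] > H[n, j] or (H[n, jj] == H[n, j] and jj > j):
            j = jj
    i = n
    matches = 0
    cols = 0
    while i > 0:
        if j == 0:
            cols += 1  # `a` overhang past the start of `b`
            i -= 1
            continue
        s = 1 if a[i - 1] == b[j - 1] else -1
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += a[i - 1] == b[j - 1]
            cols += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i, j - 1] - _GAP:
            cols += 1
            j -= 1
        else:
            cols += 1
            i -= 1
    return matches / cols if cols else 0.0


@dataclass
class Cluster:
    """A centroid OTU: members are (seq_id, identity-to-rep, abundance)."""

    cluster_id: str
    threshold: float
    representative: str
    representative_seq: str
    members: list[tuple[str, float, float]]

    @property
    def total_abundance(self) -> float:
        return sum(m[2] for m in self.members)


def cluster_greedy(
    seqs: Sequence[tuple[str, str, float]],
    threshold: float,
) -> list[Cluster]:
    """Abundance-sorted greedy centroid clustering at an identity threshold.

    Sequences (seq_id, sequence, abundance) are processed in decreasing
    abundance (ties broken by id); each joins the first existing centroid
    with identity >= threshold, in centroid founding order, else founds a
    new cluster whose representative it becomes.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(seqs, key=lambda r: (-r[2], r[0]))
    clusters: list[Cluster] = []
    for sid, seq, ab in order:
        placed = False
        for cl in clusters:
            ident = pairwise_identity(seq, cl.representative_seq)
            if ident >= threshold:
                cl.members.append((sid, ident, ab))
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(
                    cluster_id=f"otu{len(clusters):04d}",
                    threshold=threshold,
                    representative=sid,
                    representative_seq=seq,
                    members=[(sid, 1.0, ab)],
                )
            )
    return clusters


def nearest_reference(
    query: str, references: Sequence[tuple[str, str]]
) -> tuple[str, float]:
    """Best-identity reference for a query; ties go to the smaller ref id."""
    if not references:
        raise ValueError("reference set must be non-empty")
    best_id, best_ident = None, -1.0
    for rid, rseq in sorted(references, key=lambda r: r[0]):
        ident = pairwise_identity(query, rseq)
        if ident > best_ident:
            best_id, best_ident = rid, ident
    return best_id, best_ident


def _cluster_of(clusters: list[Cluster]) -> dict[str, str]:
    return {sid: cl.cluster_id for cl in clusters for sid, _, _ in cl.members}


def build_linkage(
    parsed: Sequence[ParsedFusion],
    references: Sequence[tuple[str, str]] | None = None,
    ssu_threshold: float = 0.97,
    target_threshold: float = 0.95,
    novelty_cutoff: float = 0.95,
) -> tuple[pd.DataFrame, list[Cluster], list[Cluster]]:
    """Function <-> phylotype linkage from validated fusion reads.

    Target segments and 16S segments are dereplicated and clustered
    independently; each read then contributes one fusion count to its
    (target cluster, 16S OTU) cell. When a reference set is supplied,
    each 16S OTU representative is assigned its nearest reference and the
    OTU is called novel below ``novelty_cutoff`` identity.

    Returns the linkage table plus the two cluster lists.
    """
    parsed = list(parsed)
    if not parsed:
        cols = [
            "target_cluster_id",
            "ssu_otu_id",
            "n_fusions",
            "target_representative",
            "ssu_representative",
            "nearest_ref_id",
            "nearest_ref_identity",
            "novel",
        ]
        return pd.DataFrame(columns=cols), [], []

    t_unique: dict[str, str] = {}
    s_unique: dict[str, str] = {}
    t_counts: dict[str, float] = {}
    s_counts: dict[str, float] = {}
    for p in parsed:
        t_unique.setdefault(p.target_segment, f"t{len(t_unique):05d}")
        s_unique.setdefault(p.ssu_segment, f"s{len(s_unique):05d}")
        t_counts[p.target_segment] = t_counts.get(p.target_segment, 0) + 1
        s_counts[p.ssu_segment] = s_counts.get(p.ssu_segment, 0) + 1

    t_clusters = cluster_greedy(
        [(uid, seq, t_counts[seq]) for seq, uid in t_unique.items()], target_threshold
    )
    s_clusters = cluster_greedy(
        [(uid, seq, s_counts[seq]) for seq, uid in s_unique.items()], ssu_threshold
    )
    t_map = _cluster_of(t_clusters)
    s_map = _cluster_of(s_clusters)
    t_rep = {cl.cluster_id: cl.representative_seq for cl in t_clusters}
    s_rep = {cl.cluster_id: cl.representative_seq for cl in s_clusters}

    counts: dict[tuple[str, str], int] = {}
    for p in parsed:
        key = (t_map[t_unique[p.target_segment]], s_map[s_unique[p.ssu_segment]])
        counts[key] = counts.get(key, 0) + 1

    novelty: dict[str, tuple[str | None, float | None, bool]] = {}
    for cid, rep in s_rep.items():
        if references:
            rid, ident = nearest_reference(rep, references)
            novelty[cid] = (rid, ident, ident < novelty_cutoff)
        else:
            novelty[cid] = (None, None, False)

    rows = [
        {
            "target_cluster_id": tc,
            "ssu_otu_id": sc,
            "n_fusions": n,
            "target_representative": t_rep[tc],
            "ssu_representative": s_rep[sc],
            "nearest_ref_id": novelty[sc][0],
            "nearest_ref_identity": novelty[sc][1],
            "novel": novelty[sc][2],
        }
        for (tc, sc), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows), s_clusters, t_clusters


def rarefy(items: Sequence, depth: int, seed: int = 0) -> list:
    """Seeded subsampling without replacement to a common depth."""
    items = list(items)
    if depth > len(items):
        raise ValueError("rarefaction depth exceeds the number of items")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(items), size=depth, replace=False)
    return [items[i] for i in sorted(idx)]
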