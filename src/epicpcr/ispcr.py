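"""Degenerate-primer in-silico PCR with a mismatch-fraction cutoff.

Primers are IUPAC strings scanned ungapped against both strands of each
template; a site is a hit when its substitution count is within
floor(max_mismatch_frac x primer length) — percent-cutoff semantics with
the budget rounded down. Template ambiguity codes match when the two
expansions intersect, except N in a template, which always counts as a
mismatch. Amplicons are all forward-hit x reverse-hit pairings on the same
template within a length window, on either strand; a nested (two-step)
mode re-amplifies the first-round amplicon sequences with an inner pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from epicpcr.iupac import (
    DEGENERACY,
    encode,
    expansion,
    reverse_complement,
    validate_iupac,
)


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    seq: str
    max_mismatch_frac: float = 0.20

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", validate_iupac(self.seq, f"primer {self.name}"))
        if not 0.0 <= self.max_mismatch_frac < 1.0:
            raise ValueError("max_mismatch_frac must be in [0, 1)")

    @property
    def mismatch_budget(self) -> int:
        return int(self.max_mismatch_frac * len(self.seq))


@dataclass(frozen=True)
class PrimerMatch:
    """An annealing site: ``start`` is 0-based on the forward strand.

    ``strand`` is '+' when the primer sequence matches the forward strand
    as written, '-' when it anneals to the forward strand (its reverse
    complement matches at the footprint).
    """

    start: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted product; coordinates 0-based half-open, forward strand.

    ``seq`` is oriented 5'->3' from the forward primer: the forward-strand
    subsequence for '+' products, its reverse complement for '-' ones.
    """

    source_id: str
    start: int
    end: int
    strand: str
    fwd_mismatches: int
    rev_mismatches: int
    seq: str


def iupac_match_count(primer_base: str, target_base: str) -> int:
    """0 if the ACGT target base is within the code's expansion, else 1."""
    if target_base.upper() not in "ACGT":
        raise ValueError(f"target base must be ACGT, got {target_base!r}")
    return 0 if target_base.upper() in expansion(primer_base) else 1


def expansion_size(primer_seq: str) -> int:
    """Number of concrete sequences a degenerate primer stands for."""
    seq = validate_iupac(primer_seq, "primer")
    n = 1
    for c in seq:
        n *= DEGENERACY[c]
    return n


# template encoding: IUPAC masks, but N forced to 0 so it mismatches all codes
def _encode_template(seq: str) -> np.ndarray:
    s = validate_iupac(seq, "template")
    masks = encode(s)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    masks = masks.copy()
    masks[arr == ord("N")] = 0
    return masks


def _scan_one_strand(tmpl_masks: np.ndarray, primer_masks: np.ndarray) -> np.ndarray:
    lp = len(primer_masks)
    if len(tmpl_masks) < lp:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(tmpl_masks, lp)
    return ((win & primer_masks) == 0).sum(axis=1)


def scan_primer(template: str, primer: DegeneratePrimer) -> list[PrimerMatch]:
    """All annealing sites of a primer on both strands of a template."""
    tm = _encode_template(template)
    budget = primer.mismatch_budget
    hits: list[PrimerMatch] = []
    fwd = encode(primer.seq)
    mm = _scan_one_strand(tm, fwd)
    for pos in np.flatnonzero(mm <= budget):
        hits.append(PrimerMatch(int(pos), "+", int(mm[pos])))
    rev = encode(reverse_complement(primer.seq))
    mm = _scan_one_strand(tm, rev)
    for pos in np.flatnonzero(mm <= budget):
        hits.append(PrimerMatch(int(pos), "-", int(mm[pos])))
    return hits


def insilico_amplify(
    db: Iterable[tuple[str, str]],
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    min_len: int = 40,
    max_len: int = 5000,
) -> list[Amplicon]:
    """Predict products of a primer pair over a FASTA-like (id, seq) set.

    Both orientations are considered: forward primer on the plus strand
    with the reverse primer annealing downstream, and the mirror pairing
    on the minus strand. Primer footprints may not overlap; product length
    (primer footprints included) must lie in [min_len, max_len].
    """
    out: list[Amplicon] = []
    lf, lr = len(fwd.seq), len(rev.seq)
    for source_id, seq in db:
        hits = scan_primer(seq, fwd)
        f_plus = [h for h in hits if h.strand == "+"]
        f_minus = [h for h in hits if h.strand == "-"]
        rhits = scan_primer(seq, rev)
        r_plus = [h for h in rhits if h.strand == "+"]
        r_minus = [h for h in rhits if h.strand == "-"]

        for fh in f_plus:
            for rh in r_minus:
                start, end = fh.start, rh.start + lr
                if fh.start + lf > rh.start:
                    continue  # overlapping footprints
                if not min_len <= end - start <= max_len:
                    continue
                out.append(
                    Amplicon(source_id, start, end, "+", fh.mismatches, rh.mismatches, seq[start:end])
                )
        for fh in f_minus:
            for rh in r_plus:
                start, end = rh.start, fh.start + lf
                if rh.start + lr > fh.start:
                    continue
                if not min_len <= end - start <= max_len:
                    continue
                out.append(
                    Amplicon(
                        source_id,
                        start,
                        end,
                        "-",
                        fh.mismatches,
                        rh.mismatches,
                        reverse_complement(seq[start:end]),
                    )
                )
    return out


def nested_amplify(
    db: Iterable[tuple[str, str]],
    outer_fwd: DegeneratePrimer,
    outer_rev: DegeneratePrimer,
    inner_fwd: DegeneratePrimer,
    inner_rev: DegeneratePrimer,
    min_len: int = 40,
    max_len: int = 5000,
) -> list[Amplicon]:
    """Two-step in-silico PCR: inner pair applied to outer products only."""
    outer = insilico_amplify(db, outer_fwd, outer_rev, min_len, max_len)
    inner_db = [
        (f"{a.source_id}:{a.start}-{a.end}({a.strand})", a.seq) for a in outer
    ]
    return insilico_amplify(inner_db, inner_fwd, inner_rev, min_len, max_len)
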