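"""Independent reference implementations used as test oracles.

Everything here is deliberately written the slow, obvious way — plain
Python loops and set arithmetic — so that the vectorized production code
can be checked against an implementation whose correctness is evident by
inspection.
"""

from __future__ import annotations

IUPAC_SETS = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "U": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N", "U": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# glocal alignment identity: the shorter sequence aligns end to end, end
# gaps are free in the longer sequence only and excluded from the column
# count; match +1, mismatch -1, gap -2; traceback diagonal > left > up;
# end column in the last row maximizes (score, j)


def semiglobal_identity(a: str, b: str) -> float:
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    if len(a) == len(b):
        if a > b:
            a, b = b, a
    elif len(a) > len(b):
        a, b = b, a
    n, m = len(a), len(b)
    GAP = 2
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = H[i - 1][0] - GAP
        for j in range(1, m + 1):
            s = 1 if a[i - 1] == b[j - 1] else -1
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] - GAP, H[i][j - 1] - GAP)
    j = 0
    for jj in range(m + 1):
        if H[n][jj] > H[n][j] or (H[n][jj] == H[n][j] and jj > j):
            j = jj
    i = n
    matches = cols = 0
    while i > 0:
        if j == 0:
            cols += 1
            i -= 1
            continue
        s = 1 if a[i - 1] == b[j - 1] else -1
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += a[i - 1] == b[j - 1]
            cols += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i][j - 1] - GAP:
            cols += 1
            j -= 1
        else:
            cols += 1
            i -= 1
    return matches / cols if cols else 0.0


# ---------------------------------------------------------------------------
# literal greedy centroid clustering


def greedy_clusters(
    seqs: list[tuple[str, str, float]], threshold: float, identity=semiglobal_identity
) -> list[list[str]]:
    """Partition as lists of member ids, in centroid founding order."""
    order = sorted(seqs, key=lambda r: (-r[2], r[0]))
    reps: list[str] = []
    clusters: list[list[str]] = []
    for sid, seq, _ in order:
        for k, rep in enumerate(reps):
            if identity(seq, rep) >= threshold:
                clusters[k].append(sid)
                break
        else:
            reps.append(seq)
            clusters.append([sid])
    return clusters


# ---------------------------------------------------------------------------
# brute-force degenerate-primer scanning and amplification


def match_mismatches(primer: str, window: str) -> int:
    mm = 0
    for p, t in zip(primer.upper(), window.upper()):
        if t == "N" or t not in IUPAC_SETS:
            mm += 1
        elif not (IUPAC_SETS[p] & IUPAC_SETS[t]):
            mm += 1
    return mm


def scan_hits(template: str, primer: str, max_mismatch_frac: float) -> list[tuple[int, str, int]]:
    """All (start, strand, mismatches) hits; '-' means rc(primer) matches."""
    budget = int(max_mismatch_frac * len(primer))
    hits = []
    lp = len(primer)
    for variant, strand in ((primer, "+"), (revcomp(primer), "-")):
        for pos in range(len(template) - lp + 1):
            mm = match_mismatches(variant, template[pos : pos + lp])
            if mm <= budget:
                hits.append((pos, strand, mm))
    return hits


def amplify(
    db: list[tuple[str, str]],
    fwd: str,
    rev: str,
    frac: float,
    min_len: int = 40,
    max_len: int = 5000,
) -> set[tuple[str, int, int, str]]:
    """All (source, start, end, strand) products of the primer pair."""
    out = set()
    lf, lr = len(fwd), len(rev)
    for sid, seq in db:
        fh = scan_hits(seq, fwd, frac)
        rh = scan_hits(seq, rev, frac)
        for fs, fstrand, _ in fh:
            if fstrand == "+":
                for rs, rstrand, _ in rh:
                    if rstrand != "-":
                        continue
                    start, end = fs, rs + lr
                    if fs + lf <= rs and min_len <= end - start <= max_len:
                        out.add((sid, start, end, "+"))
            else:
                for rs, rstrand, _ in rh:
                    if rstrand != "+":
                        continue
                    start, end = rs, fs + lf
                    if rs + lr <= fs and min_len <= end - start <= max_len:
                        out.add((sid, start, end, "-"))
    return out
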