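"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from first principles —
straight dynamic programming and position-by-position scans — and
shares no code with the implementation it checks.
"""

from __future__ import annotations

NEG = float("-inf")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
        "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
        "B": "V", "V": "B", "D": "H", "H": "D"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def gotoh_score(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1,
                mode: str = "local") -> float:
    """Affine-gap optimal alignment score by the three-matrix Gotoh DP.

    Gap of length k costs gap_open + (k-1)*gap_extend.  ``N`` never
    matches.  Local mode returns the best Smith-Waterman-Gotoh score
    (>= 0); global mode the full end-to-end score.
    """
    n, m = len(a), len(b)

    def s(x, y):
        return match if (x == y and x != "N") else mismatch

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a residue vs -)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    local = mode == "local"
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
        if local:
            M[i][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
        if local:
            M[0][j] = 0.0
    best = 0.0 if local else NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if local:
                diag = max(diag, 0.0)
            M[i][j] = diag + s(a[i - 1], b[j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            if local and M[i][j] > best:
                best = M[i][j]
    if local:
        return best
    return max(M[n][m], X[n][m], Y[n][m])


def column_scan_footprints(rows: list[str], min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of columns identical, non-gap and non-N in every row."""
    ncol = len(rows[0])
    inv = []
    for c in range(ncol):
        col = [r[c] for r in rows]
        inv.append(col[0] not in "-N" and all(x == col[0] for x in col))
    out = []
    start = None
    for c in range(ncol + 1):
        flag = c < ncol and inv[c]
        if flag and start is None:
            start = c
        if not flag and start is not None:
            if c - start >= min_len:
                out.append((start, c))
            start = None
    return out


def iupac_site_match(seq: str, pos: int, pattern: str) -> bool:
    if pos < 0 or pos + len(pattern) > len(seq):
        return False
    for off, code in enumerate(pattern):
        base = seq[pos + off]
        if base == "N" or base not in IUPAC[code]:
            return False
    return True


def brute_motif_scan(seq: str, pattern: str, both_strands: bool = True
                     ) -> list[tuple[int, str]]:
    """Every (offset, strand) where the pattern occurs; palindromes
    reported once per position."""
    hits = [(i, "+") for i in range(len(seq)) if iupac_site_match(seq, i, pattern)]
    rc = revcomp(pattern)
    if both_strands and rc != pattern:
        hits += [(i, "-") for i in range(len(seq)) if iupac_site_match(seq, i, rc)]
    return sorted(hits)


def brute_convert(seq: str, methylated: set[int]) -> str:
    out = []
    for i, base in enumerate(seq):
        if base == "C" and i not in methylated:
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


def brute_digest(amplicon: str, recognition: str, cut_offset: int,
                 methylated: set[int]) -> list[int]:
    """Fragment lengths by direct position scan of the converted duplex."""
    conv = brute_convert(amplicon, methylated)
    cuts = set()
    L = len(recognition)
    rc = revcomp(recognition)
    for i in range(len(conv)):
        if iupac_site_match(conv, i, recognition):
            c = i + L + cut_offset
            if 0 < c < len(conv):
                cuts.add(c)
        if rc != recognition and iupac_site_match(conv, i, rc):
            c = i - cut_offset
            if 0 < c < len(conv):
                cuts.add(c)
    bounds = [0] + sorted(cuts) + [len(conv)]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def quadratic_intersect(query: list[tuple[str, int, int]],
                        subject: list[tuple[str, int, int]],
                        min_overlap: int = 1) -> list[bool]:
    """All-pairs half-open overlap flags for each query interval."""
    flags = []
    for qc, qs, qe in query:
        hit = False
        for sc, ss, se in subject:
            if qc == sc and min(qe, se) - max(qs, ss) >= min_overlap:
                hit = True
                break
        flags.append(hit)
    return flags
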