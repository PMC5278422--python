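"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive — position-by-position scans, full
dynamic-programming tables, exhaustive enumeration — and shares no code
with the implementation it checks.
"""

from __future__ import annotations

from math import comb

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def naive_scan(name: str, seq: str, drop_n: bool = True):
    """Position-by-position N20-NGG scan of both strands.

    Returns tuples (chrom, start, end, strand, protospacer, pam) sorted
    by (chrom, start, strand).
    """
    out = []
    n = len(seq)
    for p in range(n - 1):
        if seq[p] == "G" and seq[p + 1] == "G" and p >= 21:
            window = seq[p - 21 : p + 2]
            if drop_n and "N" in window:
                continue
            out.append((name, p - 21, p + 2, "+", window[:20], window[20:]))
        if seq[p] == "C" and seq[p + 1] == "C" and p + 23 <= n:
            window = seq[p : p + 23]
            if drop_n and "N" in window:
                continue
            w = rc(window)
            out.append((name, p, p + 23, "-", w[:20], w[20:]))
    out.sort(key=lambda t: (t[0], t[1], t[3]))
    return out


def affine_glocal_score(read: str, ref: str, match=2.0, mismatch=-4.0,
                        gap_open=-6.0, gap_extend=-1.0) -> float:
    """Exhaustive affine-gap DP: global in the read, free reference ends.

    A length-L gap scores gap_open + (L-1) * gap_extend.  Leading and
    trailing reference bases are free; leading/trailing deletions are
    excluded (they are dominated by the free reference ends).
    """
    NEG = float("-inf")
    m, n = len(read), len(ref)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]

    def start(i: int) -> float:
        return 0.0 if i == 0 else NEG

    for i in range(1, m + 1):
        for j in range(0, n + 1):
            if j > 0:
                prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1],
                           start(i - 1))
                s = match if read[i - 1] == ref[j - 1] else mismatch
                M[i][j] = prev + s
                X[i][j] = max(M[i][j - 1] + gap_open,
                              X[i][j - 1] + gap_extend,
                              Y[i][j - 1] + gap_open)
            Y[i][j] = max(M[i - 1][j] + gap_open,
                          X[i - 1][j] + gap_open,
                          Y[i - 1][j] + gap_extend,
                          start(i - 1) + gap_open)
    return max(max(M[m][j], Y[m][j]) for j in range(n + 1))


def fisher_enumeration(a: int, b: int, c: int, d: int, sided: str = "two") -> float:
    """Fisher's exact p by explicit enumeration of all tables with the
    observed margins, using exact integer hypergeometric weights."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    weights = {
        x: comb(c1, x) * comb(n - c1, r1 - x) for x in range(lo, hi + 1)
    }
    total = sum(weights.values())
    obs = weights[a]
    if sided == "one":
        tail = sum(w for x, w in weights.items() if x >= a)
    else:
        tail = sum(w for w in weights.values() if w <= obs)
    return tail / total


def pearson_chi2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form Pearson statistic n(ad-bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def loxp_kmers(loxp: str, k: int) -> list[str]:
    return [loxp[i : i + k] for i in range(len(loxp) - k + 1)]
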