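"""Independent brute-force oracles used only by the test suite."""

from functools import lru_cache


def alignment_score_bruteforce(a: str, b: str, match=1.0, mismatch=-1.0,
                               gap=-2.0) -> float:
    """Optimal global alignment score by exhaustive recursion (small inputs)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def cpg_islands_bruteforce(seq: str, window=200, gc_min=0.5, oe_min=0.6,
                           min_len=200):
    """Naive per-window scan + merge; independent of the vectorised code."""
    n = len(seq)
    qualifying = []
    for start in range(0, n - window + 1):
        sub = seq[start:start + window]
        if _qualifies(sub, gc_min, oe_min):
            qualifying.append((start, start + window))
    merged = []
    for lo, hi in qualifying:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    out = []
    for lo, hi in merged:
        if hi - lo >= min_len and _qualifies(seq[lo:hi], gc_min, oe_min):
            out.append((lo + 1, hi))  # 1-based inclusive
    return out


def _qualifies(sub: str, gc_min: float, oe_min: float) -> bool:
    n_c = sub.count("C")
    n_g = sub.count("G")
    l_eff = len(sub) - sub.count("N")
    if l_eff == 0:
        return False
    gc = (n_c + n_g) / l_eff
    n_cpg = sum(1 for i in range(len(sub) - 1) if sub[i] == "C" and sub[i + 1] == "G")
    oe = (n_cpg * l_eff) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return gc > gc_min and oe > oe_min
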