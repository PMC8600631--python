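"""Exhaustive affine-gap Smith-Waterman oracle (pure Python, no heuristics).

Independent of the package's alignment engine; used to verify optimal local
alignment scores on small inputs. Gap convention matches the package: a gap
of length L costs open + (L - 1) * extend.
"""

from igrec.align import revcomp

NEG = float("-inf")


def sw_score(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2) -> float:
    n, m = len(a), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def sw_score_both_strands(a: str, b: str, **kw) -> float:
    return max(sw_score(a, b, **kw), sw_score(revcomp(a), b, **kw))
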