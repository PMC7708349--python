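"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (plain-python
recursions and enumerations) and stays independent of the package's
numba/vectorized implementations it checks.
"""

from __future__ import annotations

from functools import lru_cache


def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def semiglobal_end_costs_py(text: str, probe: str) -> list[int]:
    """min_{s<=j} levenshtein(probe, text[s:j]) for every end offset j."""
    prev = [0] * (len(text) + 1)
    for i, cp in enumerate(probe, 1):
        cur = [i]
        for j, ct in enumerate(text, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (cp != ct)))
        prev = cur
    return prev


def affine_score_oracle(a: str, b: str, match: float, mismatch: float,
                        go: float, ge: float) -> float:
    """Optimal global affine-gap score by memoized recursion over
    (i, j, state); a gap run of length k costs go + k*ge."""

    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # state = the move that produced column (i, j):
        # 0 diagonal (or the empty start), 1 gap in b (consumed a[i-1]),
        # 2 gap in a (consumed b[j-1])
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        if state == 0:
            if i == 0 or j == 0:
                return NEG
            s = match if a[i - 1] == b[j - 1] else mismatch
            return s + max(rec(i - 1, j - 1, st) for st in (0, 1, 2))
        if state == 1:
            if i == 0:
                return NEG
            return max(rec(i - 1, j, 1) + ge,
                       max(rec(i - 1, j, st) for st in (0, 2)) + go + ge)
        if j == 0:
            return NEG
        return max(rec(i, j - 1, 2) + ge,
                   max(rec(i, j - 1, st) for st in (0, 1)) + go + ge)

    res = max(rec(len(a), len(b), st) for st in (0, 1, 2))
    rec.cache_clear()
    return res


def enumerate_alignments_score(a: str, b: str, match, mismatch, go, ge) -> float:
    """True exhaustive enumeration of every monotone alignment, scored with
    affine gap runs; only feasible for short strings."""
    best = float("-inf")

    def rec(i, j, cols):
        nonlocal best
        if i == len(a) and j == len(b):
            score = 0.0
            run = None
            for x, y in cols:
                if x is None or y is None:
                    which = 0 if x is None else 1
                    score += ge + (go if run != which else 0)
                    run = which
                else:
                    score += match if x == y else mismatch
                    run = None
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], None)])
        if j < len(b):
            rec(i, j + 1, cols + [(None, b[j])])

    rec(0, 0, [])
    return best


def order_hits_oracle(hits, overlap_fraction=0.5):
    """Brute-force restatement of the pruning contract: admit hits in
    (cost, probe_id, start) order, reject overlap > fraction of the shorter."""
    ranked = sorted(hits, key=lambda h: (h.cost, h.probe_id, h.start, h.end, h.strand))
    kept = []
    for h in ranked:
        if all(max(0, min(h.end, k.end) - max(h.start, k.start))
               <= overlap_fraction * min(h.end - h.start, k.end - k.start)
               for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.end, h.probe_id))


def segmentations_exhaustive(s: str, registry):
    """All maximal-coverage segmentations of s under rank-increasing
    matching; yields lists of (sym_start, sym_end, rank, locus_label).

    Returns (best_coverage, all best segmentations).
    """
    pats = sorted(registry, key=lambda p: (p.rank, p.variant))
    from kirmotif.locus_model import _match_longest, _tokenize

    # all match lengths per (pos, pattern-row)
    matches = {}
    for p in pats:
        toks = _tokenize(p.pattern)
        for pos in range(len(s)):
            L = _match_longest(toks, s, pos)
            if L > 0:
                matches.setdefault(pos, []).append((L, p))

    best = []
    best_cov = -1

    def rec(pos, min_rank, acc, cov):
        nonlocal best, best_cov
        if pos >= len(s):
            if cov > best_cov:
                best_cov, best = cov, [list(acc)]
            elif cov == best_cov:
                best.append(list(acc))
            return
        rec(pos + 1, min_rank, acc, cov)  # leave pos unmatched
        for L, p in matches.get(pos, []):
            if p.rank > min_rank:
                acc.append((pos, pos + L, p.rank, p.locus_label))
                rec(pos + L, p.rank, acc, cov + L)
                acc.pop()

    rec(0, 0, [], 0)
    return best_cov, best
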