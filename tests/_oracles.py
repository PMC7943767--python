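"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (enumeration,
exhaustive search, closed forms) without calling the code paths it checks.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
PURINES = {"A", "G"}


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def syn_sites_oracle(codon: str) -> float:
    """NG86 synonymous site count of one codon, by direct enumeration."""
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOPS and translate(mut) == translate(codon):
                syn += 1
        s += syn / 3
    return s


def pair_diff_oracle(c1: str, c2: str) -> tuple[float, float]:
    """(sd, nd) for a codon pair by recursive pathway enumeration.

    All orderings of the differing positions are walked recursively;
    pathways through intermediate stop codons are discarded unless every
    pathway is; steps are classified synonymous iff translation is
    preserved (steps touching a stop codon count nonsynonymous).
    """

    def walk(cur: str, remaining: list[int], through_stop: bool):
        if not remaining:
            yield (0.0, 0.0, through_stop)
            return
        for i, pos in enumerate(remaining):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            stop_here = nxt in STOPS and nxt not in (c1, c2)
            if cur in STOPS or nxt in STOPS:
                step = (0.0, 1.0)
            elif translate(cur) == translate(nxt):
                step = (1.0, 0.0)
            else:
                step = (0.0, 1.0)
            rest = remaining[:i] + remaining[i + 1 :]
            for sd, nd, ts in walk(nxt, rest, through_stop or stop_here):
                yield (step[0] + sd, step[1] + nd, ts)

    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = list(walk(c1, diff, False))
    clean = [(sd, nd) for sd, nd, ts in results if not ts]
    use = clean if clean else [(sd, nd) for sd, nd, _ in results]
    return (
        sum(r[0] for r in use) / len(use),
        sum(r[1] for r in use) / len(use),
    )


def fourdtv_site_oracle(c1: str, c2: str) -> tuple[int, int]:
    """(counted_site, transversion) flags for one codon pair.

    Fourfold degeneracy is derived on the spot: the third position is
    fourfold iff all four third-base variants translate identically.
    """
    if c1[:2] != c2[:2]:
        return 0, 0
    variants = {translate(c1[:2] + b) for b in BASES}
    if len(variants) != 1 or "*" in variants:
        return 0, 0
    if c1[2] == c2[2]:
        return 1, 0
    tv = (c1[2] in PURINES) != (c2[2] in PURINES)
    return 1, int(tv)


def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by full enumeration."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def mutual_argmax_oracle(scores: dict[tuple[str, str], float]) -> set[frozenset]:
    """RBH pairs from a dense score dict by exhaustive mutual-argmax."""
    queries = {q for q, _ in scores}
    subjects = {s for _, s in scores}
    best_q = {
        q: max((s for s in subjects if (q, s) in scores), key=lambda s: scores[(q, s)])
        for q in queries
    }
    best_s = {
        s: max((q for q in queries if (q, s) in scores), key=lambda q: scores[(q, s)])
        for s in subjects
    }
    return {
        frozenset((q, b))
        for q, b in best_q.items()
        if best_s.get(b) == q and q != b
    }


def best_chain_oracle(
    points: list[tuple[int, int]], max_gap: int
) -> tuple[int, int, list[frozenset]]:
    """Exhaustive best monotone chain over rank points.

    Chains must be strictly increasing in x and strictly monotone (either
    direction) in y, with per-step gaps <= max_gap on both axes.  Returns
    (best length, total gap of a best-and-tightest chain, all optimal
    chains as sets of point indices).
    """
    n = len(points)
    best_len, best_gap = 0, 0
    best_sets: list[frozenset] = []

    def extend(chain: list[int], direction: int | None):
        nonlocal best_len, best_gap, best_sets
        gap = 0
        for a, b in zip(chain[:-1], chain[1:]):
            gap += (points[b][0] - points[a][0] - 1) + (
                abs(points[b][1] - points[a][1]) - 1
            )
        key = (len(chain), -gap)
        if key > (best_len, -best_gap):
            best_len, best_gap = len(chain), gap
            best_sets = [frozenset(chain)]
        elif key == (best_len, -best_gap):
            best_sets.append(frozenset(chain))
        last = chain[-1]
        for j in range(n):
            if j in chain:
                continue
            dx = points[j][0] - points[last][0]
            dy = points[j][1] - points[last][1]
            if dx <= 0 or dx > max_gap:
                continue
            for d in ((1, -1) if direction is None else (direction,)):
                if d * dy <= 0 or abs(dy) > max_gap:
                    continue
                extend(chain + [j], d)

    for i in range(n):
        extend([i], None)
    return best_len, best_gap, best_sets


class UnionFind:
    """Independent union–find for the clustering oracle."""

    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self) -> list[set]:
        out: dict = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return [g for g in out.values() if len(g) > 1]
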