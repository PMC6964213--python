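"""Independent brute-force reference implementations used as test oracles.

Everything here is written naively (explicit python loops, all-pairs
enumeration, union-find) and deliberately shares no code with the
package's vectorized / incremental implementations.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# Summit splitting

def brute_maxima(values) -> list[tuple[int, float]]:
    out = []
    i, n = 0, len(values)
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_down = i == 0 or values[i - 1] < values[i]
        right_down = j == n - 1 or values[j + 1] < values[i]
        if left_down and right_down and values[i] > 0:
            out.append(((i + j) // 2, float(values[i])))
        i = j + 1
    return out


def brute_split(values, valley_ratio=0.6, min_height=0.0, min_separation=1):
    """Fixed point of the valley rule, merging the shallowest pair first.

    Uses a different merge order than the package (which scans left to
    right): among all inseparable adjacent pairs, the one whose lower
    summit is lowest is merged first (ties: rightmost pair). The valley
    rule is confluent, so the fixed point must agree.
    """
    summits = brute_maxima(values)
    while True:
        worst = None
        for i in range(len(summits) - 1):
            (p1, h1), (p2, h2) = summits[i], summits[i + 1]
            valley = min(values[p1 : p2 + 1])
            separable = (
                p2 - p1 >= min_separation
                and valley < valley_ratio * min(h1, h2)
            )
            if not separable:
                key = (min(h1, h2), -i)
                if worst is None or key <= worst[0]:
                    worst = (key, i)
        if worst is None:
            break
        i = worst[1]
        (p1, h1), (p2, h2) = summits[i], summits[i + 1]
        del summits[i if h1 < h2 else i + 1]
    kept = [(p, h) for p, h in summits if h >= min_height]
    if not kept and summits:
        top = max(summits, key=lambda s: s[1])
        kept = [top]
    return kept


# ---------------------------------------------------------------------------
# PWM scanning

def brute_probabilities(counts, pseudocount):
    L = len(counts)
    probs = []
    for i in range(L):
        total = sum(counts[i]) + 4.0 * pseudocount
        probs.append([(c + pseudocount) / total for c in counts[i]])
    return probs


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_score(seq, counts, pseudocount, background, strand="+"):
    if strand == "-":
        seq = "".join(_COMP[b] for b in reversed(seq))
    probs = brute_probabilities(counts, pseudocount)
    score = 0.0
    for i, base in enumerate(seq):
        if base == "N":
            num = sum(bg * p for bg, p in zip(background, probs[i]))
            den = sum(bg * bg for bg in background)
            score += math.log2(num / den)
        else:
            j = "ACGT".index(base)
            score += math.log2(probs[i][j] / background[j])
    return score


def brute_scan(regions, genome, counts, pseudocount, background, fraction):
    """All windows on both strands with score >= fraction * max score."""
    probs = brute_probabilities(counts, pseudocount)
    L = len(counts)
    max_score = sum(
        max(math.log2(p / bg) for p, bg in zip(row, background))
        for row in probs
    )
    threshold = fraction * max_score
    hits = []
    for region in regions:
        seq = genome[region.chrom][region.start : region.end].upper()
        for off in range(len(seq) - L + 1):
            window = seq[off : off + L]
            for strand in "+-":
                score = brute_score(
                    window, counts, pseudocount, background, strand
                )
                if score >= threshold:
                    hits.append(
                        (region.chrom, region.start + off, strand, score)
                    )
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


# ---------------------------------------------------------------------------
# 2-of-3 consensus grouping (all-pairs union-find)

def brute_consensus(hits_per_scanner, tolerance=2):
    """hits: (chrom, start, strand, score, scanner_idx) tuples.

    Returns (chrom, start, strand, score, n_scanners) of kept groups.
    """
    items = []
    for scanner_idx, hits in enumerate(hits_per_scanner):
        for chrom, start, strand, score in hits:
            items.append((chrom, start, strand, score, scanner_idx))
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            if (
                items[a][0] == items[b][0]
                and items[a][2] == items[b][2]
                and abs(items[a][1] - items[b][1]) <= tolerance
            ):
                union(a, b)
    groups: dict[int, list] = {}
    for idx in range(len(items)):
        groups.setdefault(find(idx), []).append(items[idx])
    out = []
    for members in groups.values():
        scanners = {m[4] for m in members}
        if len(scanners) < 2:
            continue
        best = max(members, key=lambda m: (m[3], -m[1], -m[4]))
        out.append((best[0], best[1], best[2], best[3], len(scanners)))
    out.sort(key=lambda h: (h[0], h[1], h[2]))
    return out


# ---------------------------------------------------------------------------
# Distances and Venn tallies

def brute_distances(sites, summits, window=50):
    """All-pairs filter; sites/summits are package objects."""
    records = []
    for site in sites:
        for summit in summits:
            if summit.chrom != site.interval.chrom:
                continue
            if abs(summit.position - site.center) > window:
                continue
            sign = 1 if site.strand == "+" else -1
            records.append(
                (
                    site.center,
                    summit.experiment_id,
                    summit.position,
                    sign * (summit.position - site.center),
                )
            )
    return records


def brute_venn(summits_by_experiment, sites, window=50):
    """2^3 truth-table tally over all (site, experiment) flags."""
    experiment_ids = list(summits_by_experiment)
    counts = {}
    for site in sites:
        flags = []
        for exp in experiment_ids:
            hit = any(
                s.chrom == site.interval.chrom
                and abs(s.position - site.center) <= window
                for s in summits_by_experiment[exp]
            )
            flags.append(hit)
        members = tuple(
            exp for exp, flag in zip(experiment_ids, flags) if flag
        )
        if members:
            counts[members] = counts.get(members, 0) + 1
    return counts
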