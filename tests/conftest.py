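import math

import numpy as np
import pandas as pd
import pytest

from cageqtl.io import GenomicInterval, GenotypeMatrix, TagStream


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotypes():
    """Six samples, four variants with hand-checkable dosages."""
    variants = pd.DataFrame({
        "id": ["v1", "v2", "v3", "v4"],
        "chrom": ["chr1"] * 4,
        "pos": [100, 200, 5000, 9000],
        "ref": ["A"] * 4,
        "alt": ["G"] * 4,
        "maf": [0.4, 0.4, 0.3, 0.25],
        "alt_count": [5, 5, 4, 3],
    })
    dosages = np.array([
        [0, 0, 1, 0],
        [1, 1, 0, 0],
        [2, 2, 1, 1],
        [0, 0, 0, 0],
        [1, 1, 2, 1],
        [1, 1, 0, 1],
    ], dtype=float)
    return GenotypeMatrix([f"s{i}" for i in range(6)], variants, dosages)


def make_stream(sample_id, records):
    """records: iterable of (chrom, pos, strand, count)."""
    return TagStream(sample_id, pd.DataFrame(
        records, columns=["chrom", "pos", "strand", "count"]))


@pytest.fixture
def make_tag_stream():
    return make_stream


# ---------------------------------------------------------------------------
# independent density-clustering oracle: sweep over density levels, splitting
# any unstable segment at its weakest prefix/suffix, and record each stable
# segment's first appearance level (its detachment density) and break density


def paraclu_oracle(positions, counts, min_tags=5, fold=2.0, max_len=200):
    pos = list(positions)
    val = list(counts)
    m = len(pos)
    if m == 0:
        return []

    def break_info(i, j):
        if j - i == 1:
            return math.inf, None
        best_pre, k_pre, tot = math.inf, i, val[i]
        for k in range(i + 1, j):
            d = tot / (pos[k] - pos[i])
            if d < best_pre:
                best_pre, k_pre = d, k
            tot += val[k]
        best_suf, k_suf, tot = math.inf, j - 1, val[j - 1]
        for k in range(j - 2, i - 1, -1):
            d = tot / (pos[j - 1] - pos[k])
            if d < best_suf:
                best_suf, k_suf = d, k
            tot += val[k]
        if best_pre <= best_suf:
            return best_pre, ((i, k_pre), (k_pre, j))
        return best_suf, ((i, k_suf + 1), (k_suf + 1, j))

    info = {}

    def get(i, j):
        if (i, j) not in info:
            info[(i, j)] = break_info(i, j)
        return info[(i, j)]

    levels = {0.0}
    stack, seen = [(0, m)], set()
    while stack:
        i, j = stack.pop()
        if (i, j) in seen:
            continue
        seen.add((i, j))
        bd, parts = get(i, j)
        if math.isfinite(bd):
            levels.add(bd)
            stack.extend(parts)
    first_seen = {}
    for d in sorted(levels):
        segs, out = [(0, m)], []
        while segs:
            i, j = segs.pop()
            bd, parts = get(i, j)
            if bd > d:
                out.append((i, j))
            else:
                segs.extend(parts)
        for s in out:
            first_seen.setdefault(s, d)
    clusters = []
    for (i, j), dmin in first_seen.items():
        dmax, _ = get(i, j)
        tot = sum(val[i:j])
        length = pos[j - 1] - pos[i] + 1
        if tot < min_tags or length > max_len:
            continue
        ratio = math.inf if (dmin == 0 or math.isinf(dmax)) else dmax / dmin
        if ratio < fold:
            continue
        clusters.append((pos[i], pos[j - 1] + 1, int(tot), dmin, dmax))
    return sorted(clusters)


@pytest.fixture
def paraclu_bruteforce():
    return paraclu_oracle


@pytest.fixture
def make_intervals():
    def _make(rows):
        return [GenomicInterval(*row) for row in rows]

    return _make
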