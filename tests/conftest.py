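"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by brute force or closed
form, independently of the package's implementation paths: a quadratic
longest-common-substring DP, an all-pairs overlap-graph builder, a numpy
affine-gap Smith-Waterman, an exhaustive rank-sum enumeration, and a
set-based k-mer curve recomputation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Longest common substring (quadratic DP, numpy rows)


def lcs_length(a: str, b: str) -> int:
    """Length of the longest exact common substring of two strings."""
    if not a or not b:
        return 0
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b), dtype=np.int32)
    best = 0
    for ch in a.encode():
        cur = np.zeros_like(prev)
        match = b_arr == ch
        cur[0] = 1 if match[0] else 0
        cur[1:] = np.where(match[1:], prev[:-1] + 1, 0)
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def share_substring(a: str, b: str, min_len: int) -> bool:
    """Either-strand exact shared substring of >= min_len bases."""
    return (lcs_length(a, b) >= min_len
            or lcs_length(a, revcomp(b)) >= min_len)


def overlap_components(contigs, min_overlap: int,
                       linker=None) -> list[frozenset[str]]:
    """Connected components of the all-pairs overlap graph, built by
    brute force over every contig pair."""
    if linker is None:
        linker = lambda a, b: share_substring(a, b, min_overlap)  # noqa: E731
    ids = [cid for cid, _ in contigs]
    seqs = dict(contigs)
    adjacency = {cid: set() for cid in ids}
    for (ca, cb) in itertools.combinations(ids, 2):
        if linker(seqs[ca], seqs[cb]):
            adjacency[ca].add(cb)
            adjacency[cb].add(ca)
    seen: set[str] = set()
    components = []
    for cid in ids:
        if cid in seen:
            continue
        stack, comp = [cid], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adjacency[cur] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return components


def kmer_set_linker(min_overlap: int):
    """Pairwise linker via exact k-mer set intersection (k = min_overlap);
    equivalent to share_substring because a shared substring of length
    >= L contains a shared substring of length exactly L."""
    def link(a: str, b: str) -> bool:
        ka = {a[i:i + min_overlap] for i in range(len(a) - min_overlap + 1)}
        kb = {b[i:i + min_overlap] for i in range(len(b) - min_overlap + 1)}
        rb = revcomp(b)
        kb |= {rb[i:i + min_overlap] for i in range(len(rb) - min_overlap + 1)}
        return bool(ka & kb)
    return link


# ---------------------------------------------------------------------------
# Smith-Waterman (numpy, affine gaps, BLAST convention)


def _blosum_lookup():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    table = np.array(mat, dtype=np.float64)
    return idx, table


_BLOSUM_IDX, _BLOSUM = _blosum_lookup()


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal local alignment score under BLOSUM62 with affine gaps
    costing gap_open + L * gap_extend for a gap of length L.

    Row-wise DP: the match matrix M depends only on the previous row of
    (M, Ix, Iy); the horizontal-gap row Iy follows from the current M row
    via a running prefix maximum; the vertical-gap row Ix follows
    elementwise from the previous row.
    """
    open_total = gap_open + gap_extend
    ai = np.array([_BLOSUM_IDX[c] for c in a])
    bi = np.array([_BLOSUM_IDX[c] for c in b])
    n = len(bi)
    sub = _BLOSUM[np.ix_(ai, bi)]
    neg = -1e18
    m_prev = np.zeros(n)
    ix_prev = np.full(n, neg)
    iy_prev = np.full(n, neg)
    best = 0.0
    offsets = np.arange(n) * gap_extend
    for i in range(len(ai)):
        diag = np.maximum.reduce([m_prev, ix_prev, iy_prev])
        m_cur = np.empty(n)
        m_cur[0] = max(0.0, sub[i, 0])
        m_cur[1:] = np.maximum(0.0, sub[i, 1:] + np.maximum(diag[:-1], 0.0))
        run = np.maximum.accumulate(m_cur + offsets)
        iy_cur = np.full(n, neg)
        iy_cur[1:] = run[:-1] - open_total - offsets[1:] + gap_extend
        ix_cur = np.maximum(m_prev - open_total, ix_prev - gap_extend)
        best = max(best, float(m_cur.max()))
        m_prev, ix_prev, iy_prev = m_cur, ix_cur, iy_cur
    return best


def sw_best_hits(queries: dict[str, str], subjects: dict[str, str],
                 min_score: float = 40.0) -> dict[str, tuple[str, float]]:
    """Exhaustive best-hit table under :func:`sw_score`; ties to the
    lexicographically smallest subject id."""
    hits = {}
    for qid in sorted(queries):
        best_sid, best = None, -math.inf
        for sid in sorted(subjects):
            s = sw_score(queries[qid], subjects[sid])
            if s > best:
                best_sid, best = sid, s
        if best_sid is not None and best >= min_score:
            hits[qid] = (best_sid, best)
    return hits


# ---------------------------------------------------------------------------
# Exact rank-sum enumeration


def wilcoxon_enumeration(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all C(n+m, n) rank
    assignments (tie-free inputs only): P(|W - E[W]| >= |w_obs - E[W]|)."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs no ties"
    ranks = {v: r for r, v in enumerate(pooled, start=1)}
    n, m = len(x), len(y)
    w_obs = sum(ranks[v] for v in x)
    mu = n * (n + m + 1) / 2
    dev = abs(w_obs - mu)
    total = extreme = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        total += 1
        if abs(sum(combo) - mu) >= dev - 1e-9:
            extreme += 1
    return extreme / total


def hypergeom_closed_form(study_hits, study_size, pop_hits, pop_size) -> float:
    """Upper-tail hypergeometric via explicit binomial sums."""
    num = sum(
        math.comb(pop_hits, k) * math.comb(pop_size - pop_hits, study_size - k)
        for k in range(study_hits, min(study_size, pop_hits) + 1)
    )
    return num / math.comb(pop_size, study_size)


# ---------------------------------------------------------------------------
# k-mer curve recomputation


def kmer_curve_oracle(reads, k, batch_size):
    """(reads_sampled, fraction) points recomputed with fresh sets: for
    each batch, the union of all earlier batches is rebuilt from scratch."""
    def canonical(kmer):
        rc = revcomp(kmer)
        return kmer if kmer <= rc else rc

    def batch_kmers(batch):
        out = []
        for _rid, seq in batch:
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" not in kmer:
                    out.append(canonical(kmer))
        return out

    batches = [reads[i:i + batch_size] for i in range(0, len(reads), batch_size)]
    points = []
    for bi, batch in enumerate(batches):
        earlier = set()
        for prev in batches[:bi]:
            earlier |= set(batch_kmers(prev))
        kmers = batch_kmers(batch)
        if kmers:
            new = len(set(kmers) - earlier)
            # count multiplicity: first occurrence within the batch counts
            seen = set(earlier)
            new = 0
            for km in kmers:
                if km not in seen:
                    seen.add(km)
                    new += 1
            points.append((sum(len(b) for b in batches[:bi + 1]),
                           new / len(kmers)))
    return points


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def small_transcriptome():
    from xerotome.synthetic import SimulationConfig, simulate_transcriptome

    cfg = SimulationConfig(seed=11, n_loci=40)
    return simulate_transcriptome(cfg)


@pytest.fixture(scope="session")
def asa_table():
    from xerotome.thermostability import load_asa_table

    return load_asa_table()
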