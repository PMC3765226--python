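"""RPKM with uniquely-mappable lengths, k-mer discovery curves, sample
correlations, z-scaling and K-means clustering along a developmental axis.

Unique mappability is defined on read-length windows: the uniquely
mappable length of a contig is the number of windows whose strand-canonical
sequence occurs exactly once across the whole reference set — a k-mer
surrogate for MAPQ-based unique alignment. RPKM is then
10^9 * count / (total_unique_reads * mappable_length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .curation import reverse_complement
from .formats_io import ExpressionMatrix
from .stats import pearson

DEFAULT_READ_LEN = 36  # reads are trimmed to 36 nt before counting
DEFAULT_K = 25


@dataclass(frozen=True)
class KmerCurvePoint:
    reads_sampled: int
    discovery_fraction: float


@dataclass
class ClusterModel:
    k: int
    assignments: dict[str, int]
    centroids: np.ndarray
    within_ss: float


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def unique_mappable_length(contigs: Mapping[str, str],
                           read_len: int = DEFAULT_READ_LEN) -> dict[str, int]:
    """Per contig, count read-length windows occurring exactly once
    (strand-canonical) across the whole reference. Windows containing N
    are unmappable. Contigs shorter than ``read_len`` get 0."""
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if not contigs:
        raise ValueError("empty reference")
    counts: dict[str, int] = {}
    windows: dict[str, list[str]] = {}
    for cid, seq in contigs.items():
        seq = seq.upper()
        wins = []
        for i in range(len(seq) - read_len + 1):
            w = seq[i:i + read_len]
            if "N" in w:
                wins.append(None)
                continue
            c = _canonical(w)
            wins.append(c)
            counts[c] = counts.get(c, 0) + 1
        windows[cid] = wins
    return {
        cid: sum(1 for w in wins if w is not None and counts[w] == 1)
        for cid, wins in windows.items()
    }


def compute_rpkm(unique_read_count: int, mappable_len: int,
                 total_unique_reads: int) -> float:
    """10^9 * count / (total * mappable_len); NaN when the contig has no
    uniquely mappable sequence (not zero — the quantity is undefined)."""
    if total_unique_reads <= 0:
        raise ValueError("total_unique_reads must be positive")
    if mappable_len == 0:
        return float("nan")
    return 1e9 * unique_read_count / (total_unique_reads * mappable_len)


def rpkm_matrix(counts: Mapping[str, Mapping[str, int]],
                mappable_lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Build an RPKM matrix from per-sample count tables.

    ``counts`` maps sample id -> {contig id -> unique read count}. Contigs
    with zero mappable length are dropped (their RPKM is undefined).
    """
    samples = sorted(counts)
    loci = sorted(cid for cid, L in mappable_lengths.items() if L > 0)
    values = np.zeros((len(loci), len(samples)))
    for j, s in enumerate(samples):
        total = sum(counts[s].values())
        for i, cid in enumerate(loci):
            values[i, j] = compute_rpkm(counts[s].get(cid, 0),
                                        mappable_lengths[cid], max(total, 1))
    return ExpressionMatrix(loci, samples, values)


def trim_reads(reads: Iterable[tuple[str, str]],
               length: int = DEFAULT_READ_LEN) -> list[tuple[str, str]]:
    """Trim reads to a fixed length, dropping shorter reads."""
    return [(rid, seq[:length]) for rid, seq in reads if len(seq) >= length]


def kmer_discovery_curve(reads: Sequence[tuple[str, str]],
                         k: int = DEFAULT_K,
                         batch_size: int = 1000) -> list[KmerCurvePoint]:
    """Fraction of never-before-seen canonical k-mers per batch of reads.

    The fraction for a batch is (k-mers new to this batch) / (k-mers
    scanned in this batch); k-mers containing N are skipped.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    seen: set[str] = set()
    points: list[KmerCurvePoint] = []
    for start in range(0, len(reads), batch_size):
        batch = reads[start:start + batch_size]
        scanned = new = 0
        for _rid, seq in batch:
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                scanned += 1
                c = _canonical(kmer)
                if c not in seen:
                    seen.add(c)
                    new += 1
        if scanned:
            points.append(KmerCurvePoint(start + len(batch), new / scanned))
    return points


def sample_correlation(matrix: ExpressionMatrix, i: int | str, j: int | str,
                       log_transform: bool = True,
                       pseudocount: float = 1.0) -> float:
    """Pearson correlation between two samples over loci, by default on
    log10(RPKM + 1) so a few abundant loci do not dominate."""
    if isinstance(i, str):
        i = matrix.sample_ids.index(i)
    if isinstance(j, str):
        j = matrix.sample_ids.index(j)
    x = matrix.values[:, i]
    y = matrix.values[:, j]
    if log_transform:
        x = np.log10(x + pseudocount)
        y = np.log10(y + pseudocount)
    return pearson(x, y)


def zscale_rows(matrix: ExpressionMatrix | np.ndarray,
                ddof: int = 0) -> ExpressionMatrix | np.ndarray:
    """Row-wise z-scaling (population sd by default); zero-variance rows
    become all-zero rows."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    if isinstance(matrix, ExpressionMatrix):
        out = ExpressionMatrix.__new__(ExpressionMatrix)
        out.locus_ids = list(matrix.locus_ids)
        out.sample_ids = list(matrix.sample_ids)
        out.values = z
        return out
    return z


def _as_array(zmatrix: ExpressionMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(zmatrix, ExpressionMatrix):
        return zmatrix.values, list(zmatrix.locus_ids)
    arr = np.asarray(zmatrix, float)
    return arr, [str(i) for i in range(arr.shape[0])]


def kmeans_cluster(zmatrix: ExpressionMatrix | np.ndarray, k: int,
                   seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Lloyd's k-means from k-means++ starts; centroids are recomputed as
    the means of the final assignment so the model is self-consistent."""
    values, loci = _as_array(zmatrix)
    if k > values.shape[0]:
        raise ValueError("k exceeds number of loci")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2**31),
                tol=1e-6).fit(values)
    labels = km.labels_
    centroids = np.vstack([values[labels == c].mean(axis=0) for c in range(k)])
    within_ss = float(((values - centroids[labels]) ** 2).sum())
    return ClusterModel(
        k=k,
        assignments={loc: int(lab) for loc, lab in zip(loci, labels)},
        centroids=centroids,
        within_ss=within_ss,
    )


def choose_k(zmatrix: ExpressionMatrix | np.ndarray,
             k_range: Sequence[int], seed: int = 0) -> int:
    """Pick k at the elbow of within-group sum of squares vs k, i.e. the
    interior k maximizing the second difference of the within-SS curve."""
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    wss = [kmeans_cluster(zmatrix, k, seed=seed).within_ss for k in ks]
    second_diff = [wss[i - 1] - 2 * wss[i] + wss[i + 1]
                   for i in range(1, len(ks) - 1)]
    return ks[1 + int(np.argmax(second_diff))]


def composite_expression(zmatrix: ExpressionMatrix,
                         locus_set: Iterable[str]) -> np.ndarray:
    """Mean z-profile over a locus set (e.g. one biological process);
    an empty set yields a NaN vector."""
    wanted = set(locus_set)
    idx = [i for i, loc in enumerate(zmatrix.locus_ids) if loc in wanted]
    if not idx:
        return np.full(len(zmatrix.sample_ids), np.nan)
    return zmatrix.values[idx].mean(axis=0)


def cluster_recovery(model: ClusterModel,
                     truth: Mapping[str, int | str]) -> float:
    """Adjusted Rand index of a cluster model against planted labels."""
    loci = sorted(model.assignments)
    return float(adjusted_rand_score(
        [str(truth[loc]) for loc in loci],
        [model.assignments[loc] for loc in loci],
    ))
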