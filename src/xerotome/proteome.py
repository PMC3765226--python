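"""ORF discovery, working-set proteome selection, reciprocal-best-hit
(RBH) ortholog pairing, and protein-family size comparison.

ORFs are stop-to-stop open frames in all six frames (the default getorf
semantics): every maximal run of non-stop codons of at least ``min_aa``
residues is reported, whether or not it begins with Met. The working-set
proteome keeps, per locus, the longest ORF on the + strand of the v1
isoform that is at least 76 aa with a CDS spanning at least half the
transcript.

RBH pairing scores local alignments (Smith-Waterman, BLOSUM62, BLAST-style
gap open 11 / extend 1) in both directions and emits mutual best hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .curation import reverse_complement
from .stats import bh_adjust, wilcoxon_rank_sum

MIN_ORF_AA = 30
WORKING_SET_MIN_AA = 76  # 5th percentile of reference plant protein lengths
WORKING_SET_MIN_CDS_FRACTION = 0.5
EXHAUSTIVE_MAX_PAIRS = 10_000


@dataclass(frozen=True)
class OrfRecord:
    protein_id: str
    source_contig: str
    strand: str  # "+" or "-"
    frame: int  # 0..2 on the coding strand
    cds_start: int  # 0-based half-open on the forward contig
    cds_end: int
    aa_sequence: str


@dataclass(frozen=True)
class BestHit:
    subject_id: str
    score: float


@dataclass(frozen=True)
class RbhPair:
    protein_a: str
    protein_b: str
    score_ab: float
    identity: float


def find_orfs(contig_id: str, sequence: str,
              min_aa: int = MIN_ORF_AA) -> list[OrfRecord]:
    """All maximal stop-to-stop translations of >= ``min_aa`` residues in
    all six frames, ordered by (strand, frame, start); the closing stop
    codon, when present, is included in the CDS span."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    records: list[OrfRecord] = []
    for strand in "+-":
        working = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            usable = (n - frame) // 3 * 3
            if usable < 3:
                continue
            protein = str(Seq(working[frame:frame + usable]).translate())
            pos = 0
            for segment in protein.split("*"):
                if len(segment) >= min_aa:
                    aa_start, aa_end = pos, pos + len(segment)
                    w_start = frame + 3 * aa_start
                    w_end = frame + 3 * aa_end
                    if aa_end < len(protein):  # closed by a stop codon
                        w_end += 3
                    if strand == "+":
                        cds_start, cds_end = w_start, w_end
                    else:
                        cds_start, cds_end = n - w_end, n - w_start
                    records.append(OrfRecord(
                        protein_id="",
                        source_contig=contig_id,
                        strand=strand,
                        frame=frame,
                        cds_start=cds_start,
                        cds_end=cds_end,
                        aa_sequence=segment,
                    ))
                pos += len(segment) + 1
    records.sort(key=lambda r: (r.strand == "-", r.frame, r.cds_start))
    return [
        OrfRecord(f"{contig_id}_orf{i}", r.source_contig, r.strand, r.frame,
                  r.cds_start, r.cds_end, r.aa_sequence)
        for i, r in enumerate(records, start=1)
    ]


def select_working_set(
    orfs: Sequence[OrfRecord],
    contig_versions: Mapping[str, int],
    contig_lengths: Mapping[str, int],
    min_aa: int = WORKING_SET_MIN_AA,
    min_cds_fraction: float = WORKING_SET_MIN_CDS_FRACTION,
) -> list[OrfRecord]:
    """Working-set proteome: + strand ORFs on v1 contigs, >= ``min_aa``
    residues, CDS covering >= ``min_cds_fraction`` of the transcript;
    the longest qualifying ORF per contig (first in ORF order on ties)."""
    best: dict[str, OrfRecord] = {}
    for orf in orfs:
        if orf.strand != "+":
            continue
        if contig_versions.get(orf.source_contig) != 1:
            continue
        if len(orf.aa_sequence) < min_aa:
            continue
        span = orf.cds_end - orf.cds_start
        if span < min_cds_fraction * contig_lengths[orf.source_contig]:
            continue
        current = best.get(orf.source_contig)
        if current is None or len(orf.aa_sequence) > len(current.aa_sequence):
            best[orf.source_contig] = orf
    return [best[cid] for cid in sorted(best)]


def make_aligner(gap_open: int = 11, gap_extend: int = 1,
                 matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    """Local aligner with BLAST-convention affine gaps: a gap of length L
    costs gap_open + L * gap_extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _seed_index(sequences: Mapping[str, str],
                seed_len: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for sid, seq in sequences.items():
        for i in range(len(seq) - seed_len + 1):
            index.setdefault(seq[i:i + seed_len], set()).add(sid)
    return index


def protein_similarity_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    min_score: float = 40.0,
    mode: str = "auto",
    seed_len: int = 4,
    aligner: Align.PairwiseAligner | None = None,
) -> dict[str, BestHit]:
    """Best local-alignment hit per query.

    ``mode`` is "exhaustive" (score every pair), "seeded" (score only
    subjects sharing a ``seed_len``-mer with the query), or "auto"
    (exhaustive up to 10^4 pairs, seeded beyond). Ties go to the
    lexicographically smallest subject id. Queries whose best score falls
    below ``min_score`` get no hit.
    """
    if aligner is None:
        aligner = make_aligner()
    if mode == "auto":
        mode = ("exhaustive"
                if len(queries) * len(subjects) <= EXHAUSTIVE_MAX_PAIRS
                else "seeded")
    index = _seed_index(subjects, seed_len) if mode == "seeded" else None
    subject_ids = sorted(subjects)
    hits: dict[str, BestHit] = {}
    for qid in sorted(queries):
        qseq = queries[qid]
        if index is not None:
            cands: set[str] = set()
            for i in range(len(qseq) - seed_len + 1):
                cands |= index.get(qseq[i:i + seed_len], set())
            candidates = sorted(cands)
        else:
            candidates = subject_ids
        best_sid, best_score = None, -np.inf
        for sid in candidates:
            score = aligner.score(qseq, subjects[sid])
            if score > best_score:
                best_sid, best_score = sid, score
        if best_sid is not None and best_score >= min_score:
            hits[qid] = BestHit(best_sid, float(best_score))
    return hits


def alignment_identity(seq_a: str, seq_b: str,
                       aligner: Align.PairwiseAligner | None = None) -> float:
    """Identical positions over alignment columns of the optimal local
    alignment (gap columns count against identity)."""
    if aligner is None:
        aligner = make_aligner()
    counts = aligner.align(seq_a, seq_b)[0].counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total if total else 0.0


def reciprocal_best_hits(
    best_ab: Mapping[str, BestHit],
    best_ba: Mapping[str, BestHit],
    seqs_a: Mapping[str, str] | None = None,
    seqs_b: Mapping[str, str] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> list[RbhPair]:
    """Mutual best hits: (a, b) is emitted iff a's best subject is b and
    b's best subject is a. Identity is computed when sequences are given,
    else reported as NaN."""
    pairs = []
    for a in sorted(best_ab):
        b = best_ab[a].subject_id
        back = best_ba.get(b)
        if back is not None and back.subject_id == a:
            if seqs_a is not None and seqs_b is not None:
                ident = alignment_identity(seqs_a[a], seqs_b[b], aligner)
            else:
                ident = float("nan")
            pairs.append(RbhPair(a, b, best_ab[a].score, ident))
    return pairs


def rbh(proteome_a: Mapping[str, str], proteome_b: Mapping[str, str],
        min_score: float = 40.0, mode: str = "auto",
        compute_identity: bool = True) -> list[RbhPair]:
    """Run both search directions and pair the mutual best hits."""
    aligner = make_aligner()
    ab = protein_similarity_search(proteome_a, proteome_b, min_score, mode,
                                   aligner=aligner)
    ba = protein_similarity_search(proteome_b, proteome_a, min_score, mode,
                                   aligner=aligner)
    return reciprocal_best_hits(
        ab, ba,
        proteome_a if compute_identity else None,
        proteome_b if compute_identity else None,
        aligner=aligner,
    )


def family_size_comparison(table: pd.DataFrame,
                           focal_species: Sequence[str]) -> pd.DataFrame:
    """Per-family rank-sum comparison of focal-species member counts
    against the remaining (reference) species, BH-adjusted across
    families.

    ``table`` is a family x species count matrix (e.g. parsed from an
    OrthoMCL membership table). Returns a DataFrame indexed by family with
    median counts and raw/adjusted two-sided p-values.
    """
    focal = [s for s in table.columns if s in set(focal_species)]
    reference = [s for s in table.columns if s not in set(focal_species)]
    if not focal or not reference:
        raise ValueError("need at least one focal and one reference species")
    raw = [
        wilcoxon_rank_sum(row[focal].to_numpy(float),
                          row[reference].to_numpy(float))
        for _, row in table.iterrows()
    ]
    return pd.DataFrame(
        {
            "median_focal": table[focal].median(axis=1),
            "median_reference": table[reference].median(axis=1),
            "p_raw": raw,
            "p_adjusted": bh_adjust(raw),
        },
        index=table.index,
    )
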