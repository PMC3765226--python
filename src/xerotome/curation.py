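"""Locus binning, isoform versioning, precursor flagging, GC content and
abundance-based contamination triage.

Contigs sharing an exact common substring of at least ``min_overlap``
bases on either strand belong to the same locus; loci are the connected
components of that overlap graph. Within a locus, isoform versions are
numbered by descending abundance (v1 = most abundant) and members below
10% of the v1 abundance are flagged as potential precursor transcripts.

Triage follows the abundance rule used to rescue unidentified contigs:
contigs of known plant origin are retained, known contaminants dropped,
and unknowns retained iff their RPKM meets the lower-quartile threshold
of the high-confidence plant set (inclusive boundary).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import TranscriptContig

PRECURSOR_FRACTION = 0.10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocusBin:
    locus_id: str
    member_contig_ids: frozenset[str]


@dataclass(frozen=True)
class TriageDecision:
    contig_id: str
    origin_label: str  # plant | contaminant | unknown
    rpkm: float
    retained: bool
    threshold_used: float


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def bin_loci(contigs: Sequence[tuple[str, str]],
             min_overlap: int = 200) -> list[LocusBin]:
    """Bin contigs into loci by >= ``min_overlap`` bp exact shared
    substring on either strand.

    Two sequences share a substring of length >= L iff they share one of
    length exactly L, so linking is done on strand-canonical windows of
    length L. Locus ids are assigned Locus1, Locus2, ... in order of the
    smallest member contig id, making the partition and the naming
    invariant to input order.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not contigs:
        raise ValueError("contigs must be non-empty")
    order = sorted(range(len(contigs)), key=lambda i: contigs[i][0])
    uf = _UnionFind(len(contigs))
    seen: dict[str, int] = {}
    for i in order:
        seq = contigs[i][1].upper()
        rc = reverse_complement(seq)
        n = len(seq)
        for start in range(n - min_overlap + 1):
            w = seq[start:start + min_overlap]
            wrc = rc[n - min_overlap - start:n - start]
            canon = w if w <= wrc else wrc
            j = seen.setdefault(canon, i)
            if j != i:
                uf.union(i, j)

    components: dict[int, list[str]] = {}
    for i, (cid, _seq) in enumerate(contigs):
        components.setdefault(uf.find(i), []).append(cid)
    ordered = sorted(components.values(), key=min)
    return [
        LocusBin(f"Locus{k}", frozenset(members))
        for k, members in enumerate(ordered, start=1)
    ]


def assign_versions(bin_: LocusBin,
                    rpkm_by_contig: Mapping[str, float]) -> dict[str, int]:
    """Version members 1..m by descending RPKM; ties broken by contig id."""
    members = sorted(bin_.member_contig_ids,
                     key=lambda cid: (-rpkm_by_contig[cid], cid))
    return {cid: v for v, cid in enumerate(members, start=1)}


def flag_precursors(versions: Mapping[str, int],
                    rpkm_by_contig: Mapping[str, float],
                    fraction: float = PRECURSOR_FRACTION) -> dict[str, bool]:
    """Flag members strictly below ``fraction`` of the v1 RPKM; v1 never
    flagged (rpkm < 0.1 * v1 is impossible for v1 itself)."""
    v1 = next(cid for cid, v in versions.items() if v == 1)
    cutoff = fraction * rpkm_by_contig[v1]
    return {cid: rpkm_by_contig[cid] < cutoff for cid in versions}


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); N and other ambiguity codes excluded entirely."""
    seq = sequence.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / (gc + at)


def rpkm_triage_threshold(plant_rpkms: Sequence[float]) -> float:
    """Lower-quartile RPKM of the high-confidence plant contigs
    (linear interpolation between order statistics)."""
    arr = np.asarray(plant_rpkms, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one plant RPKM")
    return float(np.percentile(arr, 25))


def triage(records: Iterable[tuple[str, str, float]],
           threshold: float) -> list[TriageDecision]:
    """Apply the origin/abundance retention rule.

    ``records`` are (contig_id, origin_label, rpkm) triples with labels in
    {plant, contaminant, unknown}. Unknowns are retained iff
    rpkm >= threshold.
    """
    decisions = []
    for cid, label, rpkm in records:
        if label == "plant":
            keep = True
        elif label == "contaminant":
            keep = False
        elif label == "unknown":
            keep = rpkm >= threshold
        else:
            raise ValueError(f"unknown origin label {label!r}")
        decisions.append(TriageDecision(cid, label, rpkm, keep, threshold))
    return decisions


def curate_contigs(contigs: Sequence[tuple[str, str]],
                   rpkm_by_contig: Mapping[str, float],
                   min_overlap: int = 200) -> list[TranscriptContig]:
    """Full curation: bin, version, flag and name every contig."""
    out: list[TranscriptContig] = []
    seqs = dict(contigs)
    for bin_ in bin_loci(contigs, min_overlap=min_overlap):
        versions = assign_versions(bin_, rpkm_by_contig)
        flags = flag_precursors(versions, rpkm_by_contig)
        for cid, version in versions.items():
            out.append(TranscriptContig(
                contig_id=cid,
                sequence=seqs[cid],
                locus_id=bin_.locus_id,
                version=version,
                rpkm=rpkm_by_contig[cid],
                precursor=flags[cid],
            ))
    out.sort(key=lambda c: c.contig_id)
    return out
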