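"""Polymorphism filtering and per-kilobase density (PPK) summaries;
positional classification of transposable-element annotations.

Only variant calls at the quality ceiling (999 by default) are trusted —
the value the callers emit for saturated-confidence sites — which removes
low-coverage and poor-quality calls in one stroke. PPK is
1000 * (SNPs + indels) / transcript length, with each indel counted as a
single polymorphism event regardless of length.

A TE annotation is classified by which contig termini it reaches within
``end_tol`` (10 nt by default): both -> full, only the 5' terminus ->
five_prime_end, only the 3' -> three_prime_end, neither -> internal.
Contigs are oriented transcripts, so the contig 5' is the transcript 5'.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import TEAnnotation, ValidationError, VariantRecord
from .stats import wilcoxon_rank_sum

REQUIRED_QUALITY = 999
END_TOLERANCE = 10

TE_CLASSES = ("full", "five_prime_end", "three_prime_end", "internal")


@dataclass(frozen=True)
class LocusPolymorphismSummary:
    locus_id: str
    length_bp: int
    n_snps: int
    n_indels: int
    ppk: float
    coding: bool = False


def filter_variants(records: Iterable[VariantRecord],
                    required_quality: int = REQUIRED_QUALITY
                    ) -> list[VariantRecord]:
    """Keep records whose quality equals the required value exactly."""
    return [r for r in records if r.quality == required_quality]


def summarize_ppk(variants: Iterable[VariantRecord],
                  locus_lengths: Mapping[str, int],
                  coding_flags: Mapping[str, bool] | None = None
                  ) -> list[LocusPolymorphismSummary]:
    """Per-locus SNP/indel counts and PPK; loci with no variants are
    included at PPK 0. Variants on loci absent from ``locus_lengths``
    raise a validation error."""
    snps: Counter[str] = Counter()
    indels: Counter[str] = Counter()
    for r in variants:
        if r.contig_id not in locus_lengths:
            raise ValidationError(f"variant on unknown locus {r.contig_id!r}")
        (snps if r.variant_class == "snp" else indels)[r.contig_id] += 1
    coding_flags = coding_flags or {}
    out = []
    for locus_id in sorted(locus_lengths):
        length = locus_lengths[locus_id]
        n_s, n_i = snps[locus_id], indels[locus_id]
        out.append(LocusPolymorphismSummary(
            locus_id=locus_id,
            length_bp=length,
            n_snps=n_s,
            n_indels=n_i,
            ppk=1000.0 * (n_s + n_i) / length,
            coding=bool(coding_flags.get(locus_id, False)),
        ))
    return out


def compare_ppk(group_a: Sequence[LocusPolymorphismSummary],
                group_b: Sequence[LocusPolymorphismSummary]
                ) -> tuple[float, float, float]:
    """(median PPK of a, median PPK of b, two-sided rank-sum p-value)."""
    ppk_a = [s.ppk for s in group_a]
    ppk_b = [s.ppk for s in group_b]
    return (float(np.median(ppk_a)), float(np.median(ppk_b)),
            wilcoxon_rank_sum(ppk_a, ppk_b))


def classify_te_coverage(annotation: TEAnnotation, contig_len: int,
                         end_tol: int = END_TOLERANCE) -> str:
    """Positional class of a TE annotation on its contig.

    Precedence is full > end-anchored > internal: an annotation reaching
    both termini within tolerance is "full" even though it also reaches
    each single end.
    """
    if annotation.end > contig_len:
        raise ValidationError(
            f"annotation {annotation.start}-{annotation.end} beyond contig "
            f"length {contig_len}"
        )
    at_five = annotation.start <= 1 + end_tol
    at_three = annotation.end >= contig_len - end_tol
    if at_five and at_three:
        return "full"
    if at_five:
        return "five_prime_end"
    if at_three:
        return "three_prime_end"
    return "internal"


def te_class_tally(annotations: Iterable[TEAnnotation],
                   contig_lengths: Mapping[str, int],
                   end_tol: int = END_TOLERANCE
                   ) -> tuple[dict[str, int], float]:
    """Counts per coverage class and the fraction of annotations anchored
    at exactly one end (NaN when there are no annotations)."""
    tally = {cls: 0 for cls in TE_CLASSES}
    for ann in annotations:
        if ann.contig_id not in contig_lengths:
            raise ValidationError(f"annotation on unknown contig "
                                  f"{ann.contig_id!r}")
        tally[classify_te_coverage(ann, contig_lengths[ann.contig_id],
                                   end_tol)] += 1
    total = sum(tally.values())
    if total == 0:
        return tally, float("nan")
    end_anchored = tally["five_prime_end"] + tally["three_prime_end"]
    return tally, end_anchored / total
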