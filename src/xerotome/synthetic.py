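"""Synthetic-data generators emulating the statistical structure of a
two-species de novo plant transcriptome study.

Every generator is deterministic given the configuration seed and returns
a truth record sufficient to score the downstream stage that consumes its
output (planted-vs-recovered comparisons). Each operation draws from its
own pseudo-random stream, derived from (seed, operation name), so adding
an operation never perturbs the others.

What is emulated: two species' transcript sets sharing ~95% identity per
ortholog, heterozygous polymorphism at ~2 vs ~4.4 events/kb, contaminant
contigs with shifted GC and low abundance, minor precursor isoforms below
10% of the major isoform, TE fragments embedded at known positions, and
tissue expression matrices with proximal-distal gradient archetypes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats_io import ExpressionMatrix, TEAnnotation, VariantRecord

BASES = np.array(list("ACGT"))
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
STOP_CODONS = {"TAA", "TAG", "TGA"}

# Abundance strata for the triage construction (log10 RPKM, mean and sd):
# high-confidence plant contigs span a wide dynamic range, unidentified
# plant contigs are typical transcripts, contaminants are rare — the
# abundance separation that RPKM triage presupposes (most RNA in the
# sample is from the plant).
LABELED_PLANT_LOGRPKM = (1.0, 0.8)
UNKNOWN_PLANT_LOGRPKM = (1.5, 0.35)
CONTAMINANT_LOGRPKM = (-1.0, 0.5)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_loci: int = 500
    mean_transcript_len: int = 1000
    species_divergence: float = 0.05
    het_rate_a: float = 2.07  # polymorphisms/kb, species A
    het_rate_b: float = 4.39  # polymorphisms/kb, species B
    contaminant_fraction: float = 0.10
    contaminant_gc_shift: float = 0.15
    te_fraction: float = 0.10
    n_samples: int = 4
    n_gradient_archetypes: int = 6
    plant_gc: float = 0.44
    coding_fraction: float = 0.6
    isoform_fraction: float = 0.3
    unknown_label_fraction: float = 0.3
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in ("species_divergence", "contaminant_fraction",
                     "te_fraction", "plant_gc", "coding_fraction",
                     "isoform_fraction", "unknown_label_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.het_rate_a < 0 or self.het_rate_b < 0:
            raise ValueError("polymorphism rates must be >= 0")
        if self.n_gradient_archetypes < 1:
            raise ValueError("n_gradient_archetypes must be >= 1")
        if self.mean_transcript_len < 1:
            raise ValueError("mean_transcript_len must be positive")


def stream(seed: int, op_name: str) -> np.random.Generator:
    """Independent per-operation random stream derived from (seed, op)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF,
                                zlib.crc32(op_name.encode())])
    )


def _random_sequence(rng: np.random.Generator, length: int,
                     gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _codon_weights(gc: float) -> tuple[list[str], np.ndarray]:
    pb = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if a + b + c not in STOP_CODONS]
    w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in codons])
    return codons, w / w.sum()


def _coding_sequence(rng: np.random.Generator, n_codons: int,
                     gc: float) -> str:
    codons, weights = _codon_weights(gc)
    body = rng.choice(codons, size=max(n_codons - 2, 0), p=weights)
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(body) + stop


def _mutate_nt(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


@dataclass
class TranscriptomeTruth:
    """Planted properties of a simulated contig set."""

    origin: dict[str, str] = field(default_factory=dict)  # plant|contaminant
    label: dict[str, str] = field(default_factory=dict)  # plant|contaminant|unknown
    rpkm: dict[str, float] = field(default_factory=dict)
    locus: dict[str, str] = field(default_factory=dict)
    coding: dict[str, bool] = field(default_factory=dict)
    orf_span: dict[str, tuple[int, int]] = field(default_factory=dict)
    te_annotations: list[TEAnnotation] = field(default_factory=list)
    te_placement: dict[int, str] = field(default_factory=dict)  # index -> class

    @property
    def contaminant_ids(self) -> list[str]:
        return sorted(c for c, o in self.origin.items() if o == "contaminant")


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], TranscriptomeTruth]:
    """Generate plant contigs (with minor isoforms and embedded TE
    fragments) plus GC-shifted, low-abundance contaminant contigs.

    Coding loci carry an embedded + strand ORF (ATG, stop-free codons,
    closing stop) spanning 60-80% of the contig. Contaminants are an
    independent i.i.d. model with GC = plant GC + ``contaminant_gc_shift``
    — homology-free by construction. TE fragments are mutated slices
    (10% divergence) of per-family consensus sequences, placed according
    to a known coverage class.
    """
    rng = stream(config.seed, "simulate_transcriptome")
    truth = TranscriptomeTruth()
    contigs: list[tuple[str, str]] = []

    consensus_len = 6 * config.mean_transcript_len + 10
    te_families = {
        "LTR retrotransposon": _random_sequence(rng, consensus_len, 0.46),
        "DNA transposon": _random_sequence(rng, consensus_len, 0.42),
    }
    te_classes = ["full", "five_prime_end", "three_prime_end", "internal"]

    for i in range(config.n_loci):
        locus = f"PL{i + 1}"
        length = int(np.clip(rng.lognormal(np.log(config.mean_transcript_len),
                                           0.35),
                             400, 6 * config.mean_transcript_len))
        coding = rng.random() < config.coding_fraction
        if coding:
            n_codons = int(length * rng.uniform(0.6, 0.8)) // 3
            cds = _coding_sequence(rng, n_codons, config.plant_gc)
            utr5 = _random_sequence(rng, (length - len(cds)) // 2,
                                    config.plant_gc)
            utr3 = _random_sequence(rng, length - len(cds) - len(utr5),
                                    config.plant_gc)
            seq = utr5 + cds + utr3
            truth.orf_span[f"{locus}_1"] = (len(utr5), len(utr5) + len(cds))
        else:
            seq = _random_sequence(rng, length, config.plant_gc)

        if rng.random() < config.te_fraction:
            placement = te_classes[rng.integers(len(te_classes))]
            family = sorted(te_families)[rng.integers(len(te_families))]
            consensus = te_families[family]
            L = len(seq)
            if placement == "full":
                start, end = 1, L
            elif placement == "five_prime_end":
                start, end = 1, int(L * rng.uniform(0.2, 0.5))
            elif placement == "three_prime_end":
                start, end = int(L * rng.uniform(0.5, 0.8)), L
            else:
                frag = int(rng.integers(80, 181))
                start = int(rng.integers(12, L - frag - 11))
                end = start + frag - 1
            frag_len = end - start + 1
            off = int(rng.integers(0, len(consensus) - frag_len + 1))
            fragment = _mutate_nt(rng, consensus[off:off + frag_len], 0.10)
            seq = seq[:start - 1] + fragment + seq[end:]
            truth.te_annotations.append(
                TEAnnotation(f"{locus}_1", start, end, family))
            truth.te_placement[len(truth.te_annotations) - 1] = placement
            truth.orf_span.pop(f"{locus}_1", None)
            coding = False

        cid = f"{locus}_1"
        unknown = rng.random() < config.unknown_label_fraction
        mu, sd = (UNKNOWN_PLANT_LOGRPKM if unknown else LABELED_PLANT_LOGRPKM)
        major_rpkm = float(10 ** rng.normal(mu, sd))
        contigs.append((cid, seq))
        truth.origin[cid] = "plant"
        truth.label[cid] = "unknown" if unknown else "plant"
        truth.rpkm[cid] = major_rpkm
        truth.locus[cid] = locus
        truth.coding[cid] = coding

        if rng.random() < config.isoform_fraction:
            mid = f"{locus}_2"
            overlap = max(200, len(seq) // 2)
            tail = _random_sequence(rng, int(rng.integers(100, 301)),
                                    config.plant_gc)
            minor_seq = seq[:overlap] + tail
            contigs.append((mid, minor_seq))
            truth.origin[mid] = "plant"
            truth.label[mid] = truth.label[cid]
            truth.rpkm[mid] = major_rpkm * float(rng.uniform(0.01, 0.08))
            truth.locus[mid] = locus
            truth.coding[mid] = False

    n_contaminants = int(round(config.contaminant_fraction * config.n_loci))
    for i in range(n_contaminants):
        cid = f"CT{i + 1}"
        length = int(np.clip(rng.lognormal(np.log(config.mean_transcript_len),
                                           0.35),
                             400, 6 * config.mean_transcript_len))
        seq = _random_sequence(rng, length,
                               config.plant_gc + config.contaminant_gc_shift)
        contigs.append((cid, seq))
        truth.origin[cid] = "contaminant"
        truth.label[cid] = ("unknown" if rng.random() < 0.5 else "contaminant")
        truth.rpkm[cid] = float(10 ** rng.normal(*CONTAMINANT_LOGRPKM))
        truth.locus[cid] = cid
        truth.coding[cid] = False

    return contigs, truth


def diverge_sequences(contigs: Sequence[tuple[str, str]], divergence: float,
                      seed: int) -> list[tuple[str, str]]:
    """Per-site substitution copy of each contig — an orthologous second
    species at ~(1 - divergence) identity."""
    rng = stream(seed, "diverge_sequences")
    return [(cid, _mutate_nt(rng, seq, divergence)) for cid, seq in contigs]


def simulate_reads(
    contigs: Sequence[tuple[str, str]],
    depth_per_contig: float,
    read_len: int,
    seed: int,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Uniformly positioned error-free reads at Poisson depth, plus the
    per-contig read-count table (consistent with the reads by
    construction)."""
    from .curation import reverse_complement

    if contigs and read_len > min(len(s) for _, s in contigs):
        raise ValueError("read_len exceeds the shortest contig")
    rng = stream(seed, "simulate_reads")
    reads: list[tuple[str, str]] = []
    counts: dict[str, int] = {}
    for cid, seq in contigs:
        n = int(rng.poisson(depth_per_contig * len(seq) / read_len))
        counts[cid] = n
        if n == 0:
            continue
        starts = rng.integers(0, len(seq) - read_len + 1, size=n)
        flips = rng.random(n) < 0.5
        for r, (s, flip) in enumerate(zip(starts, flips)):
            frag = seq[s:s + read_len]
            if flip:
                frag = reverse_complement(frag)
            reads.append((f"{cid}_r{r + 1}", frag))
    # a sequencer interleaves fragments from all templates; downstream
    # subsampling statistics (discovery curves) assume random read order
    order = rng.permutation(len(reads))
    return [reads[i] for i in order], counts


def inject_variants(
    contigs: Sequence[tuple[str, str]],
    rate_per_kb: float,
    indel_fraction: float = 0.1,
    decoy_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Plant SNP/indel calls at Poisson(rate * len/1000) per contig, all
    at quality 999; a ``decoy_fraction`` of extra low-quality records
    emulates unfiltered noise calls. Returns (all records, truth records);
    truth is exactly the quality-999 subset."""
    rng = stream(seed, "inject_variants")
    planted: list[VariantRecord] = []
    decoys: list[VariantRecord] = []
    for cid, seq in contigs:
        L = len(seq)
        n = int(rng.poisson(rate_per_kb * L / 1000.0))
        n_decoy = int(rng.poisson(decoy_fraction * rate_per_kb * L / 1000.0))
        usable = np.arange(2, L - 4)
        k = min(n + n_decoy, usable.size)
        positions = rng.choice(usable, size=k, replace=False)
        for idx, pos in enumerate(positions):
            pos = int(pos)
            base = seq[pos - 1]
            if base not in "ACGT":
                base = "A"
            if rng.random() < indel_fraction:
                ilen = int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    ref, alt = base, base + _random_sequence(rng, ilen, 0.5)
                else:
                    ref, alt = seq[pos - 1:pos + ilen], base
            else:
                ref = base
                alt = str(rng.choice([b for b in "ACGT" if b != base]))
            if idx < n:
                planted.append(VariantRecord(cid, pos, ref, alt, 999))
            else:
                decoys.append(
                    VariantRecord(cid, pos, ref, alt,
                                  int(rng.integers(20, 999))))
    records = sorted(planted + decoys,
                     key=lambda r: (r.contig_id, r.position))
    return records, planted


def _zprofile(values: Sequence[float]) -> np.ndarray:
    v = np.asarray(values, float)
    return (v - v.mean()) / v.std()


def gradient_archetypes(n_samples: int, n_archetypes: int) -> np.ndarray:
    """Unit-variance expression shapes along an ordered developmental
    axis: monotone up, monotone down, two peaked and two valley shapes."""
    t = np.linspace(0.0, 1.0, n_samples)
    peak2 = np.exp(-((t - 1 / 3) ** 2) / 0.02)
    peak3 = np.exp(-((t - 2 / 3) ** 2) / 0.02)
    shapes = [t, -t, peak2, peak3, -peak2, -peak3]
    if n_archetypes > len(shapes):
        raise ValueError(f"at most {len(shapes)} archetypes supported")
    return np.vstack([_zprofile(s) for s in shapes[:n_archetypes]])


def simulate_expression_gradients(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """RPKM matrix of loci over ordered proximal-to-distal sections, each
    locus following one gradient archetype plus Gaussian noise (on the
    relative scale, sd = ``noise_sd``). Returns the matrix and the
    locus -> archetype truth map."""
    rng = stream(config.seed, "simulate_expression_gradients")
    profiles = gradient_archetypes(config.n_samples,
                                   config.n_gradient_archetypes)
    locus_ids = [f"G{i + 1:04d}" for i in range(config.n_loci)]
    sample_ids = [f"S{j + 1}" for j in range(config.n_samples)]
    truth = {loc: i % len(profiles) for i, loc in enumerate(locus_ids)}
    baseline = 10 ** rng.normal(1.5, 0.4, size=config.n_loci)
    noise = rng.normal(0.0, config.noise_sd,
                       size=(config.n_loci, config.n_samples))
    rel = 1.0 + 0.5 * (profiles[[truth[loc] for loc in locus_ids]] + noise)
    values = np.clip(baseline[:, None] * rel, 0.0, None)
    return ExpressionMatrix(locus_ids, sample_ids, values), truth


def random_peptides(n: int, len_range: tuple[int, int] = (50, 500),
                    seed: int = 0) -> list[str]:
    """n i.i.d.-uniform peptides with lengths uniform on ``len_range``."""
    rng = stream(seed, "random_peptides")
    lo, hi = len_range
    out = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append("".join(rng.choice(AMINO_ACIDS, size=length)))
    return out


def mutate_peptides(peptides: Sequence[str], rate: float,
                    seed: int = 0) -> list[str]:
    """Per-residue substitution copies — planted orthologs at
    ~(1 - rate) identity."""
    rng = stream(seed, "mutate_peptides")
    out = []
    for pep in peptides:
        arr = np.array(list(pep))
        hit = rng.random(arr.size) < rate
        for i in np.flatnonzero(hit):
            arr[i] = rng.choice([a for a in AMINO_ACIDS if a != arr[i]])
        out.append("".join(arr))
    return out
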