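"""Composition-based protein thermostability score.

The score is a fixed linear combination of amino-acid molar fractions and
a normalized mean residue accessible surface area (ASA):

    score = 0.75*K + 0.2*E + 0.8*Pos + 0.2*Chg - 0.2*Sml - 0.2*Tiny
            - 0.3*A - 0.1*Q - 0.02*T + 0.9*ASA

where K, E, A, Q, T are single-residue molar fractions, Pos = {R,H,K},
Chg = {D,E,H,K,R}, Sml = {A,C,D,G,N,P,S,T,V}, Tiny = {A,C,G,S,T}, and ASA
is the mean per-residue Gly-X-Gly tripeptide surface area rescaled to
[0, 1] as (mean - 75) / 180. Glycine defines the 75 Å² minimum and
tryptophan the 255 Å² maximum of the per-residue table, so poly-G scores
-0.4 and poly-W scores +0.9.

Note on the ASA normalization: dividing the raw mean (75-255 Å²) by
180 Å² would give values in [0.42, 1.42], not the dimensionless [0, 1]
range the score expects; the implemented (mean - 75)/180 mapping is the
one consistent with that range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, wilcoxon_rank_sum

ASA_MIN = 75.0
ASA_MAX = 255.0
ASA_RANGE = ASA_MAX - ASA_MIN

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
POSITIVE = set("RHK")
CHARGED = set("DEHKR")
SMALL = set("ACDGNPSTV")
TINY = set("ACGST")

COEFFICIENTS = {
    "K": 0.75, "E": 0.2, "Pos": 0.8, "Chg": 0.2, "Sml": -0.2,
    "Tiny": -0.2, "A": -0.3, "Q": -0.1, "T": -0.02, "ASA": 0.9,
}


@dataclass(frozen=True)
class CompositionProfile:
    """The ten terms of the thermostability formula for one protein."""

    K: float
    E: float
    Pos: float
    Chg: float
    Sml: float
    Tiny: float
    A: float
    Q: float
    T: float
    ASA: float
    n_nonstandard: int = 0

    def __post_init__(self) -> None:
        for name in ("K", "E", "Pos", "Chg", "Sml", "Tiny", "A", "Q", "T",
                     "ASA"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")


def load_asa_table(path: str | Path | None = None) -> dict[str, float]:
    """Load a residue -> Gly-X-Gly surface area (Å²) table.

    Defaults to the packaged Chothia tripeptide table. Any user table must
    cover all 20 standard residues with Gly at the 75 Å² minimum and Trp
    at the 255 Å² maximum.
    """
    if path is None:
        source = resources.files("xerotome.data") / "chothia_asa.tsv"
        df = pd.read_csv(source.open(), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    table = dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
    missing = STANDARD_RESIDUES - set(table)
    if missing:
        raise ValueError(f"ASA table missing residues: {sorted(missing)}")
    if min(table[r] for r in STANDARD_RESIDUES) != ASA_MIN:
        raise ValueError("ASA table minimum must be 75 (Gly)")
    if max(table[r] for r in STANDARD_RESIDUES) != ASA_MAX:
        raise ValueError("ASA table maximum must be 255 (Trp)")
    return table


def composition_profile(
    aa_sequence: str, asa_table: Mapping[str, float] | None = None
) -> CompositionProfile:
    """Compute the composition terms of the score for one protein.

    Non-standard residues (X, B, Z, U, ...) are excluded from every count
    and from the ASA mean; a warning is emitted when any are present.
    """
    if asa_table is None:
        asa_table = load_asa_table()
    seq = aa_sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    counted = [r for r in seq if r in STANDARD_RESIDUES]
    n_nonstandard = len(seq) - len(counted)
    if not counted:
        raise ValueError("sequence contains no standard residues")
    if n_nonstandard:
        warnings.warn(
            f"{n_nonstandard} non-standard residues excluded from "
            "composition profile",
            stacklevel=2,
        )
    n = len(counted)
    count = {r: 0 for r in STANDARD_RESIDUES}
    for r in counted:
        count[r] += 1
    frac = lambda group: sum(count[r] for r in group) / n  # noqa: E731
    mean_asa = sum(asa_table[r] * c for r, c in count.items()) / n
    return CompositionProfile(
        K=count["K"] / n,
        E=count["E"] / n,
        Pos=frac(POSITIVE),
        Chg=frac(CHARGED),
        Sml=frac(SMALL),
        Tiny=frac(TINY),
        A=count["A"] / n,
        Q=count["Q"] / n,
        T=count["T"] / n,
        ASA=(mean_asa - ASA_MIN) / ASA_RANGE,
        n_nonstandard=n_nonstandard,
    )


def thermostability_score(profile: CompositionProfile) -> float:
    """Evaluate the fixed linear combination on a composition profile."""
    return sum(COEFFICIENTS[name] * getattr(profile, name)
               for name in COEFFICIENTS)


def score_sequence(aa_sequence: str,
                   asa_table: Mapping[str, float] | None = None) -> float:
    """Convenience: profile + score in one call."""
    return thermostability_score(composition_profile(aa_sequence, asa_table))


def proteome_thermo_compare(
    scores_by_group: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group score summaries and BH-adjusted pairwise rank-sum tests.

    Returns ``(summaries, pairwise)``: summaries indexed by group with
    n/median/q1/q3 columns; pairwise with one row per unordered group pair
    and raw plus adjusted two-sided Wilcoxon p-values.
    """
    groups = sorted(scores_by_group)
    summaries = pd.DataFrame(
        {
            "n": [len(scores_by_group[g]) for g in groups],
            "median": [float(np.median(scores_by_group[g])) for g in groups],
            "q1": [float(np.percentile(scores_by_group[g], 25)) for g in groups],
            "q3": [float(np.percentile(scores_by_group[g], 75)) for g in groups],
        },
        index=groups,
    )
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    raw = [wilcoxon_rank_sum(scores_by_group[a], scores_by_group[b])
           for a, b in pairs]
    pairwise = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_adjusted": bh_adjust(raw) if raw else [],
        }
    )
    return summaries, pairwise
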