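"""Radical vs conservative amino-acid differences (Kr/Kc).

A model-free, non-parametric proxy for the strength of purifying selection:
over every unordered pair of sequences in a gene's alignment, and every
column where both residues are standard amino acids, count differences that
cross a physicochemical category boundary (radical) versus stay within one
(conservative).  Counts are normalized by the opportunity fractions f_r and
f_c — the fractions of the 190 unordered amino-acid pairs that are cross-
versus within-category — so that under equal substitution probabilities the
expected ratio is 1.  No tree or ancestral reconstruction is used, which
biases the statistic towards radical changes for divergent sequences; the
raw-count ratio is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .phylo_engine import AA_ALPHABET, Alignment

_AA_SET = set(AA_ALPHABET)


@dataclass(frozen=True)
class AaClassification:
    """A partition of the 20 standard amino acids into categories.

    The opportunity fractions are recomputed from the table: ``f_radical``
    is the fraction of the 190 unordered residue pairs whose members lie in
    different categories.
    """

    name: str
    category_of: dict[str, str]

    def __post_init__(self):
        assigned = set(self.category_of)
        if assigned != _AA_SET:
            raise ValueError(
                f"classification {self.name!r} must assign every standard "
                f"amino acid exactly once (missing/extra: {sorted(assigned ^ _AA_SET)})"
            )
        if len(set(self.category_of.values())) < 2:
            raise ValueError("classification needs at least 2 categories")

    @property
    def f_radical(self) -> float:
        cross = sum(
            1
            for a, b in combinations(AA_ALPHABET, 2)
            if self.category_of[a] != self.category_of[b]
        )
        return cross / 190.0

    @property
    def f_conservative(self) -> float:
        return 1.0 - self.f_radical


def _table(name: str, groups: dict[str, str]) -> AaClassification:
    cat = {}
    for label, members in groups.items():
        for aa in members:
            cat[aa] = label
    return AaClassification(name, cat)


#: Charge classes (Zhang-style): positive, negative, neutral.
CHARGE = _table(
    "charge", {"positive": "KRH", "negative": "DE", "neutral": "ACFGILMNPQSTVWY"}
)

#: Polarity classes: polar vs nonpolar.
POLARITY = _table(
    "polarity", {"polar": "RNDCQEGHKSTY", "nonpolar": "AILMFPWV"}
)

#: Polarity-and-volume classes (six groups).
POLARITY_VOLUME = _table(
    "polarity_volume",
    {
        "special": "C",
        "neutral_small": "AGPST",
        "polar_small": "NDQE",
        "polar_large": "RHK",
        "nonpolar_small": "ILMV",
        "nonpolar_large": "FWY",
    },
)

CLASSIFICATIONS = {c.name: c for c in (CHARGE, POLARITY, POLARITY_VOLUME)}


@dataclass
class KrKcResult:
    gene_id: str
    n_radical: int
    n_conservative: int
    n_comparisons: int
    ratio: float | None          # opportunity-normalized; None when undefined
    ratio_raw: float | None      # plain n_radical / n_conservative
    undefined_reason: str | None = None


def classify_pair(classification: AaClassification, residue_a: str, residue_b: str) -> str:
    """Classify one residue pair as ``same``, ``conservative`` or ``radical``."""
    if residue_a not in _AA_SET or residue_b not in _AA_SET:
        raise ValueError(f"non-standard residue pair ({residue_a!r}, {residue_b!r})")
    if residue_a == residue_b:
        return "same"
    if classification.category_of[residue_a] == classification.category_of[residue_b]:
        return "conservative"
    return "radical"


def krkc_ratio(alignment: Alignment, classification: AaClassification = CHARGE) -> KrKcResult:
    """Per-gene radical/conservative counts and normalized ratio.

    Tallies over all unordered sequence pairs and all columns where both
    residues are standard amino acids (gaps and ambiguities skipped).
    ratio = (n_radical / f_r) / (n_conservative / f_c); undefined when no
    conservative difference was observed.
    """
    taxa = alignment.taxa
    if len(taxa) < 2:
        raise ValueError("Kr/Kc needs at least 2 sequences")
    enc = alignment.encoded(taxa)  # 20 = missing

    # map residue index -> integer category id
    cats = sorted(set(classification.category_of.values()))
    cat_id = {c: i for i, c in enumerate(cats)}
    cat_of_idx = np.array(
        [cat_id[classification.category_of[a]] for a in AA_ALPHABET] + [-1]
    )

    n_rad = n_con = n_cmp = 0
    for i, j in combinations(range(len(taxa)), 2):
        a, b = enc[i], enc[j]
        valid = (a < 20) & (b < 20)
        n_cmp += int(valid.sum())
        diff = valid & (a != b)
        cross = cat_of_idx[a[diff]] != cat_of_idx[b[diff]]
        n_rad += int(cross.sum())
        n_con += int((~cross).sum())

    f_r = classification.f_radical
    f_c = classification.f_conservative
    if n_con == 0:
        reason = (
            "no differences observed" if n_rad == 0 else "no conservative differences"
        )
        return KrKcResult(alignment.gene_id, n_rad, n_con, n_cmp, None, None, reason)
    ratio = (n_rad / f_r) / (n_con / f_c)
    return KrKcResult(
        alignment.gene_id, n_rad, n_con, n_cmp, ratio, n_rad / n_con, None
    )
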