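"""Applicability domain via statistical defects of codes.

A code's statistical defect measures how inconsistently it is distributed
across the three training subsets (active, passive, calibration).  With
P, P′, P″ its probabilities (record frequency / subset size) and N, N′, N″
its frequencies in those subsets:

    d = |P − P′|/(N + N′) + |P − P″|/(N + N″) + |P′ − P″|/(N′ + N″)

Codes the training data cannot vouch for — too rare, or missing from one of
the subsets entirely — carry the maximal defect 1.0.  The defect of a
quasi-SMILES is the sum of its codes' defects, and it is in the
applicability domain when that sum stays below twice the mean defect of the
training quasi-SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import Code, QuasiSmiles
from .datasets import Dataset
from .descriptor import CorrelationWeights

__all__ = [
    "DefectTable",
    "DomainAssessment",
    "code_defect",
    "defect_table",
    "qs_defect",
    "assess",
]

_TRAIN_LABELS = ("A", "P", "C")


def code_defect(
    freqs: Sequence[int],
    sizes: Sequence[int],
    *,
    strict: bool = True,
    min_frequency: int = 4,
) -> float:
    """Statistical defect of one code from its three-subset frequencies.

    ``freqs`` are the record counts (N, N′, N″) of the code in the active,
    passive and calibration subsets of sizes ``sizes``.  Terms with a zero
    denominator contribute 0.  In strict mode a code absent from any subset
    gets defect 1.0; independently, a code whose total frequency falls below
    ``min_frequency`` gets 1.0.
    """
    n, np_, nc = (int(f) for f in freqs)
    if n < 0 or np_ < 0 or nc < 0:
        raise ValueError("negative frequency")
    if n + np_ + nc == 0:
        raise ValueError("code absent from all three subsets")
    if strict and min(n, np_, nc) == 0:
        return 1.0
    if n + np_ + nc < min_frequency:
        return 1.0
    p = [f / s for f, s in zip((n, np_, nc), sizes)]
    total = 0.0
    for (pa, pb, fa, fb) in (
        (p[0], p[1], n, np_),
        (p[0], p[2], n, nc),
        (p[1], p[2], np_, nc),
    ):
        if fa + fb > 0:
            total += abs(pa - pb) / (fa + fb)
    return total


@dataclass(frozen=True)
class DefectTable:
    """Per-code defects, either computed from a split or loaded externally.

    The table defines the modeled code vocabulary; the counts frame (when
    computed) records the per-subset frequencies and probabilities.
    """

    d: Mapping[Code, float]
    counts: pd.DataFrame | None = None
    min_frequency: int = 4
    strict: bool = True

    def __post_init__(self) -> None:
        bad = [c for c, v in self.d.items() if v < 0 or not np.isfinite(v)]
        if bad:
            raise ValueError(f"invalid defects for {bad}")

    @classmethod
    def from_mapping(cls, d: Mapping[Code, float]) -> "DefectTable":
        return cls(dict(d))

    @classmethod
    def from_tsv(cls, path, code_col: str = "code", defect_col: str = "defect") -> "DefectTable":
        from .codes import normalize_code

        frame = pd.read_csv(path, sep="\t")
        frame[code_col] = frame[code_col].map(normalize_code)
        frame = frame.drop_duplicates(code_col, keep="last")
        return cls(dict(zip(frame[code_col], frame[defect_col].astype(float))))


def defect_table(
    dataset: Dataset,
    *,
    min_frequency: int = 4,
    strict: bool = True,
) -> DefectTable:
    """Compute defects for every code appearing in the A∪P∪C subsets."""
    sub = {lab: dataset.subset(lab) for lab in _TRAIN_LABELS}
    sizes = [len(sub[lab]) for lab in _TRAIN_LABELS]
    if min(sizes) == 0:
        raise ValueError("A, P and C subsets must all be non-empty")
    counts = {lab: sub[lab].code_counts() for lab in _TRAIN_LABELS}
    vocab = sorted(dataset.vocabulary(_TRAIN_LABELS))
    rows = []
    d = {}
    for c in vocab:
        freqs = [counts[lab].get(c, 0) for lab in _TRAIN_LABELS]
        d[c] = code_defect(freqs, sizes, strict=strict, min_frequency=min_frequency)
        rows.append((c, *freqs, *(f / s for f, s in zip(freqs, sizes)), d[c]))
    frame = pd.DataFrame(
        rows, columns=["code", "N_A", "N_P", "N_C", "P_A", "P_P", "P_C", "d"]
    )
    return DefectTable(d, frame, min_frequency, strict)


def qs_defect(
    qs: QuasiSmiles,
    table: DefectTable,
    *,
    weights: CorrelationWeights | None = None,
    missing_defect: float = 0.0,
) -> float:
    """Summed statistical defect Dj of one quasi-SMILES.

    Only non-blocked codes are counted: codes blocked in ``weights`` (when
    supplied) are skipped, and codes outside the table's vocabulary — rare
    by construction — contribute ``missing_defect`` (default 0.0, the
    blocked-code reading; set 1.0 to treat unknown codes as maximally
    suspect instead).
    """
    total = 0.0
    for c in qs.codes:
        if weights is not None and c in weights.blocked:
            continue
        total += table.d.get(c, missing_defect)
    return total


@dataclass(frozen=True)
class DomainAssessment:
    """Per-record verdicts plus the threshold they were judged against."""

    per_record: pd.DataFrame  # id, Dj, n_missing, in_domain
    mean_defect: float
    threshold: float

    def in_domain_ids(self) -> list[int]:
        return list(self.per_record.loc[self.per_record.in_domain, "id"])

    def out_of_domain_ids(self) -> list[int]:
        return list(self.per_record.loc[~self.per_record.in_domain, "id"])


def assess(
    dataset: Dataset,
    table: DefectTable,
    *,
    weights: CorrelationWeights | None = None,
    missing_defect: float = 0.0,
) -> DomainAssessment:
    """Judge every record of the dataset against the domain threshold.

    The mean defect D̄ is taken over the A∪P∪C records only (the validation
    set must not influence its own admissibility), and a record is in
    domain iff Dj < 2·D̄.
    """
    dj = {}
    nmiss = {}
    for r in dataset.records:
        dj[r.id] = qs_defect(r.qs, table, weights=weights, missing_defect=missing_defect)
        nmiss[r.id] = sum(1 for c in r.qs.codes if c not in table.d)
    train_dj = [dj[r.id] for r in dataset.records if r.set_label in _TRAIN_LABELS]
    if not train_dj:
        raise ValueError("no A/P/C records to define the domain threshold")
    mean_defect = float(np.mean(train_dj))
    threshold = 2.0 * mean_defect
    frame = pd.DataFrame(
        {
            "id": [r.id for r in dataset.records],
            "Dj": [dj[r.id] for r in dataset.records],
            "n_missing": [nmiss[r.id] for r in dataset.records],
            "in_domain": [dj[r.id] < threshold for r in dataset.records],
        }
    )
    return DomainAssessment(frame, mean_defect, threshold)
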