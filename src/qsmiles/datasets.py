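"""Datasets of endpoint observations, file IO, random structured splits, and
the bundled reference fixtures.

A :class:`Record` ties a quasi-SMILES to one measured endpoint value (a
log-scale half-maximal concentration, treated as a given real) and optionally
to one of four subset labels:

* ``A`` — active training set: correlation weights are tuned to fit it,
* ``P`` — passive training set: guards against split-specific overfit,
* ``C`` — calibration set: hosts the ideality terms of the target function,
* ``V`` — validation set: untouched until final assessment.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import Code, QuasiSmiles, parse_quasi_smiles

__all__ = [
    "SET_LABELS",
    "Record",
    "Dataset",
    "SplitAssignment",
    "read_dataset",
    "write_dataset",
    "random_split",
    "split_overlap",
    "load_reference_dataset",
    "load_reference_frame",
    "load_reference_code_table",
]

SET_LABELS = ("A", "P", "C", "V")


@dataclass(frozen=True)
class Record:
    """One endpoint observation."""

    id: int
    qs: QuasiSmiles
    endpoint: float
    set_label: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.endpoint):
            raise ValueError(f"record {self.id}: endpoint must be finite")
        if self.set_label is not None and self.set_label not in SET_LABELS:
            raise ValueError(
                f"record {self.id}: unknown set label {self.set_label!r}"
            )


class Dataset:
    """An ordered collection of records with unique ids."""

    def __init__(self, records: Iterable[Record]):
        self.records: list[Record] = list(records)
        seen = collections.Counter(r.id for r in self.records)
        dupes = [i for i, c in seen.items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate record ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.records == other.records

    def subset(self, label: str) -> "Dataset":
        return Dataset(r for r in self.records if r.set_label == label)

    def set_counts(self) -> dict[str, int]:
        counts = collections.Counter(
            r.set_label for r in self.records if r.set_label is not None
        )
        return {lab: counts.get(lab, 0) for lab in SET_LABELS}

    def with_labels(self, assignment: "SplitAssignment") -> "Dataset":
        """Return a relabeled copy; every id must be covered."""
        missing = [r.id for r in self.records if r.id not in assignment.mapping]
        if missing:
            raise ValueError(f"assignment missing ids: {missing}")
        return Dataset(
            Record(r.id, r.qs, r.endpoint, assignment.mapping[r.id])
            for r in self.records
        )

    def code_counts(self, label: str | None = None) -> collections.Counter:
        """Record-level code frequencies (a code repeated within one record
        counts once), optionally restricted to one set."""
        counts: collections.Counter = collections.Counter()
        for r in self.records:
            if label is None or r.set_label == label:
                counts.update(set(r.qs.codes))
        return counts

    def vocabulary(self, labels: Sequence[str] | None = None) -> set[Code]:
        """All codes appearing in the dataset (optionally only in the
        given set labels)."""
        return {
            c
            for r in self.records
            if labels is None or r.set_label in labels
            for c in r.qs.codes
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "quasi_smiles": [r.qs.normalized for r in self.records],
                "endpoint": [r.endpoint for r in self.records],
                "set": [r.set_label or "" for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Dataset":
        required = {"id", "quasi_smiles", "endpoint"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"dataset table missing columns: {sorted(missing)}")
        records = []
        for row in frame.itertuples(index=False):
            label = getattr(row, "set", None)
            if label is not None and (pd.isna(label) or label == ""):
                label = None
            endpoint = float(row.endpoint)
            records.append(
                Record(int(row.id), parse_quasi_smiles(row.quasi_smiles), endpoint, label)
            )
        return cls(records)


@dataclass(frozen=True)
class SplitAssignment:
    """A complete id → set-label mapping produced by one random split."""

    mapping: Mapping[int, str]
    seed: int
    fractions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)

    def counts(self) -> dict[str, int]:
        counter = collections.Counter(self.mapping.values())
        return {lab: counter.get(lab, 0) for lab in SET_LABELS}


def read_dataset(source: str | Path, *, csv: bool = False) -> Dataset:
    """Read a dataset table (TSV by default, CSV via flag).

    Requires columns ``id``, ``quasi_smiles``, ``endpoint``; an optional
    ``set`` column carries A/P/C/V labels.  Extra columns are ignored.
    An empty file yields an empty dataset.
    """
    try:
        frame = pd.read_csv(
            source,
            sep="," if csv else "\t",
            dtype={"set": "string"},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return Dataset([])
    return Dataset.from_frame(frame)


def write_dataset(dataset: Dataset, target: str | Path, *, csv: bool = False) -> None:
    dataset.to_frame().to_csv(target, sep="," if csv else "\t", index=False)


def _apportion(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items over the fractions."""
    quotas = [n * f for f in fractions]
    sizes = [int(q) for q in quotas]
    remainders = sorted(
        range(len(fractions)), key=lambda i: quotas[i] - sizes[i], reverse=True
    )
    for i in remainders[: n - sum(sizes)]:
        sizes[i] += 1
    return sizes


def random_split(
    dataset: Dataset,
    fractions: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> SplitAssignment:
    """Uniformly shuffle the records and deal them into A/P/C/V.

    Set sizes follow largest-remainder apportionment, so realized fractions
    differ from the requested ones by at most one record.  Deterministic
    given the seed.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    if len(fractions) != len(SET_LABELS):
        raise ValueError(f"need {len(SET_LABELS)} fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(dataset) < len(SET_LABELS):
        raise ValueError("fewer records than sets")
    sizes = _apportion(len(dataset), fractions)
    rng = np.random.default_rng(seed)
    ids = [r.id for r in dataset.records]
    order = rng.permutation(len(ids))
    mapping: dict[int, str] = {}
    pos = 0
    for label, size in zip(SET_LABELS, sizes):
        for k in order[pos : pos + size]:
            mapping[ids[k]] = label
        pos += size
    return SplitAssignment(mapping, seed, tuple(fractions))


def split_overlap(a: SplitAssignment, b: SplitAssignment) -> float:
    """Fraction of ids assigned the same label by both splits."""
    if set(a.mapping) != set(b.mapping):
        raise ValueError("split assignments cover different id universes")
    same = sum(1 for i, lab in a.mapping.items() if b.mapping[i] == lab)
    return same / len(a.mapping)


# ---------------------------------------------------------------------------
# Bundled reference fixtures: a 102-measurement nanoparticle cytotoxicity
# dataset (split 1, with the reference model's descriptor/calculated/defect
# columns) and its per-code correlation-weight/defect table.

def _data_path(name: str) -> Path:
    return Path(resources.files("qsmiles.data") / name)


def load_reference_frame() -> pd.DataFrame:
    """The bundled split-1 table with all reference columns.

    Columns: id, quasi_smiles, endpoint, set, dcw (reference descriptor),
    calc (reference prediction), defect_sum (reference Dj), ad (YES/No).
    """
    return pd.read_csv(_data_path("split1_dataset.tsv"), sep="\t")


def load_reference_dataset() -> Dataset:
    """The bundled 102-record dataset with its original A/P/C/V labels."""
    return Dataset.from_frame(load_reference_frame())


def load_reference_code_table() -> pd.DataFrame:
    """The bundled per-code table: normalized code, group, correlation
    weight, and statistical defect.

    Tokens are stored as printed in the source (dot padding, unicode
    dashes); normalization happens here.  On normalization collisions the
    last row wins.
    """
    from .codes import normalize_code

    frame = pd.read_csv(_data_path("code_weights.tsv"), sep="\t")
    frame["code"] = frame["code"].map(normalize_code)
    frame["group"] = frame["group"].replace("-", pd.NA).ffill()
    return frame.drop_duplicates("code", keep="last").reset_index(drop=True)
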