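"""Synthetic quasi-SMILES datasets with known additive ground truth.

The generator emulates the five-slot structure of the real nanoparticle
cytotoxicity records — particle type, particle size, exposure time, endpoint
kind, cell line — drawing one code per slot uniformly and building the
endpoint as

    endpoint = intercept + Σ_slots true_weight(code) + noise

Because every record has exactly one code per slot, per-slot constants can
be shifted freely between slots and the intercept: true weights are
identified only up to that gauge, so recovery checks compare within-slot
weight differences, never absolute weights.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .codes import Code, QuasiSmiles
from .datasets import Dataset, Record

__all__ = ["GeneratorSpec", "default_slots", "generate", "degrade"]


def default_slots() -> tuple[tuple[Code, ...], ...]:
    """Five vocabularies shaped like the real data: 12 particles, 10 sizes,
    6 exposure times, 3 endpoint kinds, 5 cell lines."""
    particles = ("[ag]", "[cuo]", "[zno]", "[tio2]", "[ceo2]", "[fe2o3]",
                 "[mgo]", "[nio]", "[sb2o3]", "[sno2]", "[cu2o]", "[mn3o4]")
    sizes = ("[nm5]", "[nm10]", "[nm15]", "[nm20]", "[nm30]", "[nm42]",
             "[nm50]", "[nm90]", "[nm149]", "[nm-]")
    times = ("[12h]", "[24h]", "[36h]", "[48h]", "[60h]", "[108]")
    kinds = ("[ec50]", "[ic50]", "[lc50]")
    cells = ("[a549]", "[mcf-7]", "[thp-1]", "[hepg2]", "[caco2]")
    return (particles, sizes, times, kinds, cells)


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth of one synthetic dataset.

    ``true_weights`` maps every slot code to its additive effect on the
    endpoint; ``noise_sd`` is the Gaussian noise scale (``noise_df`` switches
    to Student-t noise with that many degrees of freedom, scaled to
    ``noise_sd``, for heavy-tail robustness checks).
    """

    slots: tuple[tuple[Code, ...], ...] = field(default_factory=default_slots)
    true_weights: Mapping[Code, float] = field(default_factory=dict)
    intercept: float = -3.5
    noise_sd: float = 0.1
    n: int = 200
    seed: int = 0
    noise_df: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(len(s) == 0 for s in self.slots):
            raise ValueError("every slot needs at least one code")

    @classmethod
    def default(cls, n: int = 200, noise_sd: float = 0.1, seed: int = 0, **kw) -> "GeneratorSpec":
        """A spec with effects drawn once, uniformly on [−1, 1], from the seed."""
        slots = kw.pop("slots", default_slots())
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
        weights = {c: float(rng.uniform(-1, 1)) for slot in slots for c in slot}
        return cls(slots=slots, true_weights=weights, n=n, noise_sd=noise_sd, seed=seed, **kw)


def generate(spec: GeneratorSpec) -> Dataset:
    """Draw a synthetic dataset; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n):
        codes = tuple(slot[rng.integers(len(slot))] for slot in spec.slots)
        value = spec.intercept + sum(spec.true_weights.get(c, 0.0) for c in codes)
        if spec.noise_sd > 0:
            if spec.noise_df is not None:
                value += spec.noise_sd * rng.standard_t(spec.noise_df)
            else:
                value += rng.normal(0.0, spec.noise_sd)
        qs = QuasiSmiles(codes, "".join(codes))
        records.append(Record(i + 1, qs, float(value)))
    return Dataset(records)


def degrade(dataset: Dataset, fraction_rare: float, seed: int = 0) -> Dataset:
    """Replace one code in a random fraction of records with a singleton.

    Each touched record gets a unique code (``[rare<i>]``) in a random
    slot, so rare-code blocking and maximal statistical defects trigger
    downstream.  ``fraction_rare=0`` returns the dataset unchanged.
    """
    if not 0 <= fraction_rare < 1:
        raise ValueError("fraction_rare must be in [0, 1)")
    if fraction_rare == 0:
        return dataset
    rng = np.random.default_rng(seed)
    n_touch = int(round(fraction_rare * len(dataset)))
    touched = set(rng.choice(len(dataset), size=n_touch, replace=False).tolist())
    records = []
    for i, r in enumerate(dataset.records):
        if i in touched:
            codes = list(r.qs.codes)
            codes[rng.integers(len(codes))] = f"[rare{i}]"
            records.append(Record(r.id, QuasiSmiles(tuple(codes), "".join(codes)),
                                  r.endpoint, r.set_label))
        else:
            records.append(r)
    return Dataset(records)
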