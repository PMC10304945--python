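import numpy as np
import pytest

import qsmiles as q
from qsmiles.domain import DefectTable


@pytest.fixture(scope="session")
def ref_ds() -> q.Dataset:
    """The bundled 102-record split-1 dataset with its original labels."""
    return q.load_reference_dataset()


@pytest.fixture(scope="session")
def ref_frame():
    """The bundled table with reference dcw/calc/defect_sum/ad columns."""
    return q.load_reference_frame()


@pytest.fixture(scope="session")
def code_table():
    return q.load_reference_code_table()


@pytest.fixture(scope="session")
def ref_defects(code_table) -> DefectTable:
    """The bundled per-code statistical defects as a lookup table."""
    return DefectTable.from_mapping(
        dict(zip(code_table["code"], code_table["defect"]))
    )


@pytest.fixture(scope="session")
def synth_spec() -> q.GeneratorSpec:
    return q.GeneratorSpec.default(n=200, noise_sd=0.1, seed=42)


@pytest.fixture(scope="session")
def synth_labeled(synth_spec) -> q.Dataset:
    """A labeled synthetic dataset with known additive ground truth."""
    ds = q.generate(synth_spec)
    return ds.with_labels(q.random_split(ds, seed=7))
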