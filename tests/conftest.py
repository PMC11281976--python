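import numpy as np
import pandas as pd
import pytest

from morphosize import MeasurementTable, VariableCatalog, VariableDef, load_catalog


@pytest.fixture
def cranium_catalog():
    return load_catalog("cranium")


@pytest.fixture
def tiny_catalog():
    return VariableCatalog(
        structure="synthetic",
        variables=(
            VariableDef("length a", "A", "linear"),
            VariableDef("length b", "B", "linear"),
            VariableDef("length c", "C", "linear"),
        ),
    )


@pytest.fixture
def mixed_catalog():
    """Two linear variables plus one angle, for pass-through behavior."""
    return VariableCatalog(
        structure="synthetic",
        variables=(
            VariableDef("length a", "A", "linear"),
            VariableDef("length b", "B", "linear"),
            VariableDef("angle t", "T", "angle"),
        ),
    )


def make_table(catalog, values, ids=None, maturity="mature", **meta_cols):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"sp{i + 1}" for i in range(len(values))]
    frame = pd.DataFrame(
        values, columns=catalog.abbreviations, index=pd.Index(ids, name="specimen_id")
    )
    meta = pd.DataFrame({"maturity": maturity, **meta_cols}, index=frame.index)
    return MeasurementTable(catalog=catalog, values=frame, meta=meta)


@pytest.fixture
def random_table(tiny_catalog):
    rng = np.random.default_rng(7)
    return make_table(tiny_catalog, rng.lognormal(4.0, 0.3, size=(20, 3)))
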