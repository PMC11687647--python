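import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from zipfadapt import (
    CompletionEngine,
    Label,
    Terminology,
    generate_terminology,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_terminology() -> Terminology:
    """Small hand-built problem list mirroring the worked log examples."""
    return Terminology(
        (
            Label(2477, "Accident vasculaire cérébral ischémique", ("avc",)),
            Label(4578, "Diabète de Type 2"),
            Label(10598, "Douleur rétrosternale", ("drs",)),
            Label(847, "Infection des voies respiratoires supérieures", ("ivrs",)),
            Label(31, "Diabète insipide"),
        )
    )


@pytest.fixture(scope="session")
def toy_engine(toy_terminology) -> CompletionEngine:
    return CompletionEngine(toy_terminology, J=30)


@pytest.fixture(scope="session")
def synth_terminology() -> Terminology:
    return generate_terminology(100, seed=7)


@pytest.fixture(scope="session")
def synth_engine(synth_terminology) -> CompletionEngine:
    return CompletionEngine(synth_terminology, J=30)


@pytest.fixture()
def toy_log() -> pd.DataFrame:
    """Raw log shaped like the hospital dataset's record schema."""
    rows = [
        ("J. Doe", "diabet", 4578, 1),
        ("J. Doe", "diab", 4578, 2),
        ("J. Doe", "ac vas", 2477, 3),
        ("B. Lee", "diab", 4578, 4),
        ("J. Doe", "diab", 4578, 5),
        ("B. Lee", "drs", 10598, 6),
        ("J. Doe", "ivrs", 847, 7),
    ]
    return pd.DataFrame(rows, columns=["user", "query", "label_id", "timestamp"])
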