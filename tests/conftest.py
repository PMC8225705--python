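import numpy as np
import pandas as pd
import pytest

from contextgem.model import build_model


@pytest.fixture
def chain_model():
    """EX_A (0..10) → A, A→B, B→EX (0..1000): optimum export = 10."""
    return build_model([
        ("EX_A", {"A": 1.0}, 0.0, 10.0),
        ("A_to_B", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        ("EX_B", {"B": -1.0}, 0.0, 1000.0),
    ], objective={"EX_B": 1.0}, model_id="chain")


@pytest.fixture
def parallel_model():
    """Two parallel A→B paths sharing uptake and export."""
    return build_model([
        ("EX_A", {"A": 1.0}, 0.0, 10.0),
        ("high_path", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        ("low_path", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        ("EX_B", {"B": -1.0}, 0.0, 1000.0),
    ], objective={"EX_B": 1.0}, model_id="parallel")


@pytest.fixture
def labelled_model():
    """Parallel model with GPRs and subsystem labels."""
    return build_model(
        [
            ("EX_A", {"A": 1.0}, 0.0, 10.0),
            ("high_path", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            ("low_path", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            ("EX_B", {"B": -1.0}, 0.0, 1000.0),
        ],
        gprs={"high_path": "(g1 and g2) or g3", "low_path": "g4"},
        subsystems={"high_path": "glycolysis", "low_path": "bypass",
                    "EX_A": "exchange", "EX_B": "exchange"},
        objective={"EX_B": 1.0},
        model_id="labelled")
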