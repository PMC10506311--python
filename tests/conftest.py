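import numpy as np
import pandas as pd
import pytest

import polymir as pm


@pytest.fixture(scope="session")
def trio_default():
    """Default-scale simulated trio (1,000 features) with its truth table."""
    matrix, truth = pm.generate_trio_counts(pm.TrioSimConfig(seed=1))
    return pm.normalize_rpm(matrix), truth


@pytest.fixture(scope="session")
def trio_calls(trio_default):
    matrix, truth = trio_default
    return pm.classify_trio(matrix), truth


@pytest.fixture(scope="session")
def degradome_clean():
    """Zero-background degradome scenario: planted sites only."""
    cfg = pm.DegradomeSimConfig(seed=3, background_tag_rate=0.0)
    return pm.generate_degradome_scenario(cfg)


@pytest.fixture(scope="session")
def hairpin_suite():
    return pm.generate_hairpin_fixtures(seed=11)


def tiny_trio(h_rows, p1_rows, p2_rows):
    """Hand-built 3x3-replicate matrix from per-genotype row lists."""
    n = len(h_rows)
    data = {}
    for rep in range(3):
        data[f"T44_{rep + 1}"] = [r[rep] for r in p1_rows]
        data[f"T45_{rep + 1}"] = [r[rep] for r in p2_rows]
        data[f"H21_{rep + 1}"] = [r[rep] for r in h_rows]
    counts = pd.DataFrame(data, index=[f"f{i}" for i in range(n)])
    roles = {c: {"T44": "P1", "T45": "P2", "H21": "H"}[c.rsplit("_", 1)[0]]
             for c in counts.columns}
    return pm.TrioCountMatrix(counts=counts, roles=roles)


@pytest.fixture
def make_tiny_trio():
    return tiny_trio


def naive_pairing_score(mirna: str, target: str) -> float:
    """Independent penalty enumeration: literal rule-by-rule walk."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    m = mirna.upper().replace("T", "U")
    t = target.upper().replace("T", "U")
    assert len(m) == len(t)
    total = 0.0
    for i in range(1, len(m) + 1):
        mb = m[i - 1]
        tb = t[len(t) - i]
        if comp[mb] == tb:
            pen = 0.0
        elif {mb, tb} == {"G", "U"}:
            pen = 0.5
        else:
            pen = 1.0
        if 2 <= i <= 13:
            pen *= 2
        total += pen
    return total


@pytest.fixture
def score_oracle():
    return naive_pairing_score
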