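"""Shared fixtures: a tiny hand-written cohort with hand-computed truth."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

CHILDREN_CSV = """\
child_id,sex,birth_date,weight_kg
A,male,2014-01-01,12.00
B,female,2016-05-01,1.90
C,male,2010-01-01,25.00
D,female,2015-12-31,10.00
E,male,1996-06-01,48.00
"""

# child A: readings (0h, 37.0), (2h, 39.0), (6h, 37.0) on 2016-07-01
#   -> one episode, onset 01:00, offset 04:00, duration 3 h, max 39.0
# child B: weight 1.9 kg -> excluded (weight)
# child C: febrile but never dosed -> excluded (no antipyretic)
# child D: dosed but never >= 38.0 -> excluded (no fever)
# child E: first record > 7000 days after birth -> excluded (age)
TEMPS_CSV = """\
child_id,timestamp,temp_c
A,2016-07-01T00:00:00,37.00
A,2016-07-01T02:00:00,39.00
A,2016-07-01T06:00:00,37.00
B,2016-07-02T10:00:00,38.50
C,2016-07-03T08:00:00,38.50
C,2016-07-03T12:00:00,37.00
D,2016-07-04T09:00:00,37.50
E,2016-07-05T21:00:00,38.50
"""

MEDS_CSV = """\
child_id,timestamp,ingredient,dose_mg
A,2016-07-01T02:00:00,acetaminophen,160
A,2016-07-01T08:00:00,dexibuprofen,
B,2016-07-02T10:30:00,ibuprofen,100
D,2016-07-04T09:30:00,ACE,
E,2016-07-05T21:30:00,IBU,120
"""

TINY_TRUTH = {
    "n_children": 5,
    "retained": ["A"],
    "first_reason": {"weight": 1, "age": 1, "no_antipyretic": 1, "no_fever": 1},
    "n_episodes": 1,
    "episode": {"onset_h": 1.0, "offset_h": 4.0, "duration_h": 3.0,
                "max_temp_c": 39.0},
    "n_cases": 1,
    "case": {"group": "combination", "pattern": "ACE-DEX",
             "baseline_temp_c": 39.0, "onset_bin": "[39,40)", "n_doses": 2},
}


@pytest.fixture
def tiny_cohort_files(tmp_path):
    paths = {}
    for name, text in [("children.csv", CHILDREN_CSV),
                       ("temperatures.csv", TEMPS_CSV),
                       ("antipyretics.csv", MEDS_CSV)]:
        p = tmp_path / name
        p.write_text(textwrap.dedent(text), encoding="utf-8")
        paths[name.split(".")[0]] = p
    return paths


@pytest.fixture
def tiny_truth():
    return TINY_TRUTH


def random_minute_series(rng: np.random.Generator, n_min: int = 4,
                         n_max: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """A random irregular temperature series with minute-resolution times
    and continuous temperatures spanning the fever threshold."""
    n = int(rng.integers(n_min, n_max + 1))
    times = np.sort(rng.choice(np.arange(0, 72 * 60), size=n, replace=False))
    times = times / 60.0
    temps = 38.0 + np.cumsum(rng.normal(0.0, 0.8, n))
    temps = np.clip(temps, 35.0, 42.0)
    return times, temps
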