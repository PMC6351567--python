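"""Assertions on the full-scale runs (see README.md in this directory).

Run the shipped configurations first; these tests read the pipeline
summaries from ``runs/`` and check the sub-ensemble writhe statistics at
the replica-to-replica tolerances (+-0.15 on means, +-0.2 on standard
deviations)."""

import json
from pathlib import Path

import pytest

RUNS = Path(__file__).parent / "runs"


def _summary(name: str) -> dict:
    path = RUNS / name / "summary.json"
    if not path.exists():
        pytest.fail(
            f"missing {path}; run the full-scale configurations first "
            "(see README.md in this directory). These runs are "
            "cluster-scale.")
    return json.loads(path.read_text())


def test_ring_brush_left_subensemble():
    s = _summary("ring-brush-left")["subensembles"]["left"]
    assert s["mean_wr"] == pytest.approx(-1.03, abs=0.15)
    assert s["std_wr"] == pytest.approx(1.58, abs=0.2)


def test_ring_brush_right_subensemble():
    s = _summary("ring-brush-right")["subensembles"]["right"]
    assert s["mean_wr"] == pytest.approx(1.02, abs=0.15)
    assert s["std_wr"] == pytest.approx(1.59, abs=0.2)


def test_ring_brush_pooled_population():
    left = _summary("ring-brush-left")["subensembles"]["left"]
    right = _summary("ring-brush-right")["subensembles"]["right"]
    mean = 0.5 * (left["mean_wr"] + right["mean_wr"])
    var = 0.5 * (left["std_wr"] ** 2 + right["std_wr"] ** 2) \
        + 0.5 * (left["mean_wr"] ** 2 + right["mean_wr"] ** 2) - mean ** 2
    assert mean == pytest.approx(0.01, abs=0.15)
    assert var ** 0.5 == pytest.approx(2.07, abs=0.2)


def test_linear_brush_subensembles_kinetically_separated():
    for name, label in (("linear-brush-left", "left"),
                        ("linear-brush-right", "right")):
        s = _summary(name)["subensembles"][label]
        sign = -1.0 if label == "left" else 1.0
        assert sign * s["mean_wr"] > 0.3
        assert not any(s["flips"])      # no handedness transition observed


def test_stiff_confined_chain_bimodal():
    import pandas as pd
    hist = pd.read_csv(RUNS / "stiff-chain-confined" / "hist_unlabeled.csv")
    p0 = hist.loc[hist.bin_center.abs() < 0.05, "P"].max()
    peak_neg = hist.loc[hist.bin_center < -0.2, "P"].max()
    peak_pos = hist.loc[hist.bin_center > 0.2, "P"].max()
    assert peak_neg > 1.5 * p0 and peak_pos > 1.5 * p0
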