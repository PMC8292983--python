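"""Biosensor trace statistics and the membrane CV metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterfb import (
    CellTrace,
    MaskedStack,
    ParameterError,
    auc,
    cn_ratio,
    fraction_responding,
    membrane_cv_timeseries,
    normalize_gcamp,
    quantify_traces,
    sustained_response,
)


def _trace(values, dt=5.0, bg=0.0, channel="gcamp", cell_id="c0"):
    values = np.asarray(values, float)
    return CellTrace(
        cell_id=cell_id,
        time=np.arange(len(values)) * dt,
        value=values,
        background=bg,
        channel=channel,
    )


# --- C/N ratio -------------------------------------------------------------


def test_cn_ratio_symmetric_inputs_give_unity():
    cyto = _trace([30.0, 30.0], channel="ktr_cyto", bg=10.0)
    nuc = _trace([30.0, 30.0], channel="ktr_nuc", bg=10.0)
    np.testing.assert_array_equal(cn_ratio(cyto, nuc), [1.0, 1.0])


def test_cn_ratio_hand_arithmetic():
    cyto = _trace([30.0, 40.0], channel="ktr_cyto", bg=10.0)
    nuc = _trace([20.0, 20.0], channel="ktr_nuc", bg=10.0)
    np.testing.assert_array_equal(cn_ratio(cyto, nuc), [2.0, 3.0])


def test_cn_ratio_flags_nonpositive_denominator_as_missing():
    cyto = _trace([30.0, 40.0], channel="ktr_cyto", bg=10.0)
    nuc = _trace([20.0, 10.0], channel="ktr_nuc", bg=10.0)  # second point at bg
    out = cn_ratio(cyto, nuc)
    assert out[0] == 2.0
    assert np.isnan(out[1])


def test_cn_ratio_requires_matching_time_grid():
    cyto = _trace([1.0, 2.0], dt=5.0, channel="ktr_cyto")
    nuc = _trace([1.0, 2.0], dt=15.0, channel="ktr_nuc")
    with pytest.raises(ParameterError):
        cn_ratio(cyto, nuc)


# --- AUC: baselined plain sum ---------------------------------------------


@pytest.mark.parametrize(
    "values, expected",
    [
        ([5.0, 5.0, 5.0], 0.0),
        ([1.0, 2.0, 3.0], 3.0),  # (0) + (1) + (2)
    ],
)
def test_auc_examples(values, expected):
    assert auc(np.array(values)) == expected


def test_auc_61_point_unit_step_is_exactly_60():
    """On the 15-min, 15-s protocol grid (61 points), a unit step after t=0
    sums to exactly 60: a plain baselined sum, not a trapezoid."""
    trace = np.ones(61)
    trace[1:] += 1.0
    assert auc(trace) == 60.0


def test_auc_rejects_too_short_traces():
    with pytest.raises(ParameterError):
        auc(np.array([1.0]))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=61),
    a=st.floats(-10, 10),
    b=st.floats(-10, 10),
)
def test_auc_is_linear_and_offset_invariant(values, a, b):
    v = np.array(values)
    assert auc(a * v + b) == pytest.approx(a * auc(v), rel=1e-9, abs=1e-6)


# --- GCaMP normalization ---------------------------------------------------


def test_normalize_gcamp_constant_trace_is_all_ones():
    np.testing.assert_array_equal(normalize_gcamp(_trace([7.0, 7.0, 7.0])), 1.0)


def test_normalize_gcamp_hand_oracle():
    np.testing.assert_array_equal(
        normalize_gcamp(_trace([2.0, 4.0, 6.0])), [1.0, 2.0, 3.0]
    )


def test_normalize_gcamp_scale_invariance():
    base = _trace([2.0, 4.0, 6.0])
    scaled = _trace([2e3, 4e3, 6e3])
    np.testing.assert_allclose(
        normalize_gcamp(base), normalize_gcamp(scaled), rtol=1e-12
    )


def test_normalize_gcamp_errors_name_the_cell():
    with pytest.raises(ParameterError, match="badcell"):
        normalize_gcamp(_trace([5.0, 20.0], bg=10.0, cell_id="badcell"))


# --- sustained-response classifier ----------------------------------------


def _norm(values):
    return np.asarray(values, float)


def test_flat_trace_is_not_sustained():
    assert not sustained_response(_norm(np.ones(37)), dt=5.0)


def test_plateau_held_over_30s_is_sustained():
    v = np.ones(37)
    v[10:25] = 4.0  # 15 samples = 70 s above half-max
    assert sustained_response(v, dt=5.0)


def test_single_frame_spike_is_transient_blinking():
    v = np.ones(37)
    v[15] = 10.0
    assert not sustained_response(v, dt=5.0)


def test_run_must_be_consecutive_not_cumulative():
    v = np.ones(37)
    v[[5, 10, 15, 20, 25, 30, 35]] = 4.0  # 35 s cumulative, never consecutive
    assert not sustained_response(v, dt=5.0)


def test_minimum_run_length_boundary_at_5s_sampling():
    # a run of n samples spans (n-1)*dt: 7 samples at 5 s = 30 s qualifies,
    # 6 samples = 25 s does not
    v6, v7 = np.ones(37), np.ones(37)
    v6[10:16] = 4.0
    v7[10:17] = 4.0
    assert not sustained_response(v6, dt=5.0)
    assert sustained_response(v7, dt=5.0)


def test_sustained_monotone_in_plateau_duration():
    v = np.ones(37)
    v[10:17] = 4.0
    assert sustained_response(v, dt=5.0)
    v[10:30] = 4.0  # extending a qualifying run never flips the call
    assert sustained_response(v, dt=5.0)


def test_sustained_scale_invariance():
    v = np.ones(37)
    v[10:20] = 4.0
    assert sustained_response(v, dt=5.0) == sustained_response(v * 1e3 / v.min() , dt=5.0)


def test_too_short_trace_is_an_error():
    with pytest.raises(ParameterError, match="too short"):
        sustained_response(np.ones(5), dt=5.0)


# --- fraction responding ---------------------------------------------------


def test_fraction_responding_labeled_field():
    flat = np.ones(37)
    responder = np.ones(37)
    responder[10:25] = 4.0
    field = [flat.copy(), flat.copy(), flat.copy(), responder]
    assert fraction_responding(field, dt=5.0) == 0.25
    assert fraction_responding([responder] * 3, dt=5.0) == 1.0
    assert fraction_responding([flat] * 5, dt=5.0) == 0.0


def test_fraction_responding_empty_field_errors():
    with pytest.raises(ParameterError):
        fraction_responding([])


# --- membrane CV metric ----------------------------------------------------


def test_uniform_frames_have_zero_delta_cv():
    frames = np.full((3, 8, 8), 5.0)
    mask = np.ones((8, 8), bool)
    np.testing.assert_array_equal(
        membrane_cv_timeseries(MaskedStack(frames, mask)), 0.0
    )


def test_two_point_distribution_delta_cv_is_exactly_one():
    """Frame 0 uniform at 1; frame 1 half pixels 0 / half 2:
    CV_1 = std/mean = 1/1, so dCV = 1 exactly."""
    f0 = np.ones((4, 4))
    f1 = np.zeros((4, 4))
    f1[:, 2:] = 2.0
    stack = MaskedStack(np.stack([f0, f1]), np.ones((4, 4), bool))
    out = membrane_cv_timeseries(stack)
    assert out[0] == 0.0
    assert out[1] == pytest.approx(1.0, rel=1e-12)


def test_delta_cv_scale_invariance_and_variance_option(rng):
    frames = rng.uniform(1, 2, size=(4, 16, 16))
    mask = np.zeros((16, 16), bool)
    mask[4:12, 4:12] = True
    stack = MaskedStack(frames, mask)
    scaled = MaskedStack(frames * 37.0, mask)
    np.testing.assert_allclose(
        membrane_cv_timeseries(stack), membrane_cv_timeseries(scaled), rtol=1e-9
    )
    var = membrane_cv_timeseries(stack, statistic="variance")
    expected = frames[:, mask].var(axis=1)
    np.testing.assert_allclose(var, expected - expected[0], rtol=1e-12)


def test_masked_stack_validation():
    with pytest.raises(ParameterError):
        MaskedStack(np.ones((2, 4, 4)), np.zeros((4, 4), bool))  # empty mask
    with pytest.raises(ParameterError):
        MaskedStack(np.ones((2, 4, 4)), np.ones((5, 5), bool))  # shape mismatch


# --- tidy-table driver -----------------------------------------------------


def test_quantify_traces_jurkat_and_fibroblast_protocols():
    import pandas as pd

    t = np.arange(37) * 5.0
    rows = []
    resp = np.ones(37)
    resp[10:25] = 4.0
    for cid, values in [("r1", 100 * resp), ("n1", 100 * np.ones(37))]:
        rows.append(
            pd.DataFrame(
                {"cell_id": cid, "field_id": "f0", "channel": "gcamp",
                 "time_s": t, "value": values + 10.0, "background": 10.0}
            )
        )
    df = pd.concat(rows, ignore_index=True)
    per_cell, per_field = quantify_traces(df, protocol="jurkat")
    assert per_cell.set_index("cell_id")["sustained"].to_dict() == {
        "r1": True, "n1": False
    }
    assert per_field["fraction_responding"].iloc[0] == 0.5

    # fibroblast: C/N ratio AUC from a cyto/nuc pair
    t61 = np.arange(61) * 15.0
    ratio = np.full(61, 2.0)
    ratio[0] = 1.0
    fib = pd.concat(
        [
            pd.DataFrame(
                {"cell_id": "k1", "field_id": "f0", "channel": "ktr_cyto",
                 "time_s": t61, "value": 10.0 + 50.0 * ratio, "background": 10.0}
            ),
            pd.DataFrame(
                {"cell_id": "k1", "field_id": "f0", "channel": "ktr_nuc",
                 "time_s": t61, "value": 60.0, "background": 10.0}
            ),
        ],
        ignore_index=True,
    )
    per_cell, _ = quantify_traces(fib, protocol="fibroblast")
    assert per_cell["ktr_auc"].iloc[0] == pytest.approx(60.0)


def test_quantify_traces_rejects_malformed_tables():
    import pandas as pd

    with pytest.raises(ParameterError, match="missing columns"):
        quantify_traces(pd.DataFrame({"cell_id": []}), protocol="jurkat")
    with pytest.raises(ParameterError):
        quantify_traces(pd.DataFrame(), protocol="confocal")
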