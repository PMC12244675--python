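import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from activegaze.stats import (
    LEARNING_DEPENDENTS,
    elevation_regression,
    fit_condition_models,
    fit_learning_models,
    fit_lmm,
    fit_orientation_models,
    simulate_learning_data,
)


def test_noiseless_slope_identified_exactly():
    """With zero noise the per-trial decay is recovered to 1e-6."""
    rows = []
    for s in range(1, 7):
        for trial in range(1, 13):
            rows.append({"subject": s, "trial": trial, "y": 5.0 + 0.3 * s - 0.1 * trial})
    df = pd.DataFrame(rows)
    res = fit_lmm(df, "y", "trial")
    assert res.slopes["trial"][0] == pytest.approx(-0.1, abs=1e-6)


def test_lmm_icc_reflects_subject_variance():
    df = simulate_learning_data(60, 12, 3.0, 0.0, subject_sd=0.5, resid_sd=0.5, seed=4)
    res = fit_lmm(df, "y", "trial")
    assert 0.3 < res.icc < 0.7  # true ICC = 0.5


def test_learning_models_cover_subsets():
    rng = np.random.default_rng(0)
    rows = []
    for s in range(1, 13):
        for trial in range(1, 13):
            present = trial % 2 == 0
            rows.append(
                {
                    "subject": s, "trial": trial,
                    "target_present": present,
                    "visible_from_start": (trial % 4 == 0) if present else None,
                    "set_size": 30,
                    "response_time": float(np.exp(3 - 0.02 * trial + rng.normal(0, 0.1))),
                    "n_fixations": int(rng.integers(20, 80)),
                    "n_lookat_fixations": int(rng.integers(10, 60)),
                    "distance": float(np.exp(2 + rng.normal(0, 0.2))),
                }
            )
    res = fit_learning_models(pd.DataFrame(rows))
    subsets = {r.subset for r in res}
    assert subsets == {"present", "absent", "present_visible", "present_not_visible"}
    for r in res:
        assert "trial" in r.slopes
        assert r.transform == LEARNING_DEPENDENTS[r.dependent]


def test_condition_models_and_anova_closed_form(rng):
    rows = []
    for s in range(1, 25):
        for trial in range(1, 9):
            present = trial <= 4
            set_size = [30, 40, 50, 60][(trial - 1) % 4]
            rt = 10 + 0.1 * set_size + (0 if present else 12) + rng.normal(0, 1)
            rows.append(
                {
                    "subject": s, "trial": trial, "target_present": present,
                    "set_size": set_size,
                    "visible_from_start": (s % 2 == 0) if present else None,
                    "response_time": rt,
                    "n_fixations": int(rng.integers(20, 120)),
                    "n_lookat_fixations": 10,
                    "distance": float(rng.uniform(5, 25)),
                    "revisits": int(rng.integers(0, 30)),
                    "correct": bool(rng.random() < 0.9),
                }
            )
    df = pd.DataFrame(rows)
    lmms, anovas, acc = fit_condition_models(df)
    by_dv = {r.dependent: r for r in lmms}
    # absent trials are slower: the presence contrast must be negative
    term = [k for k in by_dv["response_time"].slopes if "target_present" in k][0]
    assert by_dv["response_time"].slopes[term][0] < 0
    assert by_dv["response_time"].slopes["set_size"][0] > 0

    a = {x.dependent: x for x in anovas}["response_time"]
    # closed-form check of the set-size main effect on the present half
    present = df[df["target_present"]]
    groups = [g["response_time"].to_numpy() for _, g in present.groupby("set_size")]
    f_manual, _ = sps.f_oneway(*groups)
    # one-way F differs from two-way F only through the other terms; both
    # must agree that set size matters
    assert a.effects["set_size"][3] < 0.01 and f_manual > 10
    assert a.posthoc  # Tukey contrasts present
    assert "target_present * set_size" in acc.effects or len(acc.effects) >= 2


def test_two_way_anova_matches_manual_decomposition(rng):
    """Balanced two-factor toy: F statistics equal the textbook sums of
    squares computed by hand."""
    from activegaze.stats import _two_way_anova

    levels_a, levels_b, reps = 2, 3, 8
    rows = []
    for i in range(levels_a):
        for j in range(levels_b):
            for _ in range(reps):
                rows.append(
                    {"y": 1.0 + 0.5 * i - 0.3 * j + rng.normal(0, 0.4),
                     "A": f"a{i}", "B": f"b{j}"}
                )
    df = pd.DataFrame(rows)
    res = _two_way_anova(df.rename(columns={"y": "metric"}), "metric", "A", "B")

    y = df["y"].to_numpy()
    grand = y.mean()
    ss_a = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("A")
    )
    ss_b = sum(
        len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("B")
    )
    cell_means = df.groupby(["A", "B"])["y"].mean()
    ss_cells = sum(
        len(g) * (cell_means[k] - grand) ** 2 for k, g in df.groupby(["A", "B"])
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_resid = sum(
        ((g["y"] - g["y"].mean()) ** 2).sum() for _, g in df.groupby(["A", "B"])
    )
    df_resid = len(df) - levels_a * levels_b
    f_a = (ss_a / (levels_a - 1)) / (ss_resid / df_resid)
    f_b = (ss_b / (levels_b - 1)) / (ss_resid / df_resid)
    f_ab = (ss_ab / ((levels_a - 1) * (levels_b - 1))) / (ss_resid / df_resid)
    assert res.effects["A"][0] == pytest.approx(f_a, rel=1e-9)
    assert res.effects["B"][0] == pytest.approx(f_b, rel=1e-9)
    assert res.effects["A:B"][0] == pytest.approx(f_ab, rel=1e-9)
    # partial eta squared from the same sums of squares
    assert res.effects["A"][4] == pytest.approx(ss_a / (ss_a + ss_resid), rel=1e-9)


def _orientation_frame(rng, roll_offsets=None, n_per=40):
    cats = ["upright", "front_up", "side_up", "diagonal", "upside_down"]
    roll_offsets = roll_offsets or {c: 0.0 for c in cats}
    rows = []
    for s in range(1, 13):
        subj_int = rng.normal(0, 1.0)
        for c in cats:
            for _ in range(n_per // 4):
                rows.append(
                    {
                        "subject": s, "orientation": c,
                        "roll": roll_offsets.get(c, 0.0) + subj_int + rng.normal(0, 2.0),
                        "pitch": rng.normal(-5, 3),
                        "rel_elevation": rng.normal(-0.2, 0.1),
                    }
                )
    return pd.DataFrame(rows)


def test_orientation_deviation_recovery(rng):
    df = _orientation_frame(rng, roll_offsets={"front_up": 3.0})
    res = {r.dependent: r for r in fit_orientation_models(df)}
    roll = res["roll"]
    est, p = roll.slopes["front_up"]
    assert est > 1.5 and p < 0.05


def test_orientation_identical_categories_zero_deviation(rng):
    df = _orientation_frame(rng)
    df["roll"] = 1.0  # constant across every category
    res = {r.dependent: r for r in fit_orientation_models(df)}
    for term, (est, _p) in res["roll"].slopes.items():
        assert est == pytest.approx(0.0, abs=1e-8)


def test_orientation_deviation_coefficients_sum_to_zero(rng):
    df = _orientation_frame(rng, roll_offsets={"front_up": 3.0, "diagonal": -4.0})
    res = {r.dependent: r for r in fit_orientation_models(df)}
    total = sum(est for term, (est, _) in res["roll"].slopes.items())
    assert total == pytest.approx(0.0, abs=1e-8)


def test_orientation_single_category_rejected(rng):
    df = _orientation_frame(rng)
    df["orientation"] = "upright"
    with pytest.raises(ValueError, match="categories"):
        fit_orientation_models(df)


def test_elevation_regression_exact_line():
    x = np.array([0.7, 0.7, 1.0, 1.3, 1.0, 1.3])
    y = 0.76 * x + 0.95
    df = pd.DataFrame({"surface_elevation": x, "rel_elevation": y})
    slope, intercept, r, p = elevation_regression(df)
    assert slope == pytest.approx(0.76, abs=1e-12)
    assert intercept == pytest.approx(0.95, abs=1e-12)
    assert r == pytest.approx(1.0)


def test_elevation_regression_matches_closed_form():
    x = np.array([0.7, 1.0, 1.3, 0.7])
    y = np.array([-0.5, -0.3, -0.1, -0.45])
    df = pd.DataFrame({"surface_elevation": x, "rel_elevation": y})
    slope, intercept, r, p = elevation_regression(df)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    sxx = np.sum((x - x.mean()) ** 2)
    assert slope == pytest.approx(sxy / sxx, rel=1e-12)
    assert intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-12)


def test_elevation_regression_null(rng):
    x = np.repeat([0.7, 1.0, 1.3], 60)
    y = rng.normal(0, 0.1, len(x))
    slope, _, r, p = elevation_regression(
        pd.DataFrame({"surface_elevation": x, "rel_elevation": y})
    )
    assert abs(r) < 0.2


def test_elevation_regression_degenerate_x():
    df = pd.DataFrame({"surface_elevation": [0.7] * 5, "rel_elevation": range(5)})
    with pytest.raises(ValueError, match="variance"):
        elevation_regression(df)
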