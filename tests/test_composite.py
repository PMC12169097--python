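"""Principal-qFT selection and composite score construction."""

import numpy as np
import pandas as pd
import pytest

from fibroquant.composite import (
    CompositeModel,
    apply_composite,
    fit_composite,
    score_matrix,
    select_principal_qfts,
)


def make_groups(
    n_a=20,
    n_b=20,
    shifts=(0.5,),
    cv=0.05,
    n_null=5,
    seed=0,
    base=10.0,
):
    """Two-group qFT matrices with planted relative mean shifts."""
    rng = np.random.default_rng(seed)
    cols, a_cols, b_cols = [], [], []
    for i, s in enumerate(shifts):
        cols.append(f"planted_{i}")
        a_cols.append(rng.normal(base, cv * base, n_a))
        b_cols.append(rng.normal(base * (1 + s), cv * base * (1 + s), n_b))
    for i in range(n_null):
        cols.append(f"null_{i}")
        a_cols.append(rng.normal(base, cv * base, n_a))
        b_cols.append(rng.normal(base, cv * base, n_b))
    A = pd.DataFrame(np.column_stack(a_cols), columns=cols,
                     index=[f"a{i}" for i in range(n_a)])
    B = pd.DataFrame(np.column_stack(b_cols), columns=cols,
                     index=[f"b{i}" for i in range(n_b)])
    return A, B


class TestSelection:
    def test_planted_fifty_percent_shift_selected_upward(self):
        A, B = make_groups(shifts=(0.5,), seed=1)
        table = select_principal_qfts(A, B)
        row = table[table["qft"] == "planted_0"].iloc[0]
        assert row["selected"] and row["direction"] == 1

    def test_identical_distributions_not_selected(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(5, 1, 40)
        A = pd.DataFrame({"q": vals[:20]}, index=[f"a{i}" for i in range(20)])
        B = pd.DataFrame({"q": vals[:20]}, index=[f"b{i}" for i in range(20)])
        table = select_principal_qfts(A, B)
        assert not table["selected"].any()

    def test_significant_but_small_shift_fails_change_rule(self):
        # 10% shift with tiny variance: p ~ 0 but relative change < 20%
        A, B = make_groups(shifts=(0.10,), cv=0.005, seed=3)
        table = select_principal_qfts(A, B)
        row = table[table["qft"] == "planted_0"].iloc[0]
        assert row["p_value"] < 1e-6 and not row["selected"]

    def test_overlapping_groups_rejected(self):
        A, B = make_groups(seed=4)
        with pytest.raises(ValueError):
            select_principal_qfts(A, pd.concat([B, A.iloc[:1]]))

    def test_incomplete_qfts_ineligible(self):
        A, B = make_groups(shifts=(0.5,), seed=5)
        A.loc[A.index[:10], "planted_0"] = np.nan  # 50% missing in A
        table = select_principal_qfts(A, B)
        assert "planted_0" not in set(table["qft"])

    def test_selection_recovery_monte_carlo(self):
        """Planted 30%-shift qFTs (CV 10%, n=20/20) among nulls:
        sensitivity >= 0.9; 10%-shift decoys never pass the 20% rule."""
        rng_seeds = range(5)
        hits, total, decoy_hits, null_hits, n_null_total = 0, 0, 0, 0, 0
        for seed in rng_seeds:
            A, B = make_groups(shifts=(0.3,) * 10, cv=0.10, n_null=30, seed=seed)
            # decoys: highly significant 10% shifts (tiny variance) that
            # must fail the 20%-change rule no matter how small their p
            dA, dB = make_groups(shifts=(0.10,) * 5, cv=0.005, n_null=0,
                                 seed=seed + 1000)
            dA.columns = dB.columns = [f"decoy_{i}" for i in range(5)]
            A, B = pd.concat([A, dA], axis=1), pd.concat([B, dB], axis=1)
            table = select_principal_qfts(A, B).set_index("qft")
            planted = [f"planted_{i}" for i in range(10)]
            decoys = [f"decoy_{i}" for i in range(5)]
            hits += table.loc[planted, "selected"].sum()
            total += len(planted)
            decoy_hits += table.loc[decoys, "selected"].sum()
            nulls = [n for n in table.index if n.startswith("null_")]
            null_hits += table.loc[nulls, "selected"].sum()
            n_null_total += len(nulls)
        assert hits / total >= 0.9
        assert decoy_hits == 0
        # false selections need both a spurious 20% shift and p < alpha
        assert null_hits / n_null_total < 0.05


class TestFitAndApply:
    def test_bounds_map_to_scale_endpoints(self):
        A, B = make_groups(shifts=(0.5, 0.4), seed=6)
        table = select_principal_qfts(A, B)
        model = fit_composite(pd.concat([A, B]), table)
        low = {q: model.bounds[q][0] for q in model.selected_qfts}
        high = {q: model.bounds[q][1] for q in model.selected_qfts}
        # directions are +1 here, so low bounds -> min of scale
        assert apply_composite(model, low) == pytest.approx(0.0)
        assert apply_composite(model, high) == pytest.approx(10.0)
        mid = {q: (model.bounds[q][0] + model.bounds[q][1]) / 2 for q in model.selected_qfts}
        assert apply_composite(model, mid) == pytest.approx(5.0)

    def test_single_qft_model_is_monotone(self):
        A, B = make_groups(shifts=(0.5,), n_null=0, seed=7)
        table = select_principal_qfts(A, B)
        model = fit_composite(pd.concat([A, B]), table)
        xs = np.linspace(5, 20, 50)
        scores = [apply_composite(model, {"planted_0": x}) for x in xs]
        assert all(b >= a for a, b in zip(scores, scores[1:]))
        assert min(scores) >= 0.0 and max(scores) <= 10.0

    def test_unit_rescaling_invariance(self):
        A, B = make_groups(shifts=(0.5, 0.3), n_null=2, seed=8)
        table = select_principal_qfts(A, B)
        model = fit_composite(pd.concat([A, B]), table)
        scores = score_matrix(model, pd.concat([A, B]))

        A2, B2 = A * 1000.0, B * 1000.0  # same data in milli-units
        table2 = select_principal_qfts(A2, B2)
        model2 = fit_composite(pd.concat([A2, B2]), table2)
        scores2 = score_matrix(model2, pd.concat([A2, B2]))
        assert np.allclose(scores.values, scores2.values)

    def test_constant_qft_dropped_with_remainder_kept(self):
        A, B = make_groups(shifts=(0.5,), n_null=0, seed=9)
        A["const"], B["const"] = 1.0, 2.0  # selected but constant per cohort?
        table = select_principal_qfts(A, B)
        fit_data = pd.concat([A, B])
        fit_data["const"] = 3.0  # constant across the fitting cohort
        model = fit_composite(fit_data, table)
        assert "const" not in model.selected_qfts
        assert "planted_0" in model.selected_qfts

    def test_fitted_direction_orders_groups(self):
        A, B = make_groups(shifts=(0.4, -0.3), n_null=3, cv=0.1, seed=10)
        table = select_principal_qfts(A, B)
        model = fit_composite(pd.concat([A, B]), table)
        mean_a = score_matrix(model, A).mean()
        mean_b = score_matrix(model, B).mean()
        assert mean_b > mean_a

    def test_duplicate_biopsy_scores_identically(self):
        A, B = make_groups(shifts=(0.5,), seed=11)
        table = select_principal_qfts(A, B)
        model = fit_composite(pd.concat([A, B]), table)
        row = A.iloc[0]
        assert apply_composite(model, row) == apply_composite(model, row.copy())

    def test_missing_qft_policy(self):
        A, B = make_groups(shifts=(0.5, 0.4, 0.3, 0.45, 0.35), n_null=0, cv=0.05, seed=12)
        table = select_principal_qfts(A, B)
        model = fit_composite(pd.concat([A, B]), table)
        assert len(model.selected_qfts) == 5
        full = dict(A.iloc[0])
        one_missing = {k: v for k, v in full.items() if k != "planted_0"}
        s = apply_composite(model, one_missing)  # 1/5 = 20% missing: allowed
        assert 0.0 <= s <= 10.0
        two_missing = {k: v for k, v in full.items()
                       if k not in ("planted_0", "planted_1")}
        with pytest.raises(ValueError):
            apply_composite(model, two_missing)

    def test_model_json_round_trip(self, tmp_path):
        A, B = make_groups(shifts=(0.5, 0.3), seed=13)
        table = select_principal_qfts(A, B)
        model = fit_composite(pd.concat([A, B]), table, name="Ph-FCS(L)")
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = CompositeModel.from_json(path)
        assert loaded == model
        assert apply_composite(loaded, A.iloc[0]) == apply_composite(model, A.iloc[0])
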