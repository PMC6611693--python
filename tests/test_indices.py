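"""Share normalization, ROI/PHI, and the VIF audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patmine.indices import (
    MeasureTable,
    NormalizedTable,
    normalize,
    phi,
    resource_composite,
    roi,
    vif,
    MEASURES,
    RESOURCES,
)


def tidy(measure_values):
    """measure -> {phecode: value} for a single year 2000."""
    rows = []
    for m, per_d in measure_values.items():
        for p, v in per_d.items():
            rows.append({"measure": m, "phecode": p, "year": 2000, "value": v})
    return MeasureTable(pd.DataFrame(rows))


def shares(burden, resource):
    """NormalizedTable with given burden shares and identical resource shares."""
    phecodes = [f"D{i}" for i in range(len(burden))]
    X = {}
    X["burden"] = pd.DataFrame({2000: list(burden)}, index=phecodes)
    for m in RESOURCES:
        X[m] = pd.DataFrame({2000: list(resource)}, index=phecodes)
    return NormalizedTable(X=X)


class TestNormalize:
    def test_single_disease_share_is_one(self):
        X = normalize(tidy({m: {"D1": 5.0} for m in MEASURES}))
        assert X.X["burden"].at["D1", 2000] == 1.0

    def test_symmetric_values_quarter_each(self):
        X = normalize(tidy({m: {f"D{i}": 1.0 for i in range(4)} for m in MEASURES}))
        assert np.allclose(X.X["patents"][2000], 0.25)

    def test_hand_arithmetic(self):
        X = normalize(
            tidy({m: {"D1": 2.0, "D2": 3.0, "D3": 5.0} for m in MEASURES})
        )
        assert np.allclose(X.X["trials"][2000], [0.2, 0.3, 0.5])

    def test_all_zero_measure_year_named_in_error(self):
        table = tidy({m: {"D1": 1.0, "D2": 1.0} for m in MEASURES})
        table.data.loc[table.data["measure"] == "trials", "value"] = 0.0
        with pytest.raises(ValueError, match="trials"):
            normalize(MeasureTable(table.data))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(0.01, 1e6), min_size=2, max_size=8),
        scale=st.floats(1e-3, 1e3),
    )
    def test_shares_sum_to_one_and_scale_invariant(self, values, scale):
        """Normalization is inflation-proof: rescaling a measure-year by any
        positive constant leaves the shares unchanged."""
        t1 = tidy({m: {f"D{i}": v for i, v in enumerate(values)} for m in MEASURES})
        t2 = tidy(
            {m: {f"D{i}": v * scale for i, v in enumerate(values)} for m in MEASURES}
        )
        X1, X2 = normalize(t1), normalize(t2)
        for m in MEASURES:
            assert abs(X1.X[m][2000].sum() - 1.0) < 1e-12
            assert np.allclose(X1.X[m][2000], X2.X[m][2000], atol=1e-12)


class TestResourceComposite:
    def test_equal_shares_pass_through(self):
        X = shares([0.5, 0.5], [0.1, 0.9])
        R = resource_composite(X)
        assert R.at["D0", 2000] == pytest.approx(0.1)

    def test_degenerate_weights_select_one_measure(self):
        X = shares([0.5, 0.5], [0.3, 0.7])
        X.X["publications"].loc[:, 2000] = [0.9, 0.1]
        R = resource_composite(X, {"publications": 1.0, "trials": 0.0, "patents": 0.0})
        assert list(R[2000]) == [0.9, 0.1]

    def test_hand_arithmetic(self):
        X = shares([0.5, 0.5], [0.0, 0.0])
        X.X["publications"].loc["D0", 2000] = 0.1
        X.X["trials"].loc["D0", 2000] = 0.2
        X.X["patents"].loc["D0", 2000] = 0.4
        R = resource_composite(X)
        assert R.at["D0", 2000] == pytest.approx(0.7 / 3)

    def test_negative_weight_rejected(self):
        X = shares([1.0], [1.0])
        with pytest.raises(ValueError):
            resource_composite(X, {"publications": -0.5, "trials": 1.0, "patents": 0.5})


class TestROI:
    def test_alignment_gives_plus_one(self):
        series = roi(shares([0.4, 0.6], [0.4, 0.6]))
        assert np.allclose(series.wide()[2000], 1.0)

    def test_overstudied_negative_fold(self):
        series = roi(shares([0.1, 0.9], [0.2, 0.8]))
        assert series.wide().at["D0", 2000] == pytest.approx(-2.0)

    def test_understudied_positive_fold(self):
        series = roi(shares([0.3, 0.7], [0.1, 0.9]))
        assert series.wide().at["D0", 2000] == pytest.approx(3.0)

    def test_zero_share_sentinels(self):
        series = roi(shares([0.0, 1.0], [0.5, 0.5]))
        row = series.table[series.table["phecode"] == "D0"].iloc[0]
        assert row["sentinel"] == "overstudied-unbounded" and np.isnan(row["roi"])
        series = roi(shares([1.0, 0.0], [0.0, 1.0]))
        row = series.table[series.table["phecode"] == "D0"].iloc[0]
        assert row["sentinel"] == "understudied-unbounded"

    def test_sign_iff_burden_exceeds_resources(self):
        rng = np.random.default_rng(5)
        b = rng.dirichlet(np.ones(6))
        r = rng.dirichlet(np.ones(6))
        series = roi(shares(b, r)).wide()[2000]
        for i in range(6):
            if b[i] > r[i]:
                assert series.iloc[i] > 1 or series.iloc[i] == pytest.approx(1)
            elif b[i] < r[i]:
                assert series.iloc[i] < 0
        assert (np.abs(series.dropna()) >= 1 - 1e-12).all()

    def test_swap_symmetry_flips_signs(self):
        rng = np.random.default_rng(6)
        b = rng.dirichlet(np.ones(5))
        r = rng.dirichlet(np.ones(5))
        fwd = roi(shares(b, r)).wide()[2000].to_numpy()
        rev = roi(shares(r, b)).wide()[2000].to_numpy()
        assert np.allclose(fwd, -rev)


class TestPHI:
    def test_perfect_alignment_is_zero(self):
        assert phi(shares([0.25, 0.75], [0.25, 0.75]))[2000] == 0.0

    def test_maximal_misalignment_is_one(self):
        assert phi(shares([1.0, 0.0], [0.0, 1.0]))[2000] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert phi(shares([0.6, 0.4], [0.5, 0.5]))[2000] == pytest.approx(0.1)

    def test_pigou_dalton_move_never_increases_phi(self):
        """Transporting resource share toward the burden distribution
        (reducing |X_b - R| pointwise) never increases PHI."""
        rng = np.random.default_rng(7)
        b = rng.dirichlet(np.ones(6))
        r = rng.dirichlet(np.ones(6))
        base = phi(shares(b, r))[2000]
        for lam in (0.1, 0.5, 0.9, 1.0):
            moved = r + lam * (b - r)
            assert phi(shares(b, moved))[2000] <= base + 1e-12


class TestVIF:
    @staticmethod
    def from_columns(cols):
        phecodes = [f"D{i}" for i in range(len(cols["burden"]))]
        X = {
            m: pd.DataFrame({2000: list(v)}, index=phecodes)
            for m, v in cols.items()
        }
        return NormalizedTable(X=X)

    def test_orthogonal_design_gives_one(self):
        # orthogonal, centered columns embedded as shares (VIF is affine-invariant)
        h = np.array(
            [[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]]
        ).T
        cols = {m: (h[:, i] + 2) / np.sum(h[:, i] + 2) for i, m in enumerate(MEASURES)}
        # need >=5 rows: duplicate the design
        cols = {m: np.concatenate([v, v]) / 2 for m, v in cols.items()}
        result = vif(self.from_columns(cols))
        assert np.allclose(result, 1.0, atol=1e-8)

    def test_exact_copy_is_infinite(self):
        rng = np.random.default_rng(8)
        base = rng.dirichlet(np.ones(6))
        cols = {
            "burden": base,
            "publications": base,  # exact copy
            "trials": rng.dirichlet(np.ones(6)),
            "patents": rng.dirichlet(np.ones(6)),
        }
        with pytest.warns(UserWarning):
            result = vif(self.from_columns(cols))
        assert np.isinf(result["burden"]) and np.isinf(result["publications"])

    def test_known_r2_075_gives_vif_4(self):
        """Construct burden = predictor combination + orthogonal residual with
        R^2 exactly 0.75, so VIF must equal 4."""
        rng = np.random.default_rng(9)
        n = 40
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        x3 = rng.standard_normal(n)
        signal = x1 + 0.5 * x2 - 0.3 * x3
        noise = rng.standard_normal(n)
        # orthogonalize noise against [1, x1, x2, x3] then scale for R^2 = 0.75
        A = np.column_stack([np.ones(n), x1, x2, x3])
        noise -= A @ np.linalg.lstsq(A, noise, rcond=None)[0]
        signal_c = signal - signal.mean()
        noise *= np.sqrt((signal_c @ signal_c) / 3.0 / (noise @ noise))
        y = signal + noise  # var explained / total = 0.75
        cols = {
            "burden": y,
            "publications": x1,
            "trials": x2,
            "patents": x3,
        }
        # shift/scale into valid shares: VIF is invariant to affine per-column maps
        cols = {m: (v - v.min() + 1.0) / (v - v.min() + 1.0).sum() for m, v in cols.items()}
        result = vif(self.from_columns(cols))
        assert result["burden"] == pytest.approx(4.0, abs=1e-8)

    def test_agrees_with_statsmodels_oracle(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(10)
        raw = {m: rng.dirichlet(np.ones(12)) for m in MEASURES}
        mine = vif(self.from_columns(raw))
        mat = np.column_stack([raw[m] for m in MEASURES] + [np.ones(12)])
        for i, m in enumerate(MEASURES):
            theirs = variance_inflation_factor(mat, i)
            assert mine[m] == pytest.approx(theirs, rel=1e-8)

    def test_too_few_rows_rejected(self):
        cols = {m: np.full(3, 1 / 3) for m in MEASURES}
        with pytest.raises(ValueError):
            vif(self.from_columns(cols))
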