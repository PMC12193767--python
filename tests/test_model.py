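"""Final regression, applicability domain, interpretation, results API."""

import numpy as np
import pytest

from cwqsar import (
    FittedEquation,
    MonteCarloQSAR,
    Record,
    SplitDataset,
    WeightTable,
    classify_attributes,
    defect_dk,
    fit_equation,
    make_single_key,
    make_split,
)
from cwqsar.exceptions import InvalidInputError, UndefinedStatisticError
from cwqsar.model import ROLE_DECREASE, ROLE_INCREASE, ROLE_UNCLEAR
from cwqsar.weights import dcw

C = make_single_key("C")
O_ = make_single_key("O")


def _toy_split(endpoint_fn, n=20):
    """Records over C/O chains with endpoint computed from the token counts."""
    recs = []
    rng = np.random.default_rng(5)
    for i in range(n):
        length = int(rng.integers(2, 8))
        toks = ["C" if rng.random() < 0.6 else "O" for _ in range(length)]
        smiles = "".join(toks)
        recs.append(Record(f"m{i}", smiles, endpoint_fn(smiles)))
    return make_split(recs, seed=0)


class TestFitEquation:
    def test_exact_linear(self):
        table = WeightTable(weights={C: 1.0, O_: -0.5})
        split = _toy_split(lambda s: 2.0 + 3.0 * dcw(s, table))
        eq = fit_equation(split, table)
        assert eq.c0 == pytest.approx(2.0, abs=1e-9)
        assert eq.c1 == pytest.approx(3.0, abs=1e-9)
        for r in split.active:
            assert eq.predict(r.smiles) == pytest.approx(r.endpoint, abs=1e-9)

    def test_centered_intercept(self):
        table = WeightTable(weights={C: 1.0, O_: -0.5})
        split = _toy_split(lambda s: 1.0)
        x = np.array([dcw(r.smiles, table) for r in split.active])
        y = np.full_like(x, 7.5)
        # manual OLS with constant y: slope 0, intercept = mean endpoint
        split2 = SplitDataset(
            active=[Record(r.id, r.smiles, 7.5) for r in split.active],
            passive=split.passive, calibration=split.calibration,
            validation=split.validation,
        )
        eq = fit_equation(split2, table)
        assert eq.c1 == pytest.approx(0.0, abs=1e-12)
        assert eq.c0 == pytest.approx(7.5)

    def test_ols_oracle(self):
        table = WeightTable(weights={C: 1.0, O_: -0.5})
        split = _toy_split(lambda s: len(s) * 0.3 - 1.0)
        eq = fit_equation(split, table)
        x = np.array([dcw(r.smiles, table) for r in split.active])
        y = np.array([r.endpoint for r in split.active])
        slope, intercept = np.polyfit(x, y, 1)
        assert eq.c1 == pytest.approx(slope, abs=1e-9)
        assert eq.c0 == pytest.approx(intercept, abs=1e-9)

    def test_constant_descriptor_raises(self):
        table = WeightTable(weights={})
        split = _toy_split(lambda s: 1.0)
        with pytest.raises(UndefinedStatisticError):
            fit_equation(split, table)


class TestPredict:
    def test_zero_descriptor_gives_intercept(self):
        eq = FittedEquation(c0=1.5, c1=2.0, table=WeightTable(weights={}))
        assert eq.predict("CC") == pytest.approx(1.5)

    def test_scale_compensation(self):
        t1 = WeightTable(weights={C: 0.8, O_: -0.4})
        t2 = WeightTable(weights={C: 1.6, O_: -0.8})
        e1 = FittedEquation(c0=1.0, c1=2.0, table=t1)
        e2 = FittedEquation(c0=1.0, c1=1.0, table=t2)
        for s in ("CC", "COC", "OOO"):
            assert e1.predict(s) == pytest.approx(e2.predict(s))

    def test_hand_arithmetic(self):
        eq = FittedEquation(c0=0.5, c1=2.0, table=WeightTable(weights={C: 0.25}))
        # "CC": dcw = 0.5 -> 0.5 + 2*0.5 = 1.5
        assert eq.predict("CC") == pytest.approx(1.5)


class TestDefect:
    def test_equal_probabilities(self):
        assert defect_dk((3, 3, 3), (0.5, 0.5, 0.5)) == 0.0

    def test_hand_arithmetic(self):
        val = defect_dk((2, 1, 1), (0.5, 0.25, 0.5))
        assert val == pytest.approx(0.25 / 3 + 0.0 / 3 + 0.25 / 2, abs=1e-12)

    def test_absent_attribute(self):
        assert defect_dk((0, 0, 0), (0.0, 0.0, 0.0)) == 0.0

    def test_permutation_symmetry(self, rng):
        import itertools
        freqs = (4, 7, 2)
        probs = (0.1, 0.35, 0.05)
        base = defect_dk(freqs, probs)
        for perm in itertools.permutations(range(3)):
            f = tuple(freqs[i] for i in perm)
            p = tuple(probs[i] for i in perm)
            assert defect_dk(f, p) == pytest.approx(base, abs=1e-15)

    def test_nonnegative(self, rng):
        for _ in range(50):
            f = tuple(int(x) for x in rng.integers(0, 20, 3))
            p = tuple(float(x) for x in rng.uniform(0, 1, 3))
            assert defect_dk(f, p) >= 0.0


class TestDomain:
    def _eq(self):
        table = WeightTable(weights={C: 1.0, O_: 1.0})
        return FittedEquation(
            c0=0.0, c1=1.0, table=table, mean_defect=0.05,
            dk={C: 0.02, O_: 0.07},
        )

    def test_smiles_defect_distinct_keys(self):
        eq = self._eq()
        # "CC" has C (twice -> counted once) and the C-C pair (dk 0)
        assert eq.smiles_defect("CC") == pytest.approx(0.02)
        assert eq.smiles_defect("CO") == pytest.approx(0.09)

    def test_blocked_attributes_contribute_nothing(self):
        table = WeightTable(weights={C: 1.0}, blocked={O_})
        eq = FittedEquation(c0=0, c1=1, table=table, mean_defect=0.05,
                            dk={C: 0.02, O_: 0.07})
        assert eq.smiles_defect("CO") == pytest.approx(0.02)

    def test_boundary_strictness(self):
        eq = self._eq()
        # craft Dj == 2 * mean_defect exactly
        eq.dk = {C: 0.1}
        eq.mean_defect = 0.05
        ok, dj = eq.in_domain("C")
        assert dj == pytest.approx(0.1)
        assert not ok  # Dj == 2*D-bar is out of domain (strict inequality)

    def test_zero_defect_in_domain(self):
        eq = self._eq()
        eq.dk = {}
        ok, dj = eq.in_domain("CC")
        assert dj == 0.0 and ok

    def test_enumeration_oracle(self, small_dataset):
        res = MonteCarloQSAR(small_dataset).fit(
            variant="TF0", threshold_T=2, epochs_N=3, seed=3
        )
        eq = res.equation
        expected = [
            r for r in small_dataset
            if not (eq.smiles_defect(r.smiles) < 2 * eq.mean_defect)
        ]
        got = res.outliers(small_dataset)
        assert [r.id for r in got] == [r.id for r in expected]
        # repeated calls are stable
        assert [r.id for r in res.outliers(small_dataset)] == [r.id for r in got]


class TestClassifyAttributes:
    def test_printed_examples(self):
        cl = make_single_key("Cl")
        n = make_single_key("N")
        probes = [
            WeightTable(weights={cl: 1.433, n: -0.885, C: 0.5}),
            WeightTable(weights={cl: 0.096, n: -0.481, C: -0.1}),
            WeightTable(weights={cl: 0.788, n: -0.966, C: 0.3}),
        ]
        roles = {r.attribute: r.role for r in classify_attributes(probes)}
        assert roles[cl] == ROLE_INCREASE
        assert roles[n] == ROLE_DECREASE
        assert roles[C] == ROLE_UNCLEAR

    def test_zero_weight_is_unclear(self):
        probes = [
            WeightTable(weights={C: 0.0}),
            WeightTable(weights={C: 0.5}),
        ]
        assert classify_attributes(probes)[0].role == ROLE_UNCLEAR

    def test_needs_two_probes(self):
        with pytest.raises(InvalidInputError):
            classify_attributes([WeightTable(weights={C: 1.0})])

    def test_ordering_increase_then_decrease_by_frequency(self):
        k1, k2, k3 = C, O_, make_single_key("S")
        counts = {k1: (10, 0, 0), k2: (30, 0, 0), k3: (20, 0, 0)}
        probes = [
            WeightTable(weights={k1: 1.0, k2: 1.0, k3: -1.0}, counts=counts),
            WeightTable(weights={k1: 0.5, k2: 0.2, k3: -0.5}, counts=counts),
        ]
        ordered = classify_attributes(probes)
        assert [r.attribute for r in ordered] == [k2, k1, k3]


class TestModelResultsAPI:
    def test_fit_returns_results_with_stats(self, small_dataset):
        model = MonteCarloQSAR(small_dataset)
        res = model.fit(variant="TF0", threshold_T=2, epochs_N=3, n_probes=2, seed=1)
        df = res.stats_frame()
        assert list(df["set"]) == ["active", "passive", "calibration", "validation"]
        assert list(df.columns) == [
            "set", "n", "R2", "CCC", "IIC", "CII", "Q2", "CCCP", "RMSE", "F", "NA",
        ]
        assert (df["n"] > 0).all()
        assert "DCW" in res.summary()

    def test_from_dataframe(self, small_dataset):
        import pandas as pd
        df = pd.DataFrame(
            {"id": [r.id for r in small_dataset],
             "smiles": [r.smiles for r in small_dataset],
             "endpoint": [r.endpoint for r in small_dataset]}
        )
        model = MonteCarloQSAR.from_dataframe(df)
        assert model.records == list(small_dataset)

    def test_prediction_affine_in_weights(self, small_dataset):
        """Doubling all weights and halving c1 leaves predictions unchanged."""
        res = MonteCarloQSAR(small_dataset).fit(
            variant="TF0", threshold_T=2, epochs_N=2, seed=2
        )
        eq = res.equation
        doubled = WeightTable(
            weights={k: 2 * v for k, v in eq.table.weights.items()},
            blocked=set(eq.table.blocked), threshold_T=eq.table.threshold_T,
        )
        eq2 = FittedEquation(c0=eq.c0, c1=eq.c1 / 2, table=doubled)
        for r in small_dataset[:10]:
            assert eq2.predict(r.smiles) == pytest.approx(eq.predict(r.smiles), abs=1e-9)


def test_save_load_bit_exact(tmp_path, small_dataset):
    res = MonteCarloQSAR(small_dataset).fit(
        variant="TF0", threshold_T=2, epochs_N=3, seed=6
    )
    p = tmp_path / "model.txt"
    res.equation.save(p)
    eq = FittedEquation.load(p)
    for r in small_dataset:
        assert eq.predict(r.smiles) == res.equation.predict(r.smiles)
        assert eq.in_domain(r.smiles) == res.equation.in_domain(r.smiles)
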