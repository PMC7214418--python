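import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

import sctipping as st
from sctipping.cluster import ClusterAssignment
from sctipping.criticality import (
    assign_paths,
    ic_index,
    snai,
    snai_details,
    tipping_cluster,
)


def det3(R):
    """Explicit cofactor expansion of a 3x3 determinant (oracle)."""
    return (
        R[0, 0] * (R[1, 1] * R[2, 2] - R[1, 2] * R[2, 1])
        - R[0, 1] * (R[1, 0] * R[2, 2] - R[1, 2] * R[2, 0])
        + R[0, 2] * (R[1, 0] * R[2, 1] - R[1, 1] * R[2, 0])
    )


def ic_bruteforce(X, absolute=True):
    """Independent double-loop implementation of the critical transition
    index (numerator over analyte pairs, denominator over cell pairs)."""
    n, p = X.shape

    def pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    num = []
    for i in range(p):
        for j in range(i + 1, p):
            r = pearson(X[:, i], X[:, j])
            num.append(abs(r) if absolute else r)
    den = []
    for k in range(n):
        for l in range(k + 1, n):
            r = pearson(X[k], X[l])
            den.append(abs(r) if absolute else r)
    return float(np.mean(num) / np.mean(den))


class TestSnai:
    def test_two_analyte_closed_form(self):
        # construct two columns with exact sample correlation 0.8
        x = np.array([-1.0, 0.0, 1.0, 2.0, -2.0])
        x = (x - x.mean()) / x.std()
        rng = np.random.default_rng(0)
        y = 0.8 * x + np.sqrt(1 - 0.64) * self._orthonormal_noise(x, rng)
        X = np.column_stack([x, y])
        r = np.corrcoef(X, rowvar=False)[0, 1]
        assert r == pytest.approx(0.8, abs=1e-12)
        assert snai(X) == pytest.approx(1.0 / (1.0 - 0.64), abs=1e-6)

    @staticmethod
    def _orthonormal_noise(x, rng):
        e = rng.normal(size=x.size)
        e = e - e.mean()
        e = e - (e @ x) / (x @ x) * x
        return e / e.std()

    def test_three_analyte_cofactor_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 3)) @ rng.normal(size=(3, 3))
        R = np.corrcoef(X, rowvar=False)
        assert snai(X) == pytest.approx(1.0 / det3(R), rel=1e-10)

    def test_snai_at_least_one_on_valid_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X = rng.normal(size=(40, 6))
            value, _, degenerate = snai_details(X)
            if not degenerate:
                assert value >= 1.0

    def test_independent_normals_stay_near_one(self):
        rng = np.random.default_rng(6)
        values = [snai(rng.normal(size=(2000, 5))) for _ in range(50)]
        assert np.median(values) < 1.1
        assert min(values) >= 1.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 5))
        scale = rng.uniform(0.5, 3.0, 5)
        shift = rng.uniform(-2, 2, 5)
        assert snai(X * scale + shift) == pytest.approx(snai(X), rel=1e-9)

    def test_zero_variance_analyte_named(self):
        X = np.ones((10, 3))
        X[:, 1] = np.arange(10)
        X[:, 2] = np.arange(10) ** 2
        with pytest.raises(st.ValidationError, match="a0"):
            snai(X, analyte_names=["a0", "a1", "a2"])

    def test_degenerate_when_cells_do_not_outnumber_analytes(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 6))
        with pytest.warns(UserWarning, match="analytes"):
            _, _, degenerate = snai_details(X)
        assert degenerate


class TestIc:
    def test_equals_bruteforce_double_loop(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 5))
        assert ic_index(X) == pytest.approx(ic_bruteforce(X), abs=1e-10)

    def test_duplicated_analytes_raise_numerator(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 4))
        base_num = np.mean(
            np.abs(np.corrcoef(X, rowvar=False)[np.triu_indices(4, 1)])
        )
        X2 = np.hstack([X, X])
        dup_num = np.mean(
            np.abs(np.corrcoef(X2, rowvar=False)[np.triu_indices(8, 1)])
        )
        assert dup_num > base_num

    def test_monotone_response_to_shared_factor(self):
        """Injecting a stronger shared latent factor into a null cluster
        drives both indices up (median over 20 seeds per strength).

        Common random numbers are used across strengths; medians may still
        wiggle within sampling noise where the factor sits below the noise
        floor, so each step is allowed 5% relative slack while the overall
        response must rise clearly."""
        strengths = np.linspace(0.0, 2.0, 10)
        med_snai, med_ic = [], []
        for s in strengths:
            vs, vi = [], []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                X = rng.normal(size=(40, 8))
                f = rng.normal(size=40)
                h = rng.normal(size=8)
                h /= np.linalg.norm(h)
                Xs = X + s * f[:, None] * h[None, :]
                vs.append(snai(Xs))
                vi.append(ic_index(Xs))
            med_snai.append(np.median(vs))
            med_ic.append(np.median(vi))
        for med in (med_snai, med_ic):
            assert all(b >= 0.95 * a for a, b in zip(med, med[1:]))
            assert med[-1] > 1.1 * med[0]

    def test_planted_tipping_raises_ic_within_path(self):
        """Ground-truth tipping cells show higher Ic than the same-path,
        same-day non-tipping group in nearly all seeds."""
        wins, total = 0, 0
        for seed in range(50):
            table, truth = st.generate(st.GeneratorConfig(seed=seed))
            X = np.log(table.values)
            day3 = truth.frame["day"].to_numpy() == 3
            for path in ("high", "low"):
                tip = (truth.path == path) & truth.tipping
                rest = (truth.path == path) & day3 & ~truth.tipping
                if rest.sum() < 3:
                    continue
                total += 1
                if ic_index(X[tip]) > ic_index(X[rest]):
                    wins += 1
        assert wins / total >= 0.9

    def test_pathological_inputs(self):
        with pytest.raises(st.ValidationError):
            ic_index(np.ones((5, 4)))
        with pytest.raises(st.ValidationError):
            ic_index(np.random.default_rng(0).normal(size=(2, 4)))


class TestPaths:
    def _assignment(self, labels, days):
        labels = np.asarray(labels)
        return ClusterAssignment(
            labels=labels,
            day_of_cluster={int(c): int(days[c]) for c in np.unique(labels)},
            k_per_day={},
            markers_used=None,
            wss_curves={},
        )

    def test_all_negative_cluster_is_upper(self):
        a = self._assignment([0, 0, 0, 1, 1, 1], {0: 0, 1: 0})
        paths = assign_paths(a, np.array([-1, -1, -1, 2, 2, 2.0]))
        assert paths == {0: "upper", 1: "lower"}

    def test_even_split_is_unassigned_with_warning(self):
        a = self._assignment([0, 0], {0: 0})
        with pytest.warns(UserWarning, match="50/50"):
            paths = assign_paths(a, np.array([-1.0, 1.0]))
        assert paths[0] is None

    def test_cluster_paths_match_truth_majority(self):
        hits, total = 0, 0
        for seed in range(10):
            table, truth = st.generate(
                st.GeneratorConfig(n_cells_per_day=(50,) * 4, seed=seed)
            )
            lt = st.log_transform(table)
            res = st.decompose(lt)
            lam2 = st.surprisal.orient_scores_by_marker(
                res.module_scores[:, 1], lt.column("MITF")
            )
            assignment = st.cluster_by_day(lt)
            paths = assign_paths(assignment, lam2)
            for cid in assignment.cluster_ids():
                members = assignment.members(cid)
                n_high = int((truth.path[members] == "high").sum())
                true_path = "upper" if 2 * n_high > members.size else "lower"
                total += 1
                if paths[cid] == true_path:
                    hits += 1
        assert hits / total >= 0.95


class TestTippingCluster:
    def _report(self, rows):
        import pandas as pd

        from sctipping.criticality import CriticalityReport

        return CriticalityReport(
            frame=pd.DataFrame(rows), analytes_used=("a",), index_used="snai"
        )

    def test_argmax(self):
        rows = [
            {"cluster": 1, "day": 1, "path": "upper", "n_cells": 20,
             "snai": 2.0, "logdet": -0.7, "ic": 0.2, "degenerate": False},
            {"cluster": 2, "day": 3, "path": "upper", "n_cells": 20,
             "snai": 9.0, "logdet": -2.2, "ic": 0.4, "degenerate": False},
        ]
        assert tipping_cluster(self._report(rows), "upper") == 2
        assert tipping_cluster(self._report(rows), "upper", index="ic") == 2

    def test_tie_raises(self):
        rows = [
            {"cluster": 1, "day": 1, "path": "upper", "n_cells": 20,
             "snai": 5.0, "logdet": -1.6, "ic": 0.2, "degenerate": False},
            {"cluster": 2, "day": 3, "path": "upper", "n_cells": 20,
             "snai": 5.0, "logdet": -1.6, "ic": 0.2, "degenerate": False},
        ]
        with pytest.raises(st.ValidationError, match="tie"):
            tipping_cluster(self._report(rows), "upper")

    def test_all_degenerate_raises(self):
        rows = [
            {"cluster": 1, "day": 1, "path": "upper", "n_cells": 5,
             "snai": np.inf, "logdet": -np.inf, "ic": 0.2, "degenerate": True},
            {"cluster": 2, "day": 3, "path": "upper", "n_cells": 5,
             "snai": np.inf, "logdet": -np.inf, "ic": 0.3, "degenerate": True},
        ]
        with pytest.raises(st.ValidationError, match="degenerate"):
            tipping_cluster(self._report(rows), "upper")


@given(
    hs.integers(min_value=0, max_value=10_000),
    hs.integers(min_value=12, max_value=40),
    hs.integers(min_value=3, max_value=6),
)
@settings(max_examples=20, deadline=None, derandomize=True)
def test_ic_matches_bruteforce_property(seed, n, p):
    X = np.random.default_rng(seed).normal(size=(n, p))
    assert ic_index(X) == pytest.approx(ic_bruteforce(X), abs=1e-10)
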