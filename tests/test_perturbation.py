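import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scfocal.perturbation import (
    RESISTANT,
    SENSITIVE,
    compare_group_connectivity,
    de_between_populations,
    proportion_shift,
    split_cells,
)

from conftest import make_lognorm


class TestSplitCells:
    def test_positive_rho_is_resistant_at_zero(self):
        split = split_cells(pd.Series({"c1": 0.3}), mode="fixed", tau=0.0)
        assert split.labels["c1"] == RESISTANT

    def test_all_negative_rho_all_sensitive(self):
        split = split_cells(pd.Series({"a": -0.5, "b": -0.01}), mode="fixed", tau=0.0)
        assert (split.labels == SENSITIVE).all()

    def test_mean_mode_hand_example(self):
        rho = pd.Series({"a": -0.2, "b": 0.0, "c": 0.1, "d": 0.5})
        split = split_cells(rho, mode="mean")
        assert split.tau == pytest.approx(0.1)
        assert split.labels.tolist() == [SENSITIVE, SENSITIVE, SENSITIVE, RESISTANT]

    def test_boundary_rho_equals_tau_is_sensitive(self):
        split = split_cells(pd.Series({"c": 0.0}), mode="fixed", tau=0.0)
        assert split.labels["c"] == SENSITIVE

    def test_extreme_taus_label_everything_one_way(self, rng):
        rho = pd.Series(rng.uniform(-0.9, 0.9, size=50))
        assert (split_cells(rho, tau=-1.0).labels == RESISTANT).all()
        assert (split_cells(rho, tau=1.0).labels == SENSITIVE).all()

    def test_monotone_in_tau(self, rng):
        rho = pd.Series(rng.uniform(-1, 1, size=100))
        prev_resistant = None
        for tau in [-0.5, 0.0, 0.3, 0.8]:
            res = set(split_cells(rho, tau=tau).cells(RESISTANT))
            if prev_resistant is not None:
                assert res <= prev_resistant
            prev_resistant = res

    @settings(derandomize=True, max_examples=50)
    @given(
        rhos=st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=30),
        tau_lo=st.floats(-1, 1, allow_nan=False),
        tau_hi=st.floats(-1, 1, allow_nan=False),
    )
    def test_resistant_set_shrinks_as_tau_rises(self, rhos, tau_lo, tau_hi):
        lo, hi = sorted((tau_lo, tau_hi))
        rho = pd.Series(rhos, index=[f"c{i}" for i in range(len(rhos))])
        at_hi = set(split_cells(rho, tau=hi).cells(RESISTANT))
        at_lo = set(split_cells(rho, tau=lo).cells(RESISTANT))
        assert at_hi <= at_lo

    def test_missing_values_excluded_and_all_missing_errors(self):
        split = split_cells(pd.Series({"a": np.nan, "b": 0.4}))
        assert list(split.labels.index) == ["b"]
        with pytest.raises(ValueError, match="non-missing"):
            split_cells(pd.Series({"a": np.nan}))


def _split_from(labels: dict):
    rho = pd.Series({c: (0.5 if v == RESISTANT else -0.5) for c, v in labels.items()})
    return split_cells(rho, mode="fixed", tau=0.0)


class TestProportionShift:
    def _meta(self, rows):
        return pd.DataFrame(rows, columns=["cell_id", "state", "subject"])

    def _balanced_fixture(self):
        """3 subjects, identical state composition in both populations."""
        rows, labels = [], {}
        for s in range(3):
            for i in range(4):
                state = "X" if i % 2 == 0 else "Y"
                for pop, tag in ((RESISTANT, "r"), (SENSITIVE, "s")):
                    cid = f"p{s}_{tag}{i}"
                    rows.append((cid, state, f"p{s}"))
                    labels[cid] = pop
        return self._meta(rows), _split_from(labels)

    def test_identical_composition_gives_zero_deltas(self):
        meta, split = self._balanced_fixture()
        shift = proportion_shift(split, meta, "state", "subject")
        np.testing.assert_allclose(shift.deltas.to_numpy(), 0.0)
        assert (shift.stats["p"] == 1.0).all()

    def test_hand_computed_deltas(self):
        # subject p0: resistant = {X, X, Y}, sensitive = {X, Y, Y, Y}
        rows, labels = [], {}
        comp = {
            "p0": ([("X", 2), ("Y", 1)], [("X", 1), ("Y", 3)]),
            "p1": ([("X", 1), ("Y", 1)], [("X", 1), ("Y", 1)]),
            "p2": ([("X", 3), ("Y", 1)], [("X", 1), ("Y", 1)]),
        }
        for subj, (res, sen) in comp.items():
            k = 0
            for state, n in res:
                for _ in range(n):
                    cid = f"{subj}_r{k}"
                    rows.append((cid, state, subj))
                    labels[cid] = RESISTANT
                    k += 1
            for state, n in sen:
                for _ in range(n):
                    cid = f"{subj}_s{k}"
                    rows.append((cid, state, subj))
                    labels[cid] = SENSITIVE
                    k += 1
        shift = proportion_shift(_split_from(labels), self._meta(rows), "state", "subject")
        assert shift.deltas.loc["p0", "X"] == pytest.approx(2 / 3 - 1 / 4)
        assert shift.deltas.loc["p0", "Y"] == pytest.approx(1 / 3 - 3 / 4)
        assert shift.deltas.loc["p2", "X"] == pytest.approx(3 / 4 - 1 / 2)

    def test_per_subject_deltas_sum_to_zero(self):
        meta, split = self._balanced_fixture()
        shift = proportion_shift(split, meta, "state", "subject")
        np.testing.assert_allclose(shift.deltas.sum(axis=1).to_numpy(), 0.0, atol=1e-12)

    def test_subject_missing_population_dropped(self):
        meta, split = self._balanced_fixture()
        extra = pd.DataFrame(
            [(f"p9_r{i}", "X", "p9") for i in range(3)], columns=["cell_id", "state", "subject"]
        )
        labels = split.labels.copy()
        for i in range(3):
            labels[f"p9_r{i}"] = RESISTANT
        split.labels = labels
        split.rho = pd.Series(0.5, index=labels.index)
        with pytest.warns(UserWarning, match="p9"):
            shift = proportion_shift(split, pd.concat([meta, extra]), "state", "subject")
        assert "p9" not in shift.deltas.index

    def test_too_few_subjects_errors(self):
        meta, split = self._balanced_fixture()
        meta = meta.loc[meta["subject"] != "p2"]
        split.labels = split.labels[~split.labels.index.str.startswith("p2")]
        with pytest.raises(ValueError, match="3 subjects"):
            proportion_shift(split, meta, "state", "subject")


class TestDEBetweenPopulations:
    def _fixture(self):
        vals = np.ones((3, 12))
        vals[0, :6] = 3.0  # marker high in resistant cells
        cells = [f"r{i}" for i in range(6)] + [f"s{i}" for i in range(6)]
        expr = make_lognorm(vals, genes=["marker", "flat", "zero"], cells=cells)
        labels = {c: RESISTANT for c in cells[:6]}
        labels.update({c: SENSITIVE for c in cells[6:]})
        return expr, _split_from(labels)

    def test_marker_gene_positive_logfc_and_significant(self):
        expr, split = self._fixture()
        de = de_between_populations(expr, split).set_index("gene")
        assert de.loc["marker", "logFC"] > 0
        assert de.loc["marker", "adj_p"] < 0.05

    def test_identical_gene_logfc_zero(self):
        expr, split = self._fixture()
        de = de_between_populations(expr, split).set_index("gene")
        assert de.loc["flat", "logFC"] == 0.0

    def test_all_input_genes_reported(self):
        expr, split = self._fixture()
        de = de_between_populations(expr, split)
        assert de["gene"].tolist() == expr.gene_ids

    def test_small_population_errors(self):
        expr, split = self._fixture()
        split.labels = split.labels.iloc[:8]  # 6 resistant, 2 sensitive
        with pytest.raises(ValueError, match="too small"):
            de_between_populations(expr, split)


class TestCompareGroupConnectivity:
    def _meta(self, groups):
        return pd.DataFrame(
            {"cell_id": list(groups), "group": [groups[c] for c in groups]}
        )

    def test_separated_groups_match_exact_enumeration(self):
        rho = pd.Series({f"c{i}": v for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])})
        groups = {f"c{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        res = compare_group_connectivity(rho, self._meta(groups), "group")
        # enumeration: U = number of (a, b) pairs with a > b over all 3x3 pairs
        u_exact = sum(
            1 for a, b in itertools.product([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]) if a > b
        )
        assert res.statistic == u_exact == 0
        assert res.pvalue < 0.2  # continuity-corrected normal approximation

    def test_identical_distributions_p_near_one(self):
        vals = [0.1, 0.2, 0.3, 0.1, 0.2, 0.3]
        rho = pd.Series({f"c{i}": v for i, v in enumerate(vals)})
        groups = {f"c{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        res = compare_group_connectivity(rho, self._meta(groups), "group")
        assert res.pvalue > 0.9

    def test_label_swap_keeps_two_sided_p(self, rng):
        rho = pd.Series(rng.normal(size=12), index=[f"c{i}" for i in range(12)])
        groups = {f"c{i}": ("g1" if i < 5 else "g2") for i in range(12)}
        swapped = {c: ("g2" if g == "g1" else "g1") for c, g in groups.items()}
        p1 = compare_group_connectivity(rho, self._meta(groups), "group").pvalue
        p2 = compare_group_connectivity(rho, self._meta(swapped), "group").pvalue
        assert p1 == pytest.approx(p2)

    def test_wrong_group_count_errors(self):
        rho = pd.Series({f"c{i}": 0.1 * i for i in range(6)})
        groups = {f"c{i}": f"g{i % 3}" for i in range(6)}
        with pytest.raises(ValueError, match="exactly 2"):
            compare_group_connectivity(rho, self._meta(groups), "group")
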