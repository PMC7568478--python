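import numpy as np
import pandas as pd
import pytest

from quantherit import (
    PedigreeError,
    ValidationError,
    build_full_sib,
    build_midparent,
    build_offspring_parent,
    spouse_correlation,
)
from quantherit.family_structures import RelativePairSet

from conftest import adjusted_frame, toy_pedigree


class TestOffspringParent:
    def test_both_parents_half_weights(self, nuclear_family):
        ped, adj = nuclear_family
        pairs = build_offspring_parent(ped, adj)
        assert len(pairs) == 2
        assert sorted(pairs.pairs["weight"]) == [0.5, 0.5]
        assert set(pairs.pairs["predictor_value"]) == {2.0, 4.0}
        assert (pairs.pairs["dependent_value"] == 1.0).all()

    def test_single_parent_unit_weights(self):
        ped = toy_pedigree(
            [
                ("dad", "f1", None, None, "M", 60.0),
                ("mom", "f1", None, None, "F", 58.0),
                ("kid1", "f1", "dad", "mom", "M", 30.0),
                ("kid2", "f1", "dad", "mom", "F", 28.0),
            ]
        )
        adj = adjusted_frame({"dad": 2.0, "kid1": 0.5, "kid2": -0.5})  # mom missing
        pairs = build_offspring_parent(ped, adj)
        assert len(pairs) == 2
        assert (pairs.pairs["weight"] == 1.0).all()

    def test_df_is_total_offspring_minus_two(self):
        rows, adj = [], {}
        for f, k in enumerate((1, 2, 3)):
            fam = f"f{f}"
            rows.append((f"{fam}dad", fam, None, None, "M", 60.0))
            rows.append((f"{fam}mom", fam, None, None, "F", 60.0))
            adj[f"{fam}dad"] = 1.0
            adj[f"{fam}mom"] = 2.0
            for j in range(k):
                rows.append((f"{fam}kid{j}", fam, f"{fam}dad", f"{fam}mom", "M", 30.0))
                adj[f"{fam}kid{j}"] = float(j)
        pairs = build_offspring_parent(toy_pedigree(rows), adjusted_frame(adj))
        assert pairs.df == 6 - 2

    def test_weights_sum_to_offspring_count(self, big_cohort):
        from quantherit import adjust_phenotypes

        adj = adjust_phenotypes(big_cohort.phenotypes, big_cohort.pedigree)
        pairs = build_offspring_parent(big_cohort.pedigree, adj)
        is_off = big_cohort.pedigree["father_id"].notna()
        n_offspring = int(is_off.sum())  # generator always phenotypes >=1 parent
        assert pairs.pairs["weight"].sum() == pytest.approx(n_offspring)

    def test_offspring_without_phenotyped_parent_excluded(self):
        ped = toy_pedigree(
            [
                ("dad", "f1", None, None, "M", 60.0),
                ("mom", "f1", None, None, "F", 58.0),
                ("kid", "f1", "dad", "mom", "M", 30.0),
            ]
        )
        adj = adjusted_frame({"kid": 1.0})
        pairs = build_offspring_parent(ped, adj)
        assert len(pairs) == 0
        assert pairs.n_excluded == 1

    def test_own_parent_raises(self):
        ped = toy_pedigree([("a", "f1", "a", None, "M", 40.0)])
        with pytest.raises(PedigreeError, match="own parent"):
            build_offspring_parent(ped, adjusted_frame({"a": 1.0}))

    def test_raw_dependent_mode(self, nuclear_family):
        ped, adj = nuclear_family
        raw = pd.DataFrame({"individual_id": ["kid"], "raw_value": [7.5]})
        pairs = build_offspring_parent(
            ped, adj, dependent_adjusted=False, raw_values=raw
        )
        assert (pairs.pairs["dependent_value"] == 7.5).all()
        with pytest.raises(ValidationError):
            build_offspring_parent(ped, adj, dependent_adjusted=False)


class TestMidparent:
    def test_predictor_is_parent_mean(self, nuclear_family):
        ped, adj = nuclear_family
        pairs = build_midparent(ped, adj)
        assert len(pairs) == 1
        assert pairs.pairs.loc[0, "predictor_value"] == pytest.approx(3.0)
        assert pairs.pairs.loc[0, "weight"] == 1.0

    def test_single_parent_family_contributes_nothing(self):
        ped = toy_pedigree(
            [
                ("dad", "f1", None, None, "M", 60.0),
                ("kid", "f1", "dad", None, "M", 30.0),
            ]
        )
        pairs = build_midparent(ped, adjusted_frame({"dad": 2.0, "kid": 1.0}))
        assert len(pairs) == 0

    def test_siblings_share_midparent(self):
        ped = toy_pedigree(
            [
                ("dad", "f1", None, None, "M", 60.0),
                ("mom", "f1", None, None, "F", 58.0),
                ("k1", "f1", "dad", "mom", "M", 30.0),
                ("k2", "f1", "dad", "mom", "F", 28.0),
            ]
        )
        adj = adjusted_frame({"dad": 2.0, "mom": 4.0, "k1": 0.0, "k2": 1.0})
        pairs = build_midparent(ped, adj)
        assert len(pairs) == 2
        assert (pairs.pairs["predictor_value"] == 3.0).all()


class TestFullSib:
    def sibship(self, ids, values, fam="f1"):
        rows = [(f"{fam}dad", fam, None, None, "M", 60.0),
                (f"{fam}mom", fam, None, None, "F", 58.0)]
        adj = {f"{fam}dad": 0.0, f"{fam}mom": 0.0}
        for i, v in zip(ids, values):
            rows.append((i, fam, f"{fam}dad", f"{fam}mom", "M", 30.0))
            adj[i] = v
        return toy_pedigree(rows), adjusted_frame(adj)

    def test_dyad_double_entry(self):
        ped, adj = self.sibship(["a", "b"], [1.0, 2.0])
        pairs = build_full_sib(ped, adj)
        got = set(zip(pairs.pairs["dependent_value"], pairs.pairs["predictor_value"]))
        assert got == {(1.0, 2.0), (2.0, 1.0)}

    def test_triple_gives_six_ordered_pairs(self):
        ped, adj = self.sibship(["a", "b", "c"], [1.0, 2.0, 3.0])
        assert len(build_full_sib(ped, adj)) == 6

    def test_df_sums_k_minus_one(self):
        frames = []
        adjs = []
        for f, k in enumerate((2, 3, 1)):
            ped, adj = self.sibship(
                [f"f{f}s{j}" for j in range(k)], list(np.arange(k, dtype=float)),
                fam=f"f{f}",
            )
            frames.append(ped)
            adjs.append(adj)
        ped = pd.concat(frames, ignore_index=True)
        adj = pd.concat(adjs, ignore_index=True)
        pairs = build_full_sib(ped, adj)
        assert pairs.df == 1 + 2 + 0
        assert len(pairs) == 2 + 6 + 0

    def test_half_sibs_excluded(self):
        ped = toy_pedigree(
            [
                ("dad", "f1", None, None, "M", 60.0),
                ("mom1", "f1", None, None, "F", 58.0),
                ("mom2", "f1", None, None, "F", 55.0),
                ("a", "f1", "dad", "mom1", "M", 30.0),
                ("b", "f1", "dad", "mom2", "M", 28.0),
            ]
        )
        adj = adjusted_frame({"a": 1.0, "b": 2.0, "dad": 0.0, "mom1": 0.0, "mom2": 0.0})
        assert len(build_full_sib(ped, adj)) == 0

    def test_double_entry_slope_equals_correlation(self):
        rng = np.random.default_rng(5)
        frames, adjs = [], []
        for f in range(60):
            k = rng.integers(2, 5)
            ped, adj = self.sibship(
                [f"f{f}s{j}" for j in range(k)],
                list(rng.normal(size=k)),
                fam=f"f{f}",
            )
            frames.append(ped)
            adjs.append(adj)
        pairs = build_full_sib(
            pd.concat(frames, ignore_index=True), pd.concat(adjs, ignore_index=True)
        )
        x = pairs.pairs["predictor_value"].to_numpy()
        y = pairs.pairs["dependent_value"].to_numpy()
        slope = np.cov(x, y, ddof=0)[0, 1] / np.var(x)
        corr = np.corrcoef(x, y)[0, 1]
        assert slope == pytest.approx(corr, abs=1e-12)


class TestSpouseCorrelation:
    def couples(self, values_f, values_m):
        rows, adj = [], {}
        for i, (vf, vm) in enumerate(zip(values_f, values_m)):
            fam = f"f{i}"
            rows.append((f"{fam}d", fam, None, None, "M", 60.0))
            rows.append((f"{fam}m", fam, None, None, "F", 58.0))
            rows.append((f"{fam}k", fam, f"{fam}d", f"{fam}m", "M", 30.0))
            adj[f"{fam}d"] = vf
            adj[f"{fam}m"] = vm
            adj[f"{fam}k"] = 0.0
        return toy_pedigree(rows), adjusted_frame(adj)

    def test_identical_couples_give_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        ped, adj = self.couples(vals, vals)
        assert spouse_correlation(ped, adj) == pytest.approx(1.0)

    def test_independent_couples_near_zero(self):
        rng = np.random.default_rng(6)
        ped, adj = self.couples(rng.normal(size=2000), rng.normal(size=2000))
        assert abs(spouse_correlation(ped, adj)) < 3.0 / np.sqrt(2000)

    def test_too_few_couples(self):
        ped, adj = self.couples([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="3"):
            spouse_correlation(ped, adj)

    def test_generator_round_trip(self):
        from quantherit import CohortConfig, adjust_phenotypes, generate_cohort

        cfg = CohortConfig(
            n_families=5000, r_spouse_target=0.04, p_both_parents=1.0, seed=31
        )
        cohort = generate_cohort(cfg)
        adj = adjust_phenotypes(cohort.phenotypes, cohort.pedigree)
        r = spouse_correlation(cohort.pedigree, adj)
        assert r == pytest.approx(0.04, abs=3.0 / np.sqrt(5000))


class TestRelativePairSetIO:
    def test_write_read_round_trip(self, tmp_path, nuclear_family):
        ped, adj = nuclear_family
        pairs = build_offspring_parent(ped, adj)
        path = tmp_path / "pairs_op.csv"
        pairs.write(path)
        loaded = RelativePairSet.read(path)
        assert loaded.df == pairs.df
        assert loaded.pair_kind == pairs.pair_kind
        pd.testing.assert_frame_equal(
            loaded.pairs, pairs.pairs, check_dtype=False
        )

    def test_negative_df_rejected(self, nuclear_family):
        ped, adj = nuclear_family
        pairs = build_offspring_parent(ped, adj)
        with pytest.raises(ValidationError):
            RelativePairSet(
                pairs=pairs.pairs, pair_kind="offspring_parent", df=-1, n_families=1
            )
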