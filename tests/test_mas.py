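"""MAS scoring, ranking and the Cross-MAS partition (incl. brute-force oracle)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmas import (
    PipelineConfig,
    ValidationError,
    crossmas_partition,
    mas_score,
    rank_by_mas,
    significant_sets,
)


class TestMasScore:
    @pytest.mark.parametrize(
        "lfc,p,expected",
        [(2.0, 0.01, 4.0), (1.0, 1.0, 0.0), (-3.0, 1.0, 0.0), (-1.5, 1e-4, 6.0)],
    )
    def test_direct_values(self, lfc, p, expected):
        assert mas_score(lfc, p) == pytest.approx(expected)

    def test_exponents(self):
        assert mas_score(2.0, 0.01, M=2.0, A=0.5) == pytest.approx(4 * np.sqrt(2))

    def test_rejects_nonpositive_p(self):
        with pytest.raises(ValidationError):
            mas_score(1.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(
        lfc=st.floats(0.01, 10), delta=st.floats(0.01, 5),
        p=st.floats(1e-10, 0.999),
    )
    def test_monotone_in_lfc_and_p(self, lfc, delta, p):
        assert mas_score(lfc + delta, p) >= mas_score(lfc, p)
        assert mas_score(lfc, p) >= mas_score(lfc, min(p * 1.5, 1.0))


class TestRankByMas:
    def _table(self, mas, p, lfc, genes=None):
        n = len(mas)
        return pd.DataFrame(
            {
                "gene_id": genes or [f"g{i}" for i in range(n)],
                "log2fc": lfc,
                "p_bh": p,
                "mas": mas,
            }
        )

    def test_tie_broken_by_p(self):
        t = self._table([5, 3, 3, 1], [0.1, 0.02, 0.01, 0.5], [1, 1, 1, 1])
        ranked = rank_by_mas(t)
        assert list(ranked["rank"]) == [1, 3, 2, 4]

    def test_full_tie_falls_back_to_gene_id(self):
        t = self._table([2, 2, 2], [0.1, 0.1, 0.1], [1, 1, 1],
                        genes=["c", "a", "b"])
        assert list(rank_by_mas(t)["rank"]) == [3, 1, 2]

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(8)
        n = 100
        t = self._table(
            rng.choice([0.0, 1.0, 2.5, 4.0], n),
            rng.choice([0.01, 0.05, 0.5], n),
            rng.normal(size=n),
        )
        ranked = rank_by_mas(t)
        key = sorted(
            range(n),
            key=lambda i: (-t["mas"][i], t["p_bh"][i], -abs(t["log2fc"][i]),
                           t["gene_id"][i]),
        )
        expected = np.empty(n, dtype=int)
        expected[key] = np.arange(1, n + 1)
        assert np.array_equal(ranked["rank"].to_numpy(), expected)


class TestSignificantSets:
    def test_boundary_is_strict(self):
        cfg = PipelineConfig()
        t = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2fc": [1.0, -2.0, 1.2],
                "p_bh": [0.01, 0.049, 0.05],
            }
        )
        up, down = significant_sets(t, cfg)
        assert up == set() and down == {"b"}

    def test_hand_enumerated_toy_table(self):
        cfg = PipelineConfig()
        t = pd.DataFrame(
            {
                "gene_id": list("abcdef"),
                "log2fc": [2.0, -1.5, 0.5, 1.01, -3.0, 1.8],
                "p_bh": [0.001, 0.2, 0.001, 0.04, 0.049, 0.051],
            }
        )
        up, down = significant_sets(t, cfg)
        assert up == {"a", "d"}
        assert down == {"e"}


def _deg(genes, lfc, p):
    t = pd.DataFrame(
        {"gene_id": genes, "log2fc": lfc, "p_bh": p,
         "mas": mas_score(np.asarray(lfc, dtype=float), np.asarray(p, dtype=float))}
    )
    return rank_by_mas(t)


def crossmas_oracle(kd, oe, driver, cfg):
    """Exhaustive membership enumeration + explicit sorts."""
    kd = kd[kd.gene_id != driver]
    oe = oe[oe.gene_id != driver]
    up_kd, down_kd = significant_sets(kd, cfg)
    up_oe, down_oe = significant_sets(oe, cfg)
    rk = dict(zip(kd.gene_id, kd["rank"]))
    ro = dict(zip(oe.gene_id, oe["rank"]))
    sig_kd, sig_oe = up_kd | down_kd, up_oe | down_oe
    out = {
        "kd_only_up": sorted(up_kd - sig_oe, key=lambda g: (rk[g], g)),
        "kd_only_down": sorted(down_kd - sig_oe, key=lambda g: (rk[g], g)),
        "oe_only_up": sorted(up_oe - sig_kd, key=lambda g: (ro[g], g)),
        "oe_only_down": sorted(down_oe - sig_kd, key=lambda g: (ro[g], g)),
        "shared_up": sorted(up_kd & up_oe,
                            key=lambda g: (max(rk[g], ro[g]), min(rk[g], ro[g]), g)),
        "shared_down": sorted(down_kd & down_oe,
                              key=lambda g: (max(rk[g], ro[g]), min(rk[g], ro[g]), g)),
    }
    return out


class TestCrossMas:
    def test_simple_memberships(self):
        kd = _deg(["a", "b", "m"], [2.0, 1.5, -2.0], [0.01, 0.01, 0.001])
        oe = _deg(["a", "b", "m"], [0.1, 1.6, 3.0], [0.9, 0.02, 0.001])
        part = crossmas_partition(kd, oe, driver_gene="m")
        assert part.kd_only_up == ["a"]
        assert part.shared_up == ["b"]
        assert "m" not in part.detail["gene_id"].tolist()

    def test_shared_carries_max_rank(self):
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        kd = _deg(genes, rng.uniform(1.1, 4, 10), rng.uniform(1e-6, 0.04, 10))
        oe = _deg(genes, rng.uniform(1.1, 4, 10), rng.uniform(1e-6, 0.04, 10))
        part = crossmas_partition(kd, oe, driver_gene="none")
        detail = part.detail.set_index("gene_id")
        for g in part.shared_up:
            assert detail.loc[g, "max_rank"] == max(
                int(kd.set_index("gene_id").loc[g, "rank"]),
                int(oe.set_index("gene_id").loc[g, "rank"]),
            )
        ranks = [detail.loc[g, "max_rank"] for g in part.shared_up]
        assert ranks == sorted(ranks)

    def test_discordant_not_dropped(self):
        kd = _deg(["a", "b"], [2.0, 2.0], [0.01, 0.01])
        oe = _deg(["a", "b"], [-2.0, 0.0], [0.01, 0.9])
        part = crossmas_partition(kd, oe, driver_gene="none")
        assert part.discordant == ["a"]
        assert part.kd_only_up == ["b"]

    def test_matches_exhaustive_oracle_on_random_tables(self):
        rng = np.random.default_rng(77)
        genes = [f"g{i:03d}" for i in range(200)]
        cfg = PipelineConfig()
        for trial in range(5):
            kd = _deg(genes, rng.normal(0, 1.5, 200),
                      np.clip(rng.uniform(0, 0.2, 200), 1e-12, 1))
            oe = _deg(genes, rng.normal(0, 1.5, 200),
                      np.clip(rng.uniform(0, 0.2, 200), 1e-12, 1))
            part = crossmas_partition(kd, oe, driver_gene="g000", cfg=cfg)
            oracle = crossmas_oracle(kd, oe, "g000", cfg)
            assert part.sets() == oracle

    def test_symmetry_under_contrast_swap(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(80)]
        kd = _deg(genes, rng.normal(0, 2, 80), np.clip(rng.uniform(0, 0.1, 80), 1e-12, 1))
        oe = _deg(genes, rng.normal(0, 2, 80), np.clip(rng.uniform(0, 0.1, 80), 1e-12, 1))
        a = crossmas_partition(kd, oe, driver_gene="none")
        b = crossmas_partition(oe, kd, driver_gene="none")
        assert a.kd_only_up == b.oe_only_up
        assert a.oe_only_down == b.kd_only_down
        assert a.shared_up == b.shared_up

    def test_partition_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(150)]
        cfg = PipelineConfig()
        kd = _deg(genes, rng.normal(0, 2, 150), np.clip(rng.uniform(0, 0.1, 150), 1e-12, 1))
        oe = _deg(genes, rng.normal(0, 2, 150), np.clip(rng.uniform(0, 0.1, 150), 1e-12, 1))
        part = crossmas_partition(kd, oe, driver_gene="g0", cfg=cfg)
        all_sets = [set(v) for v in part.sets().values()] + [set(part.discordant)]
        union = set().union(*all_sets)
        assert sum(len(s) for s in all_sets) == len(union)
        up_kd, down_kd = significant_sets(kd[kd.gene_id != "g0"], cfg)
        up_oe, down_oe = significant_sets(oe[oe.gene_id != "g0"], cfg)
        assert union == up_kd | down_kd | up_oe | down_oe

    def test_disjoint_universes_raise(self):
        kd = _deg(["a", "b"], [1, 1], [0.5, 0.5])
        oe = _deg(["a", "c"], [1, 1], [0.5, 0.5])
        with pytest.raises(ValidationError):
            crossmas_partition(kd, oe, driver_gene="none")
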