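"""Site-count enrichment statistics, FDR, pass criteria, positional
profiles and the induction-strength utilities."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crescan.enrichment import (
    EnrichmentResult,
    adjust_fdr,
    apply_pass_criteria,
    collapse_redundant,
    cooperativity,
    count_sites,
    motif_enrichment,
    per_gene_normalize,
    positional_profile,
    select_regulated,
    strength_time_crosstab,
)
from crescan.motifs import MotifHit


def _hit(gene, offset, matrix="V$X_01"):
    return MotifHit(gene, matrix, offset, "+", 0.9, 1.0)


def exact_mww_p(x, y) -> float:
    """Independent two-sided rank-sum p by full enumeration (untied data)."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0
    m = len(x)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), m):
        r = ranks[list(idx)].sum() - m * (m + 1) / 2
        us.append(r)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestCountSites:
    def test_counts_and_zero_fill(self):
        hits = [_hit("a", -100), _hit("a", -50), _hit("a", 10), _hit("b", -700)]
        counts = count_sites(hits, ["a", "b", "c"], window=(-600, 100))
        assert counts == {"a": 3, "b": 0, "c": 0}

    def test_boundaries_half_open(self):
        hits = [_hit("a", -600), _hit("a", 99), _hit("a", 100)]
        assert count_sites(hits, ["a"], window=(-600, 100))["a"] == 2

    def test_manifest_counts_exact(self, isre, planted_promoters):
        _, manifest = planted_promoters
        genes = [f"gene{i:04d}" for i in range(50)]
        hits = [
            MotifHit(p.gene_id, p.matrix_id, p.offset, p.strand, 1.0, 1.0)
            for p in manifest.plants
        ]
        assert count_sites(hits, genes) == {
            g: manifest.counts().get(g, 0) for g in genes
        }


class TestMotifEnrichment:
    def test_null_identical_multisets(self):
        fg = {f"f{i}": c for i, c in enumerate([0, 1, 1, 2, 3])}
        bg = {f"b{i}": c for i, c in enumerate([0, 1, 1, 2, 3])}
        st_ = motif_enrichment(fg, bg)
        assert st_.enrichment == 0.0
        assert st_.p_raw >= 0.99

    def test_fourfold_example_means(self):
        fg = {f"f{i}": 4 for i in range(20)}
        bg = {f"b{i}": 1 for i in range(100)}
        st_ = motif_enrichment(fg, bg)
        assert (st_.d, st_.b) == (4.0, 1.0)
        assert st_.enrichment == 2.0
        assert st_.pct_with_sites == 100.0

    def test_exact_enumeration_oracle_untied(self):
        rng = np.random.default_rng(8)
        for m, n in [(3, 5), (5, 5), (8, 8), (2, 8)]:
            pool = rng.choice(1000, size=m + n, replace=False).astype(float)
            fg = {f"f{i}": v for i, v in enumerate(pool[:m])}
            bg = {f"b{i}": v for i, v in enumerate(pool[m:])}
            got = motif_enrichment(fg, bg).p_raw
            assert got == pytest.approx(exact_mww_p(pool[:m], pool[m:]), abs=1e-12)

    def test_undefined_enrichment_when_background_empty(self):
        fg = {"a": 2, "b": 3}
        bg = {c: 0 for c in "defg"}
        st_ = motif_enrichment(fg, bg)
        assert math.isnan(st_.enrichment)
        assert st_.diagnostic_enrichment == pytest.approx(math.log2(2.5 * 4))

    def test_too_small_inputs_raise(self):
        with pytest.raises(ValueError):
            motif_enrichment({"a": 1}, {"b": 1, "c": 2})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_antisymmetry_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        fg = {f"f{i}": int(c) for i, c in enumerate(rng.poisson(2.0, 12))}
        bg = {f"b{i}": int(c) for i, c in enumerate(rng.poisson(0.7, 30))}
        if sum(fg.values()) == 0 or sum(bg.values()) == 0:
            return
        a = motif_enrichment(fg, bg)
        b = motif_enrichment(bg, fg)
        assert a.p_raw == pytest.approx(b.p_raw, abs=1e-12)
        assert a.enrichment == pytest.approx(-b.enrichment, abs=1e-12)

    def test_power_under_fourfold_density_difference(self):
        # count-level version of the planted experiment: detected in
        # >=95% of replicates
        rng = np.random.default_rng(99)
        detected = 0
        reps = 100
        for _ in range(reps):
            fg = {f"f{i}": int(c) for i, c in enumerate(rng.poisson(2.0, 60))}
            bg = {f"b{i}": int(c) for i, c in enumerate(rng.poisson(0.5, 1000))}
            s = motif_enrichment(fg, bg)
            ok = (
                s.enrichment >= 1
                and s.p_raw < 0.005
                and s.genes_with_sites_fg >= 5
                and s.pct_with_sites >= 25
            )
            detected += ok
        assert detected >= 95


class TestAdjustFdr:
    def test_hand_applied_bh(self):
        assert adjust_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_and_singleton(self):
        assert adjust_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
        assert adjust_fdr([0.2]).tolist() == [0.2]

    def test_order_invariance_and_monotonicity(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        adj = adjust_fdr(p)
        perm = rng.permutation(40)
        assert adjust_fdr(p[perm]) == pytest.approx(adj[perm])
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


def _res(matrix_id="V$X_01", enrichment=2.0, p_adj=1e-4, genes=10, n_fg=20, p_raw=1e-5):
    return EnrichmentResult(
        matrix_id=matrix_id, n_fg=n_fg, genes_with_sites_fg=genes,
        pct_with_sites=100.0 * genes / n_fg, d=2.0, b=0.5,
        enrichment=enrichment, p_raw=p_raw, p_adj=p_adj,
    )


class TestPassCriteria:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(enrichment=2.1, p_adj=0.001, genes=10), True),
            (dict(enrichment=2.1, p_adj=0.001, genes=4), False),  # min-5 rule
            (dict(enrichment=0.9, p_adj=1e-9, genes=20), False),  # 2-fold rule
            (dict(enrichment=2.1, p_adj=0.005, genes=10), False),  # strict p
            (dict(enrichment=2.1, p_adj=0.001, genes=4, n_fg=100), False),  # 25% rule
            (dict(enrichment=math.nan, p_adj=1e-9, genes=20), False),  # b == 0
        ],
    )
    def test_rules(self, kwargs, expected):
        (out,) = apply_pass_criteria([_res(**kwargs)])
        assert out.passes is expected


class TestCollapseRedundant:
    def test_keep_lowest_p_in_group(self):
        results = [
            _res("V$NFKB_Q6_01", p_adj=1e-5),
            _res("V$NFKB_C", p_adj=1e-8),
            _res("V$E2F_01", p_adj=0.5),
        ]
        out = collapse_redundant(results)
        assert {r.matrix_id for r in out} == {"V$NFKB_C", "V$E2F_01"}

    def test_singleton_groups_identity(self):
        results = [_res("V$A_01"), _res("V$B_01")]
        assert len(collapse_redundant(results)) == 2

    def test_random_grouping_against_per_group_min(self):
        rng = np.random.default_rng(4)
        results = [
            _res(f"V$M{i:02d}_01", p_adj=float(rng.uniform()), p_raw=float(rng.uniform()))
            for i in range(30)
        ]
        groups = {r.matrix_id: f"grp{rng.integers(0, 6)}" for r in results}
        out = {r.matrix_id for r in collapse_redundant(results, groups)}
        for g in set(groups.values()):
            members = [r for r in results if groups[r.matrix_id] == g]
            best = min(members, key=lambda r: (r.p_adj, r.p_raw, r.matrix_id))
            assert best.matrix_id in out
        assert len(out) == len(set(groups.values()))


class TestPositionalProfile:
    def test_single_gene_proximal_hit_saturates(self):
        prof = positional_profile([_hit("a", -150)], ["a"], ["z"])
        assert (prof.cum_fg == 1.0).all()
        assert (prof.cum_bg == 0.0).all()
        assert prof.diff == pytest.approx(prof.cum_fg - prof.cum_bg)

    def test_geneless_hits_ignored_and_no_hits_zero(self):
        prof = positional_profile([_hit("other", -100)], ["a"], ["b"])
        assert not prof.cum_fg.any() and not prof.cum_bg.any()

    def test_brute_force_recomputation_from_manifest(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(40)]
        hits = []
        planted = {}
        for g in genes[:25]:
            dists = rng.integers(0, 20000, size=rng.integers(1, 4))
            planted[g] = dists
            hits.extend(_hit(g, -int(d)) for d in dists)
        prof = positional_profile(hits, genes[:30], genes[30:])
        for k, edge in enumerate(prof.bin_edges):
            expect = np.mean(
                [
                    1 if g in planted and (planted[g] <= edge).any() else 0
                    for g in genes[:30]
                ]
            )
            assert prof.cum_fg[k] == pytest.approx(expect)
        assert (np.diff(prof.cum_fg) >= 0).all()
        assert (np.diff(prof.cum_bg) >= 0).all()
        assert prof.cum_fg.max() <= 1.0

    def test_identical_sets_zero_difference(self):
        hits = [_hit("a", -500), _hit("b", -3000)]
        prof = positional_profile(hits, ["a", "b"], ["a", "b"])
        assert prof.diff == pytest.approx(np.zeros_like(prof.diff))


class TestSelectRegulated:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "condition", "time_window", "log2fc", "p_adj"])

    def test_thresholds_are_strict(self):
        table = self._table(
            [
                ("a", "IFN", "30-60", 1.01, 0.005),   # in (up)
                ("b", "IFN", "30-60", 1.5, 0.02),     # p too large
                ("c", "IFN", "30-60", 1.0, 0.001),    # exactly 2-fold: excluded
                ("d", "IFN", "30-60", -1.2, 0.001),   # down
            ]
        )
        assert select_regulated(table, direction="up") == ["a"]
        assert select_regulated(table, direction="down") == ["d"]
        assert select_regulated(table, direction="both") == ["a", "d"]

    def test_recovers_planted_sets_at_zero_noise(self):
        from crescan.simulate import generate_de_table

        table, truth = generate_de_table(30, 20, 950, noise_sd=0.0, seed=1)
        assert set(select_regulated(table, direction="up")) == truth["up"]
        assert set(select_regulated(table, direction="down")) == truth["down"]
        assert set(select_regulated(table)) == truth["up"] | truth["down"]


class TestCrosstab:
    def test_full_coverage_is_100(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b"], "time_window": "0-30", "log2fc": [3.0, 5.0], "p_adj": 0.001}
        )
        out = strength_time_crosstab(table, {"ISRE": {"a": 1, "b": 2}})
        assert (out["ISRE"] == 100.0).all()

    def test_empty_stratum_missing_with_warning(self):
        table = pd.DataFrame(
            {"gene_id": ["a"], "time_window": "0-30", "log2fc": [1.5], "p_adj": 0.001}
        )
        with pytest.warns(UserWarning, match="undefined"):
            out = strength_time_crosstab(table, {"ISRE": {"a": 1}}, fold_cuts=(2, 16))
        row16 = out[out["fold_cut"] == 16].iloc[0]
        assert math.isnan(row16["ISRE"])

    def test_hand_computed_percentages(self):
        table = pd.DataFrame(
            {
                "gene_id": list("abcd"),
                "time_window": "30-60",
                "log2fc": [1.5, 2.5, 3.5, 4.5],
                "p_adj": 0.001,
            }
        )
        sites = {"GAS": {"a": 1, "b": 0, "c": 2, "d": 0}}
        out = strength_time_crosstab(table, sites, fold_cuts=(2, 8, 16))
        # log2fc > 1 (=2-fold): a,b,c,d, 2 of 4 with sites; > 3: c,d -> 1/2;
        # > 4: d only -> 0
        assert out.loc[out["fold_cut"] == 2, "GAS"].iloc[0] == pytest.approx(50.0)
        assert out.loc[out["fold_cut"] == 8, "GAS"].iloc[0] == pytest.approx(50.0)
        assert out.loc[out["fold_cut"] == 16, "GAS"].iloc[0] == pytest.approx(0.0)


class TestCooperativity:
    def _table(self, genes, fc):
        return pd.DataFrame(
            {"gene_id": genes, "condition": "IFN", "time_window": "30-60",
             "log2fc": fc, "p_adj": 0.001}
        )

    def test_constant_fold_change_degenerate(self):
        genes = [f"g{i}" for i in range(9)]
        counts = {g: i % 3 for i, g in enumerate(genes)}
        res = cooperativity(counts, self._table(genes, [2.0] * 9))
        assert res.p_value >= 0.99
        assert res.medians == {"0": 2.0, "1": 2.0, ">1": 2.0}

    def test_perfect_monotone(self):
        genes = [f"g{i}" for i in range(20)]
        counts = {g: i for i, g in enumerate(genes)}
        res = cooperativity(counts, self._table(genes, [float(i) for i in range(20)]))
        assert res.rho == pytest.approx(1.0)
        assert res.p_value < 1e-15

    def test_additive_model_recovers_positive_trend(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(100)]
        counts = {g: int(c) for g, c in zip(genes, rng.poisson(1.0, 100))}
        fc = [1 + 0.8 * counts[g] + rng.normal(0, 0.5) for g in genes]
        res = cooperativity(counts, self._table(genes, fc))
        assert res.rho > 0
        assert res.p_value < 0.01


class TestPerGeneNormalize:
    def test_constant_row_zeros(self):
        mat = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("xyz"))
        assert per_gene_normalize(mat).to_numpy() == pytest.approx(np.zeros((1, 3)))

    def test_simple_row(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("xyz"))
        assert per_gene_normalize(mat).iloc[0].tolist() == [-1.0, 0.0, 1.0]

    def test_rows_sum_to_zero_random(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.normal(size=(30, 8)))
        out = per_gene_normalize(mat)
        assert out.sum(axis=1).abs().max() < 1e-9

    def test_zscore_unit_variance(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.normal(size=(10, 6)))
        out = per_gene_normalize(mat, method="zscore")
        assert out.std(axis=1, ddof=1).to_numpy() == pytest.approx(np.ones(10))
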