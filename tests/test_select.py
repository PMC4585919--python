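"""Cohesiveness, feature counts, subclassing, representative extraction and
the cohesive-strength sweep."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sigdistill import (
    GenePanel,
    SimulationConfig,
    cohesiveness,
    feature_count,
    nearest_to_center,
    select_signature,
    simulate_layer,
    subclass_partition,
    sweep_K,
    truth_panels,
)
from sigdistill.select import default_k_grid


def expr_of(points, columns=("s1", "s2")):
    return pd.DataFrame(
        np.array(list(points.values()), dtype=float),
        index=list(points),
        columns=list(columns),
    )


class TestCohesiveness:
    def test_identical_vectors_hit_infinity_sentinel(self):
        expr = expr_of({"g1": [1.0, 2.0], "g2": [1.0, 2.0]})
        coh = cohesiveness(GenePanel("c", ("g1", "g2")), expr)
        assert coh.mean_pairwise_distance == 0.0
        assert coh.cohesiveness == math.inf

    def test_single_pair(self):
        expr = expr_of({"g1": [0.0, 0.0], "g2": [3.0, 4.0]})
        coh = cohesiveness(GenePanel("c", ("g1", "g2")), expr)
        assert coh.mean_pairwise_distance == pytest.approx(5.0)
        assert coh.cohesiveness == pytest.approx(0.2)

    def test_three_collinear_vectors(self, tiny_expr):
        coh = cohesiveness(GenePanel("c", ("g1", "g2", "g3")), tiny_expr)
        assert coh.mean_pairwise_distance == pytest.approx(4 / 3)
        assert coh.cohesiveness == pytest.approx(0.75)

    def test_singleton_class(self, tiny_expr):
        coh = cohesiveness(GenePanel("c", ("g1",)), tiny_expr)
        assert coh.cohesiveness == math.inf

    def test_unknown_gene_listed(self, tiny_expr):
        with pytest.raises(KeyError, match="gX"):
            cohesiveness(GenePanel("c", ("g1", "gX")), tiny_expr)

    def test_tighter_class_is_more_cohesive(self):
        tight = expr_of({"g1": [0.0, 0.0], "g2": [0.1, 0.0]})
        loose = expr_of({"g1": [0.0, 0.0], "g2": [5.0, 0.0]})
        assert (
            cohesiveness(GenePanel("c", ("g1", "g2")), tight).cohesiveness
            > cohesiveness(GenePanel("c", ("g1", "g2")), loose).cohesiveness
        )


class TestFeatureCount:
    @pytest.fixture()
    def coh(self, tiny_expr):
        # mean pairwise distance 4/3
        return cohesiveness(GenePanel("c", ("g1", "g2", "g3")), tiny_expr)

    def test_formula(self):
        expr = expr_of({f"g{i}": [5.0 * i, 0.0] for i in range(6)})
        coh = cohesiveness(GenePanel("c", tuple(f"g{i}" for i in range(6))), expr)
        assert coh.cohesiveness == pytest.approx(1 / coh.mean_pairwise_distance)
        assert feature_count(coh, 1.0) == min(
            6, max(1, round(coh.mean_pairwise_distance))
        )

    def test_infinite_cohesiveness_needs_one_gene(self, tiny_expr):
        coh = cohesiveness(GenePanel("c", ("g1",)), tiny_expr)
        for K in (1e-6, 1.0, 1e6):
            assert feature_count(coh, K) == 1

    def test_clamped_to_class_size(self, coh):
        assert feature_count(coh, 1e9) == 3
        assert feature_count(coh, 1e-9) == 1

    def test_nonpositive_K_rejected(self, coh):
        with pytest.raises(ValueError, match="K"):
            feature_count(coh, 0.0)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_monotone_in_K(self, k1, k2):
        expr = expr_of({"g1": [0.0, 0.0], "g2": [0.0, 1.0], "g3": [0.0, 2.0]})
        coh = cohesiveness(GenePanel("c", ("g1", "g2", "g3")), expr)
        lo, hi = sorted((k1, k2))
        assert feature_count(coh, lo) <= feature_count(coh, hi)


class TestSubclassPartition:
    def test_extremes(self, tiny_expr):
        genes = GenePanel("c", ("g1", "g2", "g3"))
        assert subclass_partition(genes, tiny_expr, 1).n_classes == 1
        singles = subclass_partition(genes, tiny_expr, 3)
        assert all(len(m) == 1 for m in singles.classes.values())

    def test_out_of_range_rejected(self, tiny_expr):
        genes = GenePanel("c", ("g1", "g2"))
        with pytest.raises(ValueError):
            subclass_partition(genes, tiny_expr, 3)

    def test_planted_blocks_recovered(self):
        cfg = SimulationConfig(
            n_subtypes=1, samples_per_subtype=40, blocks_per_subtype=2,
            block_size=5, effect_size=0.0, within_block_correlation=0.95,
            n_noise_genes=0, seed=17, subtype_names=("only",),
        )
        expr, _, truth = simulate_layer(cfg)
        # push the two blocks apart so block identity dominates gene distances
        first_block = [g for g, (s, b) in truth.block_membership.items() if b == 0]
        expr.loc[first_block] += 10.0
        genes = GenePanel("c", tuple(truth.block_membership))
        part = subclass_partition(genes, expr, 2)
        got = set(map(frozenset, part.classes.values()))
        expected = {
            frozenset(g for g, (s, b) in truth.block_membership.items() if b == bi)
            for bi in (0, 1)
        }
        assert got == expected


class TestNearestToCenter:
    def test_singleton(self, tiny_expr):
        assert nearest_to_center(["g2"], tiny_expr) == "g2"

    def test_picks_member_nearest_the_mean(self):
        expr = expr_of({"a": [0.0, 0.0], "b": [2.0, 2.0], "c": [10.0, 10.0]})
        # center (4, 4): distances sqrt(32), sqrt(8), sqrt(72)
        assert nearest_to_center(["a", "b", "c"], expr) == "b"

    def test_tie_broken_by_gene_id(self):
        expr = expr_of({"zz": [0.0, 0.0], "aa": [2.0, 0.0]})
        assert nearest_to_center(["zz", "aa"], expr) == "aa"


@pytest.fixture(scope="module")
def selected(planted):
    _, expr, labels, truth = planted
    return truth, sweep_K(expr, labels, truth_panels(truth))


class TestSweep:
    def test_trace_covers_grid_and_best_is_reported(self, selected):
        _, res = selected
        assert len(res.sweep_trace) == 40  # default grid size
        best_f = max(p.f_value for p in res.sweep_trace)
        assert res.score.f_value == pytest.approx(best_f)
        chosen = [p for p in res.sweep_trace if p.K == res.chosen_K]
        assert chosen and chosen[0].f_value == pytest.approx(best_f)

    def test_ties_prefer_succinct_signatures(self, selected):
        _, res = selected
        best_f = max(p.f_value for p in res.sweep_trace)
        smallest = min(
            p.signature_size for p in res.sweep_trace if p.f_value == best_f
        )
        assert len(res.signature) == smallest

    def test_representatives_come_from_their_subclass(self, selected):
        _, res = selected
        for sel in res.per_class.values():
            assert len(sel.representatives) == sel.n_features
            rep_classes = {sel.subclasses.class_of[r] for r in sel.representatives}
            assert len(rep_classes) == len(sel.representatives)  # one per subclass

    def test_default_grid_reaches_both_regimes(self, planted):
        _, expr, _, truth = planted
        panels = truth_panels(truth)
        cohs = [cohesiveness(p, expr, class_label=n) for n, p in panels.items()]
        grid = default_k_grid(cohs)
        assert all(feature_count(c, grid[0]) == 1 for c in cohs)
        assert all(
            feature_count(c, grid[-1]) == len(c.member_genes) for c in cohs
        )

    def test_deterministic(self, planted):
        _, expr, labels, truth = planted
        a = sweep_K(expr, labels, truth_panels(truth))
        b = sweep_K(expr, labels, truth_panels(truth))
        assert a.signature.genes == b.signature.genes
        assert a.chosen_K == b.chosen_K
        assert a.sweep_trace == b.sweep_trace

    def test_noise_dilution_weakly_increases_feature_count(self, planted):
        _, expr, _, truth = planted
        subtype = next(iter(truth.informative_genes))
        clean = GenePanel("clean", truth.informative_genes[subtype])
        diluted = GenePanel(
            "diluted", truth.informative_genes[subtype] + truth.noise_genes[:5]
        )
        c_clean = cohesiveness(clean, expr)
        c_diluted = cohesiveness(diluted, expr)
        assert c_diluted.mean_pairwise_distance > c_clean.mean_pairwise_distance
        for K in (0.05, 0.1, 0.5):
            assert feature_count(c_diluted, K) >= feature_count(c_clean, K)


class TestSelectSignature:
    def test_per_subtype_on_disjoint_panels_sums_counts(self, planted):
        _, expr, labels, truth = planted
        res = select_signature(expr, labels, truth_panels(truth), mode="per_subtype")
        assert len(res.signature) == sum(
            sel.n_features for sel in res.per_class.values()
        )
        assert res.chosen_K is None

    def test_shared_genes_deduplicated(self, planted):
        _, expr, labels, truth = planted
        panels = truth_panels(truth)
        # force every class to carry one shared gene that each will select
        shared_gene = "AAA-shared"  # sorts first so it wins nearest-to-center ties
        expr = expr.copy()
        expr.loc[shared_gene] = 0.0
        overlapping = {
            name: GenePanel(name, (shared_gene,) + panel.genes[:1])
            for name, panel in panels.items()
        }
        res = select_signature(
            expr, labels, overlapping, mode="per_subtype", K_grid=[1e-9]
        )
        # K tiny -> every class selects exactly 1 representative; classes are
        # near-duplicates so dedup must shrink the union below the sum
        assert len(res.signature) < sum(s.n_features for s in res.per_class.values())

    def test_single_panel_pooled_mode(self, planted):
        _, expr, labels, truth = planted
        from sigdistill import pooled_panel

        res = select_signature(expr, labels, pooled_panel(truth), mode="pooled")
        assert set(res.signature) <= set(pooled_panel(truth))
        assert res.mode == "pooled"

    def test_unknown_mode_rejected(self, planted):
        _, expr, labels, truth = planted
        with pytest.raises(ValueError, match="mode"):
            select_signature(expr, labels, truth_panels(truth), mode="bogus")

    def test_per_subtype_requires_full_panel_coverage(self, planted):
        _, expr, labels, truth = planted
        panels = truth_panels(truth)
        panels.pop(next(iter(panels)))
        with pytest.raises(ValueError, match="missing"):
            select_signature(expr, labels, panels, mode="per_subtype")
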