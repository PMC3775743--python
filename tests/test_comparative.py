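import logging
import math

import numpy as np
import pytest

from mitorepeats import SpeciesRecord
from mitorepeats.comparative import (
    SpeciesPanel,
    TaxonomyTree,
    TreeNode,
    build_tree_from_lineages,
    clade_report,
    contrast_correlation,
    correlate,
    filter_clade,
    independent_contrasts,
    log_transform,
    per_length_correlation,
)


def _rec(name, mls, lineage=("Root", "CladeA"), dr=1.0, ir=1.0):
    return SpeciesRecord(species=name, mls_years=mls, lineage=tuple(lineage),
                         dr_total=dr, ir_total=ir)


def _panel(recs, **kw):
    return SpeciesPanel(records=list(recs), **kw)


class TestLogTransform:
    def test_log10_values(self):
        panel = log_transform(_panel([_rec("a", 10.0, ir=100.0, dr=1.0)]))
        assert panel.records[0].mls_years == pytest.approx(1.0)
        assert panel.records[0].ir_total == pytest.approx(2.0)
        assert panel.log10

    def test_zero_score_species_dropped_with_warning(self, caplog):
        recs = [_rec("a", 10), _rec("b", 20, ir=0.0), _rec("c", 30)]
        with caplog.at_level(logging.WARNING, logger="mitorepeats"):
            panel = log_transform(_panel(recs))
        assert panel.species() == ["a", "c"]
        assert "dropped 1" in caplog.text

    def test_round_trip(self):
        panel = log_transform(_panel([_rec("a", 37.5, ir=0.25, dr=3.0)]))
        assert 10 ** panel.records[0].mls_years == pytest.approx(37.5)
        assert 10 ** panel.records[0].ir_total == pytest.approx(0.25)


class TestCorrelate:
    def test_perfect_positive(self):
        p = _panel([_rec("a", 1, ir=2), _rec("b", 2, ir=4), _rec("c", 3, ir=6)], log10=True)
        res = correlate(p)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_perfect_negative(self):
        p = _panel([_rec("a", 1, ir=6), _rec("b", 2, ir=4), _rec("c", 3, ir=2)], log10=True)
        res = correlate(p)
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.spearman_rho == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]
        p = _panel([_rec(f"s{i}", xi, ir=yi) for i, (xi, yi) in enumerate(zip(x, y))],
                   log10=True)
        mx, my = sum(x) / 4, sum(y) / 4
        expected = sum((a - mx) * (b - my) for a, b in zip(x, y)) / math.sqrt(
            sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
        assert correlate(p).pearson_r == pytest.approx(expected, abs=1e-12)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 10, 20)
        y = rng.uniform(1, 10, 20)
        p1 = _panel([_rec(f"s{i}", xi, ir=yi) for i, (xi, yi) in enumerate(zip(x, y))], log10=True)
        p2 = _panel([_rec(f"s{i}", xi, ir=math.exp(yi)) for i, (xi, yi) in enumerate(zip(x, y))],
                    log10=True)
        assert correlate(p1).spearman_rho == pytest.approx(correlate(p2).spearman_rho)

    def test_errors(self):
        with pytest.raises(ValueError, match="3 species"):
            correlate(_panel([_rec("a", 1), _rec("b", 2)], log10=True))
        with pytest.raises(ValueError, match="zero variance"):
            correlate(_panel([_rec("a", 1, ir=3), _rec("b", 2, ir=3), _rec("c", 3, ir=3)],
                             log10=True))


class TestPerLength:
    def test_exclusion_reduces_n(self):
        full = [_rec(f"s{i}", float(i + 1), ir=float(i + 2)) for i in range(5)]
        missing = [*full[:4], _rec("s4", 5.0, ir=0.0)]
        out = per_length_correlation({2: _panel(full), 15: _panel(missing)})
        assert out[2].n == 5
        assert out[15].n == 4

    def test_small_class_flagged_not_error(self):
        recs = [_rec("a", 1, ir=0.0), _rec("b", 2, ir=0.0), _rec("c", 3, ir=1.0)]
        out = per_length_correlation({20: _panel(recs)})
        assert out[20] is None

    def test_planted_negative_relation_at_every_length(self):
        rng = np.random.default_rng(11)
        lengths = (10, 15, 20)
        panels = {}
        for li, length in enumerate(lengths):
            recs = []
            for i in range(12):
                mls = 10 ** rng.uniform(0.3, 2)
                score = 10 ** (0.3 * (li + 1) - 0.8 * math.log10(mls) + rng.normal(0, 0.1))
                recs.append(_rec(f"s{i}", math.log10(mls), ir=math.log10(score)))
            panels[length] = _panel(recs, log10=True)
        out = per_length_correlation(panels)
        assert all(res.pearson_r < 0 for res in out.values())


class TestTreeBuilding:
    def test_two_species_sharing_genus_form_cherry(self):
        recs = [_rec("Mus musculus", 4, ("Animalia", "Rodentia", "Mus")),
                _rec("Mus spretus", 3, ("Animalia", "Rodentia", "Mus"))]
        tree = build_tree_from_lineages(recs)
        assert sorted(tree.tip_names()) == ["Mus musculus", "Mus spretus"]
        assert len(tree.root.children) == 2  # unary Animalia/Rodentia/Mus chain collapsed

    def test_three_species_polytomy(self):
        recs = [_rec(f"Mus {i}", i + 1, ("Animalia", "Mus")) for i in range(3)]
        tree = build_tree_from_lineages(recs)
        assert len(tree.root.children) == 3

    def test_disjoint_roots_rejected(self):
        recs = [_rec("a", 1, ("Animalia", "X")), _rec("b", 2, ("Plantae", "Y"))]
        with pytest.raises(ValueError, match="root"):
            build_tree_from_lineages(recs)

    def test_inconsistent_parentage_rejected(self):
        recs = [_rec("a", 1, ("Root", "A", "G")), _rec("b", 2, ("Root", "B", "G"))]
        with pytest.raises(ValueError, match="appears under both"):
            build_tree_from_lineages(recs)


class TestContrasts:
    def test_two_tip_closed_form(self):
        tree = TaxonomyTree(root=TreeNode("r", [TreeNode("a"), TreeNode("b")]))
        panel = _panel([_rec("a", 3.0, ir=5.0), _rec("b", 1.0, ir=2.0)], log10=True)
        cs = independent_contrasts(tree, panel)
        assert len(cs) == 1
        assert cs.x[0] == pytest.approx((3.0 - 1.0) / math.sqrt(2))
        assert cs.y[0] == pytest.approx((5.0 - 2.0) / math.sqrt(2))

    def test_linear_relation_gives_contrast_correlation_one(self):
        rng = np.random.default_rng(2)
        recs = [_rec(f"s{i}", x, ir=2.0 * x - 1.0,
                     lineage=("Root", f"C{i % 3}")) for i, x in enumerate(rng.uniform(0, 5, 12))]
        tree = build_tree_from_lineages(recs)
        cs = independent_contrasts(tree, _panel(recs, log10=True))
        res = contrast_correlation(cs)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(3)
        recs = [_rec(f"s{i}", x, ir=y, lineage=("Root", f"C{i % 4}"))
                for i, (x, y) in enumerate(zip(rng.uniform(0, 5, 16), rng.uniform(0, 5, 16)))]
        flipped = [SpeciesRecord(species=r.species, mls_years=r.mls_years, lineage=r.lineage,
                                 dr_total=r.dr_total, ir_total=-r.ir_total) for r in recs]
        tree = build_tree_from_lineages(recs)
        a = contrast_correlation(independent_contrasts(tree, _panel(recs, log10=True)))
        b = contrast_correlation(independent_contrasts(tree, _panel(flipped, log10=True)))
        assert a.spearman_rho == pytest.approx(-b.spearman_rho)

    def test_bifurcating_tree_yields_n_minus_one_contrasts(self):
        recs = [_rec(f"s{i}", float(i + 1), lineage=("Root", f"C{i // 2}", f"G{i}"))
                for i in range(8)]  # 4 cherries under the root
        tree = build_tree_from_lineages(recs)
        cs = independent_contrasts(tree, _panel(recs, log10=True))
        # 4 cherries + 1 polytomy contrast at the root under the median-split rule
        assert len(cs) == 5

    def test_star_tree_random_resolution_null(self):
        rho = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            recs = [_rec(f"s{i}", x, ir=y) for i, (x, y) in
                    enumerate(zip(rng.normal(size=20), rng.normal(size=20)))]
            tree = TaxonomyTree(root=TreeNode("r", [TreeNode(r.species) for r in recs]))
            cs = independent_contrasts(tree, _panel(recs, log10=True),
                                       polytomy="random", seed=seed)
            rho.append(contrast_correlation(cs).spearman_rho)
        assert abs(np.mean(rho)) < 0.1

    def test_clade_structure_inflates_raw_but_not_contrast(self):
        rng = np.random.default_rng(7)
        recs = []
        for c, offset in enumerate((0.0, 5.0)):
            for i in range(8):
                recs.append(_rec(f"s{c}_{i}", offset + rng.normal(0, 0.3),
                                 ir=offset + rng.normal(0, 0.3),
                                 lineage=("Root", f"Clade{c}")))
        panel = _panel(recs, log10=True)
        raw = correlate(panel).pearson_r
        tree = build_tree_from_lineages(recs)
        crho = contrast_correlation(independent_contrasts(tree, panel)).spearman_rho
        assert abs(raw) > 0.9
        assert abs(crho) < abs(raw)

    def test_x_contrasts_polarized_nonnegative(self):
        rng = np.random.default_rng(8)
        recs = [_rec(f"s{i}", x, ir=y, lineage=("Root", f"C{i % 3}"))
                for i, (x, y) in enumerate(zip(rng.uniform(0, 5, 12), rng.uniform(0, 5, 12)))]
        cs = independent_contrasts(build_tree_from_lineages(recs), _panel(recs, log10=True))
        assert (cs.x >= 0).all()


class TestCladeReport:
    def _three_clade_panel(self):
        rng = np.random.default_rng(9)
        recs = []
        for c in range(3):
            for i in range(5 + c):
                mls = rng.uniform(0.5, 2.0)
                recs.append(_rec(f"s{c}_{i}", mls, ir=1.0 - mls + rng.normal(0, 0.1),
                                 dr=rng.uniform(0.5, 1.5),
                                 lineage=("Root", f"Clade{c}", f"Genus{c}{i % 2}")))
        return _panel(recs, log10=True)

    def test_per_clade_sample_sizes(self):
        panel = self._three_clade_panel()
        table = clade_report(panel, ["Clade0", "Clade1", "Clade2"], kinds=("ir",))
        assert table["n"].tolist() == [5, 6, 7]

    def test_root_clade_equals_whole_panel(self):
        panel = self._three_clade_panel()
        table = clade_report(panel, ["Root"], kinds=("ir",))
        assert table.loc[0, "n"] == len(panel)
        assert table.loc[0, "pearson_r"] == pytest.approx(correlate(panel).pearson_r)

    def test_exclusion_removes_exactly_members(self):
        panel = self._three_clade_panel()
        sub = filter_clade(panel, "Root", exclude="Clade1")
        assert len(sub) == len(panel) - 6
        assert all("Clade1" not in r.lineage for r in sub.records)

    def test_unknown_clade_is_error(self):
        panel = self._three_clade_panel()
        with pytest.raises(ValueError, match="Cladezz"):
            clade_report(panel, ["Cladezz"])
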