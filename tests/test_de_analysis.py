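import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from triadbias import (
    DEGFilter,
    DERecordSet,
    SimulationConfig,
    Triad,
    TriadSet,
    benjamini_hochberg,
    deg_table,
    filter_degs,
    homeolog_fold_changes,
    hypergeometric_enrichment,
    naive_de,
    simulate_dataset,
)


def de_from(records):
    """[(gene, log2fc, padj)] -> DERecordSet."""
    df = pd.DataFrame(records, columns=["gene_id", "log2fc", "padj"])
    return DERecordSet(df)


class TestFilterDegs:
    def test_boundary_values_are_inclusive(self):
        degs, up, down = filter_degs(de_from([("g", 1.0, 0.05)]))
        assert degs == up == {"g"} and not down

    def test_just_above_alpha_not_a_deg(self):
        degs, _, _ = filter_degs(de_from([("g", 3.0, 0.051)]))
        assert not degs

    def test_negative_log2fc_at_boundary_is_down(self):
        degs, up, down = filter_degs(de_from([("g", -1.0, 0.01)]))
        assert degs == down == {"g"} and not up

    def test_missing_padj_is_hard_error(self):
        de = DERecordSet(pd.DataFrame({"gene_id": ["g"], "log2fc": [2.0],
                                       "pvalue": [0.001]}))
        with pytest.raises(ValueError, match="adjusted p"):
            filter_degs(de)

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(8)
        de = de_from([
            (f"g{i}", lfc, p) for i, (lfc, p) in
            enumerate(zip(rng.normal(0, 2, 200), rng.uniform(0, 1, 200)))
        ])
        strict, _, _ = filter_degs(de, DEGFilter(alpha=0.01, min_abs_log2fc=2.0))
        for alpha, mfc in [(0.01, 1.0), (0.05, 2.0), (0.05, 1.0), (0.2, 0.5)]:
            relaxed, _, _ = filter_degs(de, DEGFilter(alpha=alpha, min_abs_log2fc=mfc))
            assert strict <= relaxed

    def test_deg_table_directions(self):
        t = deg_table(de_from([("u", 2.0, 0.01), ("d", -2.0, 0.01), ("n", 0.5, 0.01)]))
        assert set(t["gene_id"]) == {"u", "d"}
        assert dict(zip(t["gene_id"], t["direction"])) == {"u": "up", "d": "down"}


class TestHomeologFoldChanges:
    TRIADS = TriadSet([Triad("t1", "a1", "b1", "d1"), Triad("t2", "a2", "b2", "d2")])

    def _de(self, fcs):
        rows = [{"gene_id": g, "fold_change": fc, "padj": 0.01} for g, fc in fcs.items()]
        return DERecordSet(pd.DataFrame(rows))

    def test_d_homeolog_with_largest_fold_change_flagged(self):
        de = self._de({"a1": 2.0, "b1": 2.0, "d1": 300.0,
                       "a2": 1.0, "b2": 1.0, "d2": 1.0})
        out = homeolog_fold_changes(de, self.TRIADS).set_index("triad_id")
        assert out.at["t1", "max_homeolog"] == "D"

    def test_equal_fold_changes_flag_no_dominant_homeolog(self):
        de = self._de({"a1": 2.0, "b1": 2.0, "d1": 2.0,
                       "a2": 1.0, "b2": 1.0, "d2": 1.0})
        out = homeolog_fold_changes(de, self.TRIADS).set_index("triad_id")
        assert out.at["t1", "max_homeolog"] == ""

    def test_missing_homeolog_marks_triad_incomplete(self):
        de = self._de({"a1": 2.0, "b1": 2.0,
                       "a2": 1.0, "b2": 1.0, "d2": 1.0})  # d1 absent
        out = homeolog_fold_changes(de, self.TRIADS).set_index("triad_id")
        assert not out.at["t1", "complete"]
        assert out.at["t2", "complete"]

    def test_gene_set_restriction(self):
        de = self._de({"a1": 2.0, "b1": 2.0, "d1": 2.0,
                       "a2": 1.0, "b2": 1.0, "d2": 1.0})
        out = homeolog_fold_changes(de, self.TRIADS, gene_set={"d2"})
        assert list(out["triad_id"]) == ["t2"]


def exact_upper_tail(n_universe, n_set, n_degs, overlap):
    """Brute-force oracle: exact hypergeometric tail by combinatorial sum."""
    total = comb(n_universe, n_degs)
    return sum(
        comb(n_set, k) * comb(n_universe - n_set, n_degs - k)
        for k in range(overlap, min(n_set, n_degs) + 1)
    ) / total


class TestEnrichment:
    def test_matches_exact_enumeration_on_fixture_grid(self):
        for n_universe, n_set, n_degs in itertools.product(
            [8, 15, 20, 30], [1, 3, 5, 8], [2, 5, 10]
        ):
            if n_set > n_universe or n_degs > n_universe:
                continue
            universe = {f"g{i}" for i in range(n_universe)}
            gene_set = {f"g{i}" for i in range(n_set)}
            # DEGs overlap the set as much as possible, then fill from outside
            for overlap in range(0, min(n_set, n_degs) + 1):
                degs = {f"g{i}" for i in range(overlap)} | {
                    f"g{i}" for i in range(n_set, n_set + n_degs - overlap)
                }
                if len(degs) != n_degs or not degs <= universe:
                    continue
                out = hypergeometric_enrichment(degs, universe, {"s": gene_set})
                expected = exact_upper_tail(n_universe, n_set, n_degs,
                                            len(degs & gene_set))
                assert out.iloc[0]["p"] == pytest.approx(expected, rel=1e-12)

    def test_worked_example_universe_20(self):
        universe = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(5)}
        degs = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(5, 10)}
        out = hypergeometric_enrichment(degs, universe, {"s": gene_set})
        # full overlap of 5: p = C(5,5) C(15,5) / C(20,10)
        assert out.iloc[0]["p"] == pytest.approx(
            comb(15, 5) / comb(20, 10), rel=1e-12
        )

    def test_degs_equal_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        out = hypergeometric_enrichment(universe, universe,
                                        {"s": {f"g{i}" for i in range(4)}})
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one_when_tail_is_everything(self):
        universe = {f"g{i}" for i in range(12)}
        out = hypergeometric_enrichment({"g10", "g11"}, universe,
                                        {"s": {f"g{i}" for i in range(3)}})
        assert out.iloc[0]["p"] == pytest.approx(
            exact_upper_tail(12, 3, 2, 0), rel=1e-12
        )

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_enrichment(set(), set(), {"s": {"g"}})

    def test_degs_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment({"x"}, {"g"}, {"s": {"g"}})


class TestBenjaminiHochberg:
    def test_reproduces_textbook_step_up_on_ten_values(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042,
                      0.06, 0.074, 0.205, 0.212, 0.216])
        # independent oracle: textbook step-up, computed here from scratch
        m = len(p)
        order = np.argsort(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()


class TestNaiveDE:
    def test_identical_conditions_yield_no_degs(self, clean_dataset):
        ds = clean_dataset
        # duplicate the control replicates as fake "stress" -> exact null
        counts = ds.counts.values.copy()
        ctrl = ds.samples.samples_for("leaf", "control")
        for i, s in enumerate(ctrl):
            counts[f"fake_stress_{i}"] = counts[s]
        from triadbias import ExpressionMatrix, SampleSheet

        sheet = SampleSheet(pd.DataFrame(
            [{"sample_id": s, "tissue": "leaf", "condition": "control",
              "replicate": i + 1} for i, s in enumerate(ctrl)]
            + [{"sample_id": f"fake_stress_{i}", "tissue": "leaf",
                "condition": "stress", "replicate": i + 1}
               for i in range(len(ctrl))]
        ))
        m = ExpressionMatrix(counts[[*ctrl, *(f"fake_stress_{i}" for i in range(3))]],
                             unit="counts")
        de = naive_de(m, sheet)
        assert np.allclose(de.data["fold_change"], 1.0)
        degs, _, _ = filter_degs(de)
        assert not degs

    def test_strong_signal_gene_detected(self):
        genes = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(10)
        base = rng.poisson(50, size=(40, 6)).astype(float)
        base[0, :3] = [0, 0, 0]
        base[0, 3:] = [100, 110, 90]
        from triadbias import ExpressionMatrix, SampleSheet

        cols = [f"leaf_control_rep{i}" for i in (1, 2, 3)] + \
               [f"leaf_stress_rep{i}" for i in (1, 2, 3)]
        m = ExpressionMatrix(pd.DataFrame(base, index=genes, columns=cols),
                             unit="counts")
        sheet = SampleSheet(pd.DataFrame(
            [{"sample_id": c, "tissue": "leaf",
              "condition": c.split("_")[1], "replicate": int(c[-1])} for c in cols]
        ))
        de = naive_de(m, sheet).data.set_index("gene_id")
        assert de.at["g0", "fold_change"] > 100
        assert de.at["g0", "pvalue"] < 0.01

    def test_single_replicate_instructs_external_table(self):
        from triadbias import ExpressionMatrix, SampleSheet

        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"]),
            unit="counts",
        )
        sheet = SampleSheet(pd.DataFrame(
            [{"sample_id": "s1", "tissue": "leaf", "condition": "control",
              "replicate": 1},
             {"sample_id": "s2", "tissue": "leaf", "condition": "stress",
              "replicate": 1}]
        ))
        with pytest.raises(ValueError, match="external DE table"):
            naive_de(m, sheet)

    def test_type_one_error_near_nominal_under_null_simulation(self):
        # null negative-binomial simulation: no condition effects at all
        ds = simulate_dataset(SimulationConfig(
            seed=123, n_triads=1000, shared_effect_sd=0.0, homeolog_effect_prob=0.0
        ))
        de = naive_de(ds.counts, ds.samples)
        frac = float((de.data["pvalue"] < 0.05).mean())
        n = len(de.data)
        mc_se = np.sqrt(0.05 * 0.95 / n)
        assert frac <= 0.05 + 2 * mc_se

    def test_tpm_matrix_rejected(self, clean_dataset):
        with pytest.raises(ValueError, match="counts"):
            naive_de(clean_dataset.tpm, clean_dataset.samples)
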