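"""Association scans, signal selection, conditional analysis, burden tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from protclock.assoc import (
    burden_test,
    conditional_refine,
    pqtl_scan,
    scan_variants,
    select_signals,
)
from protclock.synthgen import GenotypeMatrix


def _geno(dosage: np.ndarray, pos=None, chrom=None) -> GenotypeMatrix:
    n, m = dosage.shape
    meta = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom or ["1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 10_000,
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
        }
    )
    ids = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    return GenotypeMatrix(meta, dosage.astype(float), ids)


@pytest.fixture(scope="module")
def random_scan_data():
    rng = np.random.default_rng(8)
    n, m = 500, 6
    g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    y = 0.4 * g[:, 2] + rng.normal(size=n)
    cov = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.integers(0, 2, n)})
    return _geno(g), y, cov


def test_scan_matches_statsmodels_per_variant(random_scan_data):
    """The vectorised FWL scan equals per-variant full OLS fits."""
    geno, y, cov = random_scan_data
    table = scan_variants(geno, y, cov)
    for j in range(geno.dosage.shape[1]):
        X = sm.add_constant(
            pd.DataFrame({"g": geno.dosage[:, j], "c1": cov["c1"], "c2": cov["c2"]})
        )
        fit = sm.OLS(y, X).fit()
        row = table.iloc[j]
        assert row["beta"] == pytest.approx(fit.params["g"], rel=1e-10)
        assert row["se"] == pytest.approx(fit.bse["g"], rel=1e-10)
        assert row["p"] == pytest.approx(fit.pvalues["g"], rel=1e-8)


def test_scan_no_covariates_equals_simple_regression_formula():
    rng = np.random.default_rng(1)
    g = rng.binomial(2, 0.4, size=(300, 1)).astype(float)
    y = 0.3 * g[:, 0] + rng.normal(size=300)
    row = scan_variants(_geno(g), y).iloc[0]
    gc = g[:, 0] - g[:, 0].mean()
    yc = y - y.mean()
    assert row["beta"] == pytest.approx(float(gc @ yc / (gc @ gc)), rel=1e-12)


def test_maf_filter_strictly_greater():
    n = 1000
    g = np.zeros((n, 2))
    g[:2, 0] = 1.0  # eaf exactly 0.001 -> excluded under strict >
    g[:3, 1] = 1.0  # eaf 0.0015 -> retained
    y = np.random.default_rng(0).normal(size=n)
    table = scan_variants(_geno(g), y, min_maf=0.001)
    assert list(table["id"]) == ["v1"]


def test_monomorphic_variant_excluded():
    g = np.zeros((100, 1))
    y = np.random.default_rng(0).normal(size=100)
    assert len(scan_variants(_geno(g), y)) == 0


def test_rank_deficient_covariates_rejected():
    rng = np.random.default_rng(0)
    g = rng.binomial(2, 0.3, (50, 1)).astype(float)
    cov = pd.DataFrame({"a": np.ones(50), "b": 2 * np.ones(50)})
    with pytest.raises(ValueError, match="rank"):
        scan_variants(_geno(g), rng.normal(size=50), cov)


def test_perfect_association_hits_p_floor():
    rng = np.random.default_rng(2)
    g = rng.binomial(2, 0.5, size=(200, 1)).astype(float)
    row = scan_variants(_geno(g), g[:, 0].copy()).iloc[0]
    assert row["beta"] == pytest.approx(1.0)
    assert row["p"] >= 1e-300


def _assoc_frame(ps, positions, chrom="1"):
    m = len(ps)
    return pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": [chrom] * m,
            "pos": positions,
            "ea": ["A"] * m, "oa": ["G"] * m,
            "eaf": [0.3] * m,
            "beta": [0.1] * m, "se": [0.01] * m,
            "p": ps, "n": [1000] * m,
        }
    )


def test_signal_windows_merge_within_one_megabase():
    close = _assoc_frame([1e-9, 1e-10], [1_000_000, 1_100_000])
    sigs = select_signals(close)
    assert len(sigs) == 1 and sigs[0].variant_id == "v1"

    far = _assoc_frame([1e-9, 1e-10], [1_000_000, 1_600_000])
    sigs = select_signals(far)
    assert {s.variant_id for s in sigs} == {"v0", "v1"}
    assert sigs[0].window == (1_600_000 - 500_000, 1_600_000 + 500_000)


def test_signal_selection_tiebreak_and_row_order_invariance():
    frame = _assoc_frame([1e-9, 1e-9, 0.5], [2_000_000, 1_200_000, 3_500_000])
    sigs = select_signals(frame)
    assert sigs[0].variant_id == "v1"  # equal p: smaller position wins
    shuffled = frame.iloc[[2, 0, 1]].reset_index(drop=True)
    sigs2 = select_signals(shuffled)
    assert [s.variant_id for s in sigs] == [s.variant_id for s in sigs2]


def test_signals_on_different_chromosomes_do_not_collide():
    frame = pd.concat(
        [_assoc_frame([1e-9], [1_000_000], "1"), _assoc_frame([1e-10], [1_000_000], "2")],
        ignore_index=True,
    )
    assert len(select_signals(frame)) == 2


def test_conditional_rejects_exact_copy_of_lead():
    rng = np.random.default_rng(5)
    g0 = rng.binomial(2, 0.3, size=2000).astype(float)
    y = 0.5 * g0 + rng.normal(size=2000)
    geno = _geno(np.column_stack([g0, g0]), pos=[1_000_000, 1_050_000])
    table = scan_variants(geno, y)
    sigs = select_signals(table)
    refined = conditional_refine(geno, y, None, sigs, assoc=table)
    assert refined[0].secondaries == []


def test_conditional_keeps_independent_secondary():
    rng = np.random.default_rng(6)
    n = 4000
    g0 = rng.binomial(2, 0.3, size=n).astype(float)
    g1 = rng.binomial(2, 0.3, size=n).astype(float)  # unlinked
    y = 0.5 * g0 + 0.4 * g1 + rng.normal(size=n)
    geno = _geno(np.column_stack([g0, g1]), pos=[1_000_000, 1_200_000])
    table = scan_variants(geno, y)
    refined = conditional_refine(geno, y, None, select_signals(table), assoc=table)
    sec = refined[0].secondaries
    assert len(sec) == 1
    marginal = table.set_index("id").loc[sec[0].variant_id, "beta"]
    assert sec[0].conditional_beta == pytest.approx(marginal, abs=3 * sec[0].conditional_se)


def test_conditional_rejects_linked_shadow_signal():
    """A variant in LD with the lead but with no independent effect."""
    rng = np.random.default_rng(7)
    n = 4000
    g0 = rng.binomial(2, 0.3, size=n).astype(float)
    flip = rng.random(n) < 0.55  # correlated copy, R^2 ~ 0.2-0.3
    g1 = np.where(flip, g0, rng.binomial(2, 0.3, size=n)).astype(float)
    r2 = np.corrcoef(g0, g1)[0, 1] ** 2
    assert 0.05 < r2 < 0.9
    y = 0.6 * g0 + rng.normal(size=n)
    geno = _geno(np.column_stack([g0, g1]), pos=[1_000_000, 1_200_000])
    table = scan_variants(geno, y)
    refined = conditional_refine(geno, y, None, select_signals(table), assoc=table)
    assert refined[0].secondaries == []


def test_pqtl_threshold_computed_from_test_count():
    rng = np.random.default_rng(3)
    g = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
    prots = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("ABCD"))
    out = pqtl_scan(_geno(g), ["v0"], prots, n_protein_tests=1463)
    assert out["v0"].threshold == pytest.approx(0.05 / 1463)
    out2 = pqtl_scan(_geno(g), ["v0"], prots)
    assert out2["v0"].threshold == pytest.approx(0.05 / 4)


def test_pqtl_scan_finds_planted_target_only():
    rng = np.random.default_rng(4)
    n = 1500
    g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
    prots = pd.DataFrame(rng.normal(size=(n, 30)),
                         columns=[f"P{j}" for j in range(30)])
    prots["P7"] = prots["P7"] + 0.5 * g[:, 0]
    out = pqtl_scan(_geno(g), ["v0"], prots)
    assert out["v0"].proteins == ["P7"]
    assert (out["v0"].table["p"] < out["v0"].threshold).all()


def test_pqtl_scan_requires_complete_matrix():
    g = np.ones((10, 1))
    prots = pd.DataFrame(np.ones((10, 2)))
    prots.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="complete"):
        pqtl_scan(_geno(g), ["v0"], prots)


class TestBurden:
    def _accel(self, n=800, seed=0):
        rng = np.random.default_rng(seed)
        ids = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
        return pd.Series(rng.normal(scale=2.0, size=n), index=ids), rng

    def test_recovers_planted_carrier_shift(self):
        accel, rng = self._accel()
        carriers = set(accel.index[rng.random(len(accel)) < 0.05])
        accel.loc[list(carriers)] -= 1.6
        out = burden_test({"GENE1": carriers}, accel)
        row = out.set_index("gene").loc["GENE1"]
        assert row["n_carriers"] == len(carriers)
        assert abs(row["beta"] - (-1.6)) <= 2 * row["se"]

    def test_multi_variant_carrier_still_counts_once(self):
        accel, rng = self._accel(n=100)
        carriers = {"S1", "S2"}
        once = burden_test({"G": carriers}, accel)
        # a carrier set is a set of people; listing a person for several
        # qualifying variants cannot change the dummy dosage
        again = burden_test({"G": set(list(carriers) + ["S1", "S2"])}, accel)
        pd.testing.assert_frame_equal(once, again)

    def test_zero_carriers_skipped_all_carriers_error(self):
        accel, _ = self._accel(n=50)
        out = burden_test({"EMPTY": set()}, accel)
        assert len(out) == 0
        with pytest.raises(ValueError, match="no contrast"):
            burden_test({"ALL": set(accel.index)}, accel)

    def test_unknown_carrier_rejected(self):
        accel, _ = self._accel(n=20)
        with pytest.raises(KeyError):
            burden_test({"G": {"NOT_A_SAMPLE"}}, accel)
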