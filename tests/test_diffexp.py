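"""Moderated paired t-test: limits, hyperparameter recovery, FDR, gating."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from exacmark import (
    ModerationHyperparams,
    PairedDifferentialExpression,
    ValidationError,
    bh_fdr,
    estimate_moderation,
    moderated_paired_test,
    paired_differences,
    select_candidates,
    trigamma_inverse,
)
from conftest import make_samples


def _diffs(arr, n_prot=None):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return pd.DataFrame(
        arr, index=[f"G{i}" for i in range(arr.shape[0])]
    )


# ---------------------------------------------------------------------------
# paired differences


def test_paired_differences_basic(matrix16):
    matrix, _, _ = matrix16
    d = paired_differences(matrix)
    assert d.shape == (matrix.values.shape[0], 16)
    g = matrix.values.index[0]
    p = d.columns[0]
    expect = (
        matrix.values.loc[g, f"{p}_E"] - matrix.values.loc[g, f"{p}_C"]
    )
    assert d.loc[g, p] == pytest.approx(expect)


def test_paired_differences_identical_states_zero(matrix16):
    matrix, _, _ = matrix16
    m = matrix.copy()
    exac_cols = [c for c in m.values.columns if c.endswith("_E")]
    conv_cols = [c.replace("_E", "_C") for c in exac_cols]
    m.values[exac_cols] = m.values[conv_cols].to_numpy()
    assert (paired_differences(m).to_numpy() == 0).all()


def test_unpaired_patient_errors(matrix16):
    matrix, _, _ = matrix16
    m = matrix.copy()
    drop = m.values.columns[-1]  # a convalescent sample
    m = type(m)(
        values=m.values.drop(columns=[drop]),
        samples=m.samples,
        provenance=m.provenance,
    )
    with pytest.raises(ValidationError, match="unpaired"):
        paired_differences(m)


def test_multiple_convalescent_uses_earliest():
    samples = make_samples(3)
    extra = pd.DataFrame(
        {
            "patient_id": ["P001"],
            "state": ["convalescent"],
            "cohort": ["test"],
            "timepoint_days": [90],
        },
        index=pd.Index(["P001_C90"], name="sample_id"),
    )
    samples = pd.concat([samples, extra])
    from exacmark import ProteinMatrix

    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(0, 1, (2, len(samples))),
        index=pd.Index(["A", "B"], name="protein_id"),
        columns=samples.index,
    )
    m = ProteinMatrix(values=values, samples=samples)
    d = paired_differences(m, convalescent_pick="earliest")
    assert d.loc["A", "P001"] == pytest.approx(
        values.loc["A", "P001_E"] - values.loc["A", "P001_C"]
    )
    d90 = paired_differences(m, convalescent_pick="latest")
    assert d90.loc["A", "P001"] == pytest.approx(
        values.loc["A", "P001_E"] - values.loc["A", "P001_C90"]
    )


# ---------------------------------------------------------------------------
# moderation hyperparameters


def test_trigamma_inverse_against_bracketing_oracle():
    from scipy.optimize import brentq

    for y in [1e-4, 0.01, 0.1, 0.5, 1.0, 5.0, 50.0, 1e3]:
        oracle = brentq(lambda x: special.polygamma(1, x) - y, 1e-8, 1e9, xtol=1e-12)
        assert trigamma_inverse(y) == pytest.approx(oracle, rel=1e-6)


def test_identical_variances_give_infinite_d0():
    hp = estimate_moderation([2.0, 2.0, 2.0, 2.0], df=5)
    assert math.isinf(hp.d0)
    assert hp.s0_sq == pytest.approx(2.0, rel=0.3)  # geometric-mean based limit


def test_hyperparameter_recovery_from_scaled_inv_chisq():
    # variances simulated with known d0=4, s0^2=1; estimates within 10%
    rng = np.random.default_rng(2024)
    d0, s0_sq, df, n = 4.0, 1.0, 10, 5000
    true_var = d0 * s0_sq / rng.chisquare(d0, n)  # scaled inverse chi-square
    s2 = true_var * rng.chisquare(df, n) / df
    hp = estimate_moderation(s2, df)
    assert hp.d0 == pytest.approx(d0, rel=0.10)
    assert hp.s0_sq == pytest.approx(s0_sq, rel=0.10)


def test_too_few_proteins_error():
    with pytest.raises(ValidationError):
        estimate_moderation([1.0], df=3)


# ---------------------------------------------------------------------------
# moderated test


def test_d0_zero_limit_equals_ordinary_paired_t():
    rng = np.random.default_rng(1)
    diffs = _diffs(rng.normal(0.3, 1.0, (20, 8)))
    res = moderated_paired_test(diffs, ModerationHyperparams(d0=0.0, s0_sq=1.0))
    t_ref, p_ref = stats.ttest_1samp(diffs.to_numpy(), 0.0, axis=1).statistic, None
    t_ref = np.asarray(t_ref)
    assert np.max(np.abs(res["moderated_t"].to_numpy() - t_ref)) < 1e-10
    p_ref = 2 * stats.t.sf(np.abs(t_ref), 7)
    assert np.max(np.abs(res["p_value"].to_numpy() - p_ref)) < 1e-12


def test_d0_infinite_limit_standardizes_by_s0():
    diffs = _diffs([[1.0, 2.0, 3.0], [0.5, 0.5, 0.5]])
    s0_sq = 0.25
    res = moderated_paired_test(diffs, ModerationHyperparams(d0=np.inf, s0_sq=s0_sq))
    m = diffs.mean(axis=1).to_numpy()
    expect_t = m / np.sqrt(s0_sq / 3)
    assert res["moderated_t"].to_numpy() == pytest.approx(expect_t)
    assert res["p_value"].to_numpy() == pytest.approx(2 * stats.norm.sf(np.abs(expect_t)))


def test_all_zero_differences():
    diffs = _diffs([[0.0] * 5, [0.1, 0.2, -0.1, 0.0, 0.3]])
    res = moderated_paired_test(diffs)
    assert res.loc["G0", "moderated_t"] == 0.0
    assert res.loc["G0", "p_value"] == 1.0
    assert res.loc["G0", "fold_change"] == 1.0


def test_sign_symmetry():
    rng = np.random.default_rng(3)
    diffs = _diffs(rng.normal(0.2, 1.0, (30, 10)))
    a = moderated_paired_test(diffs)
    b = moderated_paired_test(-diffs)
    assert np.allclose(np.abs(a["moderated_t"]), np.abs(b["moderated_t"]))
    assert np.allclose(a["p_value"], b["p_value"])
    assert np.allclose(a["fdr"], b["fdr"])
    assert np.allclose(a["fold_change"], b["fold_change"])
    flip = {"Up": "Down", "Down": "Up"}
    nonzero = a["mean_log2_diff"] != 0
    assert (
        a.loc[nonzero, "direction"].map(flip) == b.loc[nonzero, "direction"]
    ).all()


def test_fold_change_direction_invariants(matrix16):
    matrix, _, _ = matrix16
    res = PairedDifferentialExpression(matrix).fit().frame
    assert (res["fold_change"] >= 1.0).all()
    up = res["direction"] == "Up"
    assert (res.loc[up, "mean_log2_diff"] > 0).all()
    assert (res.loc[~up, "mean_log2_diff"] <= 0).all()
    assert np.allclose(res["fold_change"], 2.0 ** res["mean_log2_diff"].abs())
    assert res["p_value"].between(0, 1).all()
    assert res["fdr"].between(0, 1).all()


def test_single_patient_errors():
    with pytest.raises(ValidationError):
        moderated_paired_test(_diffs([[1.0], [2.0]]))


# ---------------------------------------------------------------------------
# BH-FDR


def test_bh_hand_computed_step_up():
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_fdr([0.05]) == pytest.approx([0.05])
    assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])
    # hand computation with distinct adjusted values
    # p=(0.01,0.04,0.9): adj = (0.03, 0.06, 0.9)
    assert bh_fdr([0.9, 0.01, 0.04]) == pytest.approx([0.9, 0.03, 0.06])


def test_bh_permutation_invariance_and_monotonicity():
    rng = np.random.default_rng(8)
    p = rng.uniform(0, 1, 50)
    adj = bh_fdr(p)
    perm = rng.permutation(50)
    assert np.allclose(bh_fdr(p[perm]), adj[perm])
    # raising one p never decreases any adjusted value
    p2 = p.copy()
    p2[10] = min(1.0, p2[10] + 0.3)
    assert (bh_fdr(p2) >= adj - 1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_fdr([-0.1])


# ---------------------------------------------------------------------------
# candidate gating


def test_candidate_gate_strict_inequalities():
    frame = pd.DataFrame(
        {
            "p_value": [1e-5, 1e-4, 1e-3, 0.5],
            "fdr": [0.005, 0.005, 0.01, 0.5],
            "fold_change": [1.23, 1.20, 1.5, 2.0],
            "direction": ["Up", "Down", "Up", "Up"],
        },
        index=["C9", "TTR_exact", "FDR_exact", "null"],
    )
    # FC exactly 1.20 fails '>1.2'; FDR exactly 0.01 fails '<0.01'
    assert select_candidates(frame) == ["C9"]
    # ordering is by ascending p-value
    frame.loc["TTR_exact", "fold_change"] = 1.2000001
    assert select_candidates(frame) == ["C9", "TTR_exact"]


def test_null_calibration_no_fdr_hits():
    """Under no state effect, FDR<0.01 discoveries are (almost) never made."""
    rng = np.random.default_rng(99)
    hits = 0
    for _ in range(200):
        diffs = _diffs(rng.normal(0.0, 0.42, (60, 16)))
        res = moderated_paired_test(diffs)
        hits += int((res["fdr"] < 0.01).sum() > 0)
    assert hits <= 6  # ~0 of 200 null cohorts produce discoveries


# ---------------------------------------------------------------------------
# independent cross-check against the reference Bioconductor implementation


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_matches_reference_empirical_bayes_implementation(tmp_path):
    """Dual-route check of t, p and the (d0, s0^2) estimates on one fixture."""
    rng = np.random.default_rng(7)
    diffs = _diffs(rng.normal(0.2, 0.8, (40, 12)) * rng.uniform(0.5, 2, (40, 1)))
    csv = tmp_path / "diffs.csv"
    diffs.to_csv(csv)
    script = tmp_path / "ref.R"
    script.write_text(
        """
        suppressMessages(library(limma))
        d <- as.matrix(read.csv(commandArgs(TRUE)[1], row.names = 1))
        fit <- eBayes(lmFit(d))
        out <- data.frame(t = fit$t[, 1], p = fit$p.value[, 1])
        cat(fit$df.prior, fit$s2.prior, "\n")
        write.csv(out, commandArgs(TRUE)[2])
        """
    )
    out_csv = tmp_path / "ref.csv"
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script), str(csv), str(out_csv)],
        capture_output=True,
        text=True,
        timeout=300,
    )
    assert proc.returncode == 0, proc.stderr
    d0_ref, s0_ref = map(float, proc.stdout.split()[:2])
    ref = pd.read_csv(out_csv, index_col=0)
    res = moderated_paired_test(diffs)
    assert res.attrs["d0"] == pytest.approx(d0_ref, rel=1e-4)
    assert res.attrs["s0_sq"] == pytest.approx(s0_ref, rel=1e-4)
    assert res["moderated_t"].to_numpy() == pytest.approx(
        ref["t"].to_numpy(), rel=1e-6
    )
    assert res["p_value"].to_numpy() == pytest.approx(ref["p"].to_numpy(), rel=1e-6)
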