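import numpy as np
import pandas as pd
import pytest

from ocrstats import (
    EstimationError,
    SimConfig,
    compute_deviations,
    fit_log_linear,
    simulate_plates,
)

from conftest import make_plate_df


def reference_coded_lstsq(df: pd.DataFrame):
    """Independent oracle: explicit design matrix with reference-well coding.

    Uses one reference well per biosample (its well effect pinned to 0), the
    textbook alternative parameterization; returns fitted values and the
    theta/beta estimates converted to the mean-zero-per-biosample convention.
    """
    df = df[~df["is_blank"]] if "is_blank" in df.columns else df
    y = np.log(df["ocr"].to_numpy(float))
    cells = sorted(set(zip(df["biosample"], df["interval"].astype(int))))
    cell_ix = {c: j for j, c in enumerate(cells)}
    cols = []
    for bios, sub in df.groupby("biosample"):
        wells = sorted(sub["well"].unique())
        cols.extend((bios, w) for w in wells[1:])  # first well = reference
    col_ix = {c: j + len(cells) for j, c in enumerate(cols)}
    X = np.zeros((len(df), len(cells) + len(cols)))
    for r, (b, i, w) in enumerate(zip(df["biosample"], df["interval"], df["well"])):
        X[r, cell_ix[(b, int(i))]] = 1.0
        if (b, w) in col_ix:
            X[r, col_ix[(b, w)]] = 1.0
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    # convert to mean-zero-per-biosample parameterization
    theta = {}
    beta = {}
    for bios, sub in df.groupby("biosample"):
        wells = sorted(sub["well"].unique())
        b_raw = np.array(
            [0.0] + [coef[col_ix[(bios, w)]] for w in wells[1:]]
        )
        shift = b_raw.mean()
        for w, v in zip(wells, b_raw):
            beta[w] = v - shift
        for i in (1, 2, 3, 4):
            theta[(bios, i)] = coef[cell_ix[(bios, i)]] + shift
    keyed = pd.Series(fitted, index=pd.MultiIndex.from_arrays(
        [df["well"], df["time_point"].astype(int)]))
    return theta, beta, keyed


def test_noise_free_fit_recovers_truth_exactly(noise_free):
    plates, truth = noise_free
    fit = fit_log_linear(plates.plate("P01"))
    for (bios, interv), th in fit.theta.items():
        assert th == pytest.approx(truth.theta[bios][interv - 1], abs=1e-10)
    assert np.allclose(fit.beta, 0.0, atol=1e-10)
    assert np.allclose(fit.obs["deviation"], 0.0, atol=1e-10)


@pytest.mark.parametrize("seed", range(10))
def test_fit_matches_design_matrix_oracle(seed):
    rng = np.random.default_rng(seed)
    theta_a = (np.log(100), np.log(40), np.log(150), np.log(20))
    theta_b = (np.log(80), np.log(35), np.log(120), np.log(15))
    df = make_plate_df({"A": theta_a, "B": theta_b}, wells_per_biosample=2, rng=rng)
    fit = fit_log_linear(df)
    theta_o, beta_o, fitted_o = reference_coded_lstsq(df)
    for key, val in theta_o.items():
        assert fit.theta[key] == pytest.approx(val, abs=1e-10)
    for w, val in beta_o.items():
        assert fit.beta[w] == pytest.approx(val, abs=1e-10)
    ours = fit.obs.set_index(["well", "time_point"])["fitted"]
    assert np.max(np.abs(ours.to_numpy() - fitted_o.reindex(ours.index).to_numpy())) < 1e-8


def test_well_effects_mean_zero_within_biosample(default_plates):
    plates, _ = default_plates
    fit = fit_log_linear(plates.plate("P01"))
    wb = fit.obs.drop_duplicates("well").set_index("well")["biosample"]
    for bios, wells in wb.groupby(wb):
        assert fit.beta[wells.index].mean() == pytest.approx(0.0, abs=1e-10)
    assert fit.beta.mean() == pytest.approx(0.0, abs=1e-10)


def test_location_equivariance(default_plates):
    plates, _ = default_plates
    df = plates.plate("P01")
    fit0 = fit_log_linear(df)
    c = 0.37
    shifted = df.assign(ocr=df["ocr"] * np.exp(c))
    fit1 = fit_log_linear(shifted)
    assert np.allclose(fit1.theta - fit0.theta, c, atol=1e-10)
    assert np.allclose(fit1.beta - fit0.beta, 0.0, atol=1e-10)


def test_residuals_sum_to_zero(default_plates):
    plates, _ = default_plates
    fit = fit_log_linear(plates.plate("P02"))
    assert fit.obs["resid"].sum() == pytest.approx(0.0, abs=1e-8)


def test_deviations_equal_y_minus_theta(default_plates):
    plates, _ = default_plates
    fit = fit_log_linear(plates.plate("P01"))
    d = compute_deviations(fit)
    theta = fit.theta
    manual = fit.obs["y"].to_numpy() - np.array(
        [theta[(b, int(i))] for b, i in zip(fit.obs["biosample"], fit.obs["interval"])]
    )
    assert np.allclose(d.to_numpy(), manual, atol=1e-12)
    # deviation = residual + well effect (beta is excluded from d on purpose)
    beta = fit.beta
    assert np.allclose(
        d.to_numpy(),
        fit.obs["resid"].to_numpy() + np.array([beta[w] for w in fit.obs["well"]]),
        atol=1e-10,
    )


def test_interval_offsets_shift_theta(default_plates):
    plates, _ = default_plates
    df = plates.plate("P01")
    fit0 = fit_log_linear(df)
    off = {1: 0.2, 2: -0.1, 3: 0.0, 4: 0.05}
    fit1 = fit_log_linear(df, interval_offsets=off)
    for (bios, interv), th in fit1.theta.items():
        assert th == pytest.approx(fit0.theta[(bios, interv)] - off[interv], abs=1e-10)


def test_cell_count_offset_equals_prenormalized_fit(default_plates):
    plates, _ = default_plates
    df = plates.plate("P01")
    fit_off = fit_log_linear(df, cell_count_offset=True)
    manual = df.assign(ocr=df["ocr"] / df["cell_count"])
    fit_man = fit_log_linear(manual)
    assert np.allclose(fit_off.theta, fit_man.theta, atol=1e-10)
    assert np.allclose(fit_off.beta, fit_man.beta, atol=1e-10)


def test_empty_interval_cell_raises_naming_the_cell(hand_plate):
    broken = hand_plate[
        ~((hand_plate["biosample"] == "B") & (hand_plate["interval"] == 3))
    ]
    with pytest.raises(EstimationError, match=r"'B'.*\[3\]"):
        fit_log_linear(broken)


def test_single_well_biosample_is_allowed_and_noted(hand_plate):
    df = hand_plate[
        (hand_plate["biosample"] == "A") | (hand_plate["well"] == "A3")
    ]
    fit = fit_log_linear(df)
    assert any("single well" in n for n in fit.notes)
    assert fit.beta["A3"] == pytest.approx(0.0, abs=1e-12)


def test_theta_rmse_decreases_with_more_wells():
    rmse = {}
    for wells in (4, 16):
        errs = []
        for seed in range(8):
            cfg = SimConfig(
                n_plates=1, biosamples_per_plate=5, wells_per_biosample=wells,
                sigma_plate_interval=0.0, seed=seed,
            )
            plates, truth = simulate_plates(cfg)
            fit = fit_log_linear(plates.plate("P01"))
            for (b, i), th in fit.theta.items():
                errs.append(th - truth.theta[b][i - 1])
        rmse[wells] = float(np.sqrt(np.mean(np.square(errs))))
    assert rmse[16] < rmse[4]
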