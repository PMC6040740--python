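import numpy as np
import pandas as pd
import pytest

from ocrstats import (
    SimConfig,
    across_plate_cv,
    ed_across_plate_test,
    ed_measures,
    ed_within_plate_test,
    metric_table,
    remove_outliers,
    simulate_plates,
)
from ocrstats.metrics import MEASURES


def _well_df(series_by_interval, plate_id="P01", well="A1", biosample="b"):
    rows = []
    t = 0
    for interv in (1, 2, 3, 4):
        for v in series_by_interval[interv]:
            t += 1
            rows.append(
                {"plate_id": plate_id, "well": well, "biosample": biosample,
                 "time_point": t, "interval": interv, "ocr": float(v),
                 "is_blank": False}
            )
    return pd.DataFrame(rows)


def test_ed_extremes_hand_values():
    df = _well_df({1: [100, 95, 90], 2: [40, 38, 42], 3: [150, 160, 155],
                   4: [22, 20, 21]})
    ed = ed_measures(df)
    row = ed.wells.iloc[0]
    assert (row["ocr1"], row["ocr2"], row["ocr3"], row["ocr4"]) == (90, 38, 160, 20)
    assert row["basal"] == 70
    assert row["maximal"] == 140
    assert row["atp_linked"] == 52
    assert row["proton_leak"] == 18
    assert row["spare"] == 70
    assert row["nonmito"] == 20


def test_ed_constant_well():
    df = _well_df({i: [50, 50, 50] for i in (1, 2, 3, 4)})
    row = ed_measures(df).wells.iloc[0]
    for m in ("basal", "atp_linked", "proton_leak", "spare", "maximal"):
        assert row[m] == 0
    assert row["nonmito"] == 50


def test_ed_skips_wells_missing_an_interval():
    df = _well_df({1: [100], 2: [40], 3: [150], 4: [20]})
    df = df[df["interval"] != 2]
    ed = ed_measures(df)
    assert ed.wells.empty
    assert ed.skipped_wells == [("P01", "A1")]


def test_ed_summary_aggregates_per_plate_and_biosample():
    plates, _ = simulate_plates(SimConfig(n_plates=2, seed=1))
    ed = ed_measures(plates.assay_data)
    assert set(ed.summary.columns) >= {f"{m}_mean" for m in MEASURES}
    assert (ed.summary["n_wells"] == 12).all()
    one = ed.wells[(ed.wells["plate_id"] == "P01") & (ed.wells["biosample"] == "S1")]
    agg = ed.summary[(ed.summary["plate_id"] == "P01")
                     & (ed.summary["biosample"] == "S1")].iloc[0]
    assert agg["basal_mean"] == pytest.approx(one["basal"].mean(), rel=1e-12)
    assert agg["basal_sem"] == pytest.approx(
        one["basal"].std(ddof=1) / np.sqrt(len(one)), rel=1e-12
    )


def test_within_plate_test_separated_groups():
    rng = np.random.default_rng(0)
    dfs = []
    for k, (bios, level) in enumerate([("b", 200.0), ("NHDF", 100.0)]):
        for w in range(12):
            dfs.append(_well_df(
                {i: level * np.exp(rng.normal(0, 0.05, 3)) for i in (1, 2, 3, 4)},
                well=f"{'AB'[k]}{w + 1}", biosample=bios,
            ))
    ed = ed_measures(pd.concat(dfs, ignore_index=True))
    p = ed_within_plate_test(ed, "P01", "b", "NHDF", "nonmito")
    assert p < 0.001


def test_within_plate_test_requires_two_wells_per_group():
    df = pd.concat(
        [
            _well_df({i: [100, 100, 100] for i in (1, 2, 3, 4)}, well="A1",
                     biosample="b"),
            _well_df({i: [100, 100, 100] for i in (1, 2, 3, 4)}, well="A2",
                     biosample="NHDF"),
            _well_df({i: [100, 100, 100] for i in (1, 2, 3, 4)}, well="A3",
                     biosample="NHDF"),
        ],
        ignore_index=True,
    )
    ed = ed_measures(df)
    assert np.isnan(ed_within_plate_test(ed, "P01", "b", "NHDF", "basal"))


def test_within_plate_test_type_one_error_is_calibrated():
    rng = np.random.default_rng(4)
    rej = 0
    n_sims = 300
    for _ in range(n_sims):
        from scipy import stats
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rej += p < 0.05
    assert 0.02 < rej / n_sims < 0.08


def _ed_from_plate_means(bios_means, ctl_means):
    rows = []
    for k, (a, c) in enumerate(zip(bios_means, ctl_means)):
        rows.append({"plate_id": f"P{k}", "biosample": "b", "basal_mean": a})
        rows.append({"plate_id": f"P{k}", "biosample": "NHDF", "basal_mean": c})
    from ocrstats.baselines import EDMeasures

    return EDMeasures(wells=pd.DataFrame(), summary=pd.DataFrame(rows),
                      skipped_wells=[])


def test_across_plate_signed_rank_floor_four_plates():
    ed = _ed_from_plate_means([10, 11, 12, 13], [20, 21, 22, 23])
    res = ed_across_plate_test(ed, "b", "NHDF", "basal")
    assert res["underpowered"]
    # the most extreme configuration of 4 paired differences
    assert res["p_value"] == pytest.approx(0.125, abs=1e-12)
    assert res["p_value"] > 0.05


def test_across_plate_signed_rank_five_plates_same_sign():
    ed = _ed_from_plate_means([10, 11, 12, 13, 14], [20, 21, 22, 23, 24])
    res = ed_across_plate_test(ed, "b", "NHDF", "basal")
    assert res["p_value"] == pytest.approx(0.0625, abs=1e-12)
    assert not res["underpowered"]


def test_across_plate_identical_data_gives_p_one():
    ed = _ed_from_plate_means([10, 11, 12, 13, 14], [10, 11, 12, 13, 14])
    res = ed_across_plate_test(ed, "b", "NHDF", "basal")
    assert res["p_value"] == 1.0
    assert res["mean_difference"] == 0.0


def test_within_plate_ed_gives_discordant_conclusions_where_pooling_does_not():
    # growth-replicate variability between plates makes a biosample genuinely
    # differ from the control within individual plates even when its average
    # effect is zero; per-plate rank tests then return significant results of
    # opposite sign across plates, while the pooled cross-plate test stays
    # calibrated
    from ocrstats.testing import compute_ddtheta, test_biosamples as cross_test

    discordant_ed = significant_pooled = 0
    for seed in range(6):
        cfg = SimConfig(n_plates=4, sigma_interaction=0.15, seed=seed)
        plates, _ = simulate_plates(cfg)
        ed = ed_measures(plates.assay_data)
        fits = {pid: remove_outliers(plates.plate(pid))[0] for pid in plates.plate_ids}
        res = cross_test(compute_ddtheta(fits, "NHDF")).table
        res = res[res["metric"] == "MEi_fold"].set_index("biosample")
        for bios in (b for b in ed.wells["biosample"].unique() if b != "NHDF"):
            signs = set()
            for pid in plates.plate_ids:
                p = ed_within_plate_test(ed, pid, bios, "NHDF", "maximal")
                sub = ed.wells[ed.wells["plate_id"] == pid]
                diff = (sub.loc[sub["biosample"] == bios, "maximal"].mean()
                        - sub.loc[sub["biosample"] == "NHDF", "maximal"].mean())
                if p < 0.05:
                    signs.add(np.sign(diff))
            discordant_ed += {1.0, -1.0} <= signs
            significant_pooled += res.loc[bios, "p_value"] < 0.05
    assert discordant_ed > 2 * significant_pooled


def test_ocr_stats_has_lower_across_plate_cv_than_ed_under_contamination():
    # contamination at the levels seen in real plate collections (about 15%
    # of wells, 6% of points); six plates keep the per-biosample CV stable
    cvs = {"ED": [], "OCR-Stats": []}
    for seed in range(6):
        cfg = SimConfig(n_plates=6, seed=seed, outlier_well_rate=0.15,
                        outlier_point_rate=0.06, outlier_well_magnitude=1.0)
        plates, _ = simulate_plates(cfg)
        fits = {pid: remove_outliers(plates.plate(pid))[0] for pid in plates.plate_ids}
        tab = metric_table(fits.values())
        ed = ed_measures(plates.assay_data)
        ed_tab = ed.summary.rename(
            columns={f"{m}_mean": m for m in MEASURES}
        )[["plate_id", "biosample"] + list(MEASURES)]
        for name, t in (("OCR-Stats", tab), ("ED", ed_tab)):
            t = t[t["biosample"] != "NHDF"]
            cvs[name].append(across_plate_cv(t))
    for measure in ("basal", "maximal"):
        med_os = pd.concat(cvs["OCR-Stats"])[measure].median()
        med_ed = pd.concat(cvs["ED"])[measure].median()
        assert med_os < med_ed, measure
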