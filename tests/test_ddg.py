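"""Parsing, distributions, and bootstrap model selection for |ddG| data."""

import math

import numpy as np
import pandas as pd
import pytest

from classdiv import (
    DdgGeneratorSpec,
    DegenerateFitError,
    FormatError,
    STANDARD_THERMO,
    SubstitutionEffectModel,
    ValidationError,
    bootstrap_model_selection,
    compare_distributions,
    cutoff_sweep,
    fit_exponential,
    load_property_table,
    make_ddg_table,
    master_distribution,
    multiplicative_check,
    parse_skempi_like,
    property_preprocessing,
    remove_extremes,
)
from classdiv.ddg import DdgRecord

RT = STANDARD_THERMO.RT


def make_record(abs_ddg, region="noncore", n_subs=1, receptor="IG"):
    subs = tuple(("A", 10 + i, "G") for i in range(n_subs))
    return DdgRecord(
        complex_id="TEST",
        region=region,
        receptor_class=receptor,
        kd_wt=1e-9,
        kd_mut=1e-9 * math.exp(abs_ddg / RT),
        abs_ddg=abs_ddg,
        n_substitutions=n_subs,
        substitutions=subs,
        mutation=",".join(f"{a}{p}{b}" for a, p, b in subs),
    )


class TestParsing:
    def _csv(self, tmp_path, rows):
        path = tmp_path / "skempi.csv"
        header = "complex_id,mutation,region_code,kd_wt,kd_mut,receptor_class\n"
        path.write_text(header + "\n".join(rows) + "\n")
        return path

    def test_equal_kds_give_zero_ddg(self, tmp_path):
        path = self._csv(tmp_path, ["1ABC,A10G,COR,1e-9,1e-9,IG"])
        parsed = parse_skempi_like(path)
        assert parsed.singles[0].abs_ddg == pytest.approx(0.0)
        assert parsed.singles[0].region == "core"

    def test_thirteen_fold_ratio(self, tmp_path):
        path = self._csv(tmp_path, ["1ABC,A10G,RIM,1e-9,1.3e-8,TR"])
        rec = parse_skempi_like(path).singles[0]
        assert rec.abs_ddg == pytest.approx(RT * math.log(13), abs=1e-9)
        assert rec.region == "noncore"

    def test_multi_substitutions_separated(self, tmp_path):
        path = self._csv(
            tmp_path,
            ["1ABC,A10G,COR,1e-9,2e-9,IG", "1ABD,\"A10G,S30T\",SUR,1e-9,4e-9,IG"],
        )
        parsed = parse_skempi_like(path)
        assert len(parsed.singles) == 1
        assert len(parsed.multis) == 1
        assert parsed.multis[0].n_substitutions == 2

    def test_unparseable_kd_skipped_with_warning(self, tmp_path, caplog):
        path = self._csv(
            tmp_path, ["1ABC,A10G,COR,oops,1e-9,IG", "1ABD,A10G,COR,1e-9,2e-9,IG"]
        )
        with caplog.at_level("WARNING"):
            parsed = parse_skempi_like(path)
        assert parsed.n_skipped == 1
        assert len(parsed.singles) == 1

    def test_unknown_region_code_is_error(self, tmp_path):
        path = self._csv(tmp_path, ["1ABC,A10G,XYZ,1e-9,2e-9,IG"])
        with pytest.raises(FormatError):
            parse_skempi_like(path)

    def test_missing_column_is_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("complex_id,mutation\n1ABC,A10G\n")
        with pytest.raises(FormatError):
            parse_skempi_like(path)


class TestRemoveExtremes:
    def test_boundary_is_strictly_greater(self):
        records = [make_record(v) for v in (1.0, 3.3, 3.19)]
        kept, n_removed = remove_extremes(records, 3.2)
        assert n_removed == 1
        assert [r.abs_ddg for r in kept] == [1.0, 3.19]

    def test_idempotent_and_monotone_in_cutoff(self, rng):
        records = [make_record(v) for v in rng.exponential(1.0, size=200)]
        kept, _ = remove_extremes(records, 3.2)
        again, n2 = remove_extremes(kept, 3.2)
        assert n2 == 0 and again == kept
        sizes = [len(remove_extremes(records, c)[0]) for c in (3.0, 3.1, 3.2, 3.3, 3.4)]
        assert sizes == sorted(sizes)


class TestMasterDistribution:
    def test_degenerate_core_weight(self):
        ws = master_distribution([1.0, 2.0], [5.0], w_core=1.0, w_noncore=0.0)
        assert ws.mean() == pytest.approx(1.5)

    def test_weighted_mean(self):
        ws = master_distribution([1.0, 1.0], [0.5, 0.5, 0.5])
        assert ws.mean() == pytest.approx(0.15 * 1.0 + 0.85 * 0.5)

    def test_empty_component_rejected(self):
        with pytest.raises(ValidationError):
            master_distribution([], [1.0])


class TestExponentialFit:
    def test_rate_recovery(self, rng):
        sample = rng.exponential(scale=0.5, size=10_000)  # rate 2
        fit = fit_exponential(sample)
        se = fit.rate / math.sqrt(fit.n)
        assert abs(fit.rate - 2.0) < 3 * se
        assert fit.mean == pytest.approx(fit.sd, rel=0.05)  # exp: mean == SD

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_exponential([1.0, 1.0, 1.0])


class TestCompareDistributions:
    def test_identical_samples(self, rng):
        a = rng.normal(size=60)
        u, p = compare_distributions(a, np.random.default_rng(1).permutation(a))
        assert u == pytest.approx(60 * 60 / 2)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_supports(self, rng):
        a = rng.uniform(0, 1, size=50)
        b = rng.uniform(10, 11, size=50)
        _, p = compare_distributions(a, b)
        assert p < 1e-10

    def test_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            compare_distributions([1.0], [1.0, 2.0])


class TestPropertyTable:
    def test_complete_over_20_residues(self):
        table = load_property_table()
        assert table.shape[0] == 20
        assert not table.isna().any().any()

    def test_net_charge_merge(self):
        prep = property_preprocessing()
        assert "net_charge" in prep.reduced.columns or "net_charge" in [
            c for c in prep.dropped
        ]
        raw = load_property_table()
        net = raw["charge_pos"] - raw["charge_neg"]
        assert net["R"] == 1 and net["D"] == -1 and net["A"] == 0

    def test_duplicated_column_dropped(self):
        table = load_property_table()
        table = table.assign(mw_copy=table["mw_sidechain"])
        prep = property_preprocessing(table)
        assert "mw_copy" in prep.dropped
        corr2 = prep.reduced.corr() ** 2
        off = corr2.to_numpy()[~np.eye(corr2.shape[0], dtype=bool)]
        assert np.all(off < 0.85)

    def test_explained_variance_monotone_in_components(self):
        five = property_preprocessing(n_components=5).explained_variance.sum()
        four = property_preprocessing(n_components=4).explained_variance.sum()
        assert five >= four


class TestBootstrapSelection:
    def test_no_signal_data_prefers_mean_model(self, rng):
        # |ddG| independent of the substitution => linear models cannot
        # beat the mean model's held-out RMSE by more than 2 SD
        df, _ = make_ddg_table(DdgGeneratorSpec(n_records=400, seed=3))
        model = SubstitutionEffectModel.from_csv(df)
        results = model.fit(n_reps=60, seed=3)
        assert results.selected == "mean"
        mean_rmse = results.reports["mean"].rmse_mean
        for name in ("linear_properties", "linear_pcs"):
            report = results.reports[name]
            assert report.rmse_mean > mean_rmse - 2 * report.rmse_sd

    def test_reproducible_under_seed(self):
        df, _ = make_ddg_table(DdgGeneratorSpec(n_records=100, seed=5))
        model = SubstitutionEffectModel.from_csv(df)
        a = model.fit(models=("mean",), n_reps=1, seed=42).to_dict()
        b = model.fit(models=("mean",), n_reps=1, seed=42).to_dict()
        assert a == b

    def test_implied_s_recovery_single_table(self):
        spec = DdgGeneratorSpec(seed=7)
        df, truth = make_ddg_table(spec)
        results = SubstitutionEffectModel.from_csv(df).fit(
            models=("mean",), n_reps=200, seed=7
        )
        lo, hi = results.s_ci
        assert lo <= truth["implied_s"] <= hi
        assert results.s == pytest.approx(truth["implied_s"], rel=0.1)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_model_selection([make_record(1.0)] * 5, models=("mean",))

    def test_cutoff_sweep_is_smooth(self):
        df, _ = make_ddg_table(DdgGeneratorSpec(n_records=600, cutoff=5.0, seed=9))
        records = parse_skempi_like(df).singles
        sweep = cutoff_sweep(records, n_reps=20, seed=9)
        s_values = sweep["implied_s"].to_numpy()
        assert np.all(np.isfinite(s_values))
        assert np.ptp(s_values) < 0.05  # no discontinuity across 3.0-3.4

    def test_summary_mentions_models_and_selection(self):
        df, _ = make_ddg_table(DdgGeneratorSpec(n_records=100, seed=2))
        text = SubstitutionEffectModel.from_csv(df).fit(
            models=("mean",), n_reps=10, seed=2
        ).summary()
        assert "mean" in text and "selected" in text


class TestMultiplicativeCheck:
    def test_exactly_multiplicative_records(self):
        s = 0.30
        records = [
            make_record(-m * RT * math.log(s), n_subs=m) for m in (2, 3, 4)
        ]
        check = multiplicative_check(records, s)
        assert check.residual_mean == pytest.approx(0.0, abs=1e-10)

    def test_m2_record_at_009(self):
        rec = make_record(-RT * math.log(0.09), n_subs=2)
        check = multiplicative_check([rec], 0.30)
        assert check.residuals[0] == pytest.approx(0.0, abs=1e-10)

    def test_sub_multiplicative_bias_detected(self):
        s = 0.30
        # observed effect weaker than predicted: similarity below s**m
        records = [
            make_record(-m * RT * math.log(s) + 0.5, n_subs=m) for m in (2, 3, 4)
        ]
        check = multiplicative_check(records, s)
        assert check.residual_mean < -0.5 / RT + 1e-9

    def test_requires_multi_substitution_records(self):
        with pytest.raises(ValidationError):
            multiplicative_check([make_record(1.0, n_subs=1)], 0.3)
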