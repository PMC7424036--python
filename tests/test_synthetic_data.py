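import numpy as np
import pytest

from pedpv import disproportionality as dis
from pedpv import icsr_model as im
from pedpv import synthetic_data as sd

from conftest import pair_result, two_drug_config


class TestConfigValidation:
    def test_empty_catalogs_rejected(self):
        cfg = two_drug_config(0)
        cfg.drug_catalog = []
        with pytest.raises(sd.ConfigError, match="drug catalog"):
            cfg.validate()
        cfg = two_drug_config(0)
        cfg.event_catalog = []
        with pytest.raises(sd.ConfigError, match="event catalog"):
            cfg.validate()

    def test_nonpositive_lambda_rejected(self):
        cfg = two_drug_config(0)
        cfg.injected_signals = [sd.InjectedSignal("TARGETDRUG", "TARGETEVENT", 0.0)]
        with pytest.raises(sd.ConfigError, match="lambda"):
            cfg.validate()

    def test_probability_vector_must_sum_to_one(self):
        cfg = two_drug_config(0)
        cfg.age_group_probabilities = (0.3, 0.3, 0.3, 0.3, 0.3)
        with pytest.raises(sd.ConfigError, match="sum to 1"):
            cfg.validate()

    def test_injected_pair_must_name_catalog_entries(self):
        cfg = two_drug_config(0)
        cfg.injected_signals = [sd.InjectedSignal("NOSUCHDRUG", "TARGETEVENT", 2.0)]
        with pytest.raises(sd.ConfigError, match="unknown drug"):
            cfg.validate()


def test_zero_reports_give_empty_database():
    cfg = two_drug_config(0)
    cfg.n_reports = 0
    reports, truth = sd.generate_database(cfg)
    assert reports == []
    assert truth.injected_signals == []


def test_identical_seed_gives_byte_identical_output(tmp_path):
    cfg = sd.default_notivisa_like_config(seed=7)
    cfg.n_reports = 300
    for sub in ("a", "b"):
        reports, _ = sd.generate_database(cfg)
        im.write_database(reports, tmp_path / sub)
    for name in ("reports.csv", "drugs.csv", "events.csv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_default_config_is_deterministic():
    assert sd.default_notivisa_like_config(3) == sd.default_notivisa_like_config(3)


def test_config_yaml_round_trip(tmp_path):
    cfg = sd.default_notivisa_like_config(seed=5)
    path = sd.save_config(cfg, tmp_path / "config.yaml")
    assert sd.load_config(path) == cfg


class TestDefaultCalibration:
    def test_every_case_is_structurally_valid(self):
        cfg = sd.default_notivisa_like_config(seed=2)
        reports, _ = sd.generate_database(cfg)
        assert len(reports) == 1977
        for case in reports:
            case.validate()

    def test_drug_entry_count_near_expectation(self):
        cfg = sd.default_notivisa_like_config(seed=13)
        mean_k = sd.expected_drugs_per_report(cfg)
        assert mean_k == pytest.approx(1.1275)
        var_k = sum((k + 1) ** 2 * p for k, p in enumerate(cfg.n_drugs_distribution)) - mean_k**2
        sigma = (1977 * var_k) ** 0.5
        reports, _ = sd.generate_database(cfg)
        realized = sum(len(r.drugs) for r in reports)
        assert abs(realized - 1977 * mean_k) <= 3 * sigma

    def test_death_share_matches_binomial_expectation(self):
        shares = []
        for seed in range(20):
            reports, _ = sd.generate_database(sd.default_notivisa_like_config(seed))
            shares.append(sum(r.seriousness == "death" for r in reports) / len(reports))
        assert np.mean(shares) == pytest.approx(75 / 1977, abs=0.005)


def test_null_pair_ror_covered_by_ci():
    """With no injected signal the true reporting odds ratio is 1; the 95%
    Woolf interval should cover it in at least 90 of 100 replicates."""
    hits = 0
    for seed in range(100):
        reports, _ = sd.generate_database(two_drug_config(seed, lam=1.0))
        res = pair_result(reports)
        hits += res.ci_lower < 1.0 < res.ci_upper
    assert hits >= 90


def test_detection_probability_monotone_in_lambda():
    """SDR detection of the injected pair is non-decreasing in the injected
    odds multiplier (up to one standard error of the Monte-Carlo estimate)."""
    n_reps = 50
    rates = []
    for lam in (1.0, 2.0, 5.0, 10.0):
        detected = 0
        for seed in range(n_reps):
            cfg = two_drug_config(seed, lam=lam, n_reports=2000)
            reports, _ = sd.generate_database(cfg)
            results = dis.detect_sdr(
                [pair_result(reports)], set(), {"TARGETEVENT"}
            )
            detected += results[0].is_sdr
        rates.append(detected / n_reps)
    se = max((r * (1 - r) / n_reps) ** 0.5 for r in rates) or 1 / n_reps
    for low, high in zip(rates, rates[1:]):
        assert high >= low - se


def test_false_sdr_rate_under_global_null_below_10_percent():
    cfg = sd.default_notivisa_like_config(seed=29)
    cfg.injected_signals = []  # lambda = 1 everywhere
    reports, _ = sd.generate_database(cfg)
    results = dis.screen(
        reports,
        sd.monitoring_list_from_config(cfg),
        sd.ime_list_from_config(cfg),
    )
    rate = sum(r.is_sdr for r in results) / len(results)
    assert rate < 0.10
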