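"""Comorbidity mappers: reference tables, eligibility, rules, oracle checks.

The brute-force oracle re-evaluates every (code, category) pair directly
from the method's raw tables — prefix matching by string comparison, the
DRG screen and prior-only rules as explicit conditionals, hierarchy as a
final pass — sharing no code with the production prefix-index path.
"""

from datetime import date

import numpy as np
import pytest

from comorbidikit.comorbidity import (INDEX_ONLY, INDEX_PLUS_PRIOR,
                                      METHOD_NAMES, EligibleCode,
                                      eligible_diagnoses, load_method,
                                      map_profile, profile_matrix)
from comorbidikit.errors import ConfigError
from comorbidikit.io import AdmissionRecord


def brute_force_profile(eligible, index_drg, method):
    """Independent rule evaluator: plain loops over the raw tables."""
    flags = {}
    for cat in method.categories:
        hit = False
        for ec in eligible:
            matches = any(ec.code.startswith(p) for p in method.code_map[cat])
            if not matches:
                continue
            if ec.source == "index":
                if method.drg_screen is not None and \
                        cat in method.drg_screen and \
                        index_drg in method.drg_screen[cat]:
                    continue
                if cat in method.prior_only_categories:
                    continue
            hit = True
        flags[cat] = hit
    for dom, sup in method.hierarchy_rules:
        if flags[dom]:
            flags[sup] = False
    return flags


class TestLoadMethod:
    def test_charlson_deyo_has_17_categories(self):
        assert len(load_method("charlson_deyo").categories) == 17

    def test_charlson_romano_has_17_categories(self):
        assert len(load_method("charlson_romano").categories) == 17

    def test_elixhauser_has_30_categories_and_drg_screen(self):
        m = load_method("elixhauser")
        assert len(m.categories) == 30
        assert m.drg_screen and all(m.drg_screen.values())

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            load_method("foo")

    def test_charlson_has_no_drg_screen(self):
        assert load_method("charlson_deyo").drg_screen is None

    def test_complication_prone_alternative_config(self):
        m = load_method("charlson_romano", prior_only="complication_prone")
        assert "congestive_heart_failure" in m.prior_only_categories


class TestEligibleDiagnoses:
    def _index(self, secondary=("4280",)):
        return AdmissionRecord(
            patient_id="A", admit_date=date(2002, 6, 1),
            discharge_date=date(2002, 6, 8), principal_dx="41071",
            secondary_dx=secondary, drg="121")

    def test_index_only_projects_secondary_codes(self):
        idx = self._index()
        out = eligible_diagnoses([idx], idx, INDEX_ONLY)
        assert out == [EligibleCode("4280", "index", "secondary")]

    def test_prior_admission_beyond_lookback_ignored(self):
        idx = self._index()
        old = AdmissionRecord(
            patient_id="A", admit_date=date(2001, 4, 1),   # 426 days before
            discharge_date=date(2001, 4, 3), principal_dx="25000")
        out = eligible_diagnoses([old, idx], idx, INDEX_PLUS_PRIOR)
        assert all(e.source == "index" for e in out)

    def test_prior_admission_within_lookback_contributes_all_fields(self):
        idx = self._index()
        prior = AdmissionRecord(
            patient_id="A", admit_date=date(2001, 11, 1),
            discharge_date=date(2001, 11, 3), principal_dx="25000",
            secondary_dx=("585",))
        out = eligible_diagnoses([prior, idx], idx, INDEX_PLUS_PRIOR)
        assert EligibleCode("25000", "prior", "principal") in out
        assert EligibleCode("585", "prior", "secondary") in out

    def test_index_principal_never_eligible(self):
        idx = self._index(secondary=())
        for period in (INDEX_ONLY, INDEX_PLUS_PRIOR):
            assert eligible_diagnoses([idx], idx, period) == []


class TestMapProfile:
    def test_elixhauser_drg_screen_truth_table(self):
        """CHF flag over (source, index-DRG-in-screen) combinations."""
        m = load_method("elixhauser")
        screened_drg = next(iter(m.drg_screen["congestive_heart_failure"]))
        cases = [
            (EligibleCode("4280", "index", "secondary"), screened_drg, False),
            (EligibleCode("4280", "prior", "secondary"), screened_drg, True),
            (EligibleCode("4280", "index", "secondary"), "182", True),
            (EligibleCode("4280", "prior", "secondary"), "182", True),
        ]
        for code, drg, expected in cases:
            prof = map_profile([code], drg, m, INDEX_ONLY)
            assert prof.flags["congestive_heart_failure"] is expected, \
                (code.source, drg)

    def test_charlson_prior_only_rule(self):
        m = load_method("charlson_deyo", prior_only={"congestive_heart_failure"})
        idx_code = [EligibleCode("4280", "index", "secondary")]
        pri_code = [EligibleCode("4280", "prior", "secondary")]
        assert not map_profile(idx_code, "121", m, INDEX_PLUS_PRIOR).flags[
            "congestive_heart_failure"]
        assert map_profile(pri_code, "121", m, INDEX_PLUS_PRIOR).flags[
            "congestive_heart_failure"]

    def test_diabetes_hierarchy_clears_uncomplicated(self):
        m = load_method("charlson_deyo")
        codes = [EligibleCode("25000", "index", "secondary"),
                 EligibleCode("25040", "index", "secondary")]
        flags = map_profile(codes, "121", m, INDEX_ONLY).flags
        assert flags["diabetes_with_complications"] and not flags["diabetes"]

    def test_no_codes_all_false(self):
        for name in METHOD_NAMES:
            m = load_method(name)
            flags = map_profile([], "121", m, INDEX_ONLY).flags
            assert set(flags) == set(m.categories)
            assert not any(flags.values())

    def test_mapping_is_idempotent_and_deterministic(self):
        m = load_method("elixhauser")
        codes = [EligibleCode("4280", "index", "secondary"),
                 EligibleCode("2762", "prior", "secondary")]
        p1 = map_profile(codes, "121", m, INDEX_PLUS_PRIOR)
        p2 = map_profile(codes, "121", m, INDEX_PLUS_PRIOR)
        assert p1.flags == p2.flags


def _random_eligible(rng, methods, n_codes):
    """Sample codes biased toward reference prefixes so flags actually fire."""
    pool = []
    for m in methods:
        for prefixes in m.code_map.values():
            pool.extend(prefixes)
    out = []
    for _ in range(n_codes):
        base = pool[int(rng.integers(0, len(pool)))]
        suffix = "".join(rng.choice(list("0123456789"),
                                    size=int(rng.integers(0, 3))))
        code = (base + suffix)[:6]
        source = "prior" if rng.random() < 0.4 else "index"
        position = "principal" if source == "prior" and rng.random() < 0.3 \
            else "secondary"
        out.append(EligibleCode(code, source, position))
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("prior_only", ["none", "complication_prone"])
    def test_matches_brute_force_on_random_fixtures(self, prior_only):
        methods = [load_method(n, prior_only=prior_only) for n in METHOD_NAMES]
        drgs = ["121", "107", "088", "182", "127"]
        rng = np.random.default_rng(20020101)
        for trial in range(300):
            m = methods[int(rng.integers(0, 3))]
            eligible = _random_eligible(rng, methods,
                                        int(rng.integers(0, 6)))
            drg = drgs[int(rng.integers(0, len(drgs)))]
            got = map_profile(eligible, drg, m, INDEX_PLUS_PRIOR).flags
            want = brute_force_profile(eligible, drg, m)
            assert got == want, (trial, m.name, eligible, drg)


class TestPeriodMonotonicity:
    def test_prior_evidence_only_adds(self):
        """index_only flags ⊆ index_plus_prior flags, pre-hierarchy; and
        post-hierarchy for categories no rule suppresses."""
        rng = np.random.default_rng(77)
        import comorbidikit as ck
        cfg = ck.load_scenario("dominance", seed=17, n_patients=300)
        ds, _ = ck.simulate_population(cfg)
        cohort, _ = ck.build_cohort(ds, "AMI")
        by_patient = ds.admissions_by_patient()
        for name in METHOD_NAMES:
            m = load_method(name)
            bare = ck.ComorbidityMethod(
                name=m.name, categories=m.categories, code_map=m.code_map,
                drg_screen=m.drg_screen,
                prior_only_categories=m.prior_only_categories,
                hierarchy_rules=[])
            suppressed = {s for _, s in m.hierarchy_rules}
            for e in cohort:
                adms = by_patient[e.patient_id]
                drg = e.index_admission.drg
                for variant in (m, bare):
                    fi = map_profile(
                        eligible_diagnoses(adms, e.index_admission, INDEX_ONLY),
                        drg, variant, INDEX_ONLY).flags
                    fp = map_profile(
                        eligible_diagnoses(adms, e.index_admission,
                                           INDEX_PLUS_PRIOR),
                        drg, variant, INDEX_PLUS_PRIOR).flags
                    for cat in variant.categories:
                        if variant is bare or cat not in suppressed:
                            assert fp[cat] >= fi[cat], (name, cat)


class TestProfileMatrix:
    def test_shapes_and_zero_row(self, tiny_dataset):
        from comorbidikit.cohort import build_cohort
        cohort, _ = build_cohort(tiny_dataset, "AMI")
        romano = profile_matrix(cohort, tiny_dataset,
                                load_method("charlson_romano"), INDEX_ONLY)
        elix = profile_matrix(cohort, tiny_dataset,
                              load_method("elixhauser"), INDEX_ONLY)
        assert romano.shape == (1, 17) and elix.shape == (1, 30)
        # patient A's index carries CHF + renal secondaries
        assert romano.loc["A", "congestive_heart_failure"] == 1
        cohort_b, _ = build_cohort(tiny_dataset, "COPD")
        mat_b = profile_matrix(cohort_b, tiny_dataset,
                               load_method("charlson_deyo"), INDEX_ONLY)
        assert mat_b.loc["B"].sum() == 0  # no secondary codes at index
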