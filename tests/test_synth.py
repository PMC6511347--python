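"""The synthetic-cohort generator: determinism, phenotype fidelity, gating."""

import numpy as np
import pytest

from radargate import (
    ConfigurationError,
    InputError,
    default_blast_gate,
    default_panel,
    fit_scaling,
    gate_blasts,
    scale_to_unit,
)
from radargate.panel import normalize_marker
from radargate.synth import (
    PhenotypeSpec,
    default_phenotypes,
    derive_case_seed,
    simulate_case,
    simulate_cohort,
)


class TestSimulateCase:
    def test_same_seed_is_bit_identical(self, phenotypes):
        a = simulate_case(phenotypes["hypergranular"], n_events=2000, seed=7)
        b = simulate_case(phenotypes["hypergranular"], n_events=2000, seed=7)
        for t in (1, 2, 3, 4):
            np.testing.assert_array_equal(a.tubes[t].values, b.tubes[t].values)
        assert a.marker_status == b.marker_status

    def test_hard_constraints_hold(self, phenotypes):
        for seed in range(5):
            hyper = simulate_case(phenotypes["hypergranular"], n_events=1000,
                                  seed=seed)
            micro = simulate_case(phenotypes["microgranular"], n_events=1000,
                                  seed=seed)
            assert not hyper.marker_status["CD34"]
            assert not hyper.marker_status["HLADR"]
            assert hyper.marker_status["CD117"]
            assert micro.marker_status["CD34"]
            assert micro.marker_status["CD123"]
            assert micro.marker_status["CD2"]

    def test_blast_count_is_exact_allocation(self, phenotypes):
        case = simulate_case(phenotypes["non_apl"], n_events=10_000, seed=3)
        for t in (1, 2, 3, 4):
            n_blasts = int(np.sum(case.tubes[t].labels["population"] == "blast"))
            assert n_blasts == round(case.blast_fraction * 10_000)

    def test_hyper_blast_ssc_above_lymphocytes(self, phenotypes):
        case = simulate_case(phenotypes["hypergranular"], n_events=5000, seed=7)
        em = case.tubes[1]
        ssc = em.marker_values("SSC")
        pop = em.labels["population"]
        assert np.median(ssc[pop == "blast"]) > np.median(ssc[pop == "lymphocyte"])

    def test_micro_ssc_below_hyper(self, phenotypes):
        hyper = simulate_case(phenotypes["hypergranular"], n_events=5000, seed=1)
        micro = simulate_case(phenotypes["microgranular"], n_events=5000, seed=1)
        for t in (1, 2, 3, 4):
            h = hyper.tubes[t]
            m = micro.tubes[t]
            assert (np.median(m.marker_values("SSC")[m.labels["population"] == "blast"])
                    < np.median(h.marker_values("SSC")[h.labels["population"] == "blast"]))

    def test_marker_status_consistent_across_tubes(self, phenotypes):
        # CD34 is stained in tubes 2, 3 and 4: a CD34+ case must read
        # positive everywhere it is stained
        case = simulate_case(phenotypes["microgranular"], n_events=5000, seed=9)
        for t in (2, 3, 4):
            em = case.tubes[t]
            blast = em.labels["population"] == "blast"
            cd34 = em.marker_values("CD34")[blast]
            assert np.median(cd34) > 5000  # bright

    def test_unknown_marker_in_panel_rejected(self, phenotypes):
        spec = phenotypes["hypergranular"]
        bad = PhenotypeSpec(
            name="bad",
            marker_probability={"CD117": 1.0},  # misses most panel markers
            full_level=spec.full_level,
            ssc_level=spec.ssc_level,
            blast_fraction_range=spec.blast_fraction_range,
        )
        with pytest.raises(ConfigurationError, match="phenotype"):
            simulate_case(bad, n_events=1000, seed=0)

    def test_too_few_events_rejected(self, phenotypes):
        with pytest.raises(InputError):
            simulate_case(phenotypes["non_apl"], n_events=10, seed=0)

    def test_blasts_pass_default_gate(self, phenotypes):
        # generated blasts must be recoverable by the standard CD45/SSC gate
        # at a >= 95% rate overall (and never badly per case), so the gating
        # stage is exercised realistically
        from radargate import apply_polygon_gate

        rates = []
        for group in ("hypergranular", "microgranular", "non_apl"):
            for seed in (21, 22):
                case = simulate_case(phenotypes[group], n_events=5000, seed=seed)
                for t in (1, 2, 3, 4):
                    em = case.tubes[t]
                    scaled = scale_to_unit(em, fit_scaling(em))
                    truth = em.labels["population"] == "blast"
                    mask = apply_polygon_gate(scaled, default_blast_gate())
                    rate = mask[truth].mean()
                    assert rate >= 0.90, (group, seed, t)
                    rates.append(rate)
        assert np.mean(rates) >= 0.95


class TestSimulateCohort:
    def test_design_sizes_and_manifest(self):
        cases, manifest = simulate_cohort(6, 2, 12, n_events=1000, master_seed=42)
        assert len(cases) == 20
        assert len(manifest) == 20
        assert manifest["group"].value_counts().to_dict() == {
            "non_apl": 12, "hypergranular": 6, "microgranular": 2,
        }

    def test_empty_cohort_valid_empty_manifest(self):
        cases, manifest = simulate_cohort(0, 0, 0, n_events=1000, master_seed=1)
        assert cases == []
        assert manifest.empty
        assert "case_id" in manifest.columns

    def test_same_master_seed_identical_manifests(self):
        _, m1 = simulate_cohort(2, 1, 2, n_events=1000, master_seed=5)
        _, m2 = simulate_cohort(2, 1, 2, n_events=1000, master_seed=5)
        assert m1.equals(m2)

    def test_exact_frequency_allocation_matches_table(self):
        # 6 hypergranular cases: CD56 at 17% -> exactly 1 positive;
        # CD64 at 50% -> exactly 3; 2 microgranular: CD7 at 50% -> exactly 1
        cases, manifest = simulate_cohort(6, 2, 0, n_events=1000, master_seed=11)
        hyper = manifest[manifest.group == "hypergranular"]
        micro = manifest[manifest.group == "microgranular"]
        assert hyper["status_CD56"].sum() == 1
        assert hyper["status_CD64"].sum() == 3
        assert hyper["status_CD2"].sum() == 1
        assert micro["status_CD7"].sum() == 1
        assert micro["status_CD34"].sum() == 2  # hard constraint

    def test_bernoulli_mode_matches_rates_within_3_se(self):
        # 200 independent non-APL cases: HLA-DR positivity ~ 58%
        n = 200
        phenos = default_phenotypes()
        positives = 0
        for i in range(n):
            case = simulate_case(phenos["non_apl"], n_events=1000,
                                 seed=derive_case_seed(77, i))
            positives += case.marker_status["HLADR"]
        p = 0.58
        se = np.sqrt(p * (1 - p) / n)
        assert abs(positives / n - p) <= 3 * se

    def test_negative_sizes_rejected(self):
        with pytest.raises(InputError):
            simulate_cohort(-1, 0, 0)


def test_all_panel_markers_have_phenotype_entries(phenotypes):
    panel = default_panel()
    keys = {normalize_marker(m) for t in panel.tubes for m in t.markers}
    keys.discard("CD45")
    for spec in phenotypes.values():
        assert keys <= set(spec.marker_probability)
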