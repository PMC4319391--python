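"""ECR/BTIF filtering, PAS and SPCD scoring, and pathway cloud construction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pascloud import (
    ConfigurationError,
    ExpressionMatrix,
    GeneRole,
    GeneSignal,
    Group,
    GroupDesign,
    Pathway,
    PathwayDatabase,
    Role,
    TolerancePolicy,
    build_cloud,
    compute_btif,
    compute_ecr,
    compute_pas,
    compute_spcd,
    profile,
)

POLICY = TolerancePolicy()


class TestTolerancePolicy:
    def test_invalid_fold_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            TolerancePolicy(fold_upper=0.9)
        with pytest.raises(ConfigurationError):
            TolerancePolicy(fold_lower=1.2)

    def test_explicit_pseudocount_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            TolerancePolicy(pseudocount=0.0)

    def test_auto_pseudocount_scales_with_matrix_median(self):
        values = np.array([[10.0, 20.0], [30.0, 40.0]])
        assert POLICY.resolve_pseudocount(values) == pytest.approx(25.0 * 1e-8)

    def test_auto_pseudocount_floor_without_data(self):
        assert POLICY.resolve_pseudocount() == 1e-12


class TestEcr:
    def test_equal_case_and_control_is_one(self):
        assert compute_ecr(10.0, 10.0, POLICY) == pytest.approx(1.0, rel=1e-6)

    def test_doubling_gives_two(self):
        assert compute_ecr(20.0, 10.0, POLICY) == pytest.approx(2.0, rel=1e-6)

    def test_zero_control_guarded_by_pseudocount(self):
        ecr = compute_ecr(5.0, 0.0, POLICY)
        assert math.isfinite(ecr) and ecr > 1e6


class TestBtif:
    @pytest.mark.parametrize(
        "ecr,deviation_sds,expected",
        [
            (1.4, 10.0, 0),   # inside fold tolerance: never flagged
            (0.7, 10.0, 0),   # inside on the low side
            (2.0, 1.5, 0),    # beyond fold but within 2 SD: both criteria needed
            (2.0, 3.0, 1),    # both criteria met
            (0.5, 3.0, 1),    # low-side fold with deviation
        ],
    )
    def test_two_criteria_must_hold_simultaneously(self, ecr, deviation_sds, expected):
        control_mean, control_sd = 10.0, 1.0
        case_value = control_mean + deviation_sds * control_sd
        assert compute_btif(ecr, case_value, control_mean, control_sd, POLICY) == expected

    def test_boundary_folds_are_inside_tolerance(self):
        # thresholds are strict: exactly 3/2 or 2/3 does not trigger
        assert compute_btif(1.5, 100.0, 10.0, 1.0, POLICY) == 0
        assert compute_btif(2 / 3, 0.0, 10.0, 1.0, POLICY) == 0

    def test_zero_sd_reduces_to_any_difference(self):
        assert compute_btif(2.0, 20.0, 10.0, 0.0, POLICY) == 1
        assert compute_btif(2.0, 10.0, 10.0, 0.0, POLICY) == 0

    def test_sd_criterion_can_be_disabled(self):
        lax = TolerancePolicy(use_sd_criterion=False)
        assert compute_btif(2.0, 10.5, 10.0, 5.0, lax) == 1


class TestComputePas:
    def test_all_flags_zero_gives_exact_zero(self, demo_pathway):
        signals = {g: GeneSignal(g, "s", ecr=5.0, btif=0)
                   for g in demo_pathway.gene_ids}
        assert compute_pas(demo_pathway, signals) == 0.0

    def test_single_activator_tenfold(self):
        p = Pathway("P", "", (GeneRole("A", Role.ACTIVATOR, 1.0),))
        assert compute_pas(p, {"A": GeneSignal("A", "s", 10.0, 1)}) == pytest.approx(1.0)

    def test_activator_and_repressor_sum(self):
        p = Pathway("P", "", (GeneRole("A", Role.ACTIVATOR, 1.0),
                              GeneRole("R", Role.REPRESSOR, -1.0)))
        signals = {"A": GeneSignal("A", "s", 100.0, 1),
                   "R": GeneSignal("R", "s", 0.01, 1)}
        # +1*log10(100) + (-1)*log10(0.01) = 2 + 2
        assert compute_pas(p, signals) == pytest.approx(4.0, abs=1e-9)

    def test_unmeasured_members_skipped(self, demo_pathway):
        signals = {"ACT1": GeneSignal("ACT1", "s", 10.0, 1)}
        assert compute_pas(demo_pathway, signals) == pytest.approx(1.0)

    def test_no_measured_member_is_undefined_marker(self, demo_pathway):
        assert compute_pas(demo_pathway, {}) is None


class TestComputeSpcd:
    def test_all_unit_levels_give_one(self, demo_pathway):
        levels = {g: 1.0 for g in demo_pathway.gene_ids}
        assert compute_spcd(demo_pathway, levels) == pytest.approx(1.0)

    def test_hand_product(self, demo_pathway):
        levels = {"ACT1": 10.0, "ACT2": 10.0, "REP1": 2.0}
        assert compute_spcd(demo_pathway, levels) == pytest.approx(50.0)

    def test_neutral_members_ignored(self):
        p = Pathway("P", "", (GeneRole("A", Role.ACTIVATOR, 1.0),
                              GeneRole("N", Role.NEUTRAL, 0.0)))
        assert compute_spcd(p, {"A": 3.0, "N": 100.0}) == pytest.approx(3.0)

    def test_no_activators_or_repressors_is_undefined(self):
        p = Pathway("P", "", (GeneRole("N", Role.NEUTRAL, 0.0),))
        assert compute_spcd(p, {"N": 5.0}) is None

    def test_ten_to_pas_matches_spcd_on_worked_example(self):
        p = Pathway("P", "", (GeneRole("A", Role.ACTIVATOR, 1.0),
                              GeneRole("R", Role.REPRESSOR, -1.0)))
        ecrs = {"A": 100.0, "R": 0.01}
        signals = {g: GeneSignal(g, "s", e, 1) for g, e in ecrs.items()}
        pas = compute_pas(p, signals)
        assert 10.0**pas == pytest.approx(compute_spcd(p, ecrs), rel=1e-9)
        assert 10.0**pas == pytest.approx(1e4, rel=1e-9)


class TestProfile:
    def test_case_equal_to_control_mean_gives_zero_pas(self, demo_db, demo_design):
        genes = sorted({g for p in demo_db for g in p.gene_ids})
        df = pd.DataFrame(10.0, index=genes, columns=["c1", "c2", "n1", "n2", "n3"])
        prof = profile(ExpressionMatrix(df), demo_design, demo_db)
        assert (prof.aggregate == 0.0).all()

    def test_demo_fixture_pas(self, demo_matrix, demo_design, demo_db):
        # P1: ACT1, ACT2 at ECR 4 (flagged, constant controls), REP1 at ECR 0.2
        # with |case-mean| = 8 > 2*SD(=2): PAS = 2*log10(4) - log10(0.2)
        prof = profile(demo_matrix, demo_design, demo_db)
        expected = 2 * math.log10(4.0) - math.log10(0.2)
        assert prof.aggregate["P1"] == pytest.approx(expected, rel=1e-6)
        assert prof.aggregate["P2"] == 0.0

    def test_aggregate_mean_and_sd_over_case_samples(self, demo_db):
        # craft per-sample PAS 1 and 3 for P2's single activator ACT3
        genes = ["ACT1", "ACT2", "REP1", "ACT3", "REP2"]
        df = pd.DataFrame(10.0, index=genes, columns=["c1", "c2", "n1", "n2", "n3"])
        df.loc["ACT3", "c1"] = 100.0    # ECR 10 -> PAS 1
        df.loc["ACT3", "c2"] = 10000.0  # ECR 1000 -> PAS 3
        design = GroupDesign(assignment={
            "c1": Group.CASE, "c2": Group.CASE,
            "n1": Group.CONTROL, "n2": Group.CONTROL, "n3": Group.CONTROL})
        prof = profile(ExpressionMatrix(df), design, demo_db)
        assert prof.aggregate["P2"] == pytest.approx(2.0, rel=1e-6)
        assert prof.sd["P2"] == pytest.approx(math.sqrt(2.0), rel=1e-6)

    def test_single_case_sample_aggregate_is_that_sample(self, demo_db):
        genes = ["ACT1", "ACT2", "REP1", "ACT3", "REP2"]
        df = pd.DataFrame(10.0, index=genes, columns=["c1", "n1", "n2", "n3"])
        df.loc["ACT1", "c1"] = 100.0
        design = GroupDesign(assignment={
            "c1": Group.CASE,
            "n1": Group.CONTROL, "n2": Group.CONTROL, "n3": Group.CONTROL})
        prof = profile(ExpressionMatrix(df), design, demo_db)
        assert prof.aggregate["P1"] == prof.per_sample.loc["P1", "c1"]

    def test_unmeasured_pathway_is_nan_with_coverage_zero(self, demo_design):
        db = PathwayDatabase((
            Pathway("PX", "", (GeneRole("MISSING", Role.ACTIVATOR, 1.0),)),))
        df = pd.DataFrame(10.0, index=["OTHER"],
                          columns=["c1", "c2", "n1", "n2", "n3"])
        prof = profile(ExpressionMatrix(df), demo_design, db)
        assert math.isnan(prof.aggregate["PX"])
        assert prof.n_measured["PX"] == 0

    def test_profile_is_deterministic(self, demo_matrix, demo_design, demo_db):
        p1 = profile(demo_matrix, demo_design, demo_db)
        p2 = profile(demo_matrix, demo_design, demo_db)
        assert p1.per_sample.equals(p2.per_sample)


class TestBuildCloud:
    def _profile_from(self, aggregates: dict) -> "object":
        from pascloud.pas_engine import PasProfile
        idx = list(aggregates)
        per_sample = pd.DataFrame({"c1": pd.Series(aggregates)})
        return PasProfile(
            per_sample=per_sample,
            aggregate=pd.Series(aggregates),
            sd=pd.Series(0.0, index=idx),
            n_members=pd.Series(1, index=idx),
            n_measured=pd.Series(1, index=idx),
        )

    def test_all_zero_profile_gives_empty_cloud(self):
        cloud = build_cloud(self._profile_from({"P1": 0.0, "P2": 0.0}))
        assert len(cloud) == 0

    def test_threshold_and_labels(self):
        prof = self._profile_from({"P1": 2.0, "P2": -1.0, "P3": 0.1})
        cloud = build_cloud(prof, threshold=0.5)
        assert cloud.pathway_ids == ("P1", "P2")
        labels = {e.pathway_id: e.label for e in cloud.entries}
        assert labels == {"P1": "activated", "P2": "repressed"}

    def test_zero_threshold_keeps_every_nonzero(self):
        prof = self._profile_from({"P1": 1e-9, "P2": -1e-9, "P3": 0.0})
        assert len(build_cloud(prof, threshold=0.0)) == 2

    def test_sorted_by_abs_pas_ties_by_id(self):
        prof = self._profile_from({"PB": 1.0, "PA": -1.0, "PC": 3.0})
        assert build_cloud(prof).pathway_ids == ("PC", "PA", "PB")

    def test_undefined_pas_excluded(self):
        prof = self._profile_from({"P1": float("nan"), "P2": 1.0})
        assert build_cloud(prof).pathway_ids == ("P2",)


# -- properties ---------------------------------------------------------------

@st.composite
def pathway_with_ecrs(draw):
    """Random unit-weight pathway plus strictly positive ECRs per member."""
    n = draw(st.integers(1, 8))
    members, ecrs = [], {}
    for i in range(n):
        role = draw(st.sampled_from([Role.ACTIVATOR, Role.REPRESSOR]))
        g = f"G{i}"
        members.append(GeneRole(g, role, 1.0 if role is Role.ACTIVATOR else -1.0))
        ecrs[g] = draw(st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False))
    return Pathway("P", "", tuple(members)), ecrs


@settings(max_examples=200, deadline=None)
@given(pe=pathway_with_ecrs())
def test_eq1_eq2_consistency_property(pe):
    """10**PAS equals SPCD whenever |arr| = 1 and every flag is raised."""
    pathway, ecrs = pe
    signals = {g: GeneSignal(g, "s", e, 1) for g, e in ecrs.items()}
    pas = compute_pas(pathway, signals)
    spcd = compute_spcd(pathway, ecrs)
    assert 10.0**pas == pytest.approx(spcd, rel=1e-9)


def test_annihilation_no_flag_no_pas(demo_db, demo_design):
    """If no gene in the experiment passes BTIF, every pathway PAS is exactly 0."""
    genes = sorted({g for p in demo_db for g in p.gene_ids})
    rng = np.random.default_rng(7)
    # perturbations within the fold tolerance (ratio in [0.8, 1.25])
    base = pd.DataFrame(10.0, index=genes, columns=["c1", "c2", "n1", "n2", "n3"])
    base[["c1", "c2"]] *= rng.uniform(0.8, 1.25, size=(len(genes), 2))
    prof = profile(ExpressionMatrix(base), demo_design, demo_db)
    assert (prof.per_sample == 0.0).all().all()


def test_monotonicity_raising_activator_never_lowers_pas(demo_matrix, demo_design,
                                                         demo_db):
    """Increasing a case activator's expression never decreases that pathway's PAS."""
    base = profile(demo_matrix, demo_design, demo_db).aggregate["P1"]
    for value in [41.0, 60.0, 200.0, 5000.0]:
        bumped = demo_matrix.values.copy()
        bumped.loc["ACT1", "c1"] = value
        pas = profile(ExpressionMatrix(bumped), demo_design, demo_db).aggregate["P1"]
        assert pas >= base - 1e-12
        base = pas


@settings(max_examples=100, deadline=None)
@given(pe=pathway_with_ecrs())
def test_restricted_antisymmetry_reciprocal_ecrs_negate_pas(pe):
    """With the SD criterion off, reciprocal ECRs negate PAS exactly.

    The fold bounds 3/2 and 2/3 are reciprocal, so flipping every ECR to
    its reciprocal preserves each BTIF decision.
    """
    pathway, ecrs = pe
    lax = TolerancePolicy(use_sd_criterion=False, pseudocount=1e-300)

    def pas_of(ratios):
        signals = {
            g: GeneSignal(g, "s", e, compute_btif(e, 0.0, 0.0, 0.0, lax))
            for g, e in ratios.items()
        }
        return compute_pas(pathway, signals)

    forward = pas_of(ecrs)
    backward = pas_of({g: 1.0 / e for g, e in ecrs.items()})
    assert backward == pytest.approx(-forward, abs=1e-9)
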