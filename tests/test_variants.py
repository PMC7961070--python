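"""Filter cascade, TMB and gene summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from tilmark.variants import (
    Consequence,
    FilterReason,
    FilterThresholds,
    GeneSubsetReport,
    SomaticCallSet,
    VariantClass,
    VariantRecord,
    apply_germline_filter,
    apply_site_filters,
    audit_records,
    call_somatic,
    compute_tmb,
    gene_mutation_matrix,
    gene_subset_report,
)

T = FilterThresholds()


def make_record(**kwargs):
    base = dict(
        patient_id="P01",
        chrom="chr1",
        pos=1000,
        ref="A",
        alt="T",
        variant_class=VariantClass.SNV,
        depth=200,
        call_quality=60.0,
        nc_fraction=0.01,
        strand_bias=-90.0,
        vaf=0.20,
        pop_maf_enf=None,
        gene="TP53",
        consequence=Consequence.NON_SYNONYMOUS,
    )
    base.update(kwargs)
    return VariantRecord(**base)


class TestRecordInvariants:
    def test_vaf_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_record(vaf=1.2)

    def test_snv_requires_single_bases(self):
        with pytest.raises(ValueError):
            make_record(ref="AT", alt="A", variant_class=VariantClass.SNV)


@pytest.mark.parametrize(
    "kwargs, expected_reasons",
    [
        # boundary conventions as printed: depth < 100 fails, 100 passes
        ({"depth": 99}, {FilterReason.LOW_DEPTH}),
        ({"depth": 100}, set()),
        ({"call_quality": 39.9}, {FilterReason.LOW_QUALITY}),
        ({"call_quality": 40.0}, set()),
        # NC >= 0.03 is inclusive
        ({"nc_fraction": 0.03}, {FilterReason.HIGH_NC}),
        ({"nc_fraction": 0.0299}, set()),
        # VAF < 0.05 strict: exactly 0.05 passes
        ({"vaf": 0.05}, set()),
        ({"vaf": 0.0499}, {FilterReason.LOW_VAF}),
        # strand bias > -80 fails; -80 itself passes
        ({"strand_bias": -80.0}, set()),
        ({"strand_bias": -79.9}, {FilterReason.STRAND_BIAS}),
        # multiple independent predicates accumulate
        (
            {"depth": 50, "vaf": 0.01},
            {FilterReason.LOW_DEPTH, FilterReason.LOW_VAF},
        ),
    ],
)
def test_site_filter_boundaries(kwargs, expected_reasons):
    (verdict,) = apply_site_filters([make_record(**kwargs)], T)
    assert set(verdict.reasons) == expected_reasons
    assert verdict.passed == (not expected_reasons)


def test_nc_filter_applies_to_snvs_only():
    indel = make_record(
        ref="AT", alt="A", variant_class=VariantClass.INDEL, nc_fraction=0.5,
        depth=200, call_quality=60, strand_bias=-90, vaf=0.2,
    )
    (verdict,) = apply_site_filters([indel], T)
    assert verdict.passed


def test_missing_strand_bias_fails_closed_with_warning():
    rec = make_record(strand_bias=None)
    with pytest.warns(UserWarning, match="strand-bias"):
        (verdict,) = apply_site_filters([rec], T)
    assert FilterReason.MISSING_METRIC in verdict.reasons
    open_t = FilterThresholds(fail_open_on_missing=True)
    (verdict,) = apply_site_filters([rec], open_t)
    assert verdict.passed


@pytest.mark.parametrize(
    "vaf, maf, always, excluded",
    [
        (0.50, 0.01, False, True),   # het window + positive MAF
        (0.50, None, False, False),  # absent from the population database
        (0.20, 0.01, False, False),  # MAF only excludes inside the windows
        (0.20, 0.01, True, True),    # unless MAF always excludes
        (0.40, 0.01, False, True),   # closed window bounds
        (0.60, 0.01, False, True),
        (0.80, 0.01, False, False),  # homozygous bound is strict
        (0.81, 0.01, False, True),
        (0.50, 0.0, False, False),   # MAF = 0 means not a polymorphism
    ],
)
def test_germline_filter(vaf, maf, always, excluded):
    t = FilterThresholds(maf_always_excludes=always)
    (verdict,) = apply_germline_filter([make_record(vaf=vaf, pop_maf_enf=maf)], t)
    assert (FilterReason.GERMLINE_VAF_MAF in verdict.reasons) == excluded


class TestCallSomatic:
    def test_indel_excluded_from_count(self):
        snv = make_record()
        indel = make_record(pos=2000, ref="AT", alt="A",
                            variant_class=VariantClass.INDEL)
        assert call_somatic([snv, indel]).n_somatic_snv == 1

    def test_empty_input(self):
        assert call_somatic([], patient_id="P01").n_somatic_snv == 0

    def test_germline_removed_from_clean_snvs(self):
        clean = [make_record(pos=1000 * i) for i in range(1, 6)]
        germ = [
            make_record(pos=1000 * i, vaf=0.5, pop_maf_enf=0.01)
            for i in range(6, 8)
        ]
        assert call_somatic(clean + germ).n_somatic_snv == 5
        assert call_somatic(clean[:3] + germ).n_somatic_snv == 3

    def test_nonsynonymous_toggle(self):
        t = FilterThresholds(count_only_nonsynonymous=True)
        syn = make_record(consequence=Consequence.SYNONYMOUS)
        non = make_record(pos=2000)
        assert call_somatic([syn, non], t).n_somatic_snv == 1

    def test_callset_rejects_non_snv(self):
        indel = make_record(ref="AT", alt="A", variant_class=VariantClass.INDEL)
        with pytest.raises(ValueError):
            SomaticCallSet(patient_id="P01", records=(indel,))


class TestTmb:
    @pytest.mark.parametrize("k, expected", [(0, 0.0), (2, 3.8), (8, 15.3)])
    def test_closed_form_matches_printed_values(self, k, expected):
        cs = SomaticCallSet(
            "P", tuple(make_record(pos=1000 * (i + 1)) for i in range(k))
        )
        res = compute_tmb(cs, panel_mb=0.524)
        assert res.tmb == pytest.approx(k / 0.524)
        assert round(res.tmb, 1) == expected

    def test_bad_panel_size(self):
        with pytest.raises(ValueError):
            compute_tmb(SomaticCallSet("P", ()), panel_mb=0.0)

    def test_monotone_in_snv_count(self):
        cs1 = SomaticCallSet("P", (make_record(),))
        cs2 = SomaticCallSet("P", (make_record(), make_record(pos=2000)))
        assert compute_tmb(cs2).tmb - compute_tmb(cs1).tmb == pytest.approx(1 / 0.524)


class TestGeneMutationMatrix:
    def test_single_patient_single_gene(self):
        cs = SomaticCallSet("P01", (make_record(gene="TP53"),))
        gm = gene_mutation_matrix([cs])
        assert gm.percent_patients["TP53"] == 100.0

    def test_percentage_over_cohort(self):
        sets = [SomaticCallSet(f"P{i:02d}", ()) for i in range(1, 10)]
        sets.append(SomaticCallSet("P10", (make_record(patient_id="P10"),)))
        gm = gene_mutation_matrix(sets)
        assert gm.percent_patients["TP53"] == pytest.approx(10.0)

    def test_boolean_cell_vs_total_count(self):
        cs = SomaticCallSet(
            "P01", (make_record(pos=1000), make_record(pos=2000))
        )
        gm = gene_mutation_matrix([cs])
        assert gm.matrix.loc["P01", "TP53"]
        assert gm.total_mutations["TP53"] == 2


class TestGeneSubsetReport:
    def test_disjoint_gene_list(self):
        rep = gene_subset_report({"P01": [make_record()]}, {"NOPE"})
        assert (rep.n_variants, rep.n_genes_affected) == (0, 0)
        assert (rep.per_patient == 0).all()

    def test_mean_over_patients(self):
        rep = gene_subset_report(
            {
                "P01": [make_record(pos=i) for i in (1, 2, 3)],
                "P02": [make_record(patient_id="P02")],
            },
            {"TP53"},
        )
        assert rep.mean == pytest.approx(2.0)
        assert rep.n_variants == 4
        assert rep.sd == pytest.approx(np.std([3, 1], ddof=1))

    def test_empty_gene_list_is_config_error(self):
        with pytest.raises(ValueError):
            gene_subset_report({}, set())


# -- properties ---------------------------------------------------------------

metric_params = hst.fixed_dictionaries(
    {
        "depth": hst.integers(min_value=0, max_value=300),
        "call_quality": hst.floats(0, 100, allow_nan=False),
        "nc_fraction": hst.floats(0, 0.2, allow_nan=False),
        "strand_bias": hst.floats(-200, 50, allow_nan=False),
        "vaf": hst.floats(0, 1, allow_nan=False),
        "pop_maf_enf": hst.one_of(hst.none(), hst.floats(0, 0.5, allow_nan=False)),
        "is_indel": hst.booleans(),
    }
)


def _build_records(params_list):
    records = []
    for i, p in enumerate(params_list):
        p = dict(p)
        indel = p.pop("is_indel")
        records.append(
            make_record(
                pos=1000 * (i + 1),
                variant_class=VariantClass.INDEL if indel else VariantClass.SNV,
                ref="AT" if indel else "A",
                alt="A" if indel else "T",
                **p,
            )
        )
    return records


@settings(max_examples=200, deadline=None)
@given(hst.lists(metric_params, max_size=20))
def test_audit_completeness(params_list):
    """Every record is either retained somatic or carries >= 1 reason."""
    records = _build_records(params_list)
    verdicts = audit_records(records, T)
    retained = {r.key for r in call_somatic(records, T, patient_id="P01").records}
    for v in verdicts:
        assert (v.record.key in retained) != bool(v.reasons)


@settings(max_examples=100, deadline=None)
@given(hst.lists(metric_params, max_size=15))
def test_cascade_commutes_with_joint_evaluation(params_list):
    """Site-then-germline equals jointly evaluated predicates."""
    records = [
        VariantRecord(
            **{
                **r.__dict__,
                "ref": "A",
                "alt": "T",
                "variant_class": VariantClass.SNV,
            }
        )
        for r in _build_records(params_list)
    ]
    staged = [
        r
        for r, sv in zip(records, apply_site_filters(records, T))
        if sv.passed
    ]
    staged = [
        r
        for r, gv in zip(staged, apply_germline_filter(staged, T))
        if gv.passed
    ]
    joint = [r for r in call_somatic(records, T, patient_id="P01").records]
    assert [r.key for r in staged] == [r.key for r in joint]
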