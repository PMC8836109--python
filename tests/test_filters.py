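"""Tier filters: boundary semantics, panel fractions, exhaustive oracles,
and threshold monotonicity."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famprio import (
    ExonicClass,
    FilterConfig,
    RegionClass,
    VariantRecord,
    cadd_filter,
    coding_filter,
    conservation_filter,
    deleteriousness_filter,
    frequency_filter,
    intolerance_filter,
    nonsynonymous_filter,
    qc_filter,
)
from famprio.model import (
    INTOLERANCE_SCORE_NAMES,
    MissingFrequencyPolicy,
    MissingScorePolicy,
    PREDICTORS,
)


def _v(**kwargs):
    base = dict(chrom="1", pos=100, ref="A", alt="G")
    base.update(kwargs)
    return VariantRecord(**base)


class TestQc:
    @pytest.mark.parametrize(
        "qual,depth,expected",
        [
            (21, 6, True),
            (20, 100, False),   # quality bound is strict
            (100, 5, False),    # coverage bound is strict
            (20.01, 6, True),
        ],
    )
    def test_strict_bounds(self, config, qual, depth, expected):
        assert qc_filter(_v(qual=qual, depth=depth), config).passed is expected


class TestFrequency:
    def test_rare_in_both_panels_passes(self, config):
        v = _v(maf_exac_nontcga=2.21e-4, maf_gnomad_nfe=3.33e-4,
               local_cohort_freq=0.01)
        assert frequency_filter(v, config).passed

    def test_all_missing_passes_under_treat_as_rare(self, config):
        assert frequency_filter(_v(), config).passed

    def test_all_missing_fails_under_drop(self):
        config = FilterConfig(missing_frequency_policy=MissingFrequencyPolicy.DROP)
        assert not frequency_filter(_v(), config).passed

    def test_common_variant_fails(self, config):
        assert not frequency_filter(_v(maf_1kg=0.5), config).passed

    def test_maf_boundary_inclusive(self, config):
        assert frequency_filter(_v(maf_1kg=0.001), config).passed
        assert not frequency_filter(_v(maf_1kg=0.0011), config).passed

    def test_local_frequency_strict(self, config):
        assert not frequency_filter(_v(local_cohort_freq=0.05), config).passed
        assert frequency_filter(_v(local_cohort_freq=0.049), config).passed


class TestRegionAndClassification:
    @pytest.mark.parametrize(
        "region,expected",
        [
            (RegionClass.EXONIC, True),
            (RegionClass.SPLICING, True),
            (RegionClass.INTERGENIC, False),
            (RegionClass.INTRONIC, False),
            (RegionClass.UTR, False),
        ],
    )
    def test_coding(self, region, expected):
        assert coding_filter(_v(region_class=region)).passed is expected

    @pytest.mark.parametrize(
        "cls,expected",
        [
            (ExonicClass.NONSYNONYMOUS_SNV, True),
            (ExonicClass.SYNONYMOUS_SNV, False),
            (ExonicClass.UNKNOWN, True),
            (ExonicClass.FRAMESHIFT_DELETION, True),
            (ExonicClass.STOPGAIN, True),
            (ExonicClass.NONFRAMESHIFT, False),
        ],
    )
    def test_nonsynonymous(self, cls, expected):
        assert nonsynonymous_filter(_v(exonic_classification=cls)).passed is expected


class TestCadd:
    @pytest.mark.parametrize(
        "cadd,expected",
        [(25.3, True), (10.0, True), (9.99, False), (None, False)],
    )
    def test_inclusive_threshold(self, config, cadd, expected):
        assert cadd_filter(_v(cadd_phred=cadd), config).passed is expected


class TestConservation:
    @pytest.mark.parametrize(
        "gerp,phylop,phastcons,expected,satisfied",
        [
            (4.14, 4.217, 1.0, True, 3),
            (2.33, 1.849, 1.0, True, 2),   # PhyloP below cutoff, 2 of 3 enough
            (0.0, 0.0, 0.0, False, 0),
            (2.0, 3.0, 0.3, True, 2),      # GERP/PhyloP inclusive, PhastCons strict
            (None, 4.0, 1.0, True, 2),     # missing counts as unsatisfied
            (None, None, 1.0, False, 1),
        ],
    )
    def test_two_of_three(self, config, gerp, phylop, phastcons, expected, satisfied):
        d = conservation_filter(
            _v(gerp=gerp, phylop=phylop, phastcons=phastcons), config
        )
        assert d.passed is expected
        assert d.detail["satisfied"] == satisfied
        assert d.detail["denominator"] == 3


def _intol_variant(states):
    """states: 5-tuple over {'f','u','m'} for the intolerance panel members
    (three ratio scores, Z, pLI)."""
    value = {"f": -1.0, "u": 0.5, "m": None}
    scores = {name: value[s] for name, s in zip(INTOLERANCE_SCORE_NAMES, states[:3])}
    z = {"f": 1.0, "u": -1.0, "m": None}[states[3]]
    pli = {"f": 0.95, "u": 0.1, "m": None}[states[4]]
    return _v(intolerance_scores=scores, z_score=z, pli=pli)


class TestIntolerance:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ("fffff", True),    # 5/5 = 100%
            ("fffuu", True),    # 3/5 = 60%, inclusive boundary
            ("ffuuu", False),   # 2/5 = 40%
            ("ffumm", True),    # 2/3 of available
            ("mmmmm", False),   # empty panel fails closed
        ],
    )
    def test_fractions(self, config, states, expected):
        assert intolerance_filter(_intol_variant(states), config).passed is expected

    def test_exhaustive_against_counting_oracle(self, config):
        """All 3^5 {favorable, unfavorable, missing} panels agree with a
        direct count over available members."""
        for states in itertools.product("fum", repeat=5):
            d = intolerance_filter(_intol_variant(states), config)
            fav = states.count("f")
            avail = 5 - states.count("m")
            expected = avail > 0 and fav / avail >= 0.6
            assert d.passed is expected, states
            assert (d.detail["favorable"], d.detail["available"]) == (fav, avail)

    def test_count_unfavorable_policy_uses_full_panel(self):
        config = FilterConfig(missing_score_policy=MissingScorePolicy.COUNT_UNFAVORABLE)
        # 3 favorable of 3 available, but 3/5 of the full panel = 60% still passes
        assert intolerance_filter(_intol_variant("fffmm"), config).passed
        # 2 favorable: 2/5 = 40% fails even though 2/2 available
        assert not intolerance_filter(_intol_variant("ffmmm"), config).passed


def _panel_variant(flags):
    """flags: 12-tuple over {'f','u','m'} aligned with PREDICTORS."""
    fav = {"SIFT": "D", "Polyphen2_HumDiv": "D", "Polyphen2_HumVar": "P",
           "LRT": "D", "MutationTaster": "A", "MutationAssessor": "H",
           "FATHMM": "D", "MetaSVM": "D", "MetaLR": "D", "VEST3": 0.9,
           "PROVEAN": "D", "ReliabilityIndex": 9.0}
    unf = {"SIFT": "T", "Polyphen2_HumDiv": "B", "Polyphen2_HumVar": "B",
           "LRT": "N", "MutationTaster": "N", "MutationAssessor": "L",
           "FATHMM": "T", "MetaSVM": "T", "MetaLR": "T", "VEST3": 0.1,
           "PROVEAN": "N", "ReliabilityIndex": 2.0}
    panel = {}
    for name, flag in zip(PREDICTORS, flags):
        panel[name] = {"f": fav[name], "u": unf[name], "m": None}[flag]
    return _v(deleteriousness_panel=panel)


class TestDeleteriousness:
    @pytest.mark.parametrize(
        "n_fav,n_present,expected",
        [
            (8, 12, True),    # 66.67%
            (12, 12, True),   # 100%
            (6, 12, False),   # 50%
            (5, 6, True),     # 83.33% of a reduced denominator
            (0, 0, False),    # empty panel fails closed
        ],
    )
    def test_fractions(self, config, n_fav, n_present, expected):
        flags = "f" * n_fav + "u" * (n_present - n_fav) + "m" * (12 - n_present)
        d = deleteriousness_filter(_panel_variant(flags), config)
        assert d.passed is expected
        assert d.detail["favorable"] == n_fav
        assert d.detail["denominator"] == n_present

    def test_exhaustive_against_counting_oracle(self, config):
        """All 2^12 favorable/unfavorable panels agree with a direct count."""
        for bits in itertools.product("fu", repeat=12):
            d = deleteriousness_filter(_panel_variant(bits), config)
            fav = bits.count("f")
            assert d.passed is (fav / 12 >= 0.6), bits

    def test_unknown_code_treated_unfavorable(self, config):
        v = _panel_variant("f" * 12)
        v.deleteriousness_panel["SIFT"] = "Q"  # not a known code
        d = deleteriousness_filter(v, config)
        assert d.detail["favorable"] == 11 and d.passed


def test_bundled_candidates_pass_all_score_filters(config, by_gene):
    """Every bundled candidate passes the CADD, conservation, intolerance and
    deleteriousness filters under default thresholds; the C2orf42 row passes
    conservation via exactly 2 of 3 scores and GNA13 sits exactly on the 60%
    intolerance boundary."""
    for gene, v in by_gene.items():
        assert cadd_filter(v, config).passed, gene
        assert conservation_filter(v, config).passed, gene
        assert intolerance_filter(v, config).passed, gene
        assert deleteriousness_filter(v, config).passed, gene
    c2 = conservation_filter(by_gene["C2orf42"], config)
    assert c2.detail["satisfied"] == 2
    gna = intolerance_filter(by_gene["GNA13"], config).detail
    assert gna["favorable"] / gna["denominator"] == pytest.approx(0.6)


_score = st.one_of(st.none(), st.floats(-10, 10, allow_nan=False))


@settings(deadline=None, max_examples=150, derandomize=True)
@given(
    cadd=st.one_of(st.none(), st.floats(0, 60)),
    gerp=_score, phylop=_score,
    phastcons=st.one_of(st.none(), st.floats(0, 1)),
    tighten=st.floats(0, 5),
)
def test_tightening_thresholds_never_admits_more(cadd, gerp, phylop, phastcons,
                                                 tighten):
    """Raising any score cutoff can only remove variants, never add them."""
    v = _v(cadd_phred=cadd, gerp=gerp, phylop=phylop, phastcons=phastcons)
    loose = FilterConfig()
    tight = FilterConfig(
        cadd_min=loose.cadd_min + tighten,
        gerp_min=loose.gerp_min + tighten,
        phylop_min=loose.phylop_min + tighten,
        phastcons_min=min(1.0, loose.phastcons_min + tighten / 10),
    )
    for f in (cadd_filter, conservation_filter):
        if f(v, tight).passed:
            assert f(v, loose).passed
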