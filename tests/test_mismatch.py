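"""Mismatch profiling, binding-site location and risk classification.

The profiler's independent oracle is brute force: a degenerate primer
denotes a set of concrete sequences, and the profile total must equal
the minimum Hamming distance between the region and any expansion.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minicoi.alphabet import ALPHABET, allowed_bases
from minicoi.mismatch import (
    MismatchProfile,
    PositionCall,
    RiskLevel,
    TemplateRegion,
    classify_risk,
    locate_binding_site,
    profile_mismatches,
    profile_reverse,
)
from minicoi.primers import DegeneratePrimer, get_primer
from minicoi.synthetic import random_region


def brute_force_min_distance(primer_seq: str, region: str) -> int:
    """Minimum Hamming distance over all concrete expansions of the primer."""
    best = len(primer_seq) + 1
    pools = [sorted(allowed_bases(c)) for c in primer_seq]
    for expansion in itertools.product(*pools):
        d = sum(1 for a, b in zip(expansion, region) if a != b)
        best = min(best, d)
    return best


primer_strategy = st.text(alphabet=sorted(ALPHABET), min_size=4, max_size=12).filter(
    lambda s: int(np.prod([len(allowed_bases(c)) for c in s])) <= 2**12
)
concrete = st.text(alphabet="ACGT", min_size=4, max_size=12)


@given(st.data())
@settings(max_examples=60)
def test_profile_total_equals_bruteforce_expansion_minimum(data):
    pseq = data.draw(primer_strategy)
    region = data.draw(st.text(alphabet="ACGT", min_size=len(pseq), max_size=len(pseq)))
    primer = DegeneratePrimer("probe", pseq, "forward")
    prof = profile_mismatches(primer, TemplateRegion("r", region))
    assert prof.total == brute_force_min_distance(pseq, region)


def test_profile_against_own_expansion_is_zero(ml):
    # any concrete expansion of the primer matches it perfectly
    expansion = "".join(sorted(allowed_bases(c))[0] for c in ml.sequence)
    prof = profile_mismatches(ml, TemplateRegion("self", expansion))
    assert prof.total == 0


def test_profile_contract_checks(ml):
    with pytest.raises(ValueError, match="length"):
        profile_mismatches(ml, TemplateRegion("short", "ACGT"))
    partial = TemplateRegion("p", "", covered="partial")
    with pytest.raises(ValueError, match="cover"):
        profile_mismatches(ml, partial)


def test_ambiguous_template_positions_flagged(ml):
    expansion = "".join(sorted(allowed_bases(c))[0] for c in ml.sequence)
    region = TemplateRegion("n", "N" + expansion[1:])
    prof = profile_mismatches(ml, region)
    assert prof.total == 0
    assert prof.ambiguous_positions == (1,)
    assert prof.per_position[0] is PositionCall.AMBIGUOUS_TEMPLATE


class TestLocator:
    def test_planted_site_recovered(self, ml):
        rng = np.random.default_rng(0)
        flank = "".join(rng.choice(list("ACGT"), 10))
        site = "".join(sorted(allowed_bases(c))[-1] for c in ml.sequence)
        tail = "".join(rng.choice(list("ACGT"), 30))
        region = locate_binding_site(flank + site + tail, ml)
        assert (region.start, region.best_score, region.covered) == (10, 0, "full")

    def test_fixture_region_as_own_template(self, ml, all_fixture_regions):
        reg = all_fixture_regions[0]
        found = locate_binding_site(reg.bases, ml)
        assert found.start == 0 and found.covered == "full"

    def test_score_equals_sliding_window_minimum(self, ml):
        rng = np.random.default_rng(42)
        template = "".join(rng.choice(list("ACGT"), 500))
        planted = random_region(ml, 3, seed=5).bases
        template = template[:200] + planted + template[200 + 26:]
        found = locate_binding_site(template, ml)
        # exhaustive oracle
        scores = [
            profile_mismatches(ml, TemplateRegion("w", template[s : s + 26])).total
            for s in range(len(template) - 25)
        ]
        assert found.best_score == min(scores)
        assert found.start == scores.index(min(scores))

    def test_hopeless_template_reported_not_guessed(self, ml):
        found = locate_binding_site("A" * 100, ml, max_scan_mismatches=3)
        assert found.covered == "none"
        assert found.best_score is not None and found.best_score > 3

    def test_short_template_partial(self, ml):
        assert locate_binding_site("ACGT", ml).covered == "partial"

    def test_empty_template_rejected(self, ml):
        with pytest.raises(ValueError, match="empty"):
            locate_binding_site("", ml)


class TestReverse:
    def test_exact_target_scores_zero(self):
        jg = get_primer("jgHCO2198")
        region = random_region(jg, 0, seed=1)
        # coding strand carries the reverse complement of the binding strand
        from minicoi.alphabet import reverse_complement

        template = "GGCC" * 10 + reverse_complement(region.bases) + "TTAA" * 10
        prof = profile_reverse(jg, template)
        assert isinstance(prof, MismatchProfile) and prof.total == 0

    def test_planted_substitution_maps_to_primer_coordinate(self):
        from minicoi.alphabet import reverse_complement

        jg = get_primer("jgHCO2198")
        binding = list(random_region(jg, 0, seed=2).bases)
        # choose a non-degenerate primer position and break it
        k = next(
            i for i, c in enumerate(jg.sequence) if len(allowed_bases(c)) == 1
        )
        binding[k] = sorted(set("ACGT") - allowed_bases(jg.sequence[k]))[0]
        template = "GG" * 20 + reverse_complement("".join(binding)) + "CC" * 20
        prof = profile_reverse(jg, template)
        assert prof.mismatch_positions == (k + 1,)

    def test_jg_matches_hco_target(self):
        # jgHCO2198's ambiguity sets contain HCO2198 at every position
        from minicoi.alphabet import reverse_complement

        hco, jg = get_primer("HCO2198"), get_primer("jgHCO2198")
        template = reverse_complement(hco.sequence)
        prof = profile_reverse(jg, template)
        assert prof.total == 0

    def test_uncovered_region_returned_not_raised(self):
        jg = get_primer("jgHCO2198")
        out = profile_reverse(jg, "ACGT")
        assert out.covered == "partial"

    def test_forward_primer_rejected(self, ml):
        with pytest.raises(ValueError, match="reverse"):
            profile_reverse(ml, "ACGT" * 20)


def _profile(positions, length=26):
    calls = [
        PositionCall.MISMATCH if i + 1 in positions else PositionCall.MATCH
        for i in range(length)
    ]
    return MismatchProfile(
        primer_name="p", template_id="t",
        per_position=tuple(calls), mismatch_positions=tuple(sorted(positions)),
    )


class TestRisk:
    @pytest.mark.parametrize(
        "positions,level",
        [
            ((), RiskLevel.NEGLIGIBLE),
            ((5,), RiskLevel.REDUCED),
            ((5, 9), RiskLevel.REDUCED),
            ((5, 9, 14), RiskLevel.SEVERE),
            ((26,), RiskLevel.SEVERE),  # lone 3'-terminal mismatch
            ((5, 9, 24), RiskLevel.FAILURE_LIKELY),
            ((5, 9, 14, 20), RiskLevel.FAILURE_LIKELY),  # 4 internal
            ((3, 6, 9, 12, 18, 24), RiskLevel.FAILURE_LIKELY),
        ],
    )
    def test_levels(self, positions, level):
        assert classify_risk(_profile(positions)).level is level

    def test_rationale_cites_rule(self):
        cat = classify_risk(_profile((5, 9)))
        assert "1/10" in cat.rationale
        cat = classify_risk(_profile((5, 9, 14, 20)))
        assert "four or more" in cat.rationale

    @given(
        st.sets(st.integers(min_value=1, max_value=26), max_size=8),
        st.integers(min_value=1, max_value=26),
    )
    def test_adding_a_mismatch_never_lowers_risk(self, positions, extra):
        before = classify_risk(_profile(tuple(positions))).level
        after = classify_risk(_profile(tuple(positions | {extra}))).level
        assert after >= before
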