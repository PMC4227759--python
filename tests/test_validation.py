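"""Constraint validation: identity screening, repeats, overhang fidelity, frames.

The longest-common-substring production path (binary search over k-mer
sets) is checked for exact agreement with an independent quadratic
dynamic-programming oracle.
"""

import random

import numpy as np
import pytest

from paperclip.assembly import AssemblyElement, plan_assembly
from paperclip.clip_design import Part
from paperclip.clip_ligation import LigationWorksheet
from paperclip.fixtures import TOY1, TOY2, PlantSpec, generate_fixture_parts, toy_parts
from paperclip.seqcore import NucSeq, reverse_complement
from paperclip.validation import (
    ValidationReport,
    check_identical_regions,
    check_overhang_fidelity,
    check_reading_frame,
    check_repeated_parts,
    longest_common_substring,
    longest_internal_repeat,
    validate_design,
)
from paperclip.assembly import AssemblyPlan


def lcs_dp(a: str, b: str) -> int:
    """Independent O(nm) dynamic-programming longest-common-substring oracle."""
    if not a or not b:
        return 0
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    best = 0
    for ch in a.encode():
        cur = np.zeros_like(prev)
        match = b_arr == ch
        cur[1:][match] = prev[:-1][match] + 1
        best = max(best, int(cur.max()))
        prev = cur
    return best


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def bare_plan(library, elements):
    """An AssemblyPlan shell for validation checks that must see inputs
    plan_assembly itself would reject (e.g. duplicated parts)."""
    return AssemblyPlan(
        elements=tuple(elements),
        junctions=(),
        worksheet=LigationWorksheet(()),
        library=dict(library),
    )


class TestLongestCommonSubstring:
    def test_agrees_with_dp_oracle_on_random_pairs(self):
        rng = random.Random(0)
        for _ in range(60):
            a = rand_seq(rng, rng.randint(1, 300))
            b = rand_seq(rng, rng.randint(1, 300))
            k, pa, pb = longest_common_substring(a, b)
            assert k == lcs_dp(a, b)
            if k:
                assert a[pa - 1 : pa - 1 + k] == b[pb - 1 : pb - 1 + k]

    def test_agrees_with_dp_on_planted_regions(self):
        rng = random.Random(1)
        for planted_len in (10, 40, 41, 80):
            a = rand_seq(rng, 300)
            b = rand_seq(rng, 300)
            region = rand_seq(rng, planted_len)
            a = a[:100] + region + a[100 + planted_len :]
            b = b[:50] + region + b[50 + planted_len :]
            k, *_ = longest_common_substring(a, b)
            assert k == lcs_dp(a, b)
            assert k >= planted_len

    def test_internal_repeat_detection(self):
        rng = random.Random(2)
        s = rand_seq(rng, 300)
        repeat = rand_seq(rng, 45)
        s = s[:30] + repeat + s[75:150] + repeat + s[195:]
        k, pa, pb = longest_internal_repeat(s)
        assert k >= 45
        assert pa != pb
        assert s[pa - 1 : pa - 1 + k] == s[pb - 1 : pb - 1 + k]


class TestIdenticalRegions:
    @pytest.mark.parametrize("planted,expect_error", [(40, False), (41, True)])
    def test_threshold_is_boundary_exact(self, planted, expect_error):
        """Exactly 40 shared bases pass; 41 fail ('more than 40')."""
        lib = generate_fixture_parts(
            2, (500, 500), seed=5, planted=PlantSpec(shared_region_len=planted)
        )
        plan = bare_plan(lib, [AssemblyElement(p) for p in lib])
        findings = check_identical_regions(plan)
        errors = [f for f in findings if f.severity == "error"]
        if expect_error:
            assert len(errors) == 1
            assert errors[0].measured == 41
        else:
            assert not errors

    def test_internal_direct_repeat_flagged(self):
        rng = random.Random(8)
        repeat = rand_seq(rng, 45)
        seq = rand_seq(rng, 120) + repeat + rand_seq(rng, 100) + repeat + rand_seq(rng, 60)
        lib = {"rep": Part("rep", NucSeq(seq))}
        plan = bare_plan(lib, [AssemblyElement("rep")])
        findings = check_identical_regions(plan)
        assert any(
            f.code == "identical_region" and f.severity == "error" and f.measured >= 45
            for f in findings
        )

    def test_reverse_complement_identity_detected(self):
        """A part and its flipped copy are >40 nt identical on opposite strands."""
        lib = {
            "A": Part("A", TOY1, allow_flip=True),
            "B": Part("B", reverse_complement(TOY1)),
        }
        plan = bare_plan(lib, [AssemblyElement("A"), AssemblyElement("B")])
        findings = check_identical_regions(plan)
        assert any(f.severity == "error" and f.measured == 60 for f in findings)


class TestRepeatedParts:
    def test_duplicate_part_is_error(self, toy_library):
        plan = bare_plan(
            toy_library,
            [AssemblyElement("TOY1"), AssemblyElement("TOY2"), AssemblyElement("TOY1")],
        )
        findings = check_repeated_parts(plan)
        assert len(findings) == 1
        assert findings[0].severity == "error"

    def test_clean_plan_has_no_findings(self, three_element_plan):
        assert check_repeated_parts(three_element_plan) == []

    def test_flipped_duplicate_still_error_with_note(self):
        lib = {"TOY1": Part("TOY1", TOY1, allow_flip=True), "TOY2": Part("TOY2", TOY2)}
        plan = bare_plan(
            lib,
            [AssemblyElement("TOY1"), AssemblyElement("TOY2"), AssemblyElement("TOY1", flipped=True)],
        )
        findings = check_repeated_parts(plan)
        assert len(findings) == 1
        assert "flipped" in findings[0].message


class TestOverhangFidelity:
    def test_toy2_after_trimming_clean(self, toy_library):
        plan = bare_plan(toy_library, [AssemblyElement("TOY1"), AssemblyElement("TOY2")])
        findings = check_overhang_fidelity(plan)
        assert not [f for f in findings if f.severity == "error"]

    def test_seam_valued_upstream_internal_overhang_warns(self):
        # bases 38-40 == GGC
        rng = random.Random(4)
        seq = rand_seq(rng, 37) + "GGC" + rand_seq(rng, 40)
        if seq[-40:][:3] in ("GCC", "GGC"):
            seq = seq[:-40] + "TCA" + seq[-37:]
        lib = {"X": Part("X", NucSeq(seq)), "TOY1": Part("TOY1", TOY1)}
        plan = bare_plan(lib, [AssemblyElement("X"), AssemblyElement("TOY1")])
        findings = check_overhang_fidelity(plan)
        assert any(f.code == "seam_internal_overhang_upstream" for f in findings)

    def test_complementary_internal_overhangs_warn(self):
        # downstream internal overhang of part X = TCA; upstream internal of
        # part Y = TGA = rc(TCA); they share a ligation tube in X->Y order
        rng = random.Random(6)
        x = rand_seq(rng, 60) + "TCA" + rand_seq(rng, 37)
        y_head = rand_seq(rng, 37) + "TGA"
        y = y_head + rand_seq(rng, 50)
        if x[-40:][:3] in ("GCC", "GGC"):
            x = x[:-40] + "TCA" + x[-37:]
        if y[-40:][:3] in ("GCC", "GGC"):
            y = y[:-40] + "TCA" + y[-37:]
        lib = {"X": Part("X", NucSeq(x)), "Y": Part("Y", NucSeq(y))}
        plan = bare_plan(lib, [AssemblyElement("X"), AssemblyElement("Y")])
        findings = check_overhang_fidelity(plan)
        assert any(f.code == "complementary_internal_overhangs" for f in findings)


class TestReadingFrame:
    def _cds_plan(self, len_a, len_b, seed=0):
        rng = random.Random(seed)

        def cds(n):
            return rand_seq(rng, n)

        lib = {
            "A": Part("A", NucSeq(cds(len_a)), is_cds=True),
            "B": Part("B", NucSeq(cds(len_b)), is_cds=True),
            "bb": Part("bb", NucSeq(cds(100))),
        }
        return bare_plan(lib, [AssemblyElement("bb"), AssemblyElement("A"), AssemblyElement("B")])

    def test_in_frame_seam_inserts_alanine(self):
        findings = check_reading_frame(self._cds_plan(60, 44))
        info = [f for f in findings if f.code == "seam_codon_inserted"]
        assert len(info) == 1
        assert "A (GCC)" in info[0].message

    def test_out_of_frame_upstream_cds_warns(self):
        findings = check_reading_frame(self._cds_plan(44, 60))
        assert any(f.code == "seam_frame_shift" and f.measured == 44 for f in findings)

    def test_tag_seam_orientation_is_stop(self):
        from paperclip.seqcore import SeamSpec

        plan = self._cds_plan(60, 44)
        tag_plan = AssemblyPlan(
            elements=plan.elements,
            junctions=(),
            worksheet=LigationWorksheet(()),
            library=plan.library,
            seam=SeamSpec(NucSeq("TAG"), "custom"),
        )
        findings = check_reading_frame(tag_plan)
        assert any(f.code == "seam_stop_codon" for f in findings)

    def test_cta_seam_inserts_leucine(self):
        from paperclip.seqcore import BRICKCLIP_SEAM

        plan = self._cds_plan(60, 44)
        cta_plan = AssemblyPlan(
            elements=plan.elements,
            junctions=(),
            worksheet=LigationWorksheet(()),
            library=plan.library,
            seam=BRICKCLIP_SEAM,
        )
        findings = check_reading_frame(cta_plan)
        info = [f for f in findings if f.code == "seam_codon_inserted"]
        assert len(info) == 1 and "L (CTA)" in info[0].message


class TestValidateDesign:
    def test_clean_plan_passes(self, three_element_plan):
        report = validate_design(three_element_plan)
        assert report.passed
        assert all(f.severity != "error" for f in report.findings)

    def test_planted_41mer_fails(self):
        lib = generate_fixture_parts(
            3, (500, 500), seed=9, planted=PlantSpec(shared_region_len=41)
        )
        plan = plan_assembly(lib, [AssemblyElement(p) for p in lib])
        report = validate_design(plan)
        assert not report.passed

    def test_report_is_deterministic(self, three_element_plan):
        a = validate_design(three_element_plan)
        b = validate_design(three_element_plan)
        assert a == b

    def test_report_json_roundtrip(self):
        lib = generate_fixture_parts(
            2, (500, 500), seed=5, planted=PlantSpec(shared_region_len=41)
        )
        plan = plan_assembly(lib, [AssemblyElement(p) for p in lib])
        report = validate_design(plan)
        assert ValidationReport.from_json(report.to_json()) == report
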