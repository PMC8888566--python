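"""Reporter insert design: disruption placement, translation switch, panels."""

import dataclasses

import numpy as np
import pytest

from fluopeer.edit_sim import simulate_prime_edit
from fluopeer.fixtures import gen_random_target
from fluopeer.pam_scan import SpacerSite, find_spacer_sites
from fluopeer.pegrna_design import PegRNA, design_pegrnas
from fluopeer.pipeline import design_for_edit
from fluopeer.profiles import ABE8E, SPRY_PE2
from fluopeer.reporter_design import (
    DesignFailure,
    DisruptionSpec,
    ReporterConstruct,
    ReporterInsert,
    design_base_edit_reporter,
    design_reporter_insert,
    emit_insert_oligos,
    pam_variant_panel,
    six_frame_stop_verdicts,
    verify_reporter,
)
from fluopeer.seqcore import (
    EditSpec,
    SequenceError,
    apply_edit,
    find_stop_codons,
    reverse_complement,
    translate_frame,
)


class TestDesignReporterInsert:
    def test_added_frameshift_for_plain_substitution(self, designed_bundle):
        target, edit, bundle = designed_bundle
        insert = bundle.insert
        assert insert.disruption.kind == "added_frameshift"
        assert len(insert.disruption.bases) == 1
        assert len(insert.pre_edit_seq) % 3 == 1
        assert len(insert.post_edit_seq) % 3 == 0
        assert 45 <= len(insert.pre_edit_seq) <= 100

    def test_native_frameshift_for_frame_shifting_deletion(self):
        for seed in range(120, 160):
            target, edit = gen_random_target(seed, 200, 0.5)
            if edit.kind != "deletion" or len(edit.ref) % 3 == 0:
                continue
            try:
                bundle = design_for_edit(target, edit)
            except (SequenceError, DesignFailure):
                continue
            assert bundle.insert.disruption.kind == "native_frameshift"
            assert len(bundle.insert.pre_edit_seq) % 3 != 0
            return
        pytest.fail("no frame-shifting deletion produced a design")

    def test_native_stop_when_edit_corrects_nonsense_mutation(self):
        # plant a TAG stop whose middle A is corrected to G by the edit
        rng = np.random.default_rng(5)
        for _ in range(30):
            bases = "".join(rng.choice(list("ACGT"), size=200))
            c = 99  # stop codon at a multiple-of-3 boundary candidates will hit
            seq = bases[:c] + "TAG" + bases[c + 3:]
            edit = EditSpec("substitution", c + 2, "A", "G")
            try:
                bundle = design_for_edit(seq, edit)
            except (SequenceError, DesignFailure):
                continue
            ins = bundle.insert
            if ins.disruption.kind != "native_stop":
                continue
            assert "*" in translate_frame(ins.pre_edit_seq, 0, "+")
            assert "*" not in translate_frame(ins.post_edit_seq, 0, "+")
            return
        pytest.fail("no nonsense-correction target produced a native_stop design")

    def test_stop_dense_target_raises_design_failure_with_report(self):
        # every >=45-nt window of a TAAC repeat carries an in-frame stop in
        # any frame; only the island around the protospacer is stop-free
        island = "GCTTGCCAGTCACGTCCTGCCGG"
        sea = "TAAC" * 60
        seq = sea[:100] + island + sea[100:]
        # edit one base downstream of the island nick (0-based 117)
        edit = EditSpec("substitution", 120, seq[119], "A" if seq[119] != "A" else "T")
        site = next(
            s for s in find_spacer_sites(seq, edit, SPRY_PE2) if s.spacer == island[:20]
        )
        cands = design_pegrnas(seq, edit, site)
        peg = cands[0] if cands else PegRNA(
            site=site, spacer=site.spacer,
            pbs=reverse_complement(seq[site.nick_position - 11:site.nick_position - 1]),
            rtt=reverse_complement(apply_edit(seq, edit)[site.nick_position - 1:site.nick_position + 12]),
        )
        with pytest.raises(DesignFailure) as err:
            design_reporter_insert(seq, edit, peg)
        assert err.value.report  # per-candidate constraint report

    def test_window_covers_pegrna_footprint(self, designed_bundle):
        target, edit, bundle = designed_bundle
        ins, peg = bundle.insert, bundle.peg
        n = len(target)
        s, nick = peg.site.oriented_coords(n)
        lo = min(s, nick - peg.pbs_len)
        hi = max(s + 20 + len(peg.site.pam), nick + peg.rtt_len)
        if ins.orientation == "+":
            w0, w1 = ins.window[0] - 1, ins.window[1]
        else:
            w0, w1 = n - ins.window[1], n - ins.window[0] + 1
        assert w0 <= lo and hi <= w1


class TestVerifyReporter:
    def test_designed_insert_switches_cherry_on(self, designed_bundle):
        _, _, bundle = designed_bundle
        pre, post = verify_reporter(bundle.insert)
        assert pre.gfp_expressed and post.gfp_expressed
        assert not pre.cherry_expressed and post.cherry_expressed

    def test_disruption_removed_insert_is_rejected(self, designed_bundle):
        _, _, bundle = designed_bundle
        broken = dataclasses.replace(
            bundle.insert, pre_edit_seq=bundle.insert.post_edit_seq
        )
        with pytest.raises(SequenceError):
            verify_reporter(broken)

    def test_undersized_insert_rejected(self, designed_bundle):
        _, _, bundle = designed_bundle
        tiny = dataclasses.replace(
            bundle.insert,
            pre_edit_seq=bundle.insert.pre_edit_seq[:20],
            post_edit_seq=bundle.insert.post_edit_seq[:21],
        )
        with pytest.raises(SequenceError, match="length"):
            verify_reporter(tiny)

    def test_frameshift_blocks_cherry_even_without_stop(self):
        # a stop-free out-of-frame insert must still keep Cherry off
        insert = "GCT" * 20 + "G"
        construct = ReporterConstruct.from_insert_seq(insert)
        assert construct.gfp_expressed and not construct.cherry_expressed


class TestInsertOligos:
    def test_worked_example(self):
        top, bottom = emit_insert_oligos("ATGAAA")
        assert top == "TCGACCATGAAAG"
        assert bottom == "GTACCTTTCATGG"
        assert bottom[4:] == reverse_complement(top[4:])

    def test_annealing_identity_for_designed_insert(self, designed_bundle):
        _, _, bundle = designed_bundle
        top, bottom = emit_insert_oligos(bundle.insert)
        assert top == "TCGACC" + bundle.insert.pre_edit_seq + "G"
        assert bottom[4:] == reverse_complement(top[4:])


class TestBaseEditReporter:
    @staticmethod
    def _nonsense_target(seed, codon_start=61):
        """Target where TAG in the codon_start frame is resolved by A->G."""
        rng = np.random.default_rng(seed)
        bases = "".join(rng.choice(list("ACGT"), size=150))
        c = codon_start
        t = bases[:c] + "TAG" + bases[c + 3:]
        edit = EditSpec("substitution", c + 2, "A", "G")
        a = c + 1
        s = a - 4  # edited base at protospacer position 5
        t = t[:s + 20] + "AGG" + t[s + 23:]
        return t, edit

    def test_shifted_frame_selected_and_cherry_switches(self):
        for seed in range(40, 70):
            t, edit = self._nonsense_target(seed)
            try:
                ins = design_base_edit_reporter(t, edit, ABE8E)
            except DesignFailure:
                continue
            # codon_start % 3 == 1: the stop sits in a +1-shifted frame
            assert (ins.orientation, ins.frame_offset) == ("+", 1)
            assert ins.disruption.kind == "native_stop"
            pre, post = verify_reporter(ins)
            assert not pre.cherry_expressed and post.cherry_expressed
            return
        pytest.fail("no base-edit reporter designed across seeds")

    def test_six_frame_verdicts_on_toy(self):
        pre = "AATAGAA"
        post = apply_edit(pre, EditSpec("substitution", 4, "A", "G"))
        v = six_frame_stop_verdicts(pre, post, 3)
        assert len(v) == 6
        assert v[("+", 2)] is True  # TAG starts at 0-based index 2
        assert sum(v.values()) == 1

    def test_edit_without_stop_resolution_reports_all_six_frames(self):
        rng = np.random.default_rng(9)
        # stop-free neighbourhood: the A>G edit cannot resolve any stop
        t = ("GCC" * 60)
        t = t[:80] + "A" + t[81:]
        edit = EditSpec("substitution", 81, "A", "G")
        with pytest.raises(DesignFailure) as err:
            design_base_edit_reporter(t, edit, ABE8E)
        joined = " ".join(err.value.report)
        if "no stop-resolving frame" in joined:
            for frame in ("(+0)", "(+1)", "(+2)", "(-0)", "(-1)", "(-2)"):
                assert frame in joined

    def test_non_conversion_edit_rejected(self):
        t, edit = self._nonsense_target(40)
        with pytest.raises(SequenceError, match="conversion"):
            design_base_edit_reporter(t, EditSpec("substitution", edit.position, "A", "C"), ABE8E)


class TestPamVariantPanel:
    def test_two_variable_positions_give_sixteen_variants(self, designed_bundle):
        _, _, bundle = designed_bundle
        panel = pam_variant_panel(bundle.insert, "NGNN", [2, 4])
        assert len(panel) == 16
        assert len({v.pre_edit_seq for v in panel}) == 16

    def test_zero_variable_positions_is_identity_sized(self, designed_bundle):
        _, _, bundle = designed_bundle
        panel = pam_variant_panel(bundle.insert, "NNN", [])
        assert len(panel) == 1

    def test_three_variable_positions_give_64_distinct(self, designed_bundle):
        _, _, bundle = designed_bundle
        panel = pam_variant_panel(bundle.insert, "NNNN", [1, 2, 3])
        assert len(panel) == 64
        assert len({v.pre_edit_seq for v in panel}) == 64

    def test_variable_position_outside_template_rejected(self, designed_bundle):
        _, _, bundle = designed_bundle
        with pytest.raises(IndexError):
            pam_variant_panel(bundle.insert, "NGG", [5])
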