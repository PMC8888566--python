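"""pegRNA enumeration, nicking guides, mismatch counting, Golden Gate oligos."""

import pytest

from fluopeer.edit_sim import golden_gate_chain, simulate_prime_edit
from fluopeer.fixtures import gen_random_target
from fluopeer.pam_scan import ScanConfig, find_spacer_sites
from fluopeer.pegrna_design import (
    DesignConstraints,
    GoldenGateAcceptor,
    NickingGuide,
    PegRNA,
    design_nicking_guides,
    design_pegrnas,
    emit_pegrna_oligos,
    rtt_mismatch_count,
    validate_nicking_guide,
)
from fluopeer.profiles import SPRY_PE2
from fluopeer.seqcore import EditSpec, SequenceError, apply_edit, reverse_complement


def _site_with_distance(target, edit, d, profile=SPRY_PE2, config=None):
    sites = find_spacer_sites(str(target), edit, profile, config)
    for s in sites:
        if s.nick_to_edit == d:
            return s
    raise AssertionError(f"no site at nick distance {d}")


class TestDesignPegrnas:
    def test_enumeration_matches_independent_filter_oracle(self):
        target, edit = gen_random_target(77, 200, 0.7)  # GC-rich
        if edit.kind != "substitution":
            edit = EditSpec("substitution", edit.position, str(target)[edit.position - 1],
                            "A" if str(target)[edit.position - 1] != "A" else "C")
        site = _site_with_distance(target, edit, 3)
        cands = design_pegrnas(str(target), edit, site)
        assert cands.n_raw_pairs == 7 * 11  # PBS 9-15 x RTT 10-20

        # oracle: apply the documented filters independently on the raw grid
        n = len(target)
        oriented = str(target) if site.strand == "+" else reverse_complement(str(target))
        _, nick = site.oriented_coords(n)
        expected = set()
        for pbs_len in range(9, 16):
            pbs_region = oriented[nick - pbs_len:nick]
            if sum(b in "GC" for b in pbs_region) < 5:
                continue
            for rtt_len in range(10, 21):
                if rtt_len >= site.nick_to_edit + len(edit.alt) + 1:
                    expected.add((pbs_len, rtt_len))
        assert {(p.pbs_len, p.rtt_len) for p in cands} == expected
        for p in cands:
            assert 9 <= p.pbs_len <= 15 and p.gc_count >= 5
            assert p.extension == p.rtt + p.pbs

    def test_at_only_pbs_window_reports_gc_reason(self):
        seq = "AT" * 100
        edit = EditSpec("substitution", 100, seq[99], "G")
        site = _site_with_distance(seq, edit, 0)
        cands = design_pegrnas(seq, edit, site)
        assert cands == [] and "PBS G/C below minimum" in cands.reasons

    def test_unreachable_edit_reports_rtt_reason(self):
        target, edit = gen_random_target(78, 200, 0.6)
        if edit.kind != "substitution":
            edit = EditSpec("substitution", edit.position, str(target)[edit.position - 1],
                            "A" if str(target)[edit.position - 1] != "A" else "C")
        site = _site_with_distance(
            target, edit, 25, config=ScanConfig(-30, 10, ("NNN",))
        )
        cands = design_pegrnas(str(target), edit, site)
        assert cands == [] and "edit not reachable by RTT" in cands.reasons

    def test_pbs_is_reverse_complement_of_sequence_ending_at_nick(self, random_targets):
        for target, edit in random_targets[:6]:
            sites = find_spacer_sites(str(target), edit, SPRY_PE2)
            if not sites:
                continue
            cands = design_pegrnas(str(target), edit, sites[0])
            oriented = (
                str(target) if sites[0].strand == "+" else reverse_complement(str(target))
            )
            _, nick = sites[0].oriented_coords(len(target))
            for p in cands[:5]:
                assert reverse_complement(p.pbs) == oriented[nick - p.pbs_len:nick]

    def test_constraints_are_never_violated(self, random_targets):
        c = DesignConstraints()
        for target, edit in random_targets[:8]:
            sites = find_spacer_sites(str(target), edit, SPRY_PE2)
            if not sites:
                continue
            for p in design_pegrnas(str(target), edit, sites[0], c):
                assert c.pbs_min <= p.pbs_len <= c.pbs_max
                assert c.rtt_min <= p.rtt_len <= c.rtt_max
                assert p.gc_count >= c.pbs_min_gc
                assert edit.alt in p.flap or edit.kind == "deletion"

    def test_epeg_flag_appends_motif(self, random_targets):
        target, edit = random_targets[0]
        site = find_spacer_sites(str(target), edit, SPRY_PE2)[0]
        peg = design_pegrnas(str(target), edit, site, epeg=True)[0]
        assert peg.is_epeg and peg.full_sequence.endswith(peg.epeg_motif)

    def test_invalid_constraints_rejected(self):
        with pytest.raises(SequenceError):
            DesignConstraints(pbs_min=0)
        with pytest.raises(SequenceError):
            DesignConstraints(rtt_min=15, rtt_max=10)


class TestRttMismatchCount:
    def _peg_with_flap(self, target, site, flap, pbs_len=11):
        oriented = (
            str(target) if site.strand == "+" else reverse_complement(str(target))
        )
        _, nick = site.oriented_coords(len(target))
        pbs = reverse_complement(oriented[nick - pbs_len:nick])
        return PegRNA(site=site, spacer=site.spacer, pbs=pbs, rtt=reverse_complement(flap))

    def test_intended_substitution_and_silent_extras(self):
        target, edit = gen_random_target(81, 200, 0.5)
        edit = EditSpec("substitution", edit.position, str(target)[edit.position - 1],
                        "A" if str(target)[edit.position - 1] != "A" else "C")
        site = _site_with_distance(target, edit, 2)
        oriented = str(target) if site.strand == "+" else reverse_complement(str(target))
        _, nick = site.oriented_coords(len(target))
        pre_flap = oriented[nick:nick + 14]

        # no-op pegRNA: RTT encodes the unchanged sequence
        assert rtt_mismatch_count(self._peg_with_flap(target, site, pre_flap), str(target)) == 0

        # intended 1-bp substitution only
        cands = design_pegrnas(str(target), edit, site)
        peg = next(p for p in cands if p.rtt_len == 14)
        assert rtt_mismatch_count(peg, str(target)) == 1

        # intended change plus 2 extra silent substitutions (away from the 3' end)
        flap = list(peg.flap)
        for i in (5, 7):
            if i != site.nick_to_edit:
                flap[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[flap[i]]
        extra = self._peg_with_flap(target, site, "".join(flap))
        assert rtt_mismatch_count(extra, str(target)) == 3


class TestNickingGuides:
    def test_pe3b_flag_matches_direct_footprint_comparison(self, designed_bundle):
        target, edit, bundle = designed_bundle
        guides = design_nicking_guides(str(target), edit, bundle.peg)
        assert guides, "expected nicking guides on a 200-nt target with NNN PAM"
        pre = str(target)
        post = str(apply_edit(target, edit))
        for g in guides:
            hay_pre = pre if g.strand == "+" else reverse_complement(pre)
            hay_post = post if g.strand == "+" else reverse_complement(post)
            assert g.spacer in hay_post
            assert g.pe3b == (g.spacer not in hay_pre) or not g.pe3b
            if g.pe3b:
                assert g.spacer not in hay_pre
        assert all(g.strand != bundle.peg.site.strand for g in guides)

    def test_distant_guide_is_pe3_with_offset(self, designed_bundle):
        target, edit, bundle = designed_bundle
        guides = design_nicking_guides(str(target), edit, bundle.peg, search_span=100)
        far = [g for g in guides if abs(g.offset_from_peg_nick) >= 25]
        assert far and all(not g.pe3b for g in far if abs(g.offset_from_peg_nick) > 25)

    def test_validator_rejects_impossible_pe3b_label(self, designed_bundle):
        target, edit, bundle = designed_bundle
        guides = design_nicking_guides(str(target), edit, bundle.peg)
        honest = next(g for g in guides if not g.pe3b)
        liar = NickingGuide(
            spacer=honest.spacer, pam=honest.pam, strand=honest.strand,
            nick_position=honest.nick_position,
            offset_from_peg_nick=honest.offset_from_peg_nick, pe3b=True,
        )
        with pytest.raises(SequenceError, match="pe3b"):
            validate_nicking_guide(liar, str(target), edit)


class TestGoldenGateOligos:
    def _toy_peg(self):
        return PegRNA(
            site=None,
            spacer="ACGTAC",  # toy 6-nt spacer
            pbs="TTGGCCAAT",
            rtt="GGCCTTAAGG",
            scaffold="GTTTAAGAGCTATGCTGG",
        )

    def test_sequential_ligation_reconstructs_the_cassette(self):
        peg = self._toy_peg()
        oset = emit_pegrna_oligos(peg, GoldenGateAcceptor("toy", "CACC", "CTAG"))
        assert oset.assembled_insert() == peg.spacer + peg.scaffold + peg.extension

    def test_duplex_complementarity_invariant(self):
        oset = emit_pegrna_oligos(self._toy_peg())
        for _, top, bottom in oset.duplexes:
            assert bottom[4:] == reverse_complement(top[4:])

    def test_duplicate_overhangs_rejected(self):
        peg = self._toy_peg()
        clash = peg.scaffold[:4]
        with pytest.raises(SequenceError, match="collision"):
            emit_pegrna_oligos(peg, GoldenGateAcceptor("bad", clash, "CTAG"))

    def test_chain_rejects_mismatched_junction(self):
        oset = emit_pegrna_oligos(self._toy_peg())
        duplexes = [(t, b) for _, t, b in oset.duplexes]
        corrupted = [(duplexes[0][0], "AAAA" + duplexes[0][1][4:])] + duplexes[1:]
        with pytest.raises(SequenceError, match="junction"):
            golden_gate_chain(corrupted)
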