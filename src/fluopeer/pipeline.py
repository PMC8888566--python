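"""End-to-end design convenience: edit -> site -> pegRNA -> reporter insert."""

from __future__ import annotations

from dataclasses import dataclass

from . import edit_sim
from .pam_scan import ScanConfig, SpacerSite, find_spacer_sites
from .pegrna_design import DesignConstraints, PegRNA, design_pegrnas
from .profiles import SPRY_PE2
from .reporter_design import DesignFailure, ReporterInsert, design_reporter_insert, verify_reporter
from .seqcore import EditSpec, EditorProfile, SequenceError, apply_edit

__all__ = ["DesignBundle", "design_for_edit"]


@dataclass
class DesignBundle:
    """The chosen site, pegRNA candidates and verified reporter insert."""

    site: SpacerSite
    candidates: list
    peg: PegRNA
    insert: ReporterInsert


def design_for_edit(
    target,
    edit: EditSpec,
    profile: EditorProfile = SPRY_PE2,
    constraints: DesignConstraints | None = None,
    scan: ScanConfig | None = None,
    length_pref: int = 60,
    epeg: bool = False,
) -> DesignBundle:
    """Design a verified reporter for *edit*: top-ranked site, top pegRNA
    candidate, reporter insert. Raises :class:`~fluopeer.seqcore.SequenceError`
    (or :class:`~fluopeer.reporter_design.DesignFailure`) when no design exists.
    """
    sites = find_spacer_sites(target, edit, profile, scan)
    if not sites:
        raise SequenceError("no protospacer/PAM site in the scan window")
    errors = []
    for site in sites[:5]:
        candidates = design_pegrnas(target, edit, site, constraints, epeg=epeg)
        if not candidates:
            errors.append(f"site@{site.protospacer_start}{site.strand}: {candidates.reasons}")
            continue
        for peg in candidates[:3]:
            try:
                insert = design_reporter_insert(target, edit, peg, length_pref=length_pref)
            except DesignFailure as exc:
                errors.append(f"site@{site.protospacer_start}{site.strand}: {exc}")
                continue
            # final belt-and-braces round trip on the full target
            sim = edit_sim.simulate_prime_edit(target, peg, profile)
            if sim.status != "edited" or sim.edited_seq != apply_edit(str(target), edit):
                errors.append("full-target simulation mismatch")
                continue
            verify_reporter(insert)
            return DesignBundle(site, candidates, peg, insert)
    raise DesignFailure("no design bundle for this edit", errors)
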