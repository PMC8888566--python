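"""pegRNA / epegRNA candidate generation, nicking guides and cloning oligos.

Candidates are enumerated over the PBS x RTT length grid under the design
constraints used throughout this package: PBS 9-15 nt with at least 5 G/C,
RTT 10-20 nt, flap spanning the full alternate allele plus at least one
downstream homologous base. All surviving candidates are returned (there is
no efficiency model); the ordering is a documented heuristic preferring
PBS lengths near 12 and mid-range RTTs. Every emitted candidate's flap is
verified to reproduce the post-edit sequence through the prime-editing
simulator before it is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import edit_sim
from .pam_scan import SpacerSite
from .seqcore import (
    EditSpec,
    EditorProfile,
    SequenceError,
    as_bases,
    apply_edit,
    iupac_match,
    mirror_edit,
    reverse_complement,
)

__all__ = [
    "DesignConstraints",
    "PegRNA",
    "NickingGuide",
    "GoldenGateAcceptor",
    "OligoSet",
    "PegCandidates",
    "design_pegrnas",
    "rtt_mismatch_count",
    "design_nicking_guides",
    "emit_pegrna_oligos",
    "validate_nicking_guide",
    "SPCAS9_SCAFFOLD",
    "EPEG_MOTIF_PLACEHOLDER",
]

#: Canonical SpCas9 single-guide scaffold; user-replaceable via the
#: ``scaffold`` argument of :func:`design_pegrnas`.
SPCAS9_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)
SCAFFOLD_ID = "SpCas9-scaffold-v1"

#: Synthetic placeholder for the structured 3' motif of epegRNAs (the real
#: tevopreQ1 motif must be supplied by the user before any synthesis).
EPEG_MOTIF_PLACEHOLDER = "GGAAACCAGCTTCGGCTGGTTTCCACGT"
EPEG_MOTIF_ID = "tevopreQ1-placeholder-synthetic"


@dataclass(frozen=True)
class DesignConstraints:
    pbs_min: int = 9
    pbs_max: int = 15
    pbs_min_gc: int = 5
    rtt_min: int = 10
    rtt_max: int = 20
    forbid_rtt_start_c: bool = True  # warning-only

    def __post_init__(self) -> None:
        if not (0 < self.pbs_min <= self.pbs_max):
            raise SequenceError("need 0 < pbs_min <= pbs_max")
        if not (0 < self.rtt_min <= self.rtt_max):
            raise SequenceError("need 0 < rtt_min <= rtt_max")
        if self.pbs_min_gc > self.pbs_max:
            raise SequenceError("pbs_min_gc cannot exceed pbs_max")


@dataclass(frozen=True)
class PegRNA:
    """A designed pegRNA: spacer + scaffold + 3' extension (RTT then PBS).

    ``flap`` is the DNA sequence the RTT templates: the edited PAM-strand
    sequence immediately 3' of the nick. The 3' extension is written 5'->3'
    and equals ``rtt + pbs``.
    """

    site: SpacerSite
    spacer: str
    pbs: str
    rtt: str
    scaffold: str = SPCAS9_SCAFFOLD
    scaffold_id: str = SCAFFOLD_ID
    epeg_motif: str | None = None
    epeg_motif_id: str | None = None
    warnings: tuple[str, ...] = ()

    @property
    def extension(self) -> str:
        return self.rtt + self.pbs

    @property
    def flap(self) -> str:
        return reverse_complement(self.rtt)

    @property
    def pbs_len(self) -> int:
        return len(self.pbs)

    @property
    def rtt_len(self) -> int:
        return len(self.rtt)

    @property
    def gc_count(self) -> int:
        return self.pbs.count("G") + self.pbs.count("C")

    @property
    def is_epeg(self) -> bool:
        return self.epeg_motif is not None

    @property
    def full_sequence(self) -> str:
        return self.spacer + self.scaffold + self.extension + (self.epeg_motif or "")


class PegCandidates(list):
    """List of :class:`PegRNA` candidates carrying the designer's report.

    ``reasons`` is a machine-readable tally of why (pbs_len, rtt_len) pairs
    were rejected; it is the designer's explanation when the list is empty.
    """

    def __init__(self, items=(), reasons=None, n_raw_pairs=0):
        super().__init__(items)
        self.reasons: dict[str, int] = dict(reasons or {})
        self.n_raw_pairs = n_raw_pairs


def _oriented_view(target, edit: EditSpec, site: SpacerSite):
    """(oriented pre, oriented edit, protospacer start, nick splice index)."""
    seq = as_bases(target)
    n = len(seq)
    if site.strand == "+":
        oriented, oedit = seq, edit
    else:
        oriented, oedit = reverse_complement(seq), mirror_edit(edit, n)
    s, nick_idx = site.oriented_coords(n)
    return oriented, oedit, s, nick_idx


def design_pegrnas(
    target,
    edit: EditSpec,
    site: SpacerSite,
    constraints: DesignConstraints | None = None,
    epeg: bool = False,
    scaffold: str = SPCAS9_SCAFFOLD,
    scaffold_id: str = SCAFFOLD_ID,
    epeg_motif: str = EPEG_MOTIF_PLACEHOLDER,
    profile: EditorProfile | None = None,
) -> PegCandidates:
    """Enumerate pegRNA candidates for *edit* at *site*.

    One candidate per (pbs_len, rtt_len) pair that satisfies the
    constraints: PBS G/C count >= ``pbs_min_gc``, flap covering the whole
    alternate allele plus >=1 downstream homologous base, and simulator
    verification that the flap reproduces the post-edit sequence. Candidates
    are ordered by ``(|pbs_len - 12|, |rtt_len - rtt_mid|)`` ascending (a
    documented tie-break, not an efficiency claim). An empty result carries
    machine-readable ``reasons``.
    """
    constraints = constraints or DesignConstraints()
    profile = profile or site.profile
    edit.validate_against(target)
    if site.nick_to_edit < 0:
        raise SequenceError("site has nick_to_edit < 0; not a prime-editing candidate")
    oriented, oedit, _, nick_idx = _oriented_view(target, edit, site)
    post_oriented = apply_edit(oriented, oedit)
    expected_post = apply_edit(as_bases(target), edit)
    nick_to_edit = site.nick_to_edit
    alt_len = len(oedit.alt)
    rtt_mid = (constraints.rtt_min + constraints.rtt_max) / 2

    reasons: dict[str, int] = {}
    n_raw = 0
    out = []
    for pbs_len in range(constraints.pbs_min, constraints.pbs_max + 1):
        if nick_idx < pbs_len:
            reasons["PBS window extends past the target 5' end"] = (
                reasons.get("PBS window extends past the target 5' end", 0)
                + (constraints.rtt_max - constraints.rtt_min + 1)
            )
            n_raw += constraints.rtt_max - constraints.rtt_min + 1
            continue
        pbs_region = oriented[nick_idx - pbs_len:nick_idx]
        pbs = reverse_complement(pbs_region)
        gc = pbs.count("G") + pbs.count("C")
        for rtt_len in range(constraints.rtt_min, constraints.rtt_max + 1):
            n_raw += 1
            if gc < constraints.pbs_min_gc:
                reasons["PBS G/C below minimum"] = reasons.get("PBS G/C below minimum", 0) + 1
                continue
            if rtt_len < nick_to_edit + alt_len + 1:
                reasons["edit not reachable by RTT"] = reasons.get("edit not reachable by RTT", 0) + 1
                continue
            if nick_idx + rtt_len > len(post_oriented):
                reasons["RTT window extends past the target 3' end"] = (
                    reasons.get("RTT window extends past the target 3' end", 0) + 1
                )
                continue
            flap = post_oriented[nick_idx:nick_idx + rtt_len]
            rtt = reverse_complement(flap)
            warnings = []
            if constraints.forbid_rtt_start_c and rtt.startswith("C"):
                warnings.append("RTT starts with C (may pair with scaffold; warning only)")
            peg = PegRNA(
                site=site,
                spacer=site.spacer,
                pbs=pbs,
                rtt=rtt,
                scaffold=as_bases(scaffold),
                scaffold_id=scaffold_id,
                epeg_motif=as_bases(epeg_motif) if epeg else None,
                epeg_motif_id=EPEG_MOTIF_ID if epeg else None,
                warnings=tuple(warnings),
            )
            try:
                sim = edit_sim.simulate_prime_edit(target, peg, profile)
            except edit_sim.AmbiguousSiteError:
                reasons["ambiguous protospacer match in target"] = (
                    reasons.get("ambiguous protospacer match in target", 0) + 1
                )
                continue
            if sim.status != "edited" or sim.edited_seq != expected_post:
                reasons["flap does not reproduce the post-edit sequence"] = (
                    reasons.get("flap does not reproduce the post-edit sequence", 0) + 1
                )
                continue
            out.append(peg)

    out.sort(key=lambda p: (abs(p.pbs_len - 12), abs(p.rtt_len - rtt_mid), p.pbs_len, p.rtt_len))
    return PegCandidates(out, reasons=reasons, n_raw_pairs=n_raw)


def rtt_mismatch_count(peg: PegRNA, target, profile: EditorProfile | None = None) -> int:
    """Differences between the flap and the pre-edit PAM-strand footprint.

    Substitutions are counted position-wise over the footprint the flap
    replaces; an insertion or deletion contributes its length difference.
    A no-op pegRNA scores 0; a pegRNA encoding only the intended 1-bp
    substitution scores 1.
    """
    profile = profile or peg.site.profile
    sim = edit_sim.simulate_prime_edit(target, peg, profile)
    if sim.status == "no_site":
        raise SequenceError("pegRNA site not found in target")
    seq = as_bases(target)
    strand = sim.diagnostics["strand"]
    nick_idx = sim.diagnostics["nick_idx_oriented"]
    k = sim.diagnostics.get("flap_replaced", len(peg.flap))
    oriented = seq if strand == "+" else reverse_complement(seq)
    pre_seg = oriented[nick_idx:nick_idx + k]
    flap = peg.flap
    subs = sum(1 for a, b in zip(flap, pre_seg) if a != b)
    return subs + abs(len(flap) - len(pre_seg))


# ---------------------------------------------------------------------------
# nicking guides (PE3 / PE3b)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NickingGuide:
    """A nicking sgRNA on the strand opposite the pegRNA's PAM strand.

    ``pe3b`` guides span the edited bases and perfectly match only the
    post-edit sequence, so they nick the unedited strand only after the
    edited strand has been rewritten. Coordinates are 1-based on the
    post-edit top strand.
    """

    spacer: str
    pam: str
    strand: str
    nick_position: int
    offset_from_peg_nick: int
    pe3b: bool


def validate_nicking_guide(guide: NickingGuide, target, edit: EditSpec) -> None:
    """Reject a guide whose ``pe3b`` flag contradicts the pre/post sequences.

    A guide may only be labelled PE3b if its spacer is a perfect match to the
    post-edit sequence and an imperfect match to the pre-edit sequence (on
    its strand).
    """
    pre = as_bases(target)
    post = apply_edit(pre, edit)

    def occurs(seq: str) -> bool:
        hay = seq if guide.strand == "+" else reverse_complement(seq)
        return guide.spacer in hay

    in_pre, in_post = occurs(pre), occurs(post)
    if guide.pe3b and (in_pre or not in_post):
        raise SequenceError(
            "guide labelled pe3b but its spacer "
            + ("matches the pre-edit sequence" if in_pre else "does not match the post-edit sequence")
        )
    if not guide.pe3b and not in_pre:
        raise SequenceError("non-pe3b guide's spacer does not match the pre-edit sequence")


def design_nicking_guides(
    target,
    edit: EditSpec,
    peg: PegRNA,
    profile: EditorProfile | None = None,
    search_span: int = 100,
) -> list[NickingGuide]:
    """Scan the non-PAM strand around the pegRNA nick for nicking sgRNAs.

    Spacers are taken from the post-edit sequence; a guide whose footprint
    overlaps the edited bases and that no longer matches the pre-edit
    sequence is flagged PE3b. Plain PE3 guides are annotated with the signed
    top-strand distance between the two nicks. PE3b guides sort first, then
    by |offset|.
    """
    profile = profile or peg.site.profile
    pre = as_bases(target)
    post = apply_edit(pre, edit)
    n_pre, n_post = len(pre), len(post)
    site = peg.site
    L = profile.spacer_length

    # top-strand splice index of the pegRNA nick, in post-edit coordinates
    _, nick_idx = site.oriented_coords(n_pre)
    peg_splice = nick_idx if site.strand == "+" else n_pre - nick_idx
    if edit.ref_start0 < peg_splice:
        peg_splice += edit.length_change

    opp = "-" if site.strand == "+" else "+"
    oriented = post if opp == "+" else reverse_complement(post)
    edited_lo = edit.ref_start0
    edited_hi = edit.ref_start0 + max(len(edit.alt), 1)  # post-edit top coords

    guides = []
    for s in range(0, n_post - L + 1):
        pam_ok = None
        for pat in profile.pam_patterns:
            pam = oriented[s + L:s + L + len(pat)]
            if len(pam) == len(pat) and iupac_match(pat, pam):
                pam_ok = pam
                break
        if pam_ok is None:
            continue
        k = s + L - profile.nick_offset
        splice_top = k if opp == "+" else n_post - k
        offset = splice_top - peg_splice
        if abs(offset) > search_span:
            continue
        spacer = oriented[s:s + L]
        if opp == "+":
            foot_lo, foot_hi = s, s + L
            nick_pos1 = k
        else:
            foot_lo, foot_hi = n_post - s - L, n_post - s
            nick_pos1 = n_post - k + 1
        overlaps = foot_lo < edited_hi and edited_lo < foot_hi
        hay_pre = pre if opp == "+" else reverse_complement(pre)
        pe3b = overlaps and spacer not in hay_pre
        guides.append(
            NickingGuide(
                spacer=spacer,
                pam=pam_ok,
                strand=opp,
                nick_position=nick_pos1,
                offset_from_peg_nick=offset,
                pe3b=pe3b,
            )
        )
    for g in guides:
        validate_nicking_guide(g, target, edit)
    guides.sort(key=lambda g: (not g.pe3b, abs(g.offset_from_peg_nick), g.nick_position))
    return guides


# ---------------------------------------------------------------------------
# Golden Gate oligo emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldenGateAcceptor:
    """Destination acceptor for the three pegRNA duplex slots.

    Supplies the two vector-side 4-nt overhangs; the two internal junction
    overhangs are taken from the assembled sequence itself (the first 4 nt of
    the scaffold and of the extension), which is what makes sequential
    ligation reconstruct spacer+scaffold+extension exactly.
    """

    name: str
    left_overhang: str
    right_overhang: str

    def __post_init__(self) -> None:
        for oh in (self.left_overhang, self.right_overhang):
            if len(as_bases(oh)) != 4:
                raise SequenceError("acceptor overhangs must be 4 nt")
        object.__setattr__(self, "left_overhang", as_bases(self.left_overhang))
        object.__setattr__(self, "right_overhang", as_bases(self.right_overhang))


#: Default acceptor with the conventional U6 'CACC' spacer overhang; the
#: vector-side overhangs are acceptor data, not a published constant.
DEFAULT_ACCEPTOR = GoldenGateAcceptor("pU6-GG-acceptor", "CACC", "CTAG")


@dataclass
class OligoSet:
    """Named (top, bottom) duplexes with 4-nt 5' overhangs."""

    duplexes: list[tuple[str, str, str]]  # (name, top, bottom)
    acceptor_id: str

    def __post_init__(self) -> None:
        for name, top, bottom in self.duplexes:
            if bottom[4:] != reverse_complement(top[4:]):
                raise SequenceError(f"duplex {name}: strands do not anneal")

    def assembled_insert(self) -> str:
        """Top strand of the sequential ligation, minus the vector overhang."""
        chain = edit_sim.golden_gate_chain([(t, b) for _, t, b in self.duplexes])
        return chain[4:]


def emit_pegrna_oligos(peg: PegRNA, acceptor: GoldenGateAcceptor = DEFAULT_ACCEPTOR) -> OligoSet:
    """Emit spacer/scaffold/extension duplexes for Golden Gate assembly.

    The three duplexes chain left-to-right by overhang identity; their
    sequential ligation reconstructs ``spacer + scaffold + extension``
    (plus the 3' motif for an epegRNA) exactly. Identical overhangs anywhere
    among the four junctions are an acceptor-definition error.
    """
    S = peg.spacer
    C = peg.scaffold
    X = peg.extension + (peg.epeg_motif or "")
    for nm, seg in (("spacer", S), ("scaffold", C), ("extension", X)):
        if len(seg) < 5:
            raise SequenceError(f"{nm} slot too short for 4-nt junction overhangs")
    j1, j2 = C[:4], X[:4]
    overhangs = [acceptor.left_overhang, j1, j2, acceptor.right_overhang]
    if len(set(overhangs)) != 4:
        raise SequenceError(
            f"overhang collision in acceptor {acceptor.name}: {overhangs} are not all distinct"
        )
    duplexes = [
        ("spacer", acceptor.left_overhang + S, reverse_complement(S + j1)),
        ("scaffold", C, reverse_complement(C[4:] + j2)),
        ("extension", X, reverse_complement(X[4:] + acceptor.right_overhang)),
    ]
    return OligoSet(duplexes, acceptor_id=acceptor.name)
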