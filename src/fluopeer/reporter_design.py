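"""Fluorescent prime/base-editing reporter (fluoPEER-style) insert design.

A reporter insert is a 45-100 nt genomic window cloned between a GFP and a
Cherry cassette (GFP - P2A - insert - K0-SR - P2A - Cherry, one continuous
reading frame). Before editing the insert blocks Cherry, either through an
in-frame stop codon or a reading-frame shift; successful editing removes the
block, so Cherry fluorescence reports editing of the reporter. When the
genomic edit itself is not a nonsense/frameshift change, a 1-nt frameshift
(or stop codon) is added inside the RTT-rewritten span so that the prime
edit removes it together with installing the genomic change.

Every design is verified in silico: the pre-edit insert is run through the
prime-editing simulator and must yield exactly the designed post-edit
insert, and the translated construct must switch from Cherry-off to
Cherry-on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

from . import edit_sim
from .pegrna_design import PegRNA
from .pam_scan import ScanConfig, find_spacer_sites
from .seqcore import (
    EditSpec,
    EditorProfile,
    SequenceError,
    apply_edit,
    as_bases,
    find_stop_codons,
    mirror_edit,
    reverse_complement,
    translate_frame,
    STOP_CODONS,
)

__all__ = [
    "DisruptionSpec",
    "ReporterInsert",
    "ReporterConstruct",
    "DesignFailure",
    "design_reporter_insert",
    "verify_reporter",
    "emit_insert_oligos",
    "design_base_edit_reporter",
    "pam_variant_panel",
    "SEGMENTS",
]

# ---------------------------------------------------------------------------
# construct segments
# ---------------------------------------------------------------------------
# Stop-free, frame-preserving segment stand-ins used for translation logic
# only. GFP/Cherry/K0-SR are synthetic placeholder ORFs (the reporter logic
# depends only on frames and stop codons, not on the real fluorophore
# sequences, which users may substitute). P2A is the standard GSG-P2A
# back-translation.
P2A = (
    "GGAAGCGGAGCTACTAACTTCAGCCTGCTGAAGCAGGCTGGAGACGTGGAGGAGAACCCTGGACCT"
)
GFP_SYNTHETIC = "ATG" + "GGCGCTAGCAAGGAGCTGTTCACCGTG" * 2  # synthetic stand-in ORF
K0SR_SYNTHETIC = "GGCAAGGCTGCTAAGGCTGCTGGCAAG"  # inert in-frame spacer domain
CHERRY_SYNTHETIC = "ATG" + "GTGAGCAAGGGCGAGGAGCTGATCAAG" * 2  # synthetic stand-in ORF

SEGMENTS = {
    "GFP": GFP_SYNTHETIC,
    "P2A-1": P2A,
    "K0-SR": K0SR_SYNTHETIC,
    "P2A-2": P2A,
    "Cherry": CHERRY_SYNTHETIC,
}

for _name, _seg in SEGMENTS.items():
    assert len(_seg) % 3 == 0 and "*" not in translate_frame(_seg, 0, "+"), _name

INSERT_MIN, INSERT_MAX = 45, 100


class DesignFailure(SequenceError):
    """No (window, frame, disruption) combination satisfies the invariants.

    ``report`` lists the violated constraint for each candidate examined.
    """

    def __init__(self, message: str, report: list[str]):
        super().__init__(message + f" ({len(report)} candidates examined)")
        self.report = report


@dataclass(frozen=True)
class DisruptionSpec:
    kind: str  # none | native_stop | native_frameshift | added_stop | added_frameshift
    position: int = 0  # 1-based within the pre-edit insert
    bases: str = ""

    def __post_init__(self) -> None:
        kinds = ("none", "native_stop", "native_frameshift", "added_stop", "added_frameshift")
        if self.kind not in kinds:
            raise SequenceError(f"unknown disruption kind {self.kind!r}")
        if self.kind == "added_frameshift" and len(self.bases) % 3 == 0:
            raise SequenceError("added_frameshift bases must not be a multiple of 3")


@dataclass(frozen=True)
class ReporterInsert:
    """A designed reporter insert, pre- and post-edit.

    ``window`` is 1-based inclusive on the source target's top strand;
    ``orientation`` is the strand the insert is cloned in (the pegRNA's PAM
    strand for prime designs, the selected reading strand for base designs).
    ``frame_offset`` is the 5'-trim that aligns the reporter frame.
    """

    window: tuple[int, int]
    orientation: str
    frame_offset: int
    pre_edit_seq: str
    post_edit_seq: str
    disruption: DisruptionSpec
    peg: PegRNA | None = None
    pam_span_pre: tuple[int, int] | None = None  # 0-based half-open within pre
    pam_span_post: tuple[int, int] | None = None
    name: str = "insert"

    def validate(self) -> None:
        pre, post = self.pre_edit_seq, self.post_edit_seq
        if not (INSERT_MIN <= len(pre) <= INSERT_MAX):
            raise SequenceError(
                f"pre-edit insert length {len(pre)} outside [{INSERT_MIN}, {INSERT_MAX}]"
            )
        if len(post) % 3 != 0:
            raise SequenceError("post-edit insert length must be a multiple of 3")
        if find_stop_codons(post, 0, "+"):
            raise SequenceError("post-edit insert contains an in-frame stop codon")
        if len(pre) % 3 == 0 and not find_stop_codons(pre, 0, "+"):
            raise SequenceError(
                "pre-edit insert is in-frame and stop-free; Cherry would be on pre-edit"
            )

    @property
    def oligos(self) -> tuple[str, str]:
        return emit_insert_oligos(self)


@dataclass
class ReporterConstruct:
    """GFP - P2A - insert - K0-SR - P2A - Cherry, translated as one frame."""

    layout: tuple[tuple[str, str], ...]
    gfp_expressed: bool
    cherry_expressed: bool
    translation: str

    @classmethod
    def from_insert_seq(cls, insert_seq: str) -> "ReporterConstruct":
        layout = (
            ("GFP", SEGMENTS["GFP"]),
            ("P2A-1", SEGMENTS["P2A-1"]),
            ("insert", as_bases(insert_seq)),
            ("K0-SR", SEGMENTS["K0-SR"]),
            ("P2A-2", SEGMENTS["P2A-2"]),
            ("Cherry", SEGMENTS["Cherry"]),
        )
        full = "".join(seq for _, seq in layout)
        aa = translate_frame(full, 0, "+")
        gfp_aa = aa[: len(SEGMENTS["GFP"]) // 3]
        gfp_ok = "*" not in gfp_aa
        cherry_start = len(full) - len(SEGMENTS["Cherry"])
        cherry_ok = cherry_start % 3 == 0 and "*" not in aa[: cherry_start // 3]
        return cls(layout, gfp_ok, cherry_ok, aa)


def verify_reporter(insert: ReporterInsert) -> tuple[ReporterConstruct, ReporterConstruct]:
    """Translate the pre- and post-edit constructs and check the switch.

    Returns ``(pre, post)``. A pre-edit construct that already expresses
    Cherry indicates a design bug and raises; a post-edit construct that
    fails to express Cherry likewise.
    """
    insert.validate()
    pre = ReporterConstruct.from_insert_seq(insert.pre_edit_seq)
    post = ReporterConstruct.from_insert_seq(insert.post_edit_seq)
    if pre.cherry_expressed:
        raise SequenceError(
            "invariant violation: pre-edit construct expresses Cherry "
            "(disruption missing or ineffective)"
        )
    if not post.cherry_expressed:
        raise SequenceError("invariant violation: post-edit construct does not express Cherry")
    return pre, post


def emit_insert_oligos(insert) -> tuple[str, str]:
    """SalI/Acc65I-compatible cloning oligos for the pre-edit insert.

    top = TCGACC + insert + G, bottom = GTACC + revcomp(insert) + GG; the
    annealed duplex regenerates both GTCGAC and GGTACC sites on ligation
    into a SalI/Acc65I-cut vector.
    """
    seq = as_bases(insert.pre_edit_seq if isinstance(insert, ReporterInsert) else insert)
    top = "TCGACC" + seq + "G"
    bottom = "GTACC" + reverse_complement(seq) + "GG"
    return top, bottom


# ---------------------------------------------------------------------------
# prime-editing reporter design
# ---------------------------------------------------------------------------

def _ordered(values, center):
    return sorted(values, key=lambda v: (abs(v - center), v))


def design_reporter_insert(
    target,
    edit: EditSpec,
    peg: PegRNA,
    length_pref: int = 60,
    profile: EditorProfile | None = None,
    max_candidates: int = 400,
) -> ReporterInsert:
    """Design the reporter insert for *edit* as installed by *peg*.

    Selects a window (length near *length_pref*, clamped to 45-100 nt,
    centred on the protospacer where possible) covering the pegRNA footprint
    such that the post-edit insert is in frame and stop-free while the
    pre-edit insert is blocked. If the edit itself is a nonsense or
    frameshift change the window is used as-is (``native_*`` disruption);
    otherwise a 1-nt frameshift insertion is added inside the RTT-rewritten
    span, as far from the nick as possible while staying clear of the PAM
    and the protospacer seed. Every candidate is verified through the
    prime-editing simulator; failure raises :class:`DesignFailure` with a
    per-candidate report.
    """
    profile = profile or peg.site.profile
    seq = as_bases(target)
    n = len(seq)
    site = peg.site
    edit.validate_against(seq)
    if site.strand == "+":
        T, E = seq, edit
    else:
        T, E = reverse_complement(seq), mirror_edit(edit, n)
    s, nick_idx = site.oriented_coords(n)
    L = len(site.spacer)
    plen = len(site.pam)
    delta = E.length_change
    k_pre = peg.rtt_len - delta  # pre-edit bases replaced by the flap
    foot_lo = min(s, nick_idx - peg.pbs_len)
    foot_hi = max(s + L + plen, nick_idx + max(peg.rtt_len, k_pre))
    if foot_lo < 0 or foot_hi > n:
        raise SequenceError("pegRNA footprint extends past the target; more flank needed")

    length_pref = min(max(length_pref, INSERT_MIN), INSERT_MAX)
    native_shift = delta % 3 != 0
    report: list[str] = []
    examined = 0

    lengths = [
        w for w in range(INSERT_MIN, INSERT_MAX + 1)
        if (w + delta) % 3 == 0 and w >= foot_hi - foot_lo
    ]
    for w_len in _ordered(lengths, length_pref):
        ideal_w0 = s + (L + plen) // 2 - w_len // 2
        w0_lo, w0_hi = max(0, foot_hi - w_len), min(foot_lo, n - w_len)
        if w0_lo > w0_hi:
            continue
        for w0 in _ordered(range(w0_lo, w0_hi + 1), ideal_w0):
            if examined >= max_candidates:
                break
            examined += 1
            w1 = w0 + w_len
            g = T[w0:w1]
            E_w = EditSpec(E.kind, E.position - w0, E.ref, E.alt)
            post_g = apply_edit(g, E_w)
            tag = f"window[{w0 + 1}:{w1}]"
            if find_stop_codons(post_g, 0, "+"):
                report.append(f"{tag}: post-edit insert has an in-frame stop")
                continue
            if native_shift:
                cand = _try_candidate(
                    g, post_g,
                    DisruptionSpec("native_frameshift", E_w.ref_start0 + 1, ""),
                    peg, profile, report, tag,
                )
            elif find_stop_codons(g, 0, "+"):
                cand = _try_candidate(
                    g, post_g,
                    DisruptionSpec("native_stop", find_stop_codons(g, 0, "+")[0], ""),
                    peg, profile, report, tag,
                )
            else:
                cand = _try_added_disruption(
                    g, post_g, w0, s, L, plen, nick_idx, k_pre, peg, profile, report, tag
                )
            if cand is None:
                continue
            pre_insert, post_insert, disruption = cand
            window_top = (
                (w0 + 1, w1) if site.strand == "+" else (n - w1 + 1, n - w0)
            )
            pam_pre = (s + L - w0, s + L + plen - w0)
            shift_in_pre = len(pre_insert) - len(g)
            d_pos0 = disruption.position - 1
            pam_pre_adj = tuple(
                c + (shift_in_pre if disruption.kind.startswith("added") and c > d_pos0 else 0)
                for c in pam_pre
            )
            pam_post = tuple(
                c + (delta if E_w.ref_end0 <= pam_pre[0] else 0) for c in pam_pre
            )
            insert = ReporterInsert(
                window=window_top,
                orientation=site.strand,
                frame_offset=0,
                pre_edit_seq=pre_insert,
                post_edit_seq=post_insert,
                disruption=disruption,
                peg=peg,
                pam_span_pre=pam_pre_adj,
                pam_span_post=pam_post,
            )
            verify_reporter(insert)
            return insert
    raise DesignFailure("no reporter insert satisfies the invariants", report)


def _try_candidate(pre_insert, post_insert, disruption, peg, profile, report, tag):
    """Validate one fully-specified candidate through the simulator."""
    try:
        sim = edit_sim.simulate_prime_edit(pre_insert, peg, profile)
    except edit_sim.AmbiguousSiteError:
        report.append(f"{tag}: ambiguous protospacer match in insert")
        return None
    if sim.status != "edited" or sim.edited_seq != post_insert:
        report.append(f"{tag}: simulated prime edit does not reproduce the post-edit insert "
                      f"(status {sim.status})")
        return None
    if len(pre_insert) % 3 == 0 and not find_stop_codons(pre_insert, 0, "+"):
        report.append(f"{tag}: pre-edit insert would express Cherry")
        return None
    return pre_insert, post_insert, disruption


def _try_added_disruption(g, post_g, w0, s, L, plen, nick_idx, k_pre, peg, profile, report, tag):
    """Place a 1-nt frameshift insertion in the RTT-rewritten span.

    Candidate slots run from the far (PAM-distal) end of the rewritten span
    towards the nick, skipping the PAM and the protospacer seed (protospacer
    positions 11-20) so pegRNA binding to the reporter is unperturbed.
    """
    nick_rel = nick_idx - w0
    span_lo, span_hi = nick_rel, nick_rel + k_pre  # insertion slots, 0-based
    seed_lo, seed_hi = s + 10 - w0, s + L + plen - w0
    for d in range(span_hi, span_lo - 1, -1):
        if seed_lo <= d < seed_hi or not (0 <= d <= len(g)):
            continue
        for base in "ATGC":
            pre_insert = g[:d] + base + g[d:]
            cand = _try_candidate(
                pre_insert, post_g,
                DisruptionSpec("added_frameshift", d + 1, base),
                peg, profile, report, f"{tag} disruption@{d + 1}{base}",
            )
            if cand is not None:
                return cand
    report.append(f"{tag}: no workable frameshift slot in the RTT span")
    return None


# ---------------------------------------------------------------------------
# base-editing reporter design (six-frame stop resolution)
# ---------------------------------------------------------------------------

def six_frame_stop_verdicts(pre, post, edit_pos0: int) -> dict[tuple[str, int], bool]:
    """For each (strand, offset) frame: does the pre-edit sequence carry a
    stop codon covering the edited base that the post-edit sequence
    resolves?"""
    pre, post = as_bases(pre), as_bases(post)
    n = len(pre)
    verdicts = {}
    for strand in ("+", "-"):
        p = pre if strand == "+" else reverse_complement(pre)
        q = post if strand == "+" else reverse_complement(post)
        a = edit_pos0 if strand == "+" else n - 1 - edit_pos0
        for off in (0, 1, 2):
            c = a - ((a - off) % 3)
            ok = (
                0 <= c and c + 3 <= n
                and p[c:c + 3] in STOP_CODONS
                and q[c:c + 3] not in STOP_CODONS
            )
            verdicts[(strand, off)] = ok
    return verdicts


def design_base_edit_reporter(
    target,
    edit: EditSpec,
    profile: EditorProfile,
    length_pref: int = 60,
    scan: ScanConfig | None = None,
) -> ReporterInsert:
    """Design a base-editing reporter: the edit must resolve a stop codon in
    one of the six reading frames of the target region.

    The insert is cloned in the orientation and with the 5' trim that makes
    the reporter frame equal the selected stop-resolving frame. The post
    sequence is the base editor's full window conversion at the chosen site
    (bystander conversions included). Raises :class:`DesignFailure` listing
    all six frame verdicts when no frame qualifies.
    """
    if profile.mode != "base":
        raise SequenceError("design_base_edit_reporter needs a base-mode profile")
    if edit.kind != "substitution" or len(edit.ref) != 1:
        raise SequenceError("base-editing reporter requires a single-base substitution")
    frm, to = profile.base_conversion
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if (edit.ref, edit.alt) not in {(frm, to), (comp[frm], comp[to])}:
        raise SequenceError(
            f"edit {edit.ref}>{edit.alt} is not a {frm}->{to} conversion on either strand"
        )
    seq = as_bases(target)
    n = len(seq)
    edit.validate_against(seq)
    sites = find_spacer_sites(seq, edit, profile, scan)
    report: list[str] = []
    for site in sites:
        post = edit_sim.simulate_base_edit(seq, site, profile)[0].edited_seq
        if apply_edit(seq, edit)[edit.ref_start0] != post[edit.ref_start0]:
            report.append(f"site@{site.protospacer_start}{site.strand}: window conversion misses the edit")
            continue
        verdicts = six_frame_stop_verdicts(seq, post, edit.ref_start0)
        frames = [f for f in (("+", 0), ("+", 1), ("+", 2), ("-", 0), ("-", 1), ("-", 2)) if verdicts[f]]
        if not frames:
            report.append(
                f"site@{site.protospacer_start}{site.strand}: no stop-resolving frame; verdicts "
                + ", ".join(f"({st}{off})={'yes' if v else 'no'}" for (st, off), v in verdicts.items())
            )
            continue
        for strand, off in frames:
            insert = _base_window_search(
                seq, post, site, strand, off, edit, length_pref, report
            )
            if insert is not None:
                return insert
    raise DesignFailure("no base-editing reporter frame/window qualifies", report)


def _base_window_search(pre, post, site, strand, off, edit, length_pref, report):
    n = len(pre)
    P = pre if strand == "+" else reverse_complement(pre)
    Q = post if strand == "+" else reverse_complement(post)
    # footprint and stop codon, in the frame strand's coordinates
    s_or, _ = site.oriented_coords(n)
    L, plen = len(site.spacer), len(site.pam)
    if site.strand == "+":
        top_lo, top_hi = s_or, s_or + L + plen
    else:
        top_lo, top_hi = n - (s_or + L + plen), n - s_or
    foot_lo, foot_hi = (top_lo, top_hi) if strand == "+" else (n - top_hi, n - top_lo)
    a = edit.ref_start0 if strand == "+" else n - 1 - edit.ref_start0
    c = a - ((a - off) % 3)
    foot_lo, foot_hi = min(foot_lo, c), max(foot_hi, c + 3)

    for w_len in _ordered([w for w in range(INSERT_MIN, INSERT_MAX + 1) if w % 3 == 0], length_pref):
        if w_len < foot_hi - foot_lo:
            continue
        ideal_w0 = (foot_lo + foot_hi) // 2 - w_len // 2
        w0_lo = max(0, foot_hi - w_len)
        w0_hi = min(foot_lo, n - w_len)
        for w0 in _ordered([w for w in range(w0_lo, w0_hi + 1) if w % 3 == off % 3], ideal_w0):
            w1 = w0 + w_len
            pre_i, post_i = P[w0:w1], Q[w0:w1]
            if find_stop_codons(post_i, 0, "+"):
                report.append(f"frame({strand}{off}) window[{w0 + 1}:{w1}]: residual stop post-edit")
                continue
            pam_span = (
                (top_lo - w0, top_hi - w0) if strand == site.strand else None
            )
            insert = ReporterInsert(
                window=(w0 + 1, w1) if strand == "+" else (n - w1 + 1, n - w0),
                orientation=strand,
                frame_offset=off,
                pre_edit_seq=pre_i,
                post_edit_seq=post_i,
                disruption=DisruptionSpec("native_stop", c - w0 + 1, ""),
                peg=None,
                pam_span_pre=pam_span,
                pam_span_post=pam_span,
            )
            try:
                verify_reporter(insert)
            except SequenceError as exc:
                report.append(f"frame({strand}{off}) window[{w0 + 1}:{w1}]: {exc}")
                continue
            return insert
    return None


# ---------------------------------------------------------------------------
# PAM variant panel
# ---------------------------------------------------------------------------

def pam_variant_panel(
    insert: ReporterInsert,
    pam_template: str,
    variable_positions,
) -> list[ReporterInsert]:
    """Enumerate insert variants over a PAM template.

    ``variable_positions`` are 1-based indices into *pam_template*; each is
    assigned every base in {A,C,G,T}, giving ``4**k`` variants. Fixed
    template positions that are concrete bases overwrite the insert; IUPAC
    positions keep the insert's original base. Substitutions are applied at
    the insert's recorded PAM location in both the pre- and post-edit
    sequences.
    """
    template = pam_template.upper()
    var = sorted(set(variable_positions))
    for p in var:
        if not (1 <= p <= len(template)):
            raise IndexError(f"variable position {p} outside template of length {len(template)}")
    if insert.pam_span_pre is None:
        raise SequenceError("insert does not record a PAM location")
    start_pre = insert.pam_span_pre[0]
    start_post = (insert.pam_span_post or insert.pam_span_pre)[0]
    if start_pre + len(template) > len(insert.pre_edit_seq):
        raise SequenceError("PAM template extends past the insert")

    def build(seq: str, start: int, assignment) -> str:
        region = list(seq[start:start + len(template)])
        for i, t in enumerate(template):
            if i + 1 in var:
                continue
            if t in "ACGT":
                region[i] = t
        for p, b in zip(var, assignment):
            region[p - 1] = b
        return seq[:start] + "".join(region) + seq[start + len(template):]

    variants = []
    for assignment in product("ACGT", repeat=len(var)):
        label = "".join(assignment) or "ref"
        variants.append(
            replace(
                insert,
                pre_edit_seq=build(insert.pre_edit_seq, start_pre, assignment),
                post_edit_seq=build(insert.post_edit_seq, start_post, assignment),
                name=f"{insert.name}-PAM-{label}",
            )
        )
    return variants
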