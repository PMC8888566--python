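"""Deterministic in-silico editing engines.

``simulate_prime_edit`` replays the prime-editing mechanism on a concrete
sequence: locate the protospacer+PAM (exact match), nick the PAM strand,
check PBS annealing, synthesize the RTT-templated 3' flap and resolve it
against the displaced strand. ``simulate_base_edit`` applies a base editor's
window conversion. ``simulate_digest_ligate`` and ``golden_gate_chain`` are
string-level restriction/ligation checkers used to validate cloning oligos.

These engines are design verifiers, not efficiency or off-target models:
site recognition is exact-match and a sequence with multiple protospacer
matches is rejected as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import (
    EditorProfile,
    SequenceError,
    as_bases,
    iupac_match,
    reverse_complement,
)

__all__ = [
    "EditOutcome",
    "AmbiguousSiteError",
    "LigationError",
    "Enzyme",
    "ENZYMES",
    "simulate_prime_edit",
    "simulate_base_edit",
    "simulate_digest_ligate",
    "golden_gate_chain",
]


class AmbiguousSiteError(SequenceError):
    """The spacer matches more than one protospacer+PAM site in the input."""


class LigationError(SequenceError):
    """Sticky-end mismatch during a simulated ligation."""


@dataclass
class EditOutcome:
    edited_seq: str
    status: str  # edited | no_site | pbs_mismatch | flap_mismatch
    diagnostics: dict = field(default_factory=dict)


def _find_site_matches(seq: str, spacer: str, profile: EditorProfile):
    """All (strand, oriented protospacer start) exact spacer+PAM matches."""
    L = len(spacer)
    hits = []
    for strand in ("+", "-"):
        oriented = seq if strand == "+" else reverse_complement(seq)
        start = 0
        while True:
            i = oriented.find(spacer, start)
            if i < 0:
                break
            start = i + 1
            for pat in profile.pam_patterns:
                pam = oriented[i + L:i + L + len(pat)]
                if len(pam) == len(pat) and iupac_match(pat, pam):
                    hits.append((strand, i))
                    break
    return hits


def simulate_prime_edit(
    seq,
    peg,
    profile: EditorProfile | None = None,
    min_homology: int = 1,
    max_shift: int = 10,
) -> EditOutcome:
    """Run the prime-editing mechanism on *seq* with pegRNA *peg*.

    Steps: exact protospacer+PAM search on both strands (ambiguity is an
    error); nick ``profile.nick_offset`` nt 5' of the PAM; require the PBS to
    be the exact reverse complement of the bases immediately 5' of the nick;
    replace the displaced strand with the flap. The number of displaced
    bases replaced (``k``) is chosen by maximal 3'-suffix homology of the
    flap against the pre-edit strand, searched within ``max_shift`` of
    ``len(flap)`` (ties prefer ``k == len(flap)``, then the nearest, then the
    smaller ``k``); a best homology below ``min_homology`` is a
    ``flap_mismatch``. Failures are reported via ``status``, never silently.
    """
    s = as_bases(seq)
    profile = profile or getattr(peg.site, "profile", None)
    if profile is None:
        raise SequenceError("simulate_prime_edit needs an editor profile")
    spacer = as_bases(peg.spacer)
    hits = _find_site_matches(s, spacer, profile)
    if not hits:
        return EditOutcome(s, "no_site", {"spacer": spacer})
    if len(hits) > 1:
        raise AmbiguousSiteError(
            f"spacer {spacer} matches {len(hits)} protospacer+PAM sites; "
            "editing target is ambiguous"
        )
    strand, i = hits[0]
    oriented = s if strand == "+" else reverse_complement(s)
    nick_idx = i + len(spacer) - profile.nick_offset
    diag = {"strand": strand, "protospacer_start_oriented": i, "nick_idx_oriented": nick_idx}

    pbs = as_bases(peg.pbs)
    if nick_idx < len(pbs) or oriented[nick_idx - len(pbs):nick_idx] != reverse_complement(pbs):
        diag["pbs_expected"] = reverse_complement(oriented[max(0, nick_idx - len(pbs)):nick_idx])
        return EditOutcome(s, "pbs_mismatch", diag)
    diag["pbs_ok"] = True

    flap = as_bases(peg.flap)
    downstream = oriented[nick_idx:]
    best = None  # (hom, k)
    k_lo = max(0, len(flap) - max_shift)
    k_hi = min(len(downstream), len(flap) + max_shift)
    for k in range(k_lo, k_hi + 1):
        h = 0
        while (
            h < min(len(flap), k)
            and flap[len(flap) - 1 - h] == downstream[k - 1 - h]
        ):
            h += 1
        key = (h, k == len(flap), -abs(k - len(flap)), -k)
        if best is None or key > best[0]:
            best = (key, k, h)
    _, k, hom = best
    diag["flap_replaced"] = k
    diag["flap_homology"] = hom
    if hom < min_homology:
        return EditOutcome(s, "flap_mismatch", diag)

    edited_oriented = oriented[:nick_idx] + flap + downstream[k:]
    edited = edited_oriented if strand == "+" else reverse_complement(edited_oriented)
    return EditOutcome(edited, "edited", diag)


def simulate_base_edit(seq, site, profile: EditorProfile, exhaustive: bool = False) -> list[EditOutcome]:
    """Apply a base editor's window conversion at *site*.

    Converts every ``base_conversion[0]`` base inside ``base_edit_window``
    (protospacer coordinates, PAM-distal base = 1) to ``base_conversion[1]``.
    Returns the all-converted outcome; with ``exhaustive`` every non-empty
    subset of convertible positions yields its own outcome (bystander
    analysis). No convertible base -> single ``no_site`` outcome.
    """
    if profile.mode != "base":
        raise SequenceError("simulate_base_edit requires a base-mode profile")
    s = as_bases(seq)
    n = len(s)
    strand = site.strand
    oriented = s if strand == "+" else reverse_complement(s)
    ps, _ = site.oriented_coords(n)
    frm, to = profile.base_conversion
    w_lo, w_hi = profile.base_edit_window
    positions = [
        ps + p - 1
        for p in range(w_lo, w_hi + 1)
        if ps + p - 1 < n and oriented[ps + p - 1] == frm
    ]
    if not positions:
        return [EditOutcome(s, "no_site", {"window": (w_lo, w_hi)})]

    def convert(subset):
        chars = list(oriented)
        for idx in subset:
            chars[idx] = to
        out = "".join(chars)
        return out if strand == "+" else reverse_complement(out)

    outcomes = [
        EditOutcome(convert(positions), "edited", {"converted": list(positions), "strand": strand})
    ]
    if exhaustive:
        from itertools import combinations

        for r in range(1, len(positions) + 1):
            for subset in combinations(positions, r):
                if list(subset) == positions:
                    continue
                outcomes.append(
                    EditOutcome(convert(subset), "edited", {"converted": list(subset), "strand": strand})
                )
    return outcomes


# ---------------------------------------------------------------------------
# restriction / ligation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Enzyme:
    """A type II restriction enzyme leaving a 4-nt 5' overhang.

    ``cut`` is the top-strand cut position within (for IIP) or downstream of
    (for IIS, with ``offset``) the recognition site.
    """

    name: str
    site: str
    cut: int
    overhang_len: int = 4

    @property
    def overhang(self) -> str:
        return self.site[self.cut:self.cut + self.overhang_len]


ENZYMES = {
    "SalI": Enzyme("SalI", "GTCGAC", 1),
    "Acc65I": Enzyme("Acc65I", "GGTACC", 1),
    # IIS Golden Gate cutters: overhang sequence is context-defined, the
    # `site` here is the recognition sequence only.
    "BsaI": Enzyme("BsaI", "GGTCTC", 1),
    "BbsI": Enzyme("BbsI", "GAAGAC", 2),
}


@dataclass
class JunctionReport:
    junction: str
    ligated: bool
    junction_seq: str
    site_regenerated: bool
    detail: str = ""


def simulate_digest_ligate(vector_ends: tuple, duplex: tuple[str, str]) -> dict:
    """Ligate an annealed (top, bottom) duplex into a doubly-cut vector.

    *vector_ends* names the two enzymes (objects or names from
    :data:`ENZYMES`) that cut the vector: the first defines the left junction
    (pairs the duplex top strand's 5' overhang), the second the right
    junction (pairs the bottom strand's 5' overhang). Returns a report with
    per-junction ligation status and whether each recognition site is
    regenerated; an overhang mismatch is reported as a failure naming the
    junction.
    """
    left, right = (
        e if isinstance(e, Enzyme) else ENZYMES[e] for e in vector_ends
    )
    top, bottom = as_bases(duplex[0]), as_bases(duplex[1])
    oh = left.overhang_len
    if bottom[oh:] != reverse_complement(top[oh:]):
        raise SequenceError("duplex strands do not anneal: bottom[%d:] != revcomp(top[%d:])" % (oh, oh))
    reports = []

    top_oh = top[:left.overhang_len]
    lig_l = top_oh == left.overhang
    jseq_l = left.site[:left.cut] + top[:len(left.site) - left.cut]
    reports.append(
        JunctionReport(
            "left:" + left.name,
            lig_l,
            jseq_l,
            lig_l and jseq_l.startswith(left.site),
            "" if lig_l else f"top overhang {top_oh} != vector overhang {left.overhang}",
        )
    )

    bot_oh = bottom[:right.overhang_len]
    want = reverse_complement(right.overhang)
    lig_r = bot_oh == want
    tail = len(right.site) - right.cut - right.overhang_len
    jseq_r = (top[-right.cut:] if right.cut else "") + right.overhang + right.site[right.cut + right.overhang_len:]
    reports.append(
        JunctionReport(
            "right:" + right.name,
            lig_r,
            jseq_r,
            lig_r and jseq_r == right.site,
            "" if lig_r else f"bottom overhang {bot_oh} != revcomp(vector overhang) {want}",
        )
    )
    return {
        "ok": all(r.ligated for r in reports),
        "junctions": reports,
        "failures": [r.junction for r in reports if not r.ligated],
    }


def golden_gate_chain(duplexes) -> str:
    """Assemble sticky-ended duplexes in order; return the assembled top strand.

    Consecutive duplexes ligate when the upstream duplex's bottom 5' overhang
    is the reverse complement of the downstream duplex's top 5' overhang.
    """
    duplexes = list(duplexes)
    if not duplexes:
        raise LigationError("no duplexes to assemble")
    for idx, (a, b) in enumerate(zip(duplexes, duplexes[1:])):
        a_bot, b_top = as_bases(a[1]), as_bases(b[0])
        if a_bot[:4] != reverse_complement(b_top[:4]):
            raise LigationError(
                f"junction {idx + 1}: overhang {a_bot[:4]} does not pair {b_top[:4]}"
            )
    return "".join(as_bases(d[0]) for d in duplexes)
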