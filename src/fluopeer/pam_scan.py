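"""Protospacer/PAM site enumeration around an edit.

Finds candidate protospacer+PAM sites for a given editor profile in a window
around the edited base, on both strands, and batch-counts PAM availability
over variant flank tables (the kind of census used to ask how many pathogenic
variants have a usable PAM nearby).

Window semantics: the window ``[window_start, window_end]`` constrains the
offset of the PAM's 5'-most base relative to the edited base, measured on the
PAM strand (for multi-base edits, the 5'-most edited base on that strand is
the anchor). The default window is -10..+4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import (
    EditSpec,
    EditorProfile,
    SequenceError,
    as_bases,
    iupac_match,
    mirror_edit,
    reverse_complement,
)

__all__ = ["ScanConfig", "SpacerSite", "PamScanResult", "find_spacer_sites", "scan_variant_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    window_start: int = -10
    window_end: int = 4
    patterns: tuple[str, ...] | None = None  # None -> use profile patterns
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise SequenceError("window_start must be <= window_end")
        if self.patterns is not None:
            object.__setattr__(self, "patterns", tuple(p.upper() for p in self.patterns))
            if not self.patterns:
                raise SequenceError("patterns must be non-empty when given")


@dataclass(frozen=True)
class SpacerSite:
    """A protospacer+PAM hit.

    ``spacer`` is given in PAM-strand orientation; ``protospacer_start`` and
    ``nick_position`` are 1-based top-strand coordinates (``nick_position`` is
    the base immediately 5' of the nicked phosphodiester bond on the PAM
    strand). ``nick_to_edit`` is the signed distance from the nick to the
    edited base along the PAM strand (0 = edit at the first base 3' of the
    nick).
    """

    strand: str
    spacer: str
    pam: str
    pam_pattern: str
    protospacer_start: int
    nick_position: int
    nick_to_edit: int
    pam_offset: int  # offset of PAM 5'-most base from the edit anchor, PAM strand
    profile: EditorProfile | None = field(default=None, compare=False)

    def oriented_coords(self, seq_len: int) -> tuple[int, int]:
        """(protospacer start, nick splice index), 0-based on the PAM strand."""
        L = len(self.spacer)
        if self.strand == "+":
            s = self.protospacer_start - 1
            nick_idx = self.nick_position
        else:
            s = seq_len - (self.protospacer_start - 1) - L
            nick_idx = seq_len - self.nick_position + 1
        return s, nick_idx


def _edit_anchor(edit: EditSpec) -> int:
    """0-based index of the 5'-most edited base (insertion: first new slot)."""
    return edit.ref_start0


def find_spacer_sites(
    target,
    edit: EditSpec,
    profile: EditorProfile,
    config: ScanConfig | None = None,
    require_edit_downstream: bool = True,
) -> list[SpacerSite]:
    """Enumerate protospacer/PAM sites near *edit* for *profile*.

    One :class:`SpacerSite` is returned per (strand, position, pattern) whose
    PAM offset falls inside the scan window. With ``require_edit_downstream``
    (the default), prime-editing candidacy is enforced: the edit must lie 3'
    of the nick on the PAM strand (``nick_to_edit >= 0``); for base-mode
    profiles the edited base must instead fall inside the editing window.
    Sites are sorted by ``|nick_to_edit|``, then strand ('+' first), then
    position, then pattern order.
    """
    seq = as_bases(target)
    edit.validate_against(seq)
    if config is None:
        if profile.mode == "base":
            # PAM offset implied by the editing window: an edited base at
            # protospacer position p sits spacer_length + 1 - p nt 5' of the PAM
            lo, hi = profile.base_edit_window
            config = ScanConfig(profile.spacer_length + 1 - hi, profile.spacer_length + 1 - lo)
        else:
            config = ScanConfig()
    patterns = config.patterns or profile.pam_patterns
    L = profile.spacer_length
    max_plen = max(len(p) for p in patterns)
    if len(seq) < L + max_plen:
        raise SequenceError(
            f"target of length {len(seq)} too short for a {L}-nt spacer plus "
            f"{max_plen}-nt PAM; need at least {L + max_plen} nt of flank"
        )

    n = len(seq)
    strands = ("+", "-") if config.both_strands else ("+",)
    pattern_order = {p: i for i, p in enumerate(patterns)}
    sites: list[SpacerSite] = []
    for strand in strands:
        if strand == "+":
            oriented, oedit = seq, edit
        else:
            oriented = reverse_complement(seq)
            oedit = mirror_edit(edit, n)
        a = _edit_anchor(oedit)
        for pat in patterns:
            plen = len(pat)
            lo = a + config.window_start
            hi = a + config.window_end
            for pam_start in range(max(L, lo), min(hi, n - plen) + 1):
                if not iupac_match(pat, oriented[pam_start:pam_start + plen]):
                    continue
                s = pam_start - L
                nick_idx = s + L - profile.nick_offset
                nick_to_edit = a - nick_idx
                if require_edit_downstream:
                    if profile.mode == "base":
                        ppos = a - s + 1  # PAM-distal protospacer base = 1
                        w_lo, w_hi = profile.base_edit_window
                        if not (w_lo <= ppos <= w_hi):
                            continue
                    elif nick_to_edit < 0:
                        continue
                if strand == "+":
                    proto_start1 = s + 1
                    nick_pos1 = nick_idx
                else:
                    proto_start1 = n - s - L + 1
                    nick_pos1 = n - nick_idx + 1
                sites.append(
                    SpacerSite(
                        strand=strand,
                        spacer=oriented[s:s + L],
                        pam=oriented[pam_start:pam_start + plen],
                        pam_pattern=pat,
                        protospacer_start=proto_start1,
                        nick_position=nick_pos1,
                        nick_to_edit=nick_to_edit,
                        pam_offset=pam_start - a,
                        profile=profile,
                    )
                )
    sites.sort(
        key=lambda st: (
            abs(st.nick_to_edit),
            0 if st.strand == "+" else 1,
            st.protospacer_start,
            pattern_order[st.pam_pattern],
        )
    )
    return sites


@dataclass
class PamScanResult:
    variant_id: str
    per_pattern: dict[str, int]
    total: int  # deduplicated by (strand, position) across patterns


def _row_to_edit(row) -> EditSpec:
    kind = str(row["kind"]).lower()
    kinds = {"sub": "substitution", "ins": "insertion", "del": "deletion"}
    kind = kinds.get(kind, kind)
    ref = "" if pd.isna(row.get("ref")) else str(row.get("ref", ""))
    alt = "" if pd.isna(row.get("alt")) else str(row.get("alt", ""))
    return EditSpec(kind, int(row["edit_pos"]), ref, alt)


def scan_variant_table(
    table,
    config: ScanConfig,
    profile: EditorProfile | None = None,
) -> tuple[list[PamScanResult], dict]:
    """Count in-window PAM availability for every variant in *table*.

    *table* is a DataFrame (or records) with columns ``variant_id, flank,
    edit_pos, kind, ref, alt``. The census counts every matching (strand,
    position, pattern) site in the window, without the prime-editing
    candidacy filter; the total per variant is deduplicated by (strand,
    position). Malformed rows are skipped with a logged warning and counted
    in the summary's error tally.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(list(table))
    patterns = config.patterns
    if patterns is None:
        raise SequenceError("scan_variant_table requires config.patterns")
    profile = profile or EditorProfile("scan", patterns)
    results: list[PamScanResult] = []
    errors = 0
    for _, row in table.iterrows():
        try:
            edit = _row_to_edit(row)
            sites = find_spacer_sites(
                str(row["flank"]), edit, profile, config, require_edit_downstream=False
            )
        except Exception as exc:  # malformed row: skip, tally
            logger.warning("skipping variant %s: %s", row.get("variant_id"), exc)
            errors += 1
            continue
        per_pattern = {p: 0 for p in patterns}
        seen = set()
        for st in sites:
            per_pattern[st.pam_pattern] += 1
            seen.add((st.strand, st.protospacer_start))
        results.append(
            PamScanResult(str(row["variant_id"]), per_pattern, total=len(seen))
        )

    totals = [r.total for r in results]
    summary = {
        "n_variants": len(results),
        "n_errors": errors,
        "mean_total": float(np.mean(totals)) if totals else 0.0,
        "median_total": float(np.median(totals)) if totals else 0.0,
        "per_pattern_mean": {
            p: (float(np.mean([r.per_pattern[p] for r in results])) if results else 0.0)
            for p in patterns
        },
        "histogram": dict(
            pd.Series(totals, dtype=int).value_counts().sort_index()
        ) if totals else {},
    }
    return results, summary


def results_to_frame(results: list[PamScanResult]) -> pd.DataFrame:
    """Tabulate scan results: one row per variant, one column per pattern."""
    rows = []
    for r in results:
        row = {"variant_id": r.variant_id}
        row.update(r.per_pattern)
        row["total"] = r.total
        rows.append(row)
    return pd.DataFrame(rows)
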