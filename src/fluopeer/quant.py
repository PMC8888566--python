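"""Editing quantification: FACS ratio scores and amplicon read classes.

The flow-cytometry readout is the mean Cherry intensity divided by the mean
GFP intensity over GFP-positive events (editing per transfected plasmid);
enrichment fractions report GFP+, GFP+Cherry+ and Cherry+|GFP+. Amplicon
reads are collapsed to alleles, filtered by a minimum allele frequency, and
classified against the unedited (reference) and intended (edited) amplicons
within a comparison window of +/-R bp around the predicted nick: alleles
carrying the intended edit with no indel in the window count as prime-edited,
alleles with an in-window insertion/deletion count as indel by-products.
Editing efficiency is 100 * intended / above-minimum-frequency reads.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .seqcore import SequenceError, as_bases

__all__ = [
    "GateConfig",
    "FacsEventTable",
    "ReadClassConfig",
    "ReadClassCounts",
    "facs_ratio_score",
    "enrichment_fractions",
    "classify_amplicon_reads",
    "rank_and_correlate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GateConfig:
    """Channel gates: fixed intensities or a negative-control quantile."""

    gfp_threshold: float | str = "control-quantile"
    cherry_threshold: float | str = "control-quantile"
    control_quantile: float = 0.999

    def __post_init__(self) -> None:
        for t in (self.gfp_threshold, self.cherry_threshold):
            if isinstance(t, str):
                if t != "control-quantile":
                    raise SequenceError(f"unknown gate mode {t!r}")
            elif t < 0:
                raise SequenceError("gate thresholds must be >= 0")
        if not (0 < self.control_quantile < 1):
            raise SequenceError("control_quantile must be in (0, 1)")


@dataclass
class FacsEventTable:
    """Per-event GFP/Cherry intensities plus the gating configuration."""

    events: pd.DataFrame  # columns: gfp, cherry
    gate: GateConfig = field(default_factory=GateConfig)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.events)
        missing = {"gfp", "cherry"} - set(df.columns)
        if missing:
            raise SequenceError(f"event table missing columns {sorted(missing)}")
        vals = df[["gfp", "cherry"]].to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise SequenceError("intensities must be finite and >= 0")
        self.events = df

    @classmethod
    def from_csv(cls, path, gate: GateConfig | None = None) -> "FacsEventTable":
        return cls(pd.read_csv(path), gate or GateConfig())

    def resolve_gates(self, control: "FacsEventTable | None" = None) -> tuple[float, float]:
        def one(threshold, channel):
            if isinstance(threshold, str):
                if control is None:
                    raise SequenceError(
                        "control-quantile gating requires a negative-control event table"
                    )
                return float(
                    control.events[channel].quantile(self.gate.control_quantile)
                )
            return float(threshold)

        return one(self.gate.gfp_threshold, "gfp"), one(self.gate.cherry_threshold, "cherry")


def facs_ratio_score(
    events: FacsEventTable, control: FacsEventTable | None = None
) -> tuple[float, int]:
    """Cherry/GFP mean-intensity ratio over GFP-positive events.

    Returns ``(ratio, n_gfp_positive)``; zero GFP+ events is an error (no
    transfected cells to score).
    """
    gfp_thr, _ = events.resolve_gates(control)
    pos = events.events[events.events["gfp"] > gfp_thr]
    if len(pos) == 0:
        raise SequenceError("no GFP-positive events above the gate; nothing transfected?")
    ratio = float(pos["cherry"].mean() / pos["gfp"].mean())
    return ratio, int(len(pos))


def enrichment_fractions(
    events: FacsEventTable, control: FacsEventTable | None = None
) -> dict:
    """Fractions of GFP+, GFP+Cherry+ (of all events) and Cherry+ given GFP+."""
    gfp_thr, cherry_thr = events.resolve_gates(control)
    df = events.events
    n = len(df)
    gfp_pos = df["gfp"] > gfp_thr
    double = gfp_pos & (df["cherry"] > cherry_thr)
    f_gfp = float(gfp_pos.sum() / n) if n else 0.0
    f_double = float(double.sum() / n) if n else 0.0
    f_cond = float(double.sum() / gfp_pos.sum()) if gfp_pos.sum() else None
    return {
        "gfp_pos": f_gfp,
        "gfp_cherry_pos": f_double,
        "cherry_pos_given_gfp_pos": f_cond,
        "n_events": n,
        "n_gfp_pos": int(gfp_pos.sum()),
    }


# ---------------------------------------------------------------------------
# amplicon read classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadClassConfig:
    """Comparison range and allele-frequency floor for read classification.

    ``comparison_range_R`` is the half-width: R=70 means 140 bp flanking the
    predicted nick are considered. ``nick_position`` is 1-based on the
    amplicon.
    """

    nick_position: int
    comparison_range_R: int = 70
    min_freq: float = 0.0
    match_score: float = 2.0
    mismatch_score: float = -4.0
    open_gap_score: float = -10.0
    extend_gap_score: float = -1.0
    probe_flank: int = 5

    def __post_init__(self) -> None:
        if self.comparison_range_R <= 0:
            raise SequenceError("comparison range R must be > 0")
        if not (0 <= self.min_freq < 1):
            raise SequenceError("min_freq must be in [0, 1)")
        if self.nick_position < 1:
            raise SequenceError("nick_position is 1-based")

    @property
    def window_width(self) -> int:
        """Total flank considered around the nick (2R bp)."""
        return 2 * self.comparison_range_R


@dataclass
class ReadClassCounts:
    total_reads: int
    above_min_freq_reads: int
    intended_edit_reads: int
    indel_reads: int
    unedited_reads: int
    other_reads: int

    def __post_init__(self) -> None:
        s = self.intended_edit_reads + self.indel_reads + self.unedited_reads + self.other_reads
        if s != self.above_min_freq_reads:
            raise SequenceError("class counts do not sum to above_min_freq_reads")

    @property
    def pe_efficiency_pct(self) -> float:
        if self.above_min_freq_reads == 0:
            return 0.0
        return 100.0 * self.intended_edit_reads / self.above_min_freq_reads

    @property
    def indel_pct(self) -> float:
        if self.above_min_freq_reads == 0:
            return 0.0
        return 100.0 * self.indel_reads / self.above_min_freq_reads


def _aligner(config: ReadClassConfig) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = config.match_score
    al.mismatch_score = config.mismatch_score
    al.open_gap_score = config.open_gap_score
    al.extend_gap_score = config.extend_gap_score
    return al


def _diff_interval(wt: str, ed: str) -> tuple[int, int, int]:
    """Locate the edit as (start, end_on_wt, end_on_ed), 0-based half-open."""
    pre = 0
    while pre < min(len(wt), len(ed)) and wt[pre] == ed[pre]:
        pre += 1
    suf = 0
    while (
        suf < min(len(wt), len(ed)) - pre
        and wt[len(wt) - 1 - suf] == ed[len(ed) - 1 - suf]
    ):
        suf += 1
    return pre, len(wt) - suf, len(ed) - suf


def _windowed_compare(read: str, ref: str, aligner, win_lo: int, win_hi: int,
                      probe: tuple[int, int] | None = None):
    """Align *read* to *ref*; report in-window gap presence and whether the
    read reproduces *ref* exactly over the *probe* interval.

    Window bounds are 0-based half-open reference coordinates. Insertions are
    attributed to the reference coordinate they occur at.
    """
    aln = aligner.align(ref, read)[0]
    ref_blocks, read_blocks = aln.aligned
    gap_in_window = False
    # deletions / insertions between consecutive aligned blocks
    prev_r_end = prev_q_end = None
    events = []
    for (r0, r1), (q0, q1) in zip(ref_blocks, read_blocks):
        if prev_r_end is not None:
            if r0 > prev_r_end:  # deletion in read
                events.append(("del", prev_r_end, r0))
            if q0 > prev_q_end:  # insertion in read
                events.append(("ins", prev_r_end, prev_r_end))
        prev_r_end, prev_q_end = r1, q1
    # terminal gaps (global alignment soft spots)
    if ref_blocks.size:
        if ref_blocks[0][0] > 0:
            events.append(("del", 0, ref_blocks[0][0]))
        if ref_blocks[-1][1] < len(ref):
            events.append(("del", ref_blocks[-1][1], len(ref)))
    for kind, lo, hi in events:
        if kind == "ins":
            if win_lo <= lo <= win_hi:
                gap_in_window = True
        elif lo < win_hi and hi > win_lo:
            gap_in_window = True
    probe_match = None
    if probe is not None:
        p_lo, p_hi = probe
        matched = 0
        for (r0, r1), (q0, q1) in zip(ref_blocks, read_blocks):
            lo, hi = max(r0, p_lo), min(r1, p_hi)
            for i in range(lo, hi):
                if ref[i] == read[q0 + (i - r0)]:
                    matched += 1
        probe_match = matched == (p_hi - p_lo)
    return gap_in_window, probe_match


def classify_amplicon_reads(
    reads,
    wt_amplicon,
    edited_amplicon,
    config: ReadClassConfig,
) -> ReadClassCounts:
    """Classify amplicon reads into intended / unedited / indel / other.

    Reads (strings, Biopython records, or an iterable of either) are
    collapsed to alleles; alleles below ``min_freq`` are excluded from the
    denominator. Each remaining allele is classified inside the window
    ``[nick - R, nick + R]``: the intended edit present with no in-window
    indel -> intended; matching the reference with no in-window indel ->
    unedited; an in-window insertion/deletion -> indel; anything else ->
    other. An allele that carries the intended edit but also an extra
    in-window indel counts as indel (conservative tie-break).
    """
    wt = as_bases(wt_amplicon)
    ed = as_bases(edited_amplicon)
    if not (1 <= config.nick_position <= len(wt)) or not (1 <= config.nick_position <= len(ed)):
        raise SequenceError("nick position outside the amplicons")
    seqs = []
    for r in reads:
        seqs.append(as_bases(getattr(r, "seq", r)))
    total = len(seqs)
    alleles = Counter(seqs)
    keep = {a: c for a, c in alleles.items() if total and c / total >= config.min_freq}
    above = sum(keep.values())

    aligner = _aligner(config)
    nick0 = config.nick_position - 1
    R = config.comparison_range_R
    win_wt = (max(0, nick0 - R), min(len(wt), nick0 + R))
    win_ed = (max(0, nick0 - R), min(len(ed), nick0 + R))
    # edit locus plus anchoring flank on each side
    d_lo, d_hi_wt, d_hi_ed = _diff_interval(wt, ed)
    fl = config.probe_flank
    probe_wt = (max(0, d_lo - fl), min(len(wt), d_hi_wt + fl))
    probe_ed = (max(0, d_lo - fl), min(len(ed), d_hi_ed + fl))

    intended = indel = unedited = other = 0
    for allele, count in keep.items():
        if len(allele) < min(win_wt[1] - win_wt[0], win_ed[1] - win_ed[0]):
            logger.warning("read allele shorter than the comparison window; counted as other")
            other += count
            continue
        if allele == ed:
            intended += count
            continue
        if allele == wt:
            unedited += count
            continue
        gap_ed, edit_installed = _windowed_compare(allele, ed, aligner, *win_ed, probe=probe_ed)
        if not gap_ed and edit_installed:
            intended += count
            continue
        gap_wt, is_ref = _windowed_compare(allele, wt, aligner, *win_wt, probe=probe_wt)
        if gap_wt:
            indel += count
        elif is_ref:
            unedited += count
        else:
            other += count
    return ReadClassCounts(
        total_reads=total,
        above_min_freq_reads=above,
        intended_edit_reads=intended,
        indel_reads=indel,
        unedited_reads=unedited,
        other_reads=other,
    )


def rank_and_correlate(scores_a, scores_b) -> tuple[pd.DataFrame, float, float]:
    """Rank two scorings of the same conditions; Spearman rho and Pearson r.

    Inputs are (condition, value) pairs or mappings over an identical
    condition set (n >= 3); ties receive average ranks. Returns the joined
    rank table plus (rho, r).
    """
    a = dict(scores_a if not isinstance(scores_a, dict) else scores_a.items())
    b = dict(scores_b if not isinstance(scores_b, dict) else scores_b.items())
    if set(a) != set(b):
        only_a, only_b = sorted(set(a) - set(b)), sorted(set(b) - set(a))
        raise SequenceError(
            f"condition sets differ: only in A {only_a}, only in B {only_b}"
        )
    if len(a) < 3:
        raise SequenceError("need at least 3 conditions to correlate")
    conditions = sorted(a)
    va = np.array([float(a[c]) for c in conditions])
    vb = np.array([float(b[c]) for c in conditions])
    table = pd.DataFrame(
        {
            "condition": conditions,
            "value_a": va,
            "value_b": vb,
            "rank_a": stats.rankdata(va),
            "rank_b": stats.rankdata(vb),
        }
    )
    rho = float(stats.spearmanr(va, vb).statistic)
    r = float(stats.pearsonr(va, vb).statistic)
    return table, rho, r
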