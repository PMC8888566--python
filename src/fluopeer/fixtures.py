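"""Seeded synthetic-data generators.

Every module in the package is testable without downloads: random targets
with a valid random edit, FACS event tables with three planted log-normal
populations (untransfected / transfected-unedited / transfected-edited),
and amplicon read sets with planted intended/indel fractions and optional
uniform per-base error. All generators are deterministic under a fixed
seed, and each returns a truth record consistent with the emitted data.

The FACS populations use log-normal intensities with configurable means and
dispersion; the default separation is wide so that truth-derived gates
recover the planted fractions exactly. Indel alleles are placed at the nick
(1-3 bp by default), where prime-editing by-products cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import FacsEventTable, GateConfig
from .seqcore import EditSpec, NucleotideSequence, SequenceError, as_bases

__all__ = ["FixtureSpec", "gen_random_target", "gen_facs_events", "gen_amplicon_reads"]

_FRACTION_KEYS = (
    "gfp_pos_frac",
    "edited_given_gfp_frac",
    "edited_frac",
    "indel_frac",
    "other_frac",
    "error_rate",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Seed, size and planted parameters for a synthetic fixture."""

    seed: int
    n: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SequenceError("fixture size n must be >= 1")
        for key in _FRACTION_KEYS:
            v = self.params.get(key)
            if v is not None and not (0 <= v <= 1):
                raise SequenceError(f"{key}={v} outside [0, 1]")
        total = sum(self.params.get(k, 0) for k in ("edited_frac", "indel_frac", "other_frac"))
        if total > 1:
            raise SequenceError(f"planted read fractions sum to {total} > 1")


def gen_random_target(
    seed: int, length: int, gc_fraction: float = 0.5
) -> tuple[NucleotideSequence, EditSpec]:
    """A random target of the requested GC content plus a valid random edit.

    The edit (substitution, or a 1-6 bp insertion/deletion) is placed in the
    central 30-70% of the target so that design windows have flank on both
    sides. Deterministic under a fixed seed.
    """
    if length < 45:
        raise SequenceError("target length must be >= 45 (minimum insert window)")
    if not (0 < gc_fraction < 1):
        raise SequenceError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    bases = "".join(rng.choice(list("ACGT"), size=length, p=p))
    seq = NucleotideSequence(bases, name=f"target-seed{seed}")

    kind = rng.choice(["substitution", "insertion", "deletion"])
    pos = int(rng.integers(int(0.3 * length), int(0.7 * length)) + 1)
    if kind == "substitution":
        ref = bases[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        edit = EditSpec("substitution", pos, ref, alt)
    elif kind == "insertion":
        k = int(rng.integers(1, 7))
        alt = "".join(rng.choice(list("ACGT"), size=k))
        edit = EditSpec("insertion", pos, "", alt)
    else:
        k = int(rng.integers(1, 7))
        edit = EditSpec("deletion", pos, bases[pos - 1:pos - 1 + k], "")
    return seq, edit


def gen_facs_events(spec: FixtureSpec) -> tuple[FacsEventTable, dict]:
    """Synthetic FACS event table with three planted populations.

    Populations: untransfected (both channels background), transfected but
    unedited (GFP high, Cherry background) and transfected+edited (both
    high). Intensities are log-normal; the returned truth record carries the
    planted counts and midpoint gates that separate the populations.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    gfp_frac = p.get("gfp_pos_frac", 0.6)
    edited_frac = p.get("edited_given_gfp_frac", 0.25)
    mu_bg = np.log(p.get("background_mean", 10.0))
    mu_hi = np.log(p.get("positive_mean", 1000.0))
    sigma = p.get("sigma", 0.25)

    n = spec.n
    n_trans = round(n * gfp_frac)
    n_edit = round(n_trans * edited_frac)
    n_unedit = n_trans - n_edit
    n_bg = n - n_trans

    def lognorm(mu, size):
        return np.exp(rng.normal(mu, sigma, size))

    gfp = np.concatenate([lognorm(mu_bg, n_bg), lognorm(mu_hi, n_unedit), lognorm(mu_hi, n_edit)])
    cherry = np.concatenate([lognorm(mu_bg, n_bg), lognorm(mu_bg, n_unedit), lognorm(mu_hi, n_edit)])
    order = rng.permutation(n)
    df = pd.DataFrame({"gfp": gfp[order], "cherry": cherry[order]})
    gate_value = float(np.exp((mu_bg + mu_hi) / 2))
    table = FacsEventTable(df, GateConfig(gfp_threshold=gate_value, cherry_threshold=gate_value))
    truth = {
        "n": n,
        "n_untransfected": int(n_bg),
        "n_transfected_unedited": int(n_unedit),
        "n_transfected_edited": int(n_edit),
        "gfp_pos_frac": n_trans / n,
        "gfp_cherry_pos_frac": n_edit / n,
        "edited_given_gfp_frac": (n_edit / n_trans) if n_trans else None,
        "gate": gate_value,
    }
    return table, truth


def gen_amplicon_reads(
    wt_amplicon, edited_amplicon, spec: FixtureSpec
) -> tuple[list[str], dict]:
    """Synthetic merged amplicon reads with planted class fractions.

    Reads are drawn from {edited, indel-at-nick, other, unedited(wt)} with
    planted fractions (counts are exact: ``round(frac * n)``). Indel alleles
    insert or delete 1-3 bp at the nick. ``error_rate`` applies a uniform
    per-base substitution error on top. Returns (reads, truth).
    """
    wt = as_bases(wt_amplicon)
    ed = as_bases(edited_amplicon)
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    nick0 = int(p.get("nick_position", len(wt) // 2)) - 1
    if not (0 < nick0 < len(wt)):
        raise SequenceError("nick_position outside the amplicon")
    f_ed = p.get("edited_frac", 0.3)
    f_indel = p.get("indel_frac", 0.1)
    f_other = p.get("other_frac", 0.0)
    err = p.get("error_rate", 0.0)
    max_indel = int(p.get("max_indel", 3))

    n = spec.n
    n_ed = round(f_ed * n)
    n_indel = round(f_indel * n)
    n_other = round(f_other * n)
    n_wt = n - n_ed - n_indel - n_other

    reads: list[str] = []
    reads += [ed] * n_ed
    for _ in range(n_indel):
        # reject alleles that collide with the wt or intended sequence
        # (e.g. a 1-bp deletion inside a homopolymer spanning the edit)
        for _attempt in range(50):
            size = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5 and nick0 + size <= len(wt):
                allele = wt[:nick0] + wt[nick0 + size:]
            else:
                ins = "".join(rng.choice(list("ACGT"), size=size))
                allele = wt[:nick0] + ins + wt[nick0:]
            if allele != wt and allele != ed:
                break
        else:
            raise SequenceError("cannot plant a distinct indel allele at the nick")
        reads.append(allele)
    for _ in range(n_other):
        # scrambled window: neither wt nor edited nor a clean indel
        mid = list(wt)
        for j in range(nick0 - 2, nick0 + 3):
            mid[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mid[j]]
        reads.append("".join(mid))
    reads += [wt] * n_wt

    if err > 0:
        noisy = []
        for r in reads:
            chars = list(r)
            hits = np.nonzero(rng.random(len(chars)) < err)[0]
            for i in hits:
                chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
            noisy.append("".join(chars))
        reads = noisy
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = {
        "n": n,
        "n_edited": n_ed,
        "n_indel": n_indel,
        "n_other": n_other,
        "n_wt": n_wt,
        "edited_frac": n_ed / n,
        "indel_frac": n_indel / n,
        "nick_position": nick0 + 1,
        "error_rate": err,
    }
    return reads, truth
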