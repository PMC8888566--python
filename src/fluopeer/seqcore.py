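"""Foundational sequence types and operations.

Everything downstream (PAM scanning, pegRNA design, reporter design, the
editing simulators) is built on the small vocabulary defined here: a strictly
validated DNA sequence, an edit specification (substitution / insertion /
deletion with 1-based top-strand coordinates), and an editor profile
describing PAM preferences and nick geometry.

Coordinate conventions
----------------------
User-facing coordinates are 1-based and inclusive, matching molecular-biology
convention. Internally everything is 0-based half-open. Inserted bases are
placed immediately 3' of ``position`` on the top strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

__all__ = [
    "NucleotideSequence",
    "EditSpec",
    "EditorProfile",
    "SequenceError",
    "RefMismatchError",
    "reverse_complement",
    "translate_frame",
    "find_stop_codons",
    "apply_edit",
    "invert_edit",
    "mirror_edit",
    "iupac_match",
    "parse_edit_string",
    "as_bases",
]

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC nucleotide ambiguity codes -> allowed concrete bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

STOP_CODONS = ("TAA", "TAG", "TGA")


class SequenceError(ValueError):
    """Invalid sequence, edit or profile definition."""


class RefMismatchError(SequenceError):
    """The edit's reference allele does not match the target sequence."""


def _normalize(bases: str) -> str:
    s = str(bases).strip().upper().replace("U", "T")
    bad = set(s) - _DNA
    if bad:
        raise SequenceError(
            f"sequence contains non-ACGT characters: {sorted(bad)!r}"
        )
    if not s:
        raise SequenceError("sequence must contain at least one base")
    return s


@dataclass(frozen=True)
class NucleotideSequence:
    """An ungapped uppercase DNA sequence over {A,C,G,T}.

    Lowercase input is uppercased and U is mapped to T; anything else is
    rejected. The class behaves like a string for slicing/len/iteration.
    """

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _normalize(self.bases))

    def __str__(self) -> str:
        return self.bases

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, idx):
        return self.bases[idx]

    def __iter__(self):
        return iter(self.bases)

    def __eq__(self, other) -> bool:
        if isinstance(other, NucleotideSequence):
            return self.bases == other.bases
        if isinstance(other, str):
            return self.bases == other
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.bases)

    def gc_count(self) -> int:
        return self.bases.count("G") + self.bases.count("C")

    def gc_fraction(self) -> float:
        return self.gc_count() / len(self)


def as_bases(seq) -> str:
    """Return the validated uppercase base string of *seq* (str or sequence)."""
    if isinstance(seq, NucleotideSequence):
        return seq.bases
    return _normalize(seq)


@dataclass(frozen=True)
class EditSpec:
    """A substitution, insertion or deletion on a target's top strand.

    ``position`` is 1-based; for insertions it names the base immediately 5'
    of the inserted bases (the new bases land between ``position`` and
    ``position + 1``).
    """

    kind: str  # substitution | insertion | deletion
    position: int
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise SequenceError(f"unknown edit kind {self.kind!r}")
        object.__setattr__(self, "ref", self.ref.upper().replace("U", "T"))
        object.__setattr__(self, "alt", self.alt.upper().replace("U", "T"))
        for allele in (self.ref, self.alt):
            if set(allele) - _DNA:
                raise SequenceError(f"edit allele {allele!r} is not DNA")
        if self.position < 0 or (self.kind != "insertion" and self.position < 1):
            raise SequenceError("edit position must be positive")
        if self.kind == "substitution":
            if not self.ref or len(self.ref) != len(self.alt):
                raise SequenceError("substitution requires len(ref)==len(alt)>=1")
        elif self.kind == "deletion":
            if not self.ref or self.alt:
                raise SequenceError("deletion requires non-empty ref and empty alt")
        else:  # insertion
            if self.ref or not self.alt:
                raise SequenceError("insertion requires empty ref and non-empty alt")
        if self.ref == self.alt:
            raise SequenceError("ref and alt must differ")

    # -- derived geometry (0-based, on the top strand) --------------------
    @property
    def ref_start0(self) -> int:
        """0-based index of the first reference base affected.

        For insertions this is the index where the first inserted base will
        appear in the edited sequence (one past ``position``).
        """
        if self.kind == "insertion":
            return self.position
        return self.position - 1

    @property
    def ref_end0(self) -> int:
        return self.ref_start0 + len(self.ref)

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def validate_against(self, seq) -> None:
        s = as_bases(seq)
        if self.kind == "insertion":
            if not (0 <= self.position <= len(s)):
                raise SequenceError(
                    f"insertion position {self.position} outside sequence of length {len(s)}"
                )
            return
        if self.ref_end0 > len(s):
            raise SequenceError(
                f"edit at {self.position} (+{len(self.ref)} bp) overruns sequence of length {len(s)}"
            )
        observed = s[self.ref_start0:self.ref_end0]
        if observed != self.ref:
            raise RefMismatchError(
                f"reference mismatch at position {self.position}: "
                f"expected {self.ref!r}, observed {observed!r}"
            )


@dataclass(frozen=True)
class EditorProfile:
    """PAM preference and nick/editing geometry of a Cas9-derived editor.

    ``nick_offset`` is the distance of the nick 5' of the PAM on the
    protospacer strand: the default of 3 places the nick between protospacer
    positions 17 and 18, the canonical SpCas9 H840A nickase geometry.
    Base editors (``mode='base'``) declare an editing window in protospacer
    coordinates (PAM-distal base = position 1) and a single base conversion.
    """

    name: str
    pam_patterns: tuple[str, ...]
    spacer_length: int = 20
    nick_offset: int = 3
    mode: str = "prime"  # prime | base
    base_edit_window: tuple[int, int] | None = None
    base_conversion: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        pats = tuple(p.upper() for p in self.pam_patterns)
        object.__setattr__(self, "pam_patterns", pats)
        if not pats:
            raise SequenceError("profile needs at least one PAM pattern")
        for p in pats:
            if not p or set(p) - set(IUPAC):
                raise SequenceError(f"invalid IUPAC PAM pattern {p!r}")
        if not (0 < self.nick_offset < self.spacer_length):
            raise SequenceError("0 < nick_offset < spacer_length required")
        if self.mode not in ("prime", "base"):
            raise SequenceError(f"unknown editor mode {self.mode!r}")
        has_base_fields = self.base_edit_window is not None and self.base_conversion is not None
        if (self.mode == "base") != has_base_fields:
            raise SequenceError("base_edit_window/base_conversion present iff mode=='base'")
        if self.mode == "base":
            lo, hi = self.base_edit_window
            if not (1 <= lo <= hi <= self.spacer_length):
                raise SequenceError("base_edit_window outside protospacer")
            frm, to = self.base_conversion
            if frm not in _DNA or to not in _DNA or frm == to:
                raise SequenceError("base_conversion must be two distinct bases")

    def with_(self, **kw) -> "EditorProfile":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def reverse_complement(seq):
    """Watson-Crick reverse complement; returns the same type it was given."""
    if isinstance(seq, NucleotideSequence):
        return NucleotideSequence(seq.bases.translate(_COMPLEMENT)[::-1], name=seq.name)
    return as_bases(seq).translate(_COMPLEMENT)[::-1]


def translate_frame(seq, offset: int = 0, strand: str = "+") -> str:
    """Translate codons starting at *offset* (0..2) on the given strand.

    The trailing partial codon is ignored; stop codons render as ``'*'``.
    """
    if offset not in (0, 1, 2):
        raise SequenceError("frame offset must be 0, 1 or 2")
    if strand not in ("+", "-"):
        raise SequenceError("strand must be '+' or '-'")
    s = as_bases(seq)
    if strand == "-":
        s = reverse_complement(s)
    s = s[offset:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    return str(Seq(s).translate())


def find_stop_codons(seq, offset: int = 0, strand: str = "+") -> list[int]:
    """1-based top-strand positions of the first base of each stop codon.

    The frame is defined by *offset* on the chosen strand; for '-' the codon's
    "first base" is its 5'-most base on the minus strand, reported at its
    top-strand coordinate. Positions are sorted ascending.
    """
    s = as_bases(seq)
    n = len(s)
    read = reverse_complement(s) if strand == "-" else s
    out = []
    for i in range(offset, n - 2, 3):
        if read[i:i + 3] in STOP_CODONS:
            out.append(i + 1 if strand == "+" else n - i)
    return sorted(out)


def apply_edit(seq, edit: EditSpec):
    """Apply *edit* to *seq*, returning a sequence of the same type."""
    s = as_bases(seq)
    edit.validate_against(s)
    a, b = edit.ref_start0, edit.ref_end0
    if edit.kind == "insertion":
        a = b = edit.position
    out = s[:a] + edit.alt + s[b:]
    if isinstance(seq, NucleotideSequence):
        return NucleotideSequence(out, name=seq.name)
    return out


def invert_edit(edit: EditSpec) -> EditSpec:
    """The edit that undoes *edit* on the edited sequence."""
    if edit.kind == "substitution":
        return EditSpec("substitution", edit.position, edit.alt, edit.ref)
    if edit.kind == "deletion":
        return EditSpec("insertion", edit.position - 1, "", edit.ref)
    return EditSpec("deletion", edit.position + 1, edit.alt, "")


def mirror_edit(edit: EditSpec, length: int) -> EditSpec:
    """The same physical edit expressed on the reverse complement strand."""
    if edit.kind == "insertion":
        return EditSpec(
            "insertion", length - edit.position, "", reverse_complement(edit.alt)
        )
    pos = length - (edit.position + len(edit.ref) - 1) + 1
    return EditSpec(
        edit.kind,
        pos,
        reverse_complement(edit.ref),
        reverse_complement(edit.alt) if edit.alt else "",
    )


def iupac_match(pattern: str, bases: str) -> bool:
    """True if *bases* matches the IUPAC *pattern* position by position."""
    if len(pattern) != len(bases):
        return False
    return all(b in IUPAC[p] for p, b in zip(pattern.upper(), bases))


_EDIT_RE = re.compile(
    r"^(?P<kind>sub|ins|del):(?P<pos>\d+):(?P<ref>[ACGTUacgtu]*)>(?P<alt>[ACGTUacgtu]*)$"
)
_KINDS = {"sub": "substitution", "ins": "insertion", "del": "deletion"}


def parse_edit_string(text: str) -> EditSpec:
    """Parse the CLI edit syntax ``KIND:POS:REF>ALT`` (e.g. ``sub:1399:G>A``)."""
    m = _EDIT_RE.match(text.strip())
    if not m:
        raise SequenceError(
            f"cannot parse edit {text!r}; expected KIND:POS:REF>ALT with KIND in sub/ins/del"
        )
    return EditSpec(_KINDS[m["kind"]], int(m["pos"]), m["ref"], m["alt"])
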