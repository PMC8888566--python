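"""Built-in editor profiles.

PAM preferences follow the published specificities of the SpCas9 prime-editor
variants (PE2: NGG; NG-PE2: NG; SpG-PE2: NGN; SpRY-PE2: effectively PAM-less,
modelled as NNN) and the ABE8e adenine base editor (NGG, A->G, editing window
at protospacer positions 4-8, PAM-distal base = 1; the window is configurable
because reported windows vary between deaminase fusions).
"""

from __future__ import annotations

from .seqcore import EditorProfile

PE2 = EditorProfile("PE2", ("NGG",))
NG_PE2 = EditorProfile("NG-PE2", ("NG",))
SPG_PE2 = EditorProfile("SpG-PE2", ("NGN",))
SPRY_PE2 = EditorProfile("SpRY-PE2", ("NNN",))
ABE8E = EditorProfile(
    "ABE8e",
    ("NGG",),
    mode="base",
    base_edit_window=(4, 8),
    base_conversion=("A", "G"),
)

PROFILES: dict[str, EditorProfile] = {
    p.name: p for p in (PE2, NG_PE2, SPG_PE2, SPRY_PE2, ABE8E)
}


def get_profile(name: str) -> EditorProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown editor profile {name!r}; known: {', '.join(sorted(PROFILES))}"
        ) from None
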