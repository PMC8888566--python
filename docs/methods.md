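# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order a design flows through it.

## Coordinates and edit semantics

User-facing coordinates are 1-based inclusive on the target's top strand;
internally everything is 0-based half-open. An insertion at position *p*
places its bases immediately 3′ of *p*. Targets are concrete A/C/G/T
sequences (U is normalized to T on input); IUPAC ambiguity codes are
honoured only in PAM patterns. Multi-base edits are anchored at their
5′-most edited base.

## Editor profiles and site scanning

An `EditorProfile` holds ordered IUPAC PAM patterns, the spacer length
(20), and the nick offset — 3 nt 5′ of the PAM, i.e. between protospacer
positions 17/18, the canonical SpCas9 H840A nickase geometry; the source
protocol does not state it, so it is configurable per profile. Shipped
profiles: PE2 (NGG), NG-PE2 (NG), SpG-PE2 (NGN), SpRY-PE2 (modelled as
NNN), and ABE8e (NGG, A→G, editing window 4–8 in protospacer coordinates
with the PAM-distal base as position 1 — reported windows vary between
deaminase fusions, so the window is configurable).

`find_spacer_sites` scans both strands. The window (default −10..+4 bp)
constrains the offset of the PAM's 5′-most base from the edited base,
measured on the PAM strand. This anchor choice is one of several defensible
readings of "the region around the target site"; it is the simplest, and
the window is fully configurable to cover the alternatives. Prime-editing
candidacy additionally requires the edit to lie 3′ of the nick on the PAM
strand (`nick_to_edit ≥ 0`). For base-mode profiles the candidacy criterion
is instead that the edited base falls inside the editing window, and the
default scan window is derived from it (an edited base at protospacer
position *p* sits 21 − *p* nt 5′ of the PAM). Sites matching several
patterns are reported once per pattern; batch censuses
(`scan_variant_table`) deduplicate totals by (strand, position) and skip
the candidacy filter, since they count PAM availability, not designability.

## pegRNA design

Candidates are enumerated over the PBS × RTT grid — PBS 9–15 nt with at
least 5 G/C, RTT 10–20 nt — and kept when the flap (the RTT-templated DNA,
equal to the post-edit PAM-strand sequence starting at the nick) covers the
entire alternate allele plus at least one downstream homologous base, and
when the prime-editing simulator verifies that the flap reproduces the
post-edit sequence on the full target. Ordering prefers |PBS−12| then
|RTT−15|; this is a documented tie-break, not an efficiency claim — no
scoring model is bundled, and spacer on-target scoring is a pluggable hook
left empty. An RTT beginning with C triggers a warning (scaffold-pairing
guidance), never a filter. The scaffold constant is the canonical SpCas9
single-guide scaffold and is user-replaceable; the epegRNA 3′ motif ships
as a synthetic placeholder that must be replaced with the real structured
motif before synthesis.

Nicking guides are scanned on the strand opposite the pegRNA's PAM strand
within ±100 bp (default) of the pegRNA nick, with spacers taken from the
post-edit sequence. A guide is flagged PE3b when its footprint overlaps the
edited bases and its spacer no longer matches the pre-edit sequence; a
validator cross-checks every flag by direct string comparison.

## Editing simulation and flap resolution

`simulate_prime_edit` is a design verifier, not an efficiency or off-target
model: protospacer+PAM recognition is exact-match, and a sequence
containing two matches is rejected as ambiguous rather than silently
editing the first. The PBS must be the exact reverse complement of the
bases 5′ of the nick. Flap resolution replaces the first *k* bases 3′ of
the nick with the flap, where *k* is chosen by maximal 3′-suffix homology
between the flap and the displaced strand, searched within ±10 of
len(flap); ties prefer *k* = len(flap) (substitution-like), then the
nearest, then the smaller *k*. A best homology below 1 nt (configurable) is
a `flap_mismatch`. Because microhomology can make this register genuinely
ambiguous, the designers never trust the rule blindly: every emitted
candidate is validated by simulation against the string-spliced post-edit
sequence, and unverifiable candidates are dropped with a machine-readable
reason.

Base editing converts every matching base inside the editing window (the
all-converted product is the default outcome; exhaustive mode enumerates
bystander subsets). Restriction/ligation checking models SalI (G^TCGAC),
Acc65I (G^GTACC) and Golden Gate chains as 4-nt 5′-overhang bookkeeping.

## Reporter design

The construct is GFP–P2A–insert–K0-SR–P2A–Cherry translated as one frame;
ribosome-skipping biochemistry is not modelled because only frame and stop
logic matter for the design rules, and the K0-SR stalling domain retained
from the parent backbone is treated as an inert in-frame segment. The
GFP/Cherry/K0-SR segment constants are synthetic stop-free stand-in ORFs
(labelled as such in the source); users may substitute real sequences —
expression logic depends only on frames and stops. P2A is the standard
GSG-P2A back-translation.

`design_reporter_insert` searches windows near the preferred length
(default 60 nt, comfortably inside the 45–100 nt cloning bounds while
keeping oligos short) that cover the pegRNA footprint, preferring windows
centring the protospacer. Invariants enforced on every design: post-edit
insert length ≡ 0 (mod 3) and stop-free in the reporter frame; pre-edit
insert blocked by an in-frame stop or a non-multiple-of-3 length. When the
edit itself is nonsense or frameshift, the window is cloned as-is
(`native_*` disruption). Otherwise a 1-nt frameshift insertion is added —
at the RTT-span position farthest from the nick that avoids the PAM and
the protospacer seed (positions 11–20), so pegRNA binding to the reporter
is unperturbed and the insertion is removed together with the genomic edit;
the placement is validated by simulation and the next slot (or next base,
or next window) is tried on failure. A 1-nt insertion is preferred over an
engineered stop because single-nucleotide insertions in the RTT region
perturb editing least; the exact placement rule is this package's choice.

Base-editing reporters scan all six (strand, offset) frames for a stop
codon covering the edited base that the window conversion resolves
(bystander conversions included in the post product), then clone the
insert in the selected orientation with a 5′ trim equal to the frame
offset. Frame offsets here count 0-based codon start positions — note that
translation offset 1 means codons begin at the second base. Failure
reports list all six frame verdicts.

PAM panels substitute a template (e.g. `NNNN` with two varied positions →
16 variants) at the insert's recorded PAM location in both the pre- and
post-edit sequences.

## Quantification

The FACS score is mean(Cherry)/mean(GFP) over GFP-positive events; gates
are numeric thresholds or the 99.9th percentile of a negative-control
table. Amplicon reads are collapsed to alleles; alleles below `min_freq`
(default 0 — the external analyzer's threshold is unpublished, so nothing
is excluded by default) leave the denominator. Classification aligns each
allele globally (match 2, mismatch −4, gap open −10, extend −1; parameters
in config) and inspects the window ±R bp around the nick (R = 70 ⇒ 140 bp
of flank): an allele with no in-window gap that reproduces the intended
allele over the edit locus (±5 bp anchoring flank, configurable) is
intended; an in-window insertion/deletion is an indel — including alleles
that also carry the intended edit (conservative tie-break); a clean
reference locus is unedited; anything else is other. Deciding
intended/unedited by the edit locus rather than by full-window identity
makes recovery robust to off-site sequencing errors, matching how amplicon
analyzers count edited reads. Efficiency percentages are
100 × class / above-minimum-frequency reads. Rank correlation uses
average-rank ties and scipy's Spearman/Pearson.

## Synthetic data

Fixtures are deterministic under a fixed seed. Random targets draw bases
i.i.d. at the requested GC fraction with the edit (substitution, or 1–6 bp
insertion/deletion) placed in the central 30–70% so design windows have
flank. FACS fixtures plant three log-normal populations (background mean
10, positive mean 1000, σ = 0.25 — wide separation so truth-derived
midpoint gates recover planted fractions exactly); they do not model
spectral spillover or compensation. Read fixtures plant exact class counts
with 1–3 bp indels at the nick (where prime-editing by-products cluster),
optional uniform per-base substitution error, and reject indel alleles
that collide with the wild-type or intended sequence (possible in
homopolymers). Consequently, passing recovery tests demonstrates correct
bookkeeping and window logic, not robustness to real sequencer error
profiles, chimeric reads or alignment artefacts.

## Problem sizes and limitations

The test suite exercises 500 seeded design round trips on 200-nt targets,
200-sequence scanner/oracle comparisons, and n = 1000 read sets; these
sizes make every property check exact while completing in seconds. Known
limitations: no efficiency prediction (ranking candidates within the
constraint set is out of scope by design); exact-match site recognition
(no off-target modelling); no modelling of mismatch-repair-dependent
outcome biases or indel by-product spectra; paired-end merging, adapter
trimming and FCS binary parsing are out of scope (inputs are merged reads
and CSV event tables).
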