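# Methods

## Scope of the model

linkforge simulates the *sequence-level* logic of iterative type IIS
assembly: where enzymes cut, which sticky ends can anneal, which circular
molecules can form, and which of those survive genetic selection.  It does
not model reaction kinetics, enzyme units, buffers, transformation
efficiency or colony counts; its "success" is the existence of exactly one
selection-passing product class, the in-silico analogue of a clean plate.

## Digestion

Enzyme geometry is `recognition(cut_top/cut_bottom)` with both offsets in
nt downstream of the recognition 3′ end and the bottom-strand cut
projected onto top-strand coordinates (REBASE-style).  The registry is a
shipped plain-text table (`src/linkforge/data/enzymes.tsv`); corrections
are config, not code.  BspQI is listed as a SapI isoschizomer (identical
recognition and offsets).

Digestion is complete: every cleavable site of every supplied enzyme is
cut exactly once.  Sites whose scissile coordinates fall off a linear
molecule are reported as non-cleavable and skipped, matching physical
behaviour.  Two cuts whose scissile intervals overlap are an error — such
designs are invalid in this framework rather than silently resolvable.
Circular molecules with *k* cuts give *k* fragments; uncut circles pass
through flagged intact.

A fragment's `sequence` is the **full-span top-strand reading** between
the outermost cut coordinates, including overhang regions whose physical
bases sit on the bottom strand (read as their complement).  This makes
ligation a plain concatenation with the shared overhang written once, and
lets the stored overhang strings be re-derived from the sequence — an
invariant the tests check.  Fragment `footprint` (length minus the right
overhang) is the size used in virtual gels; footprints of a digest sum
exactly to the molecule length.

## Ligation and the product oracle

Two ends ligate iff same polarity, same nonzero length, and
reverse-complementary protruding strands.  Blunt joining is excluded by
design: the framework's junctions are exclusively sticky, and modelling
blunt joins would only create artifact products its enzymology suppresses.

`enumerate_circular` is a depth-first search over fragment chains, each
fragment used at most once per product (list a fragment twice to model
tandem-insert multiplicity explicitly), both orientations explored in a
deterministic order, products deduplicated by canonical form.  Circular
identity is the lexicographically smallest rotation over both strands — a
plasmid has no distinguished origin or strand.  Rotational duplicates are
collapsed by anchoring each product at its lowest-index member.  A
configurable frontier guard (10⁶ partial chains) bounds pathological
pools.  Every designed product elsewhere in the package is asserted, in
tests, to be an element of this enumeration on the same pool.

## The elementary cycle and the reference architecture

The cycle pipeline is: separate complete digests of pZ and donor → pooled
enumeration (≤2 fragments per product by default) → selection.  Selection
is three filters applied in order: only circular species are viable (the
T5 exonuclease step), the product must carry the cycle's expected
resistance marker, and it must not carry ccdB.  Marker and ccdB are
modelled purely as located feature annotations carried through digestion
and ligation; host permissivity for propagating ccdB donors is assumed,
not coded.  Ligation products are not re-digested: the protocol order
(pre-digests, heat inactivation, junction enzyme + ligase, exonuclease)
stabilises products that still carry next-cycle sites, and the model
reflects that end state.

The reference destination plasmid reads, circularly:
`W | origin | RBS | ATG [+prefix] [+GGT+part]* | junction cassette |
marker | backbone recognition+spacer`, where `W` (default `CGCT`) is the
4 nt backbone fusion overhang and the trailing backbone recognition cuts
into the leading `W` across the origin of the coordinate system.  The
junction cassette holds the scar bases and a minus-strand recognition
cutting back at the ORF 3′ end, so the ORF-side keeper keeps the fusion
overhang while the recognition itself leaves with the discard.  Donors
mirror this: `junction lead | part CDS | next junction cassette | new
marker | next backbone cassette | ccdB | donor origin`, with the
next-cycle backbone cassette doubling as the donor's own excision site
(its recognition stays in the keeper and becomes the next pZ's backbone
site).  Consequently one cycle's output is, by construction, byte-exact
the reference pZ of the next parity — regeneration is an identity, and
the planner can predict every intermediate by string assembly alone.

Enzyme schedules alternate with period 2: junction SapI↔BtsI and backbone
BsaI↔BbsI.  Alternation is what keeps a donor's next-cycle sites inert in
the current one-pot reaction; assigning the same junction enzyme to two
consecutive cycles is rejected by the planner, since its identical fusion
overhangs would permit part skipping.  Markers alternate over a
configurable alphabet (default `resA`/`resB`).

With this architecture a cycle's pool enumerates to exactly four circles:
the designed product, the two input religations, and the hybrid of the
two discard fragments.  Selection rejects the last three (wrong marker,
wrong marker, ccdB), which is the in-silico counterpart of background-free
plates; with ligation disabled nothing circular remains at all and the
survivor count is zero.

## Scars and frames

Every junction leaves one glycine in the fused protein, fixed here as the
codon `GGT`: for SapI-class junctions the 3 nt fusion overhang *is* the
scar codon; for BtsI-class junctions the 2 nt overhang `GG` is completed
by a `T` contributed by the incoming donor.  The codon identity is a repo
convention — the single-residue property is what the chemistry fixes, not
the base choice.  The first scar (between the start module and part 1) is
counted as part of the leader, so an *n*-part build reports *n − 1*
inter-part junctions.  `verify_orf` checks that the assembled ORF
decomposes exactly as start module + (scar + part)*, and reports the
first out-of-frame junction otherwise.

## Domestication

Internal recognition sites are removed codon-wise: repeatedly take the
leftmost site on either strand, enumerate synonymous substitutions of the
codons it overlaps that destroy it without increasing the total site
count, and apply the lexicographically smallest replacement codon
(leftmost on ties), with a visited-sequence guard against cycling.  A
site pinned by Met/Trp codons (or whose only synonym re-creates a site,
e.g. `ATG·CAG·TGG`, where the Gln swap converts BtsI into BsrDI) is
reported as stuck, never silently altered; the synthetic-CDS generator
redraws on such sequences.

Because a recognition sequence can also straddle the boundary between a
part and its fixed context (scar, junction cassette, donor lead), the
planner additionally runs a boundary repair: each part is scanned inside
every context its edges ever occupy — after the previous part, inside its
donor, ahead of the next fusion — and boundary-spanning sites are removed
by the same synonymous machinery, editing only the part's own codons.
The repaired ("effective") CDS is what both the plan prediction and the
donor builder use, keeping the two routes identical.

## Golden Gate layer

Adaptor modules add BsmBI sites whose 4 nt fusion overhangs position each
translation unit.  Fusion-site sets are validated for duplicates,
palindromes and mutual reverse complements (any of which would permit
misassembly or inverted insertion); the shipped default set is the first
valid prefix of a documented candidate list, chosen by that validator
because the design constraint — not any particular base choice — is what
matters.  The acceptor is built MoClo-style with a distinct marker and a
ccdB dropout between its sites, so TU compilation reuses the cycle's
selection machinery unchanged, and the unique survivor is checked to
contain every TU in the requested order.

## Synthetic data

All fixtures are generated, deterministically in a seed: fluorescent
proteins are stood in for by random domesticated CDSs of 236 residues
(the FP size class) because the framework's guarantees are
sequence-agnostic; markers, ccdB and origins are short labelled
placeholder ORFs/segments whose function is carried by annotation.  GC
bounds for random CDSs default to 0.35–0.65, the range of typical
bacterial coding sequence.  What passing tests therefore show is that the
*architecture* — cut geometry, overhang orthogonality, selection logic,
frame bookkeeping — is sound for any domesticated parts of these size
classes; they do not show anything about expression, folding, toxicity,
or repeat stability in a living host, and real part sequences (supplied
as FASTA/GenBank) may need domestication before use.

## Numerical and size choices

The shipped problem sizes keep every check exhaustive rather than
sampled: parts of 27–720 nt, plasmids of 0.2–4 kb, nine-cycle builds,
five-fragment Golden Gate pools.  At these sizes full enumeration and the
complete test suite run in seconds, and the enumeration frontier guard is
never approached.  Canonical rotation uses direct minimisation over all
rotations of both strands (quadratic but negligible at plasmid scale).

## Known limitations

- Complete digestion and exact-match annealing only: no partial digests,
  no thermodynamic scoring of near-cognate overhangs (designed sets are
  assumed orthogonal, and the validator enforces the designed ones).
- Single-copy fragment usage by default; tandem double inserts are only
  explored when a fragment is listed with explicit multiplicity.
- The reference pZ/pD/pL maps are a self-consistent architecture
  satisfying the framework's constraints, not reconstructions of any
  particular laboratory's vectors.
- Feature bookkeeping assumes features survive digestion only when fully
  contained in a fragment; junction-spanning annotations are dropped.
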