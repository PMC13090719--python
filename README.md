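# linkforge

In-silico iterative type IIS fusion assembly: a simulator and build planner
for growing fusion-protein ORFs part-by-part in a self-regenerating
destination plasmid, with genetic purification instead of gel purification,
plus a BsmBI Golden Gate layer that compiles finished translation units
into poly-cistronic expression constructs.

## Who this is for

Protein engineers and synthetic biologists who assemble complex fusion
proteins (tandem domain repeats, domain–linker–domain architectures,
combinatorial linker libraries) by iterative pairwise cloning, and want to
validate a build — enzyme schedules, overhang orthogonality, reading
frames, marker logistics, expected QC digests — entirely on the desk
before touching a pipette.

## The model

A **type IIS enzyme** `recognition(cut_top/cut_bottom)` cuts outside its
recognition sequence, leaving a programmable single-stranded overhang of
length `|cut_bottom − cut_top|` (5′ if `cut_bottom > cut_top`, 3′
otherwise).  The shipped registry covers BtsI `GCAGTG(2/0)`, BsrDI
`GCAATG(2/0)`, SapI/BspQI `GCTCTTC(1/4)`, BsaI `GGTCTC(1/5)`, BbsI
`GAAGAC(2/6)` and BsmBI `CGTCTC(1/5)`.  Two sticky ends ligate iff they
have the same polarity, the same length, and reverse-complementary
protruding strands; blunt ligation is excluded.

One **elementary assembly cycle** recombines the destination plasmid pZ
(origin + RBS + growing ORF + marker) with a donor plasmid pD/pL carrying
the next part:

1. pZ is digested with its backbone enzyme (BsaI or BbsI) and the cycle's
   junction enzyme (SapI or BtsI); the donor with the complementary
   backbone enzyme and the same junction enzyme.
2. Ligation joins the two keeper fragments through a 2–3 nt fusion
   overhang at the ORF 3′ end — one glycine (GGT) scar codon per junction —
   and a designed 4 nt overhang at the marker|origin boundary.
3. A T5-exonuclease step (modelled as "only circles survive"),
   a switch of antibiotic resistance, and ccdB counterselection against
   the donor backbone reduce the product set to a single clone class.

Both recognition sites spent from pZ leave with its discard fragment and
are re-supplied by the donor keeper, so the unique survivor is a pZ of
identical architecture with opposite enzyme/marker parity: the cycle
regenerates its own substrate and iterates indefinitely.  Every assembly
claim is checked against a brute-force oracle (`enumerate_circular`) that
lists *all* circular ligation products of a fragment pool up to rotation
and strand flip.

## Worked example

```python
import linkforge as lf

cfg = lf.AssemblyConfig()
fp = lf.random_cds(lf.SynthSpec(seed=11, n_residues=236,
                                forbidden_enzymes=cfg.domestication_enzymes))
parts = [lf.Part("fp1", "domain", fp.cds),
         lf.linker_cds("GGS", 3),
         lf.Part("fp2", "domain", fp.cds)]
plan = lf.plan_build(parts, cfg)
result = lf.simulate_build(plan, cfg)
```

This plans and executes a three-cycle build (domain, (GGS)₃ linker,
domain).  The printed schedule and results:

```
steps: [('fp1', 'SapI', 'BsaI', 'resB'), ('ggs3', 'BtsI', 'BbsI', 'resA'),
        ('fp2', 'SapI', 'BsaI', 'resB')]
final plasmid: 1628 bp
protein length: 485 residues
scar junctions: ((238, 'G', 'BtsI'), (248, 'G', 'SapI'))
QC ladder: [(811, 76), (841, 78), (1552, 76)]
```

Junction and backbone enzymes alternate per cycle and the marker flips
resA→resB→resA→resB.  The 485-residue protein is M, a leader glycine, the
236-residue domain, a glycine scar (protein position 238, left by the BtsI
cycle), GGSGGSGGS, another scar (position 248, SapI cycle), and the second
domain copy: exactly one non-part residue per junction.  The QC ladder is
the virtual analytical digest of each intermediate with its two resident
sites — the ORF-bearing fragment climbs 811→841→1552 bp while the
~77 bp marker cassette stays put, mirroring the band ladder one would run
on a gel.

The same pipeline is scriptable from the shell:

```bash
linkforge parts --seed 7 --out fixtures/   # synthetic pZ, donors, TUs, acceptor
linkforge digest fixtures/pz_empty.gb --enzymes SapI,BsaI
linkforge cycle --pz fixtures/pz_empty.gb --donor fixtures/donor_01_dom1.gb \
                --spec spec.yaml --out-dir step1/
linkforge gg --design design.yaml --out polycistron.gb
```

## Layout

| path | contents |
| --- | --- |
| `src/linkforge/seqmodel.py` | DNA molecules, sticky ends, fragments, GenBank/FASTA I/O |
| `src/linkforge/typeiis.py` | enzyme registry, site finding, digestion, virtual gels |
| `src/linkforge/ligation.py` | joining + exhaustive circular-product oracle |
| `src/linkforge/cycle.py` | reference pZ/pD/pL architectures, the elementary cycle |
| `src/linkforge/planner.py` | build plans, simulation, scar/frame verification |
| `src/linkforge/goldengate.py` | adaptors, fusion-site validation, TU compilation |
| `src/linkforge/partsynth.py` | deterministic synthetic parts + domestication |
| `src/linkforge/cli.py` | `linkforge` command-line tool |
| `docs/methods.md` | modelling assumptions, parameters, limitations |
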