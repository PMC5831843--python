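# ggshuffle

Design toolkit for **scarless Golden Gate gene shuffling**: given a coding
sequence and a set of beneficial point mutations, it designs a pair of
synthetic donor genes (wild type and all-mutant) whose one-pot BsaI
restriction–ligation into an acceptor vector produces *every* combination of
the mutations — and it verifies that claim by simulating the reaction at the
sequence level.  The package also carries the downstream screening analytics
used to pick winners from such a library: coupon-collector coverage
statistics, thermal-shift (ThermoFAD-style) T<sub>m</sub><sup>app</sup>
extraction, Michaelis–Menten kinetics, ΔΔG<sup>Fold</sup> candidate
filtering, and structure-based enumeration of mutable positions outside a
cofactor shell.

It is written for protein engineers building combinatorial
stability/activity libraries (FRESCO-style campaigns and similar), and for
anyone who wants a reproducible, testable model of type-IIS assembly design
rules.

## The method in brief

A CDS with *k* mutation clusters is split into *k* modules. Between two
modules the donor gene carries a mirrored pair of BsaI sites,
`NGAGACC·GGTCTCN`, cutting outward into the module bodies; BsaI (GGTCTC,
cut offsets 1/5) leaves 4-nt 5′ overhangs. The last four nucleotides of each
module are replicated at the start of the next one, so the overhang *is*
native gene sequence and ligation regenerates the gene without a scar.  The
acceptor vector contributes two fixed junction overhangs
(`5′-TGGTngagacc … ggtctcnCTTG-3′`).  Overhangs are selected so that every
pair differs in at least 3 of 4 positions and none is palindromic, which
makes cross-ligation negligible; because correct ligation destroys the
recognition sites, a final digestion step removes everything except correct
(shuffled) products. Mixing both donors in one pot therefore yields all
2<sup>k</sup> genotypes — 128 for the 7-module design the toolkit
reproduces.

Coverage of a library of N equiprobable variants screened with n clones at
valid-clone efficiency *e* uses the exact inclusion–exclusion
coupon-collector formula with n<sub>eff</sub> = round(n·e) effective draws:

P(all N seen) = Σ<sub>j=0..N</sub> (−1)<sup>j</sup> C(N,j) (1 − j/N)<sup>n_eff</sup>

evaluated in exact rational arithmetic.

## Worked example

```python
from ggshuffle import synthdata, enumerate_assemblies, genotype, validate_design
from ggshuffle.libstats import coverage_report

# a 300-codon toy gene with 8 substitutions, two of them on adjacent codons
design = synthdata.make_demo_design(seed=1)
print(design.k, design.overhangs)
# 7 ['TGGT', 'AACT', 'GCTC', 'CGAA', 'ACGG', 'GTAT', 'TAAC', 'CTTG']

print(validate_design(design).ok)
# True

products = enumerate_assemblies(design.reaction_fragments())
print(len(products), len({genotype(p, design) for p in products}))
# 128 128

report = coverage_report(k=7, n=448, efficiency=0.65)
print(report["oversampling_factor"], report["effective_draws"])
# 3.5 291
print(round(report["expected_distinct"], 1))
# 114.9
```

The adjacent mutation pair is merged into one module, so 8 substitutions
give k = 7 modules flanked by 8 fusion overhangs (the vector pair TGGT/CTTG
plus 6 native 4-mers). Simulating the one-pot reaction yields exactly
2⁷ = 128 stable circular products, one per genotype. Screening 448 clones
(3.5× the library) at 65% efficiency is expected to show ~115 of the 128
variants (the probability of having seen *all* 128 is still below 10⁻⁷ —
oversampling alone does not guarantee full coverage).

The same pipeline is available from the shell:

```bash
ggshuffle simulate cds --length-codons 300 --k-sites 7 --seed 1 --out sim/
ggshuffle design --cds sim/cds.fasta --mutations sim/mutations.csv --out design/
ggshuffle assemble --cds sim/cds.fasta --mutations sim/mutations.csv --out products/
ggshuffle stats --k 7 --clones 448 --efficiency 0.65
```

## Layout

- `ggshuffle.seqcore` — sequences, codons, mutations, FASTA/GenBank/CSV I/O
- `ggshuffle.design` — partitioning, overhang selection, donor/acceptor construction
- `ggshuffle.assembly` — type-IIS digestion, ligation enumeration, genotyping
- `ggshuffle.libstats` — library size, coverage, shuffling statistics
- `ggshuffle.screen` — Tm extraction, kinetics, ΔΔG filter, structure shell
- `ggshuffle.synthdata` — seeded generators for every input format
- `docs/methods.md` — model assumptions, defaults and limitations
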