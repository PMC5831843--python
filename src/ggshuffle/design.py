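"""Scarless shuffling-library design.

Partitions a CDS into modules around mutation sites, selects 4-nt fusion
overhangs under the uniqueness/non-palindromy rules, and emits the two
donor genes (wild-type and mutant) plus the acceptor junction definition.

Donor insert layout (k modules, overhangs O_0..O_k)::

    GGTCTCN O_0 body_1 [NGAGACC GGTCTCN O_i body_{i+1}]_{i=1..k-1} O_k NGAGACC

where O_0 / O_k are the acceptor-vector overhangs replicated at the first
fragment's start / last fragment's end, and each internal O_i is the last
4 nt of body_i replicated at the start of fragment i+1, so ligation
regenerates the gene without a single scar nucleotide.  Between modules the
excised spacer reads NGAGACC·GGTCTCN: the two mirrored recognition sites cut
outward into the neighbouring bodies and are lost in the product.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .assembly import BSAI, Enzyme, Fragment, digest, hamming, is_stable
from .seqcore import (
    MutationSpec,
    NucSeq,
    SequenceError,
    apply_mutations,
    choose_mutant_codon,
    find_recognition_sites,
    revcomp,
    translate,
)

OVERHANG_LEN = 4


class InfeasibleDesign(ValueError):
    """The CDS cannot host the requested module structure."""


class ConstraintFailure(ValueError):
    """No overhang assignment satisfies the fusion-site constraints."""

    def __init__(self, message: str, window_index: int, conflicts: list[tuple[str, str]]):
        super().__init__(message)
        self.window_index = window_index
        self.conflicts = conflicts


class MotifCollision(ValueError):
    """A mutation introduces a recognition motif inside a module body."""


def is_palindromic(overhang: str) -> bool:
    return overhang == revcomp(overhang)


def random_dna(length: int, rng: random.Random, forbidden: Sequence[str] = ()) -> str:
    """Random sequence free of the given motifs on both strands."""
    bad = [m.upper() for m in forbidden] + [revcomp(m) for m in forbidden]
    seq = "".join(rng.choice("ACGT") for _ in range(length))
    for _ in range(10 * length + 100):
        hit = next(((m, seq.find(m)) for m in bad if m in seq), None)
        if hit is None:
            return seq
        m, pos = hit
        i = pos + rng.randrange(len(m))
        seq = seq[:i] + rng.choice([b for b in "ACGT" if b != seq[i]]) + seq[i + 1 :]
    raise RuntimeError("could not purge forbidden motifs")  # pragma: no cover


@dataclass
class ModulePartition:
    """A CDS split into k modules with one mutation cluster each.

    ``boundaries`` are 0-based nucleotide positions where one module ends
    and the next begins; each sits inside its junction ``window`` so that
    the 4-nt overhang (the last 4 nt of the upstream module) never overlaps
    a mutated codon.
    """

    cds: NucSeq
    clusters: list[list[MutationSpec]]
    windows: list[tuple[int, int]]  # inclusive candidate boundary range
    boundaries: list[int]
    min_module_len: int

    @property
    def k(self) -> int:
        return len(self.clusters)

    def bodies(self, cds: NucSeq | None = None) -> list[str]:
        """Module body sequences for the given CDS (default: the WT CDS)."""
        bases = (cds or self.cds).bases
        bounds = [0, *self.boundaries, len(bases)]
        return [bases[bounds[i] : bounds[i + 1]] for i in range(self.k)]


@dataclass(frozen=True)
class FusionSite:
    """One 4-nt ligation junction; index 0 and k are the vector junctions."""

    index: int
    overhang: str
    source: Literal["native", "vector"]


@dataclass
class AcceptorSpec:
    """Acceptor vector: two fixed overhangs and a stuffer-bearing backbone.

    Digestion of ``backbone`` releases the stuffer (carrying both
    recognition sites, hence unstable) and the backbone arm exposing the
    upstream overhang on its right end and the downstream overhang on its
    left — the circular equivalent of the two vector arms.
    """

    upstream_overhang: str
    downstream_overhang: str
    backbone: NucSeq

    @classmethod
    def synthetic(
        cls,
        upstream: str = "TGGT",
        downstream: str = "CTTG",
        enzyme: Enzyme = BSAI,
        stuffer_len: int = 120,
        vector_len: int = 400,
        spacer_n: str = "A",
        seed: int = 0,
    ) -> "AcceptorSpec":
        """Build a synthetic acceptor plasmid with the standard junctions.

        Layout (circular): ``UP·N·GAGACC·stuffer·GGTCTC·N·DOWN·vector``, the
        inward-facing site pair of an expression acceptor.
        """
        rng = random.Random(seed)
        rc = revcomp(enzyme.motif)
        for _ in range(50):
            stuffer = random_dna(stuffer_len, rng, [enzyme.motif])
            vector = random_dna(vector_len, rng, [enzyme.motif])
            bases = (
                upstream.upper()
                + spacer_n
                + rc
                + stuffer
                + enzyme.motif
                + spacer_n
                + downstream.upper()
                + vector
            )
            backbone = NucSeq(bases, "circular")
            # junction-spanning accidents would add sites beyond the two designed
            if len(find_recognition_sites(backbone, enzyme.motif)) == 2:
                return cls(upstream.upper(), downstream.upper(), backbone)
        raise RuntimeError("could not build a clean acceptor backbone")  # pragma: no cover


@dataclass
class DonorConstruct:
    """One donor plasmid: the modular insert in a site-free vector."""

    variant_label: str  # "WT" | "MUT"
    insert: NucSeq
    vector_backbone: NucSeq

    @property
    def plasmid(self) -> NucSeq:
        return NucSeq(self.insert.bases + self.vector_backbone.bases, "circular")


@dataclass
class GeneDesign:
    """Complete shuffling design: partition + fusion sites + constructs."""

    cds: NucSeq
    mutations: list[MutationSpec]
    partition: ModulePartition
    fusion_sites: list[FusionSite]
    acceptor: AcceptorSpec
    donor_wt: DonorConstruct
    donor_mut: DonorConstruct
    enzyme: Enzyme = BSAI
    mut_cds: NucSeq = field(init=False)

    def __post_init__(self) -> None:
        self.mut_cds = apply_mutations(self.cds, self.mutations)

    @property
    def k(self) -> int:
        return self.partition.k

    @property
    def overhangs(self) -> list[str]:
        return [f.overhang for f in self.fusion_sites]

    def module_regions(self, variant: str = "WT") -> list[str]:
        """Top-strand stretch each module fragment contributes to a product.

        Module i (1-based, i < k) contributes O_{i-1} + body_i minus its
        last 4 nt (those arrive with the next fragment); module k
        contributes O_{k-1} + body_k in full.
        """
        cds = self.cds if variant.upper() == "WT" else self.mut_cds
        bodies = self.partition.bodies(cds)
        ohs = self.overhangs
        regions = []
        for i, body in enumerate(bodies):
            if i < len(bodies) - 1:
                regions.append(ohs[i] + body[:-OVERHANG_LEN])
            else:
                regions.append(ohs[i] + body)
        return regions

    def acceptor_backbone_fragment(self) -> Fragment:
        frags = digest(self.acceptor.backbone, self.enzyme, origin="acceptor")
        arms = [f for f in frags if self.enzyme.motif not in f.top
                and revcomp(self.enzyme.motif) not in f.top]
        if len(arms) != 1:
            raise InfeasibleDesign("acceptor backbone must yield exactly one arm")
        return arms[0]

    def reaction_fragments(self) -> list[Fragment]:
        """Everything the one-pot digestion of the three plasmids releases."""
        return (
            digest(self.donor_wt.plasmid, self.enzyme, origin="donor_wt")
            + digest(self.donor_mut.plasmid, self.enzyme, origin="donor_mut")
            + digest(self.acceptor.backbone, self.enzyme, origin="acceptor")
        )


def partition_gene(
    cds: NucSeq, muts: Sequence[MutationSpec], min_module_len: int = 60
) -> ModulePartition:
    """Split the CDS into one module per mutation cluster.

    Mutations whose codons lie closer than ``min_module_len`` nucleotides
    are merged into one cluster (the treatment the adjacent pair at
    positions 73/74 receives).  Junction windows — the boundary positions
    whose 4-nt overhang window touches no mutated codon — are attached for
    the overhang search; provisional boundaries sit at window centres.
    """
    if len(cds) % 3:
        raise InfeasibleDesign("CDS length must be a multiple of 3")
    muts = sorted(muts, key=lambda m: m.protein_pos)
    if not muts:
        raise InfeasibleDesign("need at least one mutation site")
    # validate against the reference before designing anything
    apply_mutations(cds, muts)

    clusters: list[list[MutationSpec]] = [[muts[0]]]
    for m in muts[1:]:
        prev_end = clusters[-1][-1].codon_span()[1]
        if m.codon_span()[0] - prev_end < min_module_len:
            clusters[-1].append(m)
        else:
            clusters.append([m])
    k = len(clusters)
    if len(cds) < k * min_module_len:
        raise InfeasibleDesign(
            f"CDS of {len(cds)} nt cannot host {k} modules of >= {min_module_len} nt"
        )
    windows: list[tuple[int, int]] = []
    for left, right in zip(clusters, clusters[1:]):
        lo = left[-1].codon_span()[1] + OVERHANG_LEN
        hi = right[0].codon_span()[0]
        if lo > hi:
            raise InfeasibleDesign(
                f"no junction window between clusters ending {left[-1].label} "
                f"and starting {right[0].label}"
            )
        windows.append((lo, hi))
    boundaries = [(lo + hi) // 2 for lo, hi in windows]
    return ModulePartition(cds, clusters, windows, boundaries, min_module_len)


def _overhang_ok(
    cand: str, chosen: Iterable[str], strict_revcomp: bool
) -> tuple[bool, list[tuple[str, str]]]:
    conflicts = []
    if is_palindromic(cand):
        conflicts.append((cand, "palindrome"))
    for other in chosen:
        if hamming(cand, other) < 3:
            conflicts.append((cand, other))
        elif strict_revcomp and hamming(cand, revcomp(other)) < 3:
            conflicts.append((cand, f"revcomp({other})"))
        elif cand == revcomp(other):
            # an exact reverse-complement pair would cross-ligate perfectly
            conflicts.append((cand, f"revcomp({other})"))
    return (not conflicts, conflicts)


def select_fusion_sites(
    partition: ModulePartition,
    acceptor: AcceptorSpec,
    strict_revcomp: bool = False,
) -> list[FusionSite]:
    """Pick one native 4-mer per junction window under the sticky-end rules.

    Every selected overhang (vector pair included) must be non-palindromic
    and differ from every other in at least 3 of 4 positions; strict mode
    additionally applies the 3/4 rule against reverse complements.  The
    search is deterministic: windows left to right, candidate positions
    leftmost first, chronological backtracking.  The partition's boundaries
    are updated to the chosen positions.
    """
    up, down = acceptor.upstream_overhang, acceptor.downstream_overhang
    for v in (up, down):
        if len(v) != OVERHANG_LEN or is_palindromic(v):
            raise ConstraintFailure(f"vector overhang {v} invalid", -1, [(v, v)])
    ok, conflicts = _overhang_ok(up, [down], strict_revcomp)
    if not ok:
        raise ConstraintFailure("vector overhang pair conflicts", -1, conflicts)

    bases = partition.cds.bases
    k = partition.k
    chosen: list[str] = []
    positions: list[int] = []
    last_conflicts: list[tuple[str, str]] = []
    blocking = 0

    def candidates(j: int) -> list[int]:
        lo, hi = partition.windows[j]
        return list(range(lo, hi + 1))

    def search(j: int) -> bool:
        nonlocal blocking, last_conflicts
        if j == k - 1:
            return True
        for b in candidates(j):
            cand = bases[b - OVERHANG_LEN : b]
            ok, conflicts = _overhang_ok(cand, [up, down, *chosen], strict_revcomp)
            if not ok:
                if j >= blocking:
                    blocking, last_conflicts = j, conflicts
                continue
            chosen.append(cand)
            positions.append(b)
            if search(j + 1):
                return True
            chosen.pop()
            positions.pop()
        return False

    if not search(0):
        raise ConstraintFailure(
            f"no feasible overhang assignment; blocked at junction window "
            f"{blocking + 1} of {k - 1}",
            blocking,
            last_conflicts,
        )
    partition.boundaries = positions
    sites = [FusionSite(0, up, "vector")]
    sites += [FusionSite(i + 1, o, "native") for i, o in enumerate(chosen)]
    sites.append(FusionSite(k, down, "vector"))
    return sites


def _check_bodies(bodies: list[str], enzyme: Enzyme, variant: str,
                  cds: NucSeq, muts: Sequence[MutationSpec]) -> None:
    offset = 0
    for i, body in enumerate(bodies):
        for motif in (enzyme.motif, revcomp(enzyme.motif)):
            pos = body.find(motif)
            if pos != -1:
                abs_pos = offset + pos
                hint = _recode_hint(cds, muts, abs_pos, len(motif))
                raise MotifCollision(
                    f"{variant} module {i + 1} contains {motif} at CDS position "
                    f"{abs_pos} (0-based).{hint}"
                )
        offset += len(body)


def _recode_hint(cds: NucSeq, muts: Sequence[MutationSpec], pos: int, width: int) -> str:
    for m in muts:
        lo, hi = m.codon_span()
        if lo < pos + width and hi > pos:
            wt_codon = cds.bases[lo:hi]
            chosen = m.codon_override or choose_mutant_codon(wt_codon, m.mut_aa)
            from ._codons import AA_TO_CODONS

            alts = [c for c in AA_TO_CODONS[m.mut_aa] if c != chosen]
            if alts:
                return (
                    f" Mutation {m.label} overlaps it; consider a synonymous "
                    f"codon such as {alts[0]} (codon_override)."
                )
    return ""


def build_donor_constructs(
    partition: ModulePartition,
    fusion_sites: Sequence[FusionSite],
    muts: Sequence[MutationSpec],
    enzyme: Enzyme = BSAI,
    spacer_n: str = "A",
    vector_len: int = 400,
    seed: int = 0,
) -> tuple[DonorConstruct, DonorConstruct]:
    """Emit the WT and mutant donor plasmids for the chosen design.

    Both inserts share the module boundaries and overhang set, so the
    released fragments are interchangeable between donors.  The single-N
    spacers next to each recognition site are concretized to ``spacer_n``.
    """
    if len(spacer_n) != 1 or spacer_n.upper() not in "ACGT":
        raise SequenceError("spacer_n must be a single A/C/G/T nucleotide")
    spacer_n = spacer_n.upper()
    ohs = [f.overhang for f in fusion_sites]
    if len(ohs) != partition.k + 1:
        raise InfeasibleDesign("need k+1 fusion sites for k modules")
    wt_cds = partition.cds
    mut_cds = apply_mutations(wt_cds, muts)
    rc = revcomp(enzyme.motif)

    inserts: dict[str, NucSeq] = {}
    expected_sites = 2 * partition.k
    for label, cds in (("WT", wt_cds), ("MUT", mut_cds)):
        bodies = partition.bodies(cds)
        _check_bodies(bodies, enzyme, label, cds, muts)
        # internal overhangs must be identical between variants
        for i, b in enumerate(partition.boundaries):
            if cds.bases[b - OVERHANG_LEN : b] != ohs[i + 1]:
                raise MotifCollision(
                    f"{label} overhang window at boundary {b} differs from the "
                    f"selected overhang {ohs[i + 1]} — mutation inside a fusion site?"
                )
        parts = [enzyme.motif, spacer_n, ohs[0], bodies[0]]
        for i in range(1, partition.k):
            parts += [spacer_n, rc, enzyme.motif, spacer_n, ohs[i], bodies[i]]
        parts += [ohs[-1], spacer_n, rc]
        insert = NucSeq("".join(parts))
        hits = find_recognition_sites(insert, enzyme.motif)
        if len(hits) != expected_sites:
            extra = [h.top_start for h in hits]
            raise MotifCollision(
                f"{label} insert carries {len(hits)} recognition sites, expected "
                f"{expected_sites}; site starts (0-based, top strand): {extra}"
            )
        inserts[label] = insert

    # a clean vector must not complete a motif across the insert junctions
    rng = random.Random(seed)
    for _ in range(50):
        backbone = NucSeq(random_dna(vector_len, rng, [enzyme.motif]))
        if all(
            len(find_recognition_sites(
                NucSeq(ins.bases + backbone.bases, "circular"), enzyme.motif
            )) == expected_sites
            for ins in inserts.values()
        ):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not build a clean donor backbone")
    return (
        DonorConstruct("WT", inserts["WT"], backbone),
        DonorConstruct("MUT", inserts["MUT"], backbone),
    )


def design_shuffling_library(
    cds: NucSeq,
    muts: Sequence[MutationSpec],
    acceptor: AcceptorSpec | None = None,
    min_module_len: int = 60,
    strict_revcomp: bool = False,
    enzyme: Enzyme = BSAI,
    spacer_n: str = "A",
    seed: int = 0,
) -> GeneDesign:
    """End-to-end design: partition, overhang selection, donor construction."""
    if acceptor is None:
        acceptor = AcceptorSpec.synthetic(enzyme=enzyme, spacer_n=spacer_n, seed=seed)
    partition = partition_gene(cds, muts, min_module_len)
    sites = select_fusion_sites(partition, acceptor, strict_revcomp)
    donor_wt, donor_mut = build_donor_constructs(
        partition, sites, muts, enzyme=enzyme, spacer_n=spacer_n, seed=seed
    )
    return GeneDesign(
        cds, sorted(muts, key=lambda m: m.protein_pos), partition, sites,
        acceptor, donor_wt, donor_mut, enzyme,
    )


@dataclass
class DesignReport:
    """Per-constraint validation outcome; ``ok`` iff every check passed."""

    checks: dict[str, bool]
    details: dict[str, str]

    @property
    def ok(self) -> bool:
        return all(self.checks.values())


def validate_design(design: GeneDesign, strict_revcomp: bool = False) -> DesignReport:
    """Re-check every design constraint on the finished artifact.

    Covered: overhang uniqueness (>= 3/4 mismatches, optionally also against
    reverse complements), non-palindromy, scarlessness of the WT round trip,
    absence of internal recognition motifs, mutations clear of overhang
    windows, and reading-frame preservation.
    """
    checks: dict[str, bool] = {}
    details: dict[str, str] = {}
    ohs = design.overhangs

    bad_pairs = [
        (a, b)
        for i, a in enumerate(ohs)
        for b in ohs[i + 1 :]
        if hamming(a, b) < 3 or (strict_revcomp and hamming(a, revcomp(b)) < 3)
    ]
    checks["overhang_uniqueness"] = not bad_pairs
    if bad_pairs:
        details["overhang_uniqueness"] = f"conflicting pairs: {bad_pairs}"

    palin = [o for o in ohs if is_palindromic(o)]
    checks["non_palindromy"] = not palin
    if palin:
        details["non_palindromy"] = f"palindromic overhangs: {palin}"

    regions_wt = design.module_regions("WT")
    backbone = design.acceptor_backbone_fragment()
    reconstructed = "".join(regions_wt)
    up = design.acceptor.upstream_overhang
    scarless = reconstructed == up + design.cds.bases
    checks["scarless_wt_roundtrip"] = scarless
    if not scarless:
        details["scarless_wt_roundtrip"] = "WT module chain does not respell the CDS"

    motif_free = True
    for variant in ("WT", "MUT"):
        cds = design.cds if variant == "WT" else design.mut_cds
        for i, body in enumerate(design.partition.bodies(cds)):
            if find_recognition_sites(NucSeq(body), design.enzyme.motif):
                motif_free = False
                details["no_internal_sites"] = f"{variant} module {i + 1}"
    checks["no_internal_sites"] = motif_free

    clear = True
    for b in design.partition.boundaries:
        window = range(b - OVERHANG_LEN, b)
        for m in design.mutations:
            lo, hi = m.codon_span()
            if any(lo <= p < hi for p in window):
                clear = False
                details["mutations_clear_of_overhangs"] = m.label
    checks["mutations_clear_of_overhangs"] = clear

    frame_ok = len(design.cds) % 3 == 0
    if frame_ok:
        wt_prot = translate(design.cds)
        mut_prot = translate(design.mut_cds)
        expected = list(wt_prot)
        for m in design.mutations:
            expected[m.protein_pos - 1] = m.mut_aa
        frame_ok = mut_prot == "".join(expected)
        if not frame_ok:
            details["frame_preserved"] = "mutant CDS does not translate as expected"
    checks["frame_preserved"] = frame_ok

    checks["acceptor_arm_stable"] = is_stable(NucSeq(backbone.top), design.enzyme)
    return DesignReport(checks, details)


# ---------------------------------------------------------------------------
# output writers (reports use 1-based inclusive coordinates)
# ---------------------------------------------------------------------------

def donor_to_record(design: GeneDesign, variant: str = "WT") -> SeqRecord:
    """GenBank record of a donor plasmid with module/overhang/site features."""
    donor = design.donor_wt if variant.upper() == "WT" else design.donor_mut
    plasmid = donor.plasmid
    record = SeqRecord(
        Seq(plasmid.bases),
        id=f"donor_{variant.lower()}",
        name=f"donor_{variant.lower()}",
        description=f"{variant} donor plasmid ({design.k} modules)",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for hit in find_recognition_sites(plasmid, design.enzyme.motif):
        record.features.append(
            SeqFeature(
                FeatureLocation(hit.top_start, hit.top_start + len(hit.motif),
                                strand=1 if hit.strand == "+" else -1),
                type="protein_bind",
                qualifiers={"label": [f"{design.enzyme.name} site"]},
            )
        )
    cds = design.cds if variant.upper() == "WT" else design.mut_cds
    bodies = design.partition.bodies(cds)
    offset = len(design.enzyme.motif) + 1 + OVERHANG_LEN  # GGTCTC N O_0
    spacer_block = 2 * len(design.enzyme.motif) + 2 + OVERHANG_LEN
    for i, body in enumerate(bodies):
        record.features.append(
            SeqFeature(
                FeatureLocation(offset, offset + len(body)),
                type="misc_feature",
                qualifiers={"label": [f"module_{i + 1}"]},
            )
        )
        record.features.append(
            SeqFeature(
                FeatureLocation(offset + len(body) - OVERHANG_LEN, offset + len(body)),
                type="misc_feature",
                qualifiers={"label": [f"overhang_{design.overhangs[i + 1]}"]},
            )
        )
        offset += len(body) + spacer_block
    return record


def write_design(design: GeneDesign, outdir: str | Path) -> None:
    """Write donor_wt.gb, donor_mut.gb, acceptor.gb and design.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for variant in ("WT", "MUT"):
        SeqIO.write(
            [donor_to_record(design, variant)],
            str(outdir / f"donor_{variant.lower()}.gb"),
            "genbank",
        )
    acceptor_rec = SeqRecord(
        Seq(design.acceptor.backbone.bases),
        id="acceptor",
        name="acceptor",
        description="acceptor vector with stuffer",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    SeqIO.write([acceptor_rec], str(outdir / "acceptor.gb"), "genbank")
    bounds = [0, *design.partition.boundaries, len(design.cds)]
    table = {
        # file uses 1-based inclusive coordinates
        "coordinate_convention": "1-based inclusive",
        "k": design.k,
        "modules": [
            {
                "module": i + 1,
                "start": bounds[i] + 1,
                "end": bounds[i + 1],
                "mutations": [m.label for m in design.partition.clusters[i]],
            }
            for i in range(design.k)
        ],
        "fusion_sites": [
            {"index": f.index, "overhang": f.overhang, "source": f.source}
            for f in design.fusion_sites
        ],
    }
    (outdir / "design.json").write_text(json.dumps(table, indent=2))
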