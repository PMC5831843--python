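"""In-silico one-pot Golden Gate reaction.

Type-IIS digestion with exact cut offsets, sticky-end ligation over 4-nt
5' overhangs, enumeration of circular products, and genotype calling.

Fragment representation
-----------------------
A fragment is stored by the top-strand stretch that *starts* with its left
5' overhang; the right overhang (single-stranded on the bottom strand) is
recorded as the top-strand reading of that duplex, i.e. the 4-mer the next
fragment contributes.  Ligating A before B is then legal iff
``A.right_overhang == B.left_overhang`` and the ligated top strand is simply
``A.top + B.top``.  This makes scar accounting exact: each overhang's
nucleotides appear exactly once in the product.

Stability
---------
A circular product is *stable* when neither strand carries a recognition
motif anymore — the sequence-level model of the final digestion step at the
end of the thermocycled restriction–ligation, which linearizes any product
that still contains a site (re-ligated donors, junction spacers, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .seqcore import NucSeq, revcomp

OVERHANG_LEN = 4


class DigestionError(ValueError):
    """Overlapping or truncated cut windows make the digestion ambiguous."""


class AssemblyOverflow(RuntimeError):
    """More candidate products than the configured cap."""


class UnclassifiableProduct(ValueError):
    """Product does not decompose into the design's module chain."""


@dataclass(frozen=True)
class Enzyme:
    """A type-IIS enzyme cutting downstream of its recognition motif.

    ``spacer`` is the number of nucleotides between the motif and the top-
    strand cut; the bottom-strand cut lies ``overhang_len`` further, leaving
    a 5' overhang.  BsaI is GGTCTC(1/5): spacer 1, overhang 4.
    """

    name: str
    motif: str
    spacer: int = 1
    overhang_len: int = OVERHANG_LEN


BSAI = Enzyme("BsaI", "GGTCTC", spacer=1, overhang_len=4)


@dataclass(frozen=True)
class Fragment:
    """Double-stranded fragment with 5' overhang ends (blunt = '')."""

    top: str
    left_overhang: str
    right_overhang: str
    origin: str = ""

    def __post_init__(self) -> None:
        if self.left_overhang and not self.top.startswith(self.left_overhang):
            raise ValueError("top strand must start with the left overhang")
        if len(self.top) <= len(self.left_overhang):
            raise ValueError("fragment needs at least 1 bp of duplex")

    @property
    def is_sticky(self) -> bool:
        return bool(self.left_overhang and self.right_overhang)


@dataclass
class AssemblyProduct:
    """A closed circular ligation product."""

    sequence: NucSeq
    fragments: tuple[Fragment, ...]
    stable: bool
    genotype: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def _cut_positions(seq: NucSeq, enzyme: Enzyme) -> list[int]:
    """Top-strand cut coordinates; each cut's overhang window is [t, t+4)."""
    n = len(seq)
    ext = len(enzyme.motif) + enzyme.spacer + enzyme.overhang_len
    scan = seq.bases + (seq.bases[: ext - 1] if seq.is_circular else "")
    cuts: list[int] = []
    rc = revcomp(enzyme.motif)
    start = scan.find(enzyme.motif)
    while start != -1:
        if start < n:
            cuts.append(start + len(enzyme.motif) + enzyme.spacer)
        start = scan.find(enzyme.motif, start + 1)
    start = scan.find(rc)
    while start != -1:
        if start < n:
            cuts.append(start - enzyme.spacer - enzyme.overhang_len)
        start = scan.find(rc, start + 1)
    if seq.is_circular:
        cuts = sorted({c % n for c in cuts})
    else:
        cuts = sorted(set(cuts))
        for c in cuts:
            if c < 0 or c + enzyme.overhang_len > n:
                raise DigestionError(
                    f"cut window [{c}, {c + enzyme.overhang_len}) runs off the "
                    "linear sequence"
                )
    for a, b in zip(cuts, cuts[1:]):
        if b - a < enzyme.overhang_len:
            raise DigestionError(
                f"ambiguous digestion: overhang windows at {a} and {b} overlap"
            )
    if seq.is_circular and len(cuts) > 1:
        if (cuts[0] + n) - cuts[-1] < enzyme.overhang_len:
            raise DigestionError(
                "ambiguous digestion: overhang windows overlap across the origin"
            )
    return cuts


def digest(seq: NucSeq, enzyme: Enzyme = BSAI, origin: str = "") -> list[Fragment]:
    """Cut at every recognition site on both strands simultaneously.

    A sequence without any site is returned unchanged as a single fragment
    (blunt/blunt if linear, uncut circle flagged by empty overhangs).
    """
    cuts = _cut_positions(seq, enzyme)
    n = len(seq)
    k = enzyme.overhang_len
    if not cuts:
        return [Fragment(seq.bases, "", "", origin=origin or "uncut")]
    frags: list[Fragment] = []
    if seq.is_circular:
        doubled = seq.bases + seq.bases
        for i, t in enumerate(cuts):
            t_next = cuts[(i + 1) % len(cuts)]
            span = (t_next - t) % n or n
            top = doubled[t : t + span]
            frags.append(
                Fragment(
                    top,
                    doubled[t : t + k],
                    doubled[t_next : t_next + k],
                    origin=f"{origin}[{t}:{t + span}]",
                )
            )
    else:
        bounds = [0, *cuts, n]
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            left = seq.bases[lo : lo + k] if lo in cuts else ""
            right = seq.bases[hi : hi + k] if hi in cuts else ""
            frags.append(
                Fragment(seq.bases[lo:hi], left, right, origin=f"{origin}[{lo}:{hi}]")
            )
    return frags


def is_stable(seq: NucSeq, enzyme: Enzyme = BSAI) -> bool:
    """True iff no recognition motif remains on either strand."""
    scan = seq.bases + (seq.bases[: len(enzyme.motif) - 1] if seq.is_circular else "")
    return enzyme.motif not in scan and revcomp(enzyme.motif) not in scan


def enumerate_assemblies(
    fragments: Iterable[Fragment],
    enzyme: Enzyme = BSAI,
    stable_only: bool = True,
    max_products: int = 100_000,
) -> list[AssemblyProduct]:
    """All distinct circular products closable by exact overhang matching.

    Products are deduplicated by canonical rotation of the top strand (and
    its reverse complement, since a circular duplex has no preferred
    strand).  With ``stable_only`` (the default) only products surviving the
    final digestion are returned.  Cycles revisit no overhang, matching the
    one-junction-per-overhang geometry of a valid design.
    """
    # fragments identical in sequence and ends give identical products;
    # collapse them before the cycle search
    unique: dict[tuple[str, str, str], Fragment] = {}
    for f in fragments:
        if f.is_sticky:
            unique.setdefault((f.top, f.left_overhang, f.right_overhang), f)
    by_left: dict[str, list[Fragment]] = {}
    for f in sorted(unique.values(), key=lambda f: (f.top, f.left_overhang)):
        by_left.setdefault(f.left_overhang, []).append(f)

    products: dict[str, AssemblyProduct] = {}
    seen_canonical: set[str] = set()
    # Monomeric products: cycles that use each overhang junction once,
    # anchored at their lexicographically smallest overhang so each rotation
    # class is generated once.  (Concatemers would revisit a junction; they
    # are outside this model — see religate() for the reversibility check.)
    for start in sorted(by_left):
        stack: list[tuple[tuple[Fragment, ...], str]] = [((), start)]
        while stack:
            path, node = stack.pop()
            for f in by_left.get(node, ()):  # deterministic order
                nxt = f.right_overhang
                if nxt == start:
                    _register((*path, f), enzyme, products, seen_canonical)
                    if len(products) > max_products:
                        raise AssemblyOverflow(
                            f"more than {max_products} products; raise the cap "
                            "or fix the design"
                        )
                elif nxt > start and all(p.right_overhang != nxt for p in path):
                    stack.append(((*path, f), nxt))
    out = [p for p in products.values() if p.stable or not stable_only]
    out.sort(key=lambda p: p.sequence.canonical_rotation())
    return out


def _register(
    cycle: tuple[Fragment, ...],
    enzyme: Enzyme,
    products: dict[str, AssemblyProduct],
    seen: set[str],
) -> None:
    top = "".join(f.top for f in cycle)
    seq = NucSeq(top, "circular")
    canon = min(seq.canonical_rotation(), seq.reverse_complement().canonical_rotation())
    if canon in seen:
        return
    seen.add(canon)
    products[canon] = AssemblyProduct(seq, cycle, stable=is_stable(seq, enzyme))


def religate(fragments: Sequence[Fragment], enzyme: Enzyme = BSAI) -> AssemblyProduct:
    """Chain fragments in the given order back into one circular product.

    Adjacent right/left overhangs must match exactly and the last fragment
    must close onto the first; digestion followed by ``religate`` of the
    fragments in their positional order regenerates the original construct
    (which is then *unstable*, since its recognition sites reappear).
    """
    frags = [f for f in fragments if f.is_sticky]
    if not frags:
        raise ValueError("nothing to ligate")
    for a, b in zip(frags, frags[1:] + frags[:1]):
        if a.right_overhang != b.left_overhang:
            raise ValueError(
                f"incompatible junction: {a.right_overhang} vs {b.left_overhang}"
            )
    seq = NucSeq("".join(f.top for f in frags), "circular")
    return AssemblyProduct(seq, tuple(frags), stable=is_stable(seq, enzyme))


def genotype(product: AssemblyProduct, design) -> str:
    """Bitstring of the product's module origins (0 = WT, 1 = mutant).

    The product must contain the acceptor backbone and exactly the design's
    k modules in order; any sequence mismatch raises
    :class:`UnclassifiableProduct` with the offending module and offset.
    """
    from .design import GeneDesign  # local import to avoid a cycle

    assert isinstance(design, GeneDesign)
    backbone_frag = design.acceptor_backbone_fragment()
    wt_regions = design.module_regions("WT")
    mut_regions = design.module_regions("MUT")
    expected_len = len(backbone_frag.top) + sum(len(r) for r in wt_regions)

    for seq in (product.sequence, product.sequence.reverse_complement()):
        doubled = seq.bases + seq.bases
        anchor = doubled.find(backbone_frag.top)
        if anchor == -1 or anchor >= len(seq):
            continue
        if len(seq) != expected_len:
            raise UnclassifiableProduct(
                f"invalid pattern: product length {len(seq)} != expected "
                f"{expected_len} (missing or extra module)"
            )
        offset = anchor + len(backbone_frag.top)
        bits = []
        for i, (wt, mut) in enumerate(zip(wt_regions, mut_regions)):
            observed = doubled[offset : offset + len(wt)]
            if observed == wt:
                bits.append("0")
            elif observed == mut:
                bits.append("1")
            else:
                diff = next(
                    j for j, (a, b) in enumerate(zip(observed, wt)) if a != b
                )
                raise UnclassifiableProduct(
                    f"unclassifiable: module {i + 1} matches neither variant "
                    f"(first divergence at module offset {diff})"
                )
            offset += len(wt)
        return "".join(bits)
    raise UnclassifiableProduct("invalid pattern: acceptor backbone not found")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("overhangs must have equal length")
    return sum(x != y for x, y in zip(a, b))


def fidelity_report(fusion_sites: Sequence, strict_revcomp: bool = False) -> pd.DataFrame:
    """Cross-ligation risk table: ordered overhang pairs closer than 3/4.

    Pairs are flagged when the Hamming distance between one overhang and
    another — or, in strict mode, another's reverse complement — drops below
    3, i.e. fewer than 3 of the 4 sticky-end nucleotides differ.  An empty
    table means the design meets the uniqueness rule.
    """
    ohs = [getattr(f, "overhang", f) for f in fusion_sites]
    if len(ohs) < 2:
        raise ValueError("need at least two fusion sites")
    rows = []
    for i, a in enumerate(ohs):
        for j, b in enumerate(ohs):
            if i >= j:
                continue
            d = hamming(a, b)
            if d < 3:
                rows.append((i, j, a, b, d, "direct"))
            if strict_revcomp:
                drc = hamming(a, revcomp(b))
                if drc < 3:
                    rows.append((i, j, a, revcomp(b), drc, "revcomp"))
    return pd.DataFrame(
        rows, columns=["site_i", "site_j", "overhang_i", "overhang_j", "distance", "kind"]
    )
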