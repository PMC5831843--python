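"""Nucleotide-sequence primitives shared by the whole toolkit.

Conventions
-----------
* Internal coordinates are 0-based, half-open.  Anything written to reports
  or files is 1-based inclusive and says so in its header.
* Sequences are canonicalized to uppercase A/C/G/T on construction
  (lowercase input is accepted).
* Circular sequences compare equal under rotation.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codons import AA_TO_CODONS, CODON_TO_AA, ECOLI_USAGE

_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Invalid sequence content or coordinates."""


class ReferenceDisagreement(ValueError):
    """A mutation's stated wild-type residue does not match the sequence."""


def _canonical(bases: str) -> str:
    up = bases.upper()
    for i, b in enumerate(up):
        if b not in _ALPHABET:
            raise SequenceError(f"non-ACGT character {b!r} at position {i}")
    return up


@dataclass(frozen=True)
class NucSeq:
    """A double-stranded DNA sequence given by its top strand.

    Parameters
    ----------
    bases:
        Top-strand sequence, 5'->3'.  Lowercase is accepted and upcased.
    topology:
        ``"linear"`` or ``"circular"``.  Circular sequences are
        rotation-invariant under equality comparison.
    """

    bases: str
    topology: Literal["linear", "circular"] = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _canonical(self.bases))
        if len(self.bases) < 1:
            raise SequenceError("empty sequence")
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def canonical_rotation(self) -> str:
        """Lexicographically minimal rotation (circular) or the bases (linear)."""
        if not self.is_circular:
            return self.bases
        doubled = self.bases + self.bases
        n = len(self.bases)
        return min(doubled[i : i + n] for i in range(n))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NucSeq):
            return NotImplemented
        if self.topology != other.topology:
            return False
        return self.canonical_rotation() == other.canonical_rotation()

    def __hash__(self) -> int:
        return hash((self.topology, self.canonical_rotation()))

    def reverse_complement(self) -> "NucSeq":
        return NucSeq(self.bases.translate(_COMPLEMENT)[::-1], self.topology)


def revcomp(bases: str) -> str:
    """Reverse complement of a plain top-strand string."""
    return _canonical(bases).translate(_COMPLEMENT)[::-1]


def reverse_complement(seq: NucSeq) -> NucSeq:
    return seq.reverse_complement()


@dataclass(frozen=True)
class MutationSpec:
    """One protein-level point substitution and its codon realization.

    ``protein_pos`` is the 1-based codon index in the CDS reading frame;
    ``codon_override`` pins the exact mutant codon instead of the default
    minimal-edit choice.
    """

    protein_pos: int
    wt_aa: str
    mut_aa: str
    codon_override: str | None = None

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise SequenceError("protein_pos is 1-based and must be >= 1")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AA_TO_CODONS:
                raise SequenceError(f"unknown amino acid {aa!r}")
        if self.codon_override is not None:
            cod = _canonical(self.codon_override)
            if len(cod) != 3:
                raise SequenceError("codon_override must be 3 nt")
            if CODON_TO_AA[cod] != self.mut_aa:
                raise SequenceError(
                    f"codon_override {cod} translates to {CODON_TO_AA[cod]}, "
                    f"not {self.mut_aa}"
                )
            object.__setattr__(self, "codon_override", cod)

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.protein_pos}{self.mut_aa}"

    def codon_span(self) -> tuple[int, int]:
        """0-based half-open nucleotide interval of the codon in the CDS."""
        start = (self.protein_pos - 1) * 3
        return start, start + 3


@dataclass(frozen=True)
class SiteHit:
    """A recognition-motif occurrence on one strand.

    ``position`` is the 0-based start of the motif in the coordinates of the
    reported strand itself (for '-' hits, in the reverse-complement strand
    read 5'->3').  ``top_start`` gives the same hit projected onto top-strand
    coordinates, which is what downstream cut-site arithmetic uses.
    """

    position: int
    strand: Literal["+", "-"]
    motif: str
    top_start: int


def translate(seq: NucSeq | str, frame: int = 0) -> str:
    """Translate the top strand in the given 0-based frame.

    Stops are rendered as ``'*'``; a trailing partial codon is ignored with
    a warning.
    """
    bases = seq.bases if isinstance(seq, NucSeq) else _canonical(seq)
    if frame < 0 or len(bases) - frame < 3:
        raise SequenceError("need at least one full codon after the frame offset")
    tail = (len(bases) - frame) % 3
    if tail:
        warnings.warn(
            f"ignoring trailing partial codon of {tail} nt", stacklevel=2
        )
        bases = bases[: len(bases) - tail]
    return "".join(
        CODON_TO_AA[bases[i : i + 3]] for i in range(frame, len(bases), 3)
    )


def choose_mutant_codon(wt_codon: str, mut_aa: str) -> str:
    """Minimal-nucleotide-edit codon for ``mut_aa``.

    Ties on edit distance are broken by the higher E. coli usage frequency,
    then lexicographically, so the choice is deterministic.
    """
    wt_codon = _canonical(wt_codon)
    candidates = AA_TO_CODONS[mut_aa]
    def key(c: str) -> tuple[int, float, str]:
        dist = sum(a != b for a, b in zip(wt_codon, c))
        return (dist, -ECOLI_USAGE[c], c)
    return min(candidates, key=key)


def apply_mutations(
    cds: NucSeq, muts: Iterable[MutationSpec], codon_policy: str = "minimal-edit"
) -> NucSeq:
    """Apply protein-level substitutions to a CDS.

    Each mutation's ``wt_aa`` must match the translated codon at its
    position; positions must be distinct.  Only the targeted codons change.
    """
    if codon_policy != "minimal-edit":
        raise ValueError(f"unknown codon policy {codon_policy!r}")
    muts = list(muts)
    positions = [m.protein_pos for m in muts]
    if len(set(positions)) != len(positions):
        raise SequenceError("duplicate mutation positions")
    bases = list(cds.bases)
    for m in muts:
        lo, hi = m.codon_span()
        if hi > len(bases):
            raise SequenceError(f"mutation {m.label} beyond the CDS")
        wt_codon = cds.bases[lo:hi]
        if CODON_TO_AA[wt_codon] != m.wt_aa:
            raise ReferenceDisagreement(
                f"reference disagreement at protein position {m.protein_pos}: "
                f"codon {wt_codon} is {CODON_TO_AA[wt_codon]}, expected {m.wt_aa}"
            )
        new_codon = m.codon_override or choose_mutant_codon(wt_codon, m.mut_aa)
        bases[lo:hi] = new_codon
    return NucSeq("".join(bases), cds.topology)


def find_recognition_sites(seq: NucSeq | str, motif: str) -> list[SiteHit]:
    """All occurrences of ``motif`` on both strands, sorted by top-strand start.

    Circular sequences are scanned across the origin; hits are reported once
    with their start reduced modulo the length.
    """
    motif = _canonical(motif)
    if len(motif) < 4:
        raise SequenceError("motif must be at least 4 nt")
    if isinstance(seq, str):
        seq = NucSeq(seq)
    n = len(seq)
    scan = seq.bases + (seq.bases[: len(motif) - 1] if seq.is_circular else "")
    hits: list[SiteHit] = []
    rc_motif = revcomp(motif)
    for target, strand in ((motif, "+"), (rc_motif, "-")):
        start = scan.find(target)
        while start != -1:
            if start < n:
                if strand == "+":
                    hits.append(SiteHit(start % n, "+", motif, start % n))
                else:
                    # position in the minus strand's own 5'->3' coordinates
                    minus_pos = (n - (start + len(motif))) % n
                    hits.append(SiteHit(minus_pos, "-", motif, start % n))
            start = scan.find(target, start + 1)
    hits.sort(key=lambda h: (h.top_start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# standard-format I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, topology: str = "linear") -> NucSeq:
    record = next(SeqIO.parse(str(path), "fasta"))
    return NucSeq(str(record.seq), topology)


def write_fasta(seq: NucSeq, path: str | Path, name: str = "sequence") -> None:
    record = SeqRecord(Seq(seq.bases), id=name, description=f"topology={seq.topology}")
    SeqIO.write([record], str(path), "fasta")


def read_genbank(path: str | Path) -> NucSeq:
    record = next(SeqIO.parse(str(path), "genbank"))
    topology = record.annotations.get("topology", "linear")
    return NucSeq(str(record.seq), "circular" if topology == "circular" else "linear")


def read_mutations_csv(path: str | Path) -> list[MutationSpec]:
    """Mutation table with columns protein_pos, wt_aa, mut_aa[, codon_override]."""
    out: list[MutationSpec] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            override = (row.get("codon_override") or "").strip() or None
            out.append(
                MutationSpec(
                    int(row["protein_pos"]),
                    row["wt_aa"].strip(),
                    row["mut_aa"].strip(),
                    override,
                )
            )
    return out


def write_mutations_csv(muts: Iterable[MutationSpec], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein_pos", "wt_aa", "mut_aa", "codon_override"])
        for m in muts:
            writer.writerow([m.protein_pos, m.wt_aa, m.mut_aa, m.codon_override or ""])


def read_mutations_json(path: str | Path) -> list[MutationSpec]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        MutationSpec(
            d["protein_pos"], d["wt_aa"], d["mut_aa"], d.get("codon_override")
        )
        for d in data
    ]


def write_mutations_json(muts: Iterable[MutationSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "protein_pos": m.protein_pos,
                    "wt_aa": m.wt_aa,
                    "mut_aa": m.mut_aa,
                    "codon_override": m.codon_override,
                }
                for m in muts
            ],
            fh,
            indent=2,
        )
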