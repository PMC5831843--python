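"""Seeded generators for every input the toolkit consumes.

Each generator is a pure function of its arguments (seed included): the
same call always returns bit-identical output.  They emulate the
experimental inputs of a shuffling campaign — a modular gene with spaced mutation sites, flavin
thermal-shift melt curves, sequenced clone tables from a shuffled library,
and Michaelis–Menten rate tables — so the full pipeline runs without any
external data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from ._codons import AA_TO_CODONS, CODON_TO_AA
from .design import (
    AcceptorSpec,
    GeneDesign,
    design_shuffling_library,
    random_dna,
)
from .assembly import BSAI, Enzyme
from .libstats import CloneRecord
from .screen import MeltCurve
from .seqcore import MutationSpec, NucSeq, revcomp, translate


class GenerationError(RuntimeError):
    """Generator parameters cannot produce a feasible instance."""


def make_toy_cds(
    length_codons: int = 300,
    k_sites: int = 7,
    seed: int = 0,
    adjacent_pair: bool = False,
    min_module_len: int = 60,
    enzyme: Enzyme = BSAI,
) -> tuple[NucSeq, list[MutationSpec]]:
    """A recognition-site-free CDS with evenly spaced mutation sites.

    ``k_sites`` counts mutation *clusters*; with ``adjacent_pair`` the first
    cluster holds two neighbouring substitutions (the treatment the 73/74
    pair receives), so the mutation list has ``k_sites + 1`` entries.
    Sites are spaced so every junction window is wide enough for the
    overhang search; codons at mutation sites avoid stops on both alleles.
    """
    n_nt = 3 * length_codons
    if n_nt < (k_sites + 1) * min_module_len:
        raise GenerationError(
            f"{length_codons} codons cannot host {k_sites} clusters with "
            f"min_module_len={min_module_len}"
        )
    rng = random.Random(seed)
    sense_codons = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")

    for _attempt in range(100):
        bases = random_dna(n_nt, rng, [enzyme.motif])
        codons = [bases[i : i + 3] for i in range(0, n_nt, 3)]
        # purge stops so the toy gene translates cleanly
        for i, c in enumerate(codons):
            if CODON_TO_AA[c] == "*":
                codons[i] = rng.choice(sense_codons)
        # evenly spaced cluster anchors, clear of both termini
        step = length_codons // (k_sites + 1)
        anchors = [step * (i + 1) for i in range(k_sites)]
        muts: list[MutationSpec] = []
        for j, pos in enumerate(anchors):
            targets = [pos, pos + 1] if (adjacent_pair and j == 0) else [pos]
            for p in targets:
                wt_aa = CODON_TO_AA[codons[p - 1]]
                mut_aa = rng.choice(sorted(set(AA_TO_CODONS) - {wt_aa, "*"}))
                muts.append(MutationSpec(p, wt_aa, mut_aa))
        cds = NucSeq("".join(codons))
        scan = cds.bases
        if enzyme.motif in scan or revcomp(enzyme.motif) in scan:
            continue
        try:  # the mutant allele must stay site-free too
            from .seqcore import apply_mutations

            mut_cds = apply_mutations(cds, muts)
        except ValueError:
            continue
        if enzyme.motif in mut_cds.bases or revcomp(enzyme.motif) in mut_cds.bases:
            continue
        return cds, muts
    raise GenerationError("could not generate a clean CDS; widen the parameters")


def make_demo_design(
    seed: int = 0,
    length_codons: int = 300,
    k_sites: int = 7,
    adjacent_pair: bool = True,
    min_module_len: int = 60,
    strict_revcomp: bool = False,
) -> GeneDesign:
    """A complete feasible shuffling design built from a toy CDS.

    Deterministic in ``seed``; a bounded number of derived sub-seeds is
    tried so rare constraint failures in the overhang search never
    propagate to the caller.
    """
    last: Exception | None = None
    for attempt in range(25):
        sub = (seed * 1009 + attempt * 7919) % (2**31 - 1)
        try:
            cds, muts = make_toy_cds(
                length_codons, k_sites, seed=sub,
                adjacent_pair=adjacent_pair, min_module_len=min_module_len,
            )
            acceptor = AcceptorSpec.synthetic(seed=sub)
            return design_shuffling_library(
                cds, muts, acceptor=acceptor,
                min_module_len=min_module_len,
                strict_revcomp=strict_revcomp, seed=sub,
            )
        except (ValueError, GenerationError) as exc:
            last = exc
    raise GenerationError(f"no feasible design after 25 attempts: {last}")


def simulate_melt_curve(
    tm: float = 48.5,
    transition_width: float = 2.0,
    amplitude: float = 1000.0,
    pre_baseline: tuple[float, float] = (100.0, 0.5),
    post_baseline_slope: float = -2.0,
    noise_sd: float = 0.01,
    grid: tuple[float, float, float] = (25.0, 90.0, 0.5),
    seed: int = 0,
    label: str = "sim",
) -> MeltCurve:
    """Two-state melt curve with linear baselines and Gaussian noise.

    ``noise_sd`` is relative to ``amplitude``.  The noiseless curve's first
    derivative peaks at ``tm``; a midpoint outside the grid leaves only a
    truncated transition and is reported with a warning.
    """
    import warnings

    lo, hi, step = grid
    T = np.arange(lo, hi + step / 2, step)
    if not lo <= tm <= hi:
        warnings.warn(f"tm {tm} outside the grid [{lo}, {hi}]: truncated transition")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    frac = 1.0 / (1.0 + np.exp((tm - T) / transition_width))
    pre = pre_baseline[0] + pre_baseline[1] * (T - lo)
    post = pre_baseline[0] + amplitude + post_baseline_slope * (T - tm)
    F = pre * (1 - frac) + post * frac
    rng = np.random.default_rng(seed)
    F = F + rng.normal(0.0, noise_sd * amplitude, size=T.shape)
    return MeltCurve(T, F, label)


def simulate_clone_sample(
    k: int = 7,
    n: int = 100,
    pct_pattern_ok: float = 97.0,
    seed: int = 0,
    exact: bool = False,
    n_distinct: int | None = None,
) -> list[CloneRecord]:
    """Sequenced-clone table from a shuffled library of 2**k genotypes.

    Default: each clone is independently valid with probability
    ``pct_pattern_ok``/100 and valid genotypes are uniform draws (the
    duplication model behind the coverage math).  ``exact=True`` instead
    builds a sample with exactly ``round(n*pct/100)`` valid clones and, if
    ``n_distinct`` is given, exactly that many distinct genotypes among
    them — the composition reported for the sequenced library (97 valid /
    65 distinct per 100).
    """
    rng = random.Random(seed)
    N = 2**k
    if not 0 <= pct_pattern_ok <= 100:
        raise ValueError("pct_pattern_ok must lie in [0, 100]")

    def geno(i: int) -> str:
        return format(i, f"0{k}b")

    if exact:
        n_ok = round(n * pct_pattern_ok / 100)
        d = n_distinct if n_distinct is not None else n_ok
        if not 0 <= d <= min(n_ok, N):
            raise ValueError("n_distinct must fit the valid clone count and 2**k")
        distinct = rng.sample(range(N), d)
        genos = [geno(i) for i in distinct]
        genos += [geno(rng.choice(distinct)) for _ in range(n_ok - d)]
        rng.shuffle(genos)
        clones = [CloneRecord(g) for g in genos]
        clones += [CloneRecord("invalid", pattern_ok=False)] * (n - n_ok)
        rng.shuffle(clones)
        return clones

    clones = []
    for _ in range(n):
        if rng.random() < pct_pattern_ok / 100:
            clones.append(CloneRecord(geno(rng.randrange(N))))
        else:
            clones.append(CloneRecord("invalid", pattern_ok=False))
    return clones


def simulate_mm_data(
    kcat: float = 13.7,
    km: float = 1.52,
    enzyme_conc: float = 1.0,
    s_grid: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
    noise_pct: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Michaelis–Menten rate table v = kcat*E*S/(Km+S) with relative noise."""
    if min(s_grid) >= km or max(s_grid) <= km:
        raise ValueError("substrate grid should span Km")
    rng = np.random.default_rng(seed)
    out = []
    for s in s_grid:
        v = kcat * enzyme_conc * s / (km + s)
        v *= 1.0 + rng.normal(0.0, noise_pct / 100.0)
        out.append((float(s), float(v)))
    return out
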