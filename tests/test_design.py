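"""Module partitioning, overhang selection and donor construction."""

import itertools
import random

import pytest

from ggshuffle.assembly import digest, enumerate_assemblies, hamming
from ggshuffle.design import (
    AcceptorSpec,
    ConstraintFailure,
    InfeasibleDesign,
    ModulePartition,
    _overhang_ok,
    build_donor_constructs,
    design_shuffling_library,
    is_palindromic,
    partition_gene,
    select_fusion_sites,
    validate_design,
)
from ggshuffle.seqcore import MutationSpec, NucSeq, revcomp, translate
from ggshuffle import synthdata


class TestPartition:
    def test_adjacent_pair_merges_into_one_module(self, demo_design):
        # 8 substitutions, two on neighbouring codons -> 7 modules
        assert len(demo_design.mutations) == 8
        assert demo_design.k == 7
        assert len(demo_design.partition.clusters[0]) == 2

    def test_single_mutation_single_module(self):
        cds, muts = synthdata.make_toy_cds(80, 1, seed=2)
        part = partition_gene(cds, muts)
        assert part.k == 1 and part.windows == [] and part.boundaries == []
        assert part.bodies() == [cds.bases]

    def test_three_sites_three_modules_with_window_oracle(self):
        cds, _ = synthdata.make_toy_cds(100, 1, seed=4)
        muts = [
            MutationSpec(p, translate(cds)[p - 1], "W" if translate(cds)[p - 1] != "W" else "F")
            for p in (20, 50, 80)
        ]
        part = partition_gene(cds, muts, min_module_len=60)
        assert part.k == 3
        # exhaustive check: windows contain exactly the boundaries whose
        # overhang window clears every mutated codon
        spans = [m.codon_span() for m in muts]
        for (lo, hi), (left, right) in zip(part.windows, zip(spans, spans[1:])):
            feasible = [
                b
                for b in range(4, len(cds))
                if left[1] <= b - 4 and b <= right[0]
            ]
            assert (lo, hi) == (min(feasible), max(feasible))

    def test_too_short_cds_is_infeasible(self):
        cds, muts = synthdata.make_toy_cds(100, 2, seed=5)
        # closer-than-min sites merge into one cluster first, so force the
        # infeasibility through the total-length check
        with pytest.raises(InfeasibleDesign):
            partition_gene(cds, muts, min_module_len=301)

    def test_modules_tile_cds(self, demo_design):
        assert "".join(demo_design.partition.bodies()) == demo_design.cds.bases


class TestFusionSites:
    def test_seven_module_design_has_eight_sites(self, demo_design):
        assert len(demo_design.fusion_sites) == 8
        assert demo_design.fusion_sites[0].overhang == "TGGT"
        assert demo_design.fusion_sites[-1].overhang == "CTTG"
        assert [f.index for f in demo_design.fusion_sites] == list(range(8))

    def test_vector_pair_distance_and_palindromy(self):
        # hand computation on the fixed acceptor junctions
        assert hamming("TGGT", "CTTG") == 4 >= 3
        assert not is_palindromic("TGGT") and not is_palindromic("CTTG")

    def test_palindromic_candidate_rejected(self):
        ok, conflicts = _overhang_ok("GATC", ["TGGT"], strict_revcomp=False)
        assert not ok and ("GATC", "palindrome") in conflicts
        assert revcomp("GATC") == "GATC"

    def test_all_windows_palindromic_raises_constraint_failure(self):
        cds, muts = synthdata.make_toy_cds(100, 2, seed=6)
        part = partition_gene(cds, muts)
        lo, _ = part.windows[0]
        # shrink the window to a position we poison with a palindrome
        bases = list(cds.bases)
        bases[lo - 4 : lo] = "GATC"
        poisoned = ModulePartition(
            NucSeq("".join(bases)), part.clusters, [(lo, lo)], [lo], 60
        )
        with pytest.raises(ConstraintFailure) as err:
            select_fusion_sites(poisoned, AcceptorSpec.synthetic(seed=0))
        assert err.value.window_index == 0
        assert err.value.conflicts

    def test_boundaries_updated_into_windows(self, demo_design):
        part = demo_design.partition
        for b, (lo, hi) in zip(part.boundaries, part.windows):
            assert lo <= b <= hi

    def test_selected_overhangs_are_native_4mers(self, demo_design):
        bases = demo_design.cds.bases
        for site, b in zip(
            demo_design.fusion_sites[1:-1], demo_design.partition.boundaries
        ):
            assert site.overhang == bases[b - 4 : b]
            assert site.source == "native"


class TestDonorConstructs:
    def test_recognition_heptamer_count_follows_layout(self, small_design):
        # 2(k-1) + 2 heptamers per insert
        k = small_design.k
        insert = small_design.donor_wt.insert.bases
        count = insert.count("GGTCTC") + insert.count("GAGACC")
        assert count == 2 * (k - 1) + 2 == 2 * k

    def test_wt_and_mut_donors_expose_identical_overhangs(self, demo_design):
        frags_wt = digest(demo_design.donor_wt.plasmid)
        frags_mut = digest(demo_design.donor_mut.plasmid)
        ends = lambda fs: sorted((f.left_overhang, f.right_overhang) for f in fs)
        assert ends(frags_wt) == ends(frags_mut)

    def test_wt_donor_roundtrip_reconstructs_cds(self, small_design):
        d = small_design
        frags = digest(d.donor_wt.plasmid) + digest(d.acceptor.backbone)
        products = enumerate_assemblies(frags)
        assert len(products) == 1
        doubled = products[0].sequence.bases * 2
        up, down = d.acceptor.upstream_overhang, d.acceptor.downstream_overhang
        assert (up + d.cds.bases + down) in doubled

    def test_mut_donor_translates_to_mutated_protein(self, demo_design):
        d = demo_design
        prot = list(translate(d.cds))
        for m in d.mutations:
            prot[m.protein_pos - 1] = m.mut_aa
        assert translate(d.mut_cds) == "".join(prot)

    def test_spacer_nucleotide_configurable(self):
        d = synthdata.make_demo_design(
            seed=7, length_codons=100, k_sites=2, adjacent_pair=False
        )
        d2 = design_shuffling_library(
            d.cds, d.mutations, acceptor=d.acceptor, spacer_n="G", seed=7
        )
        assert d2.donor_wt.insert.bases.startswith("GGTCTCG")


class TestValidateDesign:
    def test_valid_design_passes_all_checks(self, demo_design):
        report = validate_design(demo_design)
        assert report.ok, report.details

    def test_duplicated_overhang_fails_uniqueness(self, small_design):
        import copy

        broken = copy.deepcopy(small_design)
        site = broken.fusion_sites[1]
        broken.fusion_sites[1] = type(site)(site.index, "TGGT", site.source)
        report = validate_design(broken)
        assert not report.checks["overhang_uniqueness"]

    def test_constraint_check_is_permutation_symmetric(self, demo_design):
        ohs = demo_design.overhangs
        rng = random.Random(0)

        def brute(ohs):
            return all(
                hamming(a, b) >= 3
                for a, b in itertools.combinations(ohs, 2)
            ) and not any(is_palindromic(o) for o in ohs)

        base = brute(ohs)
        for _ in range(10):
            perm = ohs[:]
            rng.shuffle(perm)
            assert brute(perm) == base

    def test_checker_agrees_with_bruteforce_on_random_overhang_sets(self):
        rng = random.Random(42)
        for _ in range(100):
            ohs = [
                "".join(rng.choice("ACGT") for _ in range(4)) for _ in range(5)
            ]
            brute = all(
                hamming(a, b) >= 3 for a, b in itertools.combinations(ohs, 2)
            ) and not any(is_palindromic(o) for o in ohs)
            fast = all(
                _overhang_ok(o, ohs[:i], strict_revcomp=False)[0]
                and o != revcomp(o)
                for i, o in enumerate(ohs)
            )
            # _overhang_ok additionally vetoes exact revcomp duplicates
            if fast != brute:
                assert any(
                    a == revcomp(b) for a, b in itertools.combinations(ohs, 2)
                )


def test_acceptor_backbone_digests_into_arm_and_stuffer():
    acc = AcceptorSpec.synthetic(seed=3)
    frags = digest(acc.backbone)
    assert len(frags) == 2
    arm = [f for f in frags if "GGTCTC" not in f.top and "GAGACC" not in f.top]
    stuffer = [f for f in frags if f not in arm]
    assert len(arm) == 1 and len(stuffer) == 1
    assert arm[0].left_overhang == "CTTG" and arm[0].right_overhang == "TGGT"
    assert stuffer[0].left_overhang == "TGGT" and stuffer[0].right_overhang == "CTTG"
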