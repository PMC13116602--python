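import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from serpin_atlas.rcl_scanner import (
    RCLMatch,
    ScanParams,
    hamming_with_run_constraint,
    iterate_to_fixed_point,
    mismatch_budget,
    scan_protein,
    scan_proteome,
)
from serpin_atlas.sequence_io import ProteinRecord

from .oracles import brute_force_best_match

AAS = "ACDEFGHIKLMNPQRSTVWY"


class TestHamming:
    def test_identity(self):
        assert hamming_with_run_constraint("AVVA", "AVVA", 1) == (0, True)

    def test_single_mismatch_ok(self):
        assert hamming_with_run_constraint("AVVA", "AVGA", 1) == (1, True)

    def test_adjacent_mismatches_inadmissible_despite_budget(self):
        assert hamming_with_run_constraint("AVVA", "AGGA", 2) == (2, False)

    def test_unequal_lengths(self):
        with pytest.raises(ValueError):
            hamming_with_run_constraint("AA", "AAA", 1)

    def test_x_mismatches_everything(self):
        count, ok = hamming_with_run_constraint("AXA", "AXA", 2)
        assert count == 1  # the X column counts as a mismatch even vs X

    @given(
        st.text(alphabet=AAS, min_size=10, max_size=10),
        st.text(alphabet=AAS + "X", min_size=10, max_size=10),
        st.integers(min_value=0, max_value=10),
    )
    def test_matches_naive_recount(self, a, b, budget):
        positions = [
            i for i, (x, y) in enumerate(zip(a, b)) if x != y or "X" in (x, y)
        ]
        expect_ok = len(positions) <= budget and all(
            q - p > 1 for p, q in zip(positions, positions[1:])
        )
        assert hamming_with_run_constraint(a, b, budget) == (len(positions), expect_ok)


class TestScanProtein:
    QUERIES = {"q1": "WWHHWWHHWW"}

    def test_exact_copy_at_cterm(self):
        p = ProteinRecord("p", "M" + "A" * 100 + self.QUERIES["q1"])
        m = scan_protein(p, self.QUERIES)
        assert m is not None and m.mismatch_count == 0
        assert p.sequence[m.start : m.end] == self.QUERIES["q1"]

    def test_match_outside_cterm_window_ignored(self):
        # RCL planted 150 residues from the C-terminus of a 300-aa protein
        seq = "A" * 140 + self.QUERIES["q1"] + "A" * 150
        assert scan_protein(ProteinRecord("p", seq), self.QUERIES) is None

    def test_fewest_mismatches_wins(self):
        q = {"q": "WWWWWWWWWW"}
        # two admissible sites: 2 mismatches then 1 mismatch
        site2 = "WAWWWAWWWW"
        site1 = "WWWWAWWWWW"
        seq = "G" * 30 + site2 + "GGG" + site1 + "GGG"
        m = scan_protein(ProteinRecord("p", seq), q)
        assert m.mismatch_count == 1
        assert seq[m.start : m.end] == site1

    def test_equal_mismatches_earlier_offset_wins(self):
        q = {"q": "WWWWWWWWWW"}
        site = "WWWWAWWWWW"
        seq = "G" * 30 + site + "GGG" + site + "GGG"
        m = scan_protein(ProteinRecord("p", seq), q)
        assert m.start == 30

    def test_query_span_must_lie_inside_window(self):
        q = {"q": "WWHHW"}
        # planted copy ends exactly one residue before the window starts
        seq = "A" * 90 + "WWHHW" + "A" * 100
        params = ScanParams(window_len=100)
        assert scan_protein(ProteinRecord("p", seq), q, params) is None
        # one residue further right and it is inside
        seq2 = "A" * 95 + "WWHHW" + "A" * 95
        assert scan_protein(ProteinRecord("p", seq2), q, params) is not None

    def test_matches_brute_force_enumeration(self):
        rng = random.Random(11)
        queries = {
            "qa": "".join(rng.choice(AAS) for _ in range(9)),
            "qb": "".join(rng.choice(AAS) for _ in range(12)),
        }
        params = ScanParams(window_len=60, max_mismatch_fraction=0.3)
        for _ in range(250):
            n = rng.randint(5, 200)
            seq = "".join(rng.choice(AAS) for _ in range(n))
            # plant a corrupted query half the time so hits actually occur
            if rng.random() < 0.5 and n > 20:
                q = queries[rng.choice(list(queries))]
                pos = rng.randint(max(0, n - 60), n - len(q))
                corrupted = list(q)
                for i in range(0, len(q), 4):
                    if rng.random() < 0.5:
                        corrupted[i] = rng.choice(AAS)
                seq = seq[:pos] + "".join(corrupted) + seq[pos + len(q):]
            got = scan_protein(ProteinRecord("p", seq), queries, params)
            expect = brute_force_best_match(seq, queries, 60, 0.3)
            if expect is None:
                assert got is None
            else:
                assert (got.query_rcl_id, got.start, got.mismatch_count) == expect

    def test_budget_monotonicity(self):
        rng = random.Random(5)
        queries = {"q": "".join(rng.choice(AAS) for _ in range(10))}
        proteins = [
            ProteinRecord(f"p{i}", "".join(rng.choice(AAS) for _ in range(80)))
            for i in range(40)
        ]
        hits = {}
        for frac in (0.1, 0.2, 0.3, 0.4):
            found = {
                p.protein_id
                for p, _ in scan_proteome(
                    proteins, queries, ScanParams(max_mismatch_fraction=frac)
                )
            }
            for prev_frac, prev in hits.items():
                assert prev <= found, f"hit lost going {prev_frac} -> {frac}"
            hits[frac] = found


def _protein_with_rcl(name: str, rcl: str, rng: random.Random) -> ProteinRecord:
    body = "".join(rng.choice("GHPQ") for _ in range(120))
    return ProteinRecord(name, "M" + body + rcl + "GHPQG")


class TestIteration:
    def test_bridge_locus_found_in_round_two(self):
        rng = random.Random(2)
        seed = "WWWWHHHHWWWWHHHH"  # 16-mer, budget floor(0.3*16) = 4
        a_rcl = list(seed)
        for pos in (0, 2, 4, 6):
            a_rcl[pos] = "Y"
        a_rcl = "".join(a_rcl)  # 4 mismatches from seed: reachable
        b_rcl = list(a_rcl)
        for pos in (8, 10, 12, 14):
            b_rcl[pos] = "C"
        b_rcl = "".join(b_rcl)  # 4 from A, 8 from seed: bridge only
        proteins = [
            _protein_with_rcl("A", a_rcl, rng),
            _protein_with_rcl("B", b_rcl, rng),
        ]
        direct = scan_proteome(proteins, {"seed": seed})
        assert [p.protein_id for p, _ in direct] == ["A"]
        hits, counts = iterate_to_fixed_point(proteins, {"seed": seed}, max_rounds=5)
        assert {p.protein_id for p, _ in hits} == {"A", "B"}
        assert counts[0] == 1 and counts[1] == 2 and counts[-1] == 2

    def test_max_rounds_one_equals_single_scan(self):
        rng = random.Random(3)
        seed = "WWWWHHHHWWWWHHHH"
        proteins = [_protein_with_rcl("A", seed, rng)]
        hits, counts = iterate_to_fixed_point(proteins, {"seed": seed}, max_rounds=1)
        single = scan_proteome(proteins, {"seed": seed})
        assert [(p.protein_id, m) for p, m in hits] == [
            (p.protein_id, m) for p, m in single
        ]
        assert counts == [1]

    def test_fixed_point_is_stable(self, small_sim):
        hits, counts = iterate_to_fixed_point(
            [p for p in small_sim.proteins], small_sim.seeds
        )
        again, _ = iterate_to_fixed_point(
            [p for p in small_sim.proteins], small_sim.seeds
        )
        assert [(p.protein_id, m) for p, m in hits] == [
            (p.protein_id, m) for p, m in again
        ]
        assert counts[-1] == counts[-2] if len(counts) > 1 else True


class TestScanProteome:
    def test_empty_seed_set(self):
        assert scan_proteome([ProteinRecord("p", "MAAA")], {}) == []

    def test_duplicate_proteins_give_identical_hits(self):
        seed = {"q": "WWHHWWHHWW"}
        p1 = ProteinRecord("a", "M" + "G" * 50 + seed["q"])
        p2 = ProteinRecord("b", p1.sequence)
        hits = scan_proteome([p1, p2], seed)
        assert len(hits) == 2
        (m1, m2) = (hits[0][1], hits[1][1])
        assert (m1.start, m1.end, m1.mismatch_count) == (
            m2.start, m2.end, m2.mismatch_count,
        )

    def test_planted_sensitivity_and_decoy_specificity(self, small_sim):
        # translated ids follow the transcript (t_<name>)
        planted = {f"t_{p.protein_id}" for p in small_sim.proteins}
        from serpin_atlas.sequence_io import translate_representative

        all_proteins = [
            translate_representative(small_sim.genome, g) for g in small_sim.genes
        ]
        hits = scan_proteome(all_proteins, small_sim.seeds)
        assert {p.protein_id for p, _ in hits} == planted
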