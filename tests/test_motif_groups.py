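import math
import random

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from serpin_atlas.motif_groups import (
    MotifHit,
    OccurrenceMatrix,
    build_occurrence_matrix,
    column_entropies,
    entropy_windows,
    internal_motif_scan,
    parse_external_hits,
    parse_fimo_tsv,
    parse_meme_text,
    two_step_cluster,
)
from serpin_atlas.synthetic_atlas import planted_motif_matrix

AAS = "ACDEFGHIKLMNPQRSTVWY"


class TestEntropy:
    def test_conserved_alignment_has_zero_entropy(self):
        msa = ["MKWVTF"] * 5
        assert column_entropies(msa) == [0.0] * 6

    def test_two_equiprobable_residues_one_bit(self):
        msa = ["A", "C"]
        assert column_entropies(msa) == [pytest.approx(1.0)]

    def test_gap_counts_as_symbol(self):
        msa = ["A", "-"]
        assert column_entropies(msa) == [pytest.approx(1.0)]

    def test_window_ranking_matches_direct_recomputation(self):
        rng = random.Random(9)
        msa = [
            "".join(rng.choice(AAS[: 1 + (j % 7)]) for j in range(40))
            for _ in range(12)
        ]
        ent = column_entropies(msa)
        w = 5
        means = [sum(ent[i : i + w]) / w for i in range(len(ent) - w + 1)]
        top = entropy_windows(msa, window=w, top_k=1)[0]
        assert top[2] == pytest.approx(max(means))
        assert means[top[0]] == pytest.approx(max(means))

    def test_windows_do_not_overlap(self):
        rng = random.Random(4)
        msa = ["".join(rng.choice("ACDE") for _ in range(30)) for _ in range(6)]
        wins = entropy_windows(msa, window=6, top_k=4)
        for (s1, e1, _), (s2, e2, _) in zip(wins, wins[1:]):
            assert e1 <= s2

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            column_entropies(["AA", "A"])


class TestOccurrenceMatrix:
    def test_duplicate_hits_idempotent(self):
        h = MotifHit("m1", "s1", 0, 5)
        m1 = build_occurrence_matrix([h], ["s1", "s2"])
        m2 = build_occurrence_matrix([h, h, h], ["s1", "s2"])
        assert m1.table.equals(m2.table)

    def test_all_zero_rows_kept(self):
        m = build_occurrence_matrix([MotifHit("m1", "s1", 0, 5)], ["s1", "s2"])
        assert list(m.table.index) == ["s1", "s2"]
        assert m.table.loc["s2"].sum() == 0

    def test_unknown_sequence_rejected(self):
        with pytest.raises(ValueError, match="unknown sequence"):
            build_occurrence_matrix([MotifHit("m1", "sX", 0, 5)], ["s1"])

    def test_q_value_threshold(self):
        hits = [
            MotifHit("m1", "s1", 0, 5, q_value=0.01),
            MotifHit("m2", "s1", 0, 5, q_value=0.5),
        ]
        m = build_occurrence_matrix(hits, ["s1"], q_threshold=0.05)
        assert m.table.loc["s1", "m1"] == 1
        assert m.table.loc["s1", "m2"] == 0

    def test_hit_order_invariance(self):
        hits = [MotifHit("m1", "s1", 0, 5), MotifHit("m2", "s2", 1, 6)]
        a = build_occurrence_matrix(hits, ["s1", "s2"])
        b = build_occurrence_matrix(list(reversed(hits)), ["s1", "s2"])
        assert a.table.equals(b.table)


class TestTwoStepCluster:
    def _block_matrix(self):
        data = np.zeros((10, 6), dtype=int)
        data[:5, :3] = 1
        data[5:, 3:] = 1
        ids = [f"s{i}" for i in range(10)]
        return OccurrenceMatrix(
            table=pd.DataFrame(data, index=ids, columns=[f"m{j}" for j in range(6)])
        )

    def test_block_diagonal_two_groups(self):
        groups = two_step_cluster(self._block_matrix(), k_range=range(2, 5), seed=0)
        assert groups.k_final == 2
        assert groups.provisional == groups.final
        first_block = {groups.final[f"s{i}"] for i in range(5)}
        second_block = {groups.final[f"s{i}"] for i in range(5, 10)}
        assert len(first_block) == len(second_block) == 1
        assert first_block != second_block

    def test_deterministic_for_fixed_seed(self):
        m = self._block_matrix()
        g1 = two_step_cluster(m, seed=7)
        g2 = two_step_cluster(m, seed=7)
        assert g1.final == g2.final and g1.provisional == g2.provisional

    def test_planted_six_groups_recovered(self):
        matrix, truth = planted_motif_matrix(
            n_groups=6, per_group=12, overlap=0.15, seed=3,
        )
        groups = two_step_cluster(matrix, k_range=range(2, 11), seed=3)
        ids = matrix.sequence_ids
        truth_labels = [truth[s] for s in ids]
        ari_final = adjusted_rand_score(truth_labels, [groups.final[s] for s in ids])
        ari_prov = adjusted_rand_score(
            truth_labels, [groups.provisional[s] for s in ids]
        )
        assert ari_final >= 0.9
        assert ari_final >= ari_prov - 1e-9

    def test_unusable_k_range_rejected(self):
        with pytest.raises(ValueError):
            two_step_cluster(self._block_matrix(), k_range=[50])


class TestInternalScan:
    def test_exact_consensus_hit(self):
        hits = internal_motif_scan({"s1": "GGGNAVYFKGGGG"}, {"m": "NAVYFKG"})
        assert any(h.start == 3 and h.score == 7 for h in hits)

    def test_absent_beyond_budget_no_hit(self):
        hits = internal_motif_scan({"s1": "G" * 30}, {"m": "NAVYFKGWWW"})
        assert hits == []

    def test_agrees_with_brute_enumeration(self):
        rng = random.Random(21)
        seqs = {
            f"s{i}": "".join(rng.choice("NAVYFKGW") for _ in range(40))
            for i in range(10)
        }
        motif = "NAVYFKG"
        frac = 0.2
        budget = int(frac * len(motif))
        hits = internal_motif_scan(seqs, {"m": motif}, max_mismatch_fraction=frac)
        got = {(h.sequence_id, h.start) for h in hits}
        expect = set()
        for sid, seq in seqs.items():
            for start in range(len(seq) - len(motif) + 1):
                window = seq[start : start + len(motif)]
                mm = [i for i in range(len(motif)) if window[i] != motif[i]]
                if len(mm) <= budget and all(
                    b - a > 1 for a, b in zip(mm, mm[1:])
                ):
                    expect.add((sid, start))
        assert got == expect


FIMO_TSV = """motif_id\tmotif_alt_id\tsequence_name\tstart\tstop\tstrand\tscore\tp-value\tq-value\tmatched_sequence
m187\tMEME-1\ts1\t5\t11\t+\t12.3\t1e-6\t0.001\tNAIYFKG
m188\tMEME-2\ts2\t40\t55\t+\t20.1\t1e-8\t0.0001\tEEGTVAAAATGVVIVR
"""

MEME_TXT = """MEME version 5.5.0

ALPHABET= ACDEFGHIKLMNPQRSTVWY

MOTIF m1 MEME-1
letter-probability matrix: alength= 20 w= 2 nsites= 10 E= 1e-5
 1.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0
 0.0 1.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0

MOTIF m2 MEME-2
letter-probability matrix: alength= 20 w= 3 nsites= 8 E= 1e-3
 0.0 0.0 1.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0
 0.0 0.0 0.0 1.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0
 0.0 0.0 0.0 0.0 1.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0

MOTIF m3 MEME-3
letter-probability matrix: alength= 20 w= 1 nsites= 5 E= 0.1
 0.0 0.0 0.0 0.0 0.0 1.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0 0.0
"""


class TestExternalParsers:
    def test_fimo_minimal(self, tmp_path):
        p = tmp_path / "fimo.tsv"
        p.write_text(FIMO_TSV)
        hits = parse_fimo_tsv(p)
        assert len(hits) == 2
        assert hits[0].motif_id == "m187"
        assert (hits[0].start, hits[0].end) == (4, 11)  # converted to half-open
        assert hits[1].q_value == pytest.approx(0.0001)

    def test_meme_text_catalog(self, tmp_path):
        p = tmp_path / "meme.txt"
        p.write_text(MEME_TXT)
        motifs = parse_meme_text(p)
        assert [m.motif_id for m in motifs] == ["m1", "m2", "m3"]
        assert [m.width for m in motifs] == [2, 3, 1]
        assert motifs[0].consensus == "AC"
        assert motifs[1].e_value == pytest.approx(1e-3)

    def test_sniffer_dispatch(self, tmp_path):
        f = tmp_path / "fimo.tsv"
        f.write_text(FIMO_TSV)
        m = tmp_path / "meme.txt"
        m.write_text(MEME_TXT)
        assert parse_external_hits(f)[0] == "fimo"
        assert parse_external_hits(m)[0] == "meme"

    def test_unrecognized_file_names_offending_line(self, tmp_path):
        p = tmp_path / "junk.txt"
        p.write_text("this is not a motif file\n")
        with pytest.raises(ValueError, match="not a motif file"):
            parse_external_hits(p)

    def test_truncated_meme_rejected(self, tmp_path):
        p = tmp_path / "trunc.txt"
        p.write_text("MEME version 5.5.0\n\nMOTIF m1 MEME-1\n")
        with pytest.raises(ValueError, match="m1"):
            parse_meme_text(p)
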