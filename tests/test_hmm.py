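"""Profile-HMM construction, forward bit scores, and variant scoring."""

import math

import numpy as np
import pytest

import varfunc.hmm as hmm_mod
from varfunc import (
    FamilyModel,
    HmmError,
    ProfileHMM,
    build_profile,
    ceo_cluster,
    classify,
    dump_profile,
    full_window,
    hmmvar_score,
    load_profile,
    map_variant_to_column,
    plant_variant,
    score_variant_across_clusters,
    select_region,
    sequence_bitscore,
    simulate_family,
)
from varfunc.msa import AMINO_ACIDS
from conftest import make_msa


def forced_match_hmm(emissions: np.ndarray) -> ProfileHMM:
    """A profile whose only allowed path is begin -> M_1 ... M_m -> end."""
    m = emissions.shape[0]
    t_match = np.tile([1.0, 0.0, 0.0], (m + 1, 1))
    return ProfileHMM(
        match_emissions=emissions,
        insert_emissions=np.full((m + 1, 20), 1 / 20),
        t_from_match=t_match,
        t_from_insert=t_match.copy(),
        t_from_delete=t_match.copy(),
    )


def conserved_hmm(consensus: str, p: float = 0.9) -> ProfileHMM:
    em = np.full((len(consensus), 20), (1 - p) / 19)
    for j, c in enumerate(consensus):
        em[j, AMINO_ACIDS.index(c)] = p
    return forced_match_hmm(em)


class TestBuildProfile:
    def _window(self, rows):
        return full_window(make_msa(rows))

    def test_laplace_match_emissions(self):
        w = self._window(["ACDEFGH"] * 4)
        hmm = build_profile(w, [0, 1, 2, 3], pseudocount=1.0)
        # column of four A's: P(A) = 5/24, any other residue 1/24
        assert hmm.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(5 / 24)
        assert hmm.match_emissions[0, AMINO_ACIDS.index("W")] == pytest.approx(1 / 24)

    def test_gap_heavy_column_not_a_match_state(self):
        rows = ["A-CDE", "A-CDE", "AWCDE", "A-CDE", "A-CDE"]
        hmm = build_profile(self._window(rows), [0, 1, 2, 3, 4],
                            match_gap_threshold=0.5)
        assert hmm.n_match == 4

    def test_gap_free_cluster_match_count(self):
        w = self._window(["ACDEFGH"] * 3)
        assert build_profile(w, [0, 1, 2]).n_match == 7

    def test_singleton_cluster_rejected(self):
        w = self._window(["ACDEFGH"] * 3)
        with pytest.raises(HmmError, match="subfamily too small"):
            build_profile(w, [0])

    def test_distributions_normalised(self):
        model = FamilyModel(n_subfamilies=2, rows_per_subfamily=6,
                            width=20, conservation=0.9, seed=0)
        msa, _ = simulate_family(model)
        hmm = build_profile(full_window(msa), list(range(6)))
        hmm.validate()   # every emission/transition row sums to 1 +- 1e-9

    def test_row_order_invariance(self):
        w = self._window(["ACDEF", "ACDEW", "ACDEY", "ACDEF"])
        a = build_profile(w, [0, 1, 2, 3])
        b = build_profile(w, [3, 1, 0, 2])
        assert np.allclose(a.match_emissions, b.match_emissions)
        assert np.allclose(a.t_from_match, b.t_from_match)


class TestBitscore:
    def test_background_model_scores_zero(self):
        hmm = forced_match_hmm(np.full((5, 20), 1 / 20))
        assert sequence_bitscore(hmm, "ACDEF") == pytest.approx(0.0, abs=1e-9)

    def test_consensus_beats_every_single_substitution(self):
        consensus = "ACDEF"
        hmm = conserved_hmm(consensus, 0.9)
        s0 = sequence_bitscore(hmm, consensus)
        for pos in range(5):
            for aa in AMINO_ACIDS:
                if aa == consensus[pos]:
                    continue
                neighbor = consensus[:pos] + aa + consensus[pos + 1:]
                assert sequence_bitscore(hmm, neighbor) < s0

    def test_deterministic(self):
        hmm = conserved_hmm("ACDEF")
        assert sequence_bitscore(hmm, "ACDEW") == sequence_bitscore(hmm, "ACDEW")

    def test_long_sequence_stays_finite(self):
        # insert/delete paths must carry a 10,000-residue sequence through a
        # 5-column model without underflow
        rows = ["ACDEF", "ACDEF", "ACDEW"]
        hmm = build_profile(full_window(make_msa(rows)), [0, 1, 2])
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=10_000))
        assert math.isfinite(sequence_bitscore(hmm, seq))

    def test_illegal_character_errors(self):
        hmm = conserved_hmm("ACDEF")
        with pytest.raises(HmmError, match="illegal residue"):
            sequence_bitscore(hmm, "ACDEB")

    def test_empty_sequence_errors(self):
        with pytest.raises(HmmError):
            sequence_bitscore(conserved_hmm("ACDEF"), "")


class TestHmmvarScore:
    def test_ratio_and_difference_arithmetic(self, monkeypatch):
        scores = {"ACDEF": 4.0, "ACDEW": 2.0}
        monkeypatch.setattr(hmm_mod, "sequence_bitscore",
                            lambda h, s: scores[s])
        hmm = conserved_hmm("ACDEF")
        assert hmmvar_score(hmm, "ACDEF", "ACDEW", "ratio") == pytest.approx(2.0)
        assert hmmvar_score(hmm, "ACDEF", "ACDEW", "difference") == pytest.approx(2.0)

    def test_neutral_fixed_point(self, monkeypatch):
        monkeypatch.setattr(hmm_mod, "sequence_bitscore", lambda h, s: 3.0)
        hmm = conserved_hmm("ACDEF")
        assert hmmvar_score(hmm, "ACDEF", "ACDEW", "ratio") == pytest.approx(1.0)
        assert hmmvar_score(hmm, "ACDEF", "ACDEW", "difference") == pytest.approx(0.0)

    def test_better_fitting_mutant_scores_below_neutral(self):
        hmm = conserved_hmm("ACDEF", 0.9)
        # mutant = consensus fits better than a non-consensus wild type
        assert hmmvar_score(hmm, "WCDEF", "ACDEF", "difference") < 0.0

    def test_conserved_column_mutation_above_neutral(self):
        rows = ["ACDEF"] * 4
        w = full_window(make_msa(rows))
        hmm = build_profile(w, [0, 1, 2, 3])
        assert hmmvar_score(hmm, "ACDEF", "WCDEF", "ratio") > 1.0
        assert hmmvar_score(hmm, "ACDEF", "WCDEF", "difference") > 0.0

    def test_identical_sequences_error(self):
        with pytest.raises(HmmError):
            hmmvar_score(conserved_hmm("ACDEF"), "ACDEF", "ACDEF")

    def test_multiple_substitutions_error(self):
        with pytest.raises(HmmError):
            hmmvar_score(conserved_hmm("ACDEF"), "ACDEF", "WWDEF")

    def test_zero_denominator_errors_in_ratio_mode(self, monkeypatch):
        monkeypatch.setattr(hmm_mod, "sequence_bitscore",
                            lambda h, s: 0.0 if s == "ACDEW" else 2.0)
        with pytest.raises(HmmError, match="undefined ratio"):
            hmmvar_score(conserved_hmm("ACDEF"), "ACDEF", "ACDEW", "ratio")


@pytest.fixture(scope="module")
def planted():
    model = FamilyModel(seed=1)
    msa, _ = simulate_family(model)
    variant, _ = plant_variant(model, "GoF")
    col = map_variant_to_column(msa, variant)
    window = select_region(msa, col)
    partition = ceo_cluster(window, restarts=2, shuffles=20, seed=1)
    return window, partition, variant


class TestScoreAcrossClusters:
    def test_min_other_semantics(self, planted):
        window, partition, variant = planted
        s = score_variant_across_clusters(window, partition, variant,
                                          mode="difference")
        others = {l: v for l, v in s.per_cluster_score.items() if l != 0}
        assert s.target_score == s.per_cluster_score[0]
        assert s.min_other_score == min(others.values())
        assert s.per_cluster_score[s.argmin_cluster] == s.min_other_score

    def test_planted_gain_fits_other_subfamily_better(self, planted):
        window, partition, variant = planted
        s = score_variant_across_clusters(window, partition, variant,
                                          mode="difference")
        assert s.min_other_score < s.target_score

    def test_significance_floor_triggers_no_call(self, planted):
        window, partition, variant = planted
        s = score_variant_across_clusters(window, partition, variant,
                                          significance_floor=1e9)
        assert s.no_call
        assert classify(s, 2.7).predicted == "no_call"

    def test_singleton_target_cluster_rejected(self, planted):
        window, _, variant = planted
        from varfunc.clustering import ClusterPartition
        labels = [1] * window.n_rows
        labels[window.query_index] = 0
        lonely = ClusterPartition(labels=labels, k=2)
        with pytest.raises(HmmError, match="size 1"):
            score_variant_across_clusters(window, lonely, variant)


def test_region_fasta_emission(planted):
    import io
    from varfunc import write_region_fasta

    window, partition, variant = planted
    s = score_variant_across_clusters(window, partition, variant, mode="difference")
    buf = io.StringIO()
    write_region_fasta(s, variant, buf)
    text = buf.getvalue()
    assert text.startswith(f">wild_{variant}\n{s.wild}\n")
    assert s.mutant in text and s.wild != s.mutant


class TestProfileIO:
    def test_dump_load_roundtrip(self, tmp_path):
        rows = ["ACDEF", "AC-EF", "ACDEW", "ACDEF"]
        hmm = build_profile(full_window(make_msa(rows)), [0, 1, 2, 3])
        path = tmp_path / "profile.txt"
        dump_profile(hmm, path)
        again = load_profile(path)
        assert np.array_equal(again.match_emissions, hmm.match_emissions)
        assert np.array_equal(again.t_from_delete, hmm.t_from_delete)
        assert sequence_bitscore(again, "ACDEF") == sequence_bitscore(hmm, "ACDEF")
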