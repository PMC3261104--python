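"""Common Module Profiling: similarity scoring and chi-square over-representation."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genesift import (
    APPROACHES,
    DomainCombination,
    DomainDB,
    SearchSpace,
    cmp_ab_initio,
    cmp_seeded,
    combination_stats,
    similarity_score,
)

signature = st.dictionaries(
    st.sampled_from([f"PF{i}" for i in range(8)]),
    st.integers(min_value=1, max_value=4),
    min_size=1,
    max_size=5,
)


def space_of(per_locus):
    return SearchSpace(approach=APPROACHES["adjacent"], per_locus=per_locus)


class TestSimilarityScore:
    def test_identical_signatures_score_one(self):
        sig = {"PF04812": 1, "PF04814": 1}
        assert similarity_score(sig, dict(sig)) == 1.0

    def test_disjoint_signatures_score_zero(self):
        assert similarity_score({"PF1": 2}, {"PF2": 1}) == 0.0

    def test_shared_two_of_three_domains(self):
        # HNF-1-like pair: min-sum 2 / max-sum 3
        a = {"PF04812": 1, "PF04814": 1}
        b = {"PF04812": 1, "PF04814": 1, "PFX": 1}
        assert similarity_score(a, b) == pytest.approx(2 / 3)
        assert similarity_score(a, b) >= 0.4  # a seeded prediction

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            similarity_score({}, {"PF1": 1})

    @given(signature, signature)
    def test_symmetric_and_bounded(self, a, b):
        s = similarity_score(a, b)
        assert 0.0 <= s <= 1.0
        assert s == similarity_score(b, a)
        assert (s == 1.0) == (Counter(a) == Counter(b))

    @given(signature, signature)
    def test_adding_shared_domain_never_decreases_score(self, a, b):
        s0 = similarity_score(a, b)
        a2, b2 = dict(a), dict(b)
        a2["PF_NEW"] = b2["PF_NEW"] = 1
        assert similarity_score(a2, b2) >= s0 - 1e-12


class TestCmpSeeded:
    def make_db(self, sigs):
        return DomainDB(signature_of_gene={g: Counter(s) for g, s in sigs.items()})

    def test_no_shared_domain_no_prediction(self):
        db = self.make_db({"SEED": {"PF1": 1}, "CAND": {"PF2": 1}})
        space = space_of({"L1": ["CAND"], "L2": ["OTHER"]})
        assert cmp_seeded(space, {"SEED"}, db) == []

    def test_identical_candidate_ranks_first(self):
        db = self.make_db(
            {"SEED": {"PF1": 1, "PF2": 1}, "CAND": {"PF1": 1, "PF2": 1}, "PART": {"PF1": 1, "PF3": 1, "PF4": 1}}
        )
        space = space_of({"L1": ["CAND"], "L2": ["PART"]})
        preds = cmp_seeded(space, {"SEED"}, db, threshold=0.2)
        assert preds[0].gene_id == "CAND"
        assert preds[0].score == 1.0 and preds[0].rank == 1
        assert preds[0].seed_gene == "SEED"

    def test_threshold_inclusive_at_exactly_0_4(self):
        # min-sum 2 / max-sum 5 = 0.4 exactly
        db = self.make_db(
            {"SEED": {"A": 1, "B": 1, "C": 1, "D": 1, "E": 1}, "CAND": {"A": 1, "B": 1}}
        )
        space = space_of({"L1": ["CAND"]})
        preds = cmp_seeded(space, {"SEED"}, db)
        assert [p.gene_id for p in preds] == ["CAND"]
        assert preds[0].score == pytest.approx(0.4)

    def test_unannotated_seeds_give_empty_result(self):
        db = self.make_db({"CAND": {"PF1": 1}})
        space = space_of({"L1": ["CAND"]})
        assert cmp_seeded(space, {"SEED"}, db) == []

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            cmp_seeded(space_of({}), set(), DomainDB())


def genome_db(n_genes, carriers, carrier_domain="DC", bg_domain="DBG", genome_count=None):
    """All genes single-domain; `carriers` get the rare domain."""
    sigs = {}
    for i in range(1, n_genes + 1):
        g = f"G{i:04d}"
        sigs[g] = Counter({carrier_domain if g in carriers else bg_domain: 1})
    return DomainDB(signature_of_gene=sigs, genome_gene_count=genome_count or n_genes)


class TestCombinationStats:
    def test_single_domain_extrema_coincide(self):
        db = genome_db(100, {"G0001", "G0002"})
        combo = DomainCombination.from_signature("G0001", {"DC": 1})
        stats = combination_stats(combo, [f"G{i:04d}" for i in range(1, 51)], db)
        assert stats.p_corr == stats.p_indep_unique == pytest.approx(0.02)
        assert stats.chi2_min == stats.chi2_max_unique

    def test_observed_equal_expected_gives_zero_chi2(self):
        db = genome_db(100, {f"G{i:04d}" for i in range(1, 51)})
        combo = DomainCombination.from_signature("G0001", {"DC": 1})
        # space of 2 genes, one carrier: observed 1 == expected 2*0.5
        stats = combination_stats(combo, ["G0001", "G0060"], db)
        assert stats.observed == 1
        assert stats.chi2_min == stats.chi2_max == 0.0

    def test_hand_computed_chi2(self):
        # n=50, f(d)=0.02, observed 5 -> expected 1, chi2 = 16
        carriers = {f"G{i:04d}" for i in range(1, 6)}
        db = genome_db(250, carriers)
        combo = DomainCombination.from_signature("G0001", {"DC": 1})
        space_genes = [f"G{i:04d}" for i in range(1, 51)]
        stats = combination_stats(combo, space_genes, db)
        assert stats.p_corr == pytest.approx(5 / 250)
        assert stats.expected_corr == pytest.approx(1.0)
        assert stats.observed == 5
        assert stats.chi2_min == pytest.approx(16.0)

    def test_copy_counts_drive_p_indep_below_unique(self):
        sigs = {f"G{i}": Counter({"PF1": 1, "PF2": 1}) for i in range(5)}
        sigs.update({f"H{i}": Counter({"PF9": 1}) for i in range(5)})
        sigs["GX"] = Counter({"PF1": 2, "PF2": 1})
        db = DomainDB(signature_of_gene=sigs)
        combo = DomainCombination.from_signature("GX", sigs["GX"])
        stats = combination_stats(combo, list(sigs), db)
        f1, f2 = db.frequency("PF1"), db.frequency("PF2")
        assert stats.p_indep == pytest.approx(f1 * f1 * f2)
        assert stats.p_indep_unique == pytest.approx(f1 * f2)
        assert stats.p_indep < stats.p_indep_unique < stats.p_corr

    def test_domain_absent_from_genome_rejected(self):
        db = genome_db(10, set())
        combo = DomainCombination.from_signature("X", {"NOPE": 1})
        with pytest.raises(ValueError):
            combination_stats(combo, ["G0001"], db)

    @pytest.mark.parametrize("seed", range(8))
    def test_probability_and_chi2_ordering(self, seed):
        rng = np.random.default_rng(seed)
        domains = [f"PF{i}" for i in range(12)]
        sigs = {}
        for i in range(60):
            picks = rng.choice(12, size=rng.integers(1, 4), replace=False)
            sigs[f"G{i:03d}"] = Counter(
                {domains[k]: int(rng.integers(1, 4)) for k in picks}
            )
        db = DomainDB(signature_of_gene=sigs)
        space_genes = sorted(sigs)[:25]
        for g in space_genes:
            combo = DomainCombination.from_signature(g, sigs[g])
            stats = combination_stats(combo, space_genes, db)
            assert stats.p_indep <= stats.p_indep_unique <= stats.p_corr
            if stats.observed > stats.expected_corr:
                assert stats.chi2_min <= stats.chi2_max_unique <= stats.chi2_max


def planted_space_and_db(n_carrier_loci):
    """40-gene space in 8 loci; rare-domain carriers in the first k loci.

    Genome: 2000 annotated genes, 10 carrying the rare domain
    (f = 0.005); 5 potential carriers sit in the space, one per locus,
    but only the first `n_carrier_loci` are carriers.
    """
    sigs = {}
    per_locus = {}
    space_ids = [f"S{i:03d}" for i in range(40)]
    for j in range(8):
        per_locus[f"L{j+1}"] = space_ids[j * 5 : (j + 1) * 5]
    carriers = {space_ids[j * 5] for j in range(n_carrier_loci)}
    for g in space_ids:
        sigs[g] = Counter({"DC": 1} if g in carriers else {"DBG": 1})
    # pad the genome: carriers outside the space keep f(DC) at 10/2000
    for i in range(2000 - 40):
        g = f"B{i:04d}"
        sigs[g] = Counter({"DC": 1} if i < 10 - n_carrier_loci else {"DBG": 1})
    return space_of(per_locus), DomainDB(signature_of_gene=sigs)


class TestCmpAbInitio:
    def test_five_locus_carrier_combination_emitted(self):
        space, db = planted_space_and_db(5)
        preds = cmp_ab_initio(space, db)
        carriers = {g for g in space.all_genes if db.signature_of_gene[g] == Counter({"DC": 1})}
        assert {p.gene_id for p in preds} == carriers
        # observed 5, expected 40 * 0.005 = 0.2 -> chi2_min = 115.2
        assert preds[0].score == pytest.approx(115.2)
        assert all(len(p.supporting_loci) >= 1 for p in preds)

    def test_four_locus_version_suppressed(self):
        space, db = planted_space_and_db(4)
        # observed 4 -> chi2_min = (4 - 0.2)^2 / 0.2 = 72.2 < 100
        assert cmp_ab_initio(space, db) == []

    def test_single_locus_combination_suppressed_regardless_of_chi2(self):
        sigs = {f"G{i}": Counter({"DBG": 1}) for i in range(100)}
        sigs["G0"] = sigs["G1"] = Counter({"DC": 1})
        db = DomainDB(signature_of_gene=sigs, genome_gene_count=2000)
        space = space_of({"L1": ["G0", "G1"], "L2": ["G5"]})
        assert cmp_ab_initio(space, db) == []

    def test_chi2_cutoff_inclusive(self):
        # engineered so chi2_min lands exactly on the printed cutoff of 100
        sigs = {f"S{i:03d}": Counter({"DC": 1} if i < 11 else {"DBG": 1}) for i in range(100)}
        for i in range(1000):  # abundant background domain: never over-represented
            sigs[f"B{i:04d}"] = Counter({"DBG": 1})
        db = DomainDB(signature_of_gene=sigs)
        per_locus = {f"L{j}": [f"S{i:03d}" for i in range(j * 10, (j + 1) * 10)] for j in range(10)}
        space = space_of(per_locus)
        stats_preds = cmp_ab_initio(space, db)
        # f = 11/1100 = 0.01, n = 100, expected 1.0, observed 11 -> chi2 = 100
        assert len(stats_preds) == 11
        assert stats_preds[0].score == pytest.approx(100.0)

    def test_seeds_excluded_from_ab_initio(self):
        space, db = planted_space_and_db(5)
        carriers = sorted(
            g for g in space.all_genes if db.signature_of_gene[g] == Counter({"DC": 1})
        )
        preds = cmp_ab_initio(space, db, seeds={carriers[0]})
        assert carriers[0] not in {p.gene_id for p in preds}

    def test_null_fixture_emits_nothing(self):
        # domains assigned independently at genome frequencies: far below cutoffs
        rng = np.random.default_rng(3)
        emitted = 0
        for _ in range(200):
            sigs = {
                f"G{i:03d}": Counter({f"PF{int(rng.integers(10))}": 1}) for i in range(400)
            }
            db = DomainDB(signature_of_gene=sigs)
            genes = sorted(sigs)[:30]
            per_locus = {f"L{j}": genes[j * 3 : (j + 1) * 3] for j in range(10)}
            emitted += len(cmp_ab_initio(space_of(per_locus), db))
        assert emitted == 0


class TestConfigurableMatching:
    def test_match_copies_narrows_observed(self):
        sigs = {f"G{i}": Counter({"DC": 1}) for i in range(3)}
        sigs["GD"] = Counter({"DC": 2})
        sigs.update({f"H{i}": Counter({"DBG": 1}) for i in range(6)})
        db = DomainDB(signature_of_gene=sigs)
        combo = DomainCombination.from_signature("GD", {"DC": 2})
        loose = combination_stats(combo, sorted(sigs), db)
        strict = combination_stats(combo, sorted(sigs), db, match_copies=True)
        assert loose.observed == 4
        assert strict.observed == 1

    def test_similarity_function_pluggable(self):
        db = DomainDB(
            signature_of_gene={"SEED": Counter({"PF1": 1}), "CAND": Counter({"PF2": 1})}
        )
        space = space_of({"L1": ["CAND"]})
        assert cmp_seeded(space, {"SEED"}, db) == []
        preds = cmp_seeded(space, {"SEED"}, db, similarity=lambda a, b: 1.0)
        assert [p.gene_id for p in preds] == ["CAND"]
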