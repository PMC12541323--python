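"""Scoring pipeline: read assignment, demux, filtering, Eq-style scores, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sh2swap import oligo_design as od, quantify as qt, synthetic_data as sd
from sh2swap.seq_core import NucleotideSequence


def _table(data, variants):
    df = pd.DataFrame(data, index=variants)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sample", "replicate"])
    return df


class TestAssignReads:
    @pytest.fixture(scope="class")
    def refs(self):
        rng = np.random.default_rng(41)
        bases = "ACGT"
        out = []
        for i in range(10):
            seq = "".join(bases[j] for j in rng.integers(0, 4, 120))
            out.append(NucleotideSequence(f"v{i}", seq))
        return out

    def test_error_free_reads_assign_to_source(self, refs):
        reads = [refs[3].bases[10:90], refs[7].bases[0:80]]
        counts, unassigned = qt.assign_reads(reads, refs, k=25)
        assert counts == {"v3": 1, "v7": 1} and unassigned == 0

    def test_reverse_strand_reads_assign(self, refs):
        rc = NucleotideSequence("r", refs[2].bases[:80]).reverse_complement().bases
        counts, _ = qt.assign_reads([rc], refs, k=25)
        assert counts == {"v2": 1}

    def test_constant_region_only_read_is_unassigned(self):
        shared = "ACGTACGTACGTACGTACGTACGTACGTACGT"  # 32 nt constant
        refs = [
            NucleotideSequence("a", shared + "AAAAAAAAAAAAAAAAAAAAAAAAA"),
            NucleotideSequence("b", shared + "CCCCCCCCCCCCCCCCCCCCCCCCC"),
        ]
        counts, unassigned = qt.assign_reads([shared], refs, k=25)
        assert counts == {} and unassigned == 1

    def test_identical_references_rejected_at_index_build(self):
        refs = [NucleotideSequence("a", "ACGT" * 10), NucleotideSequence("b", "ACGT" * 10)]
        with pytest.raises(ValueError, match="indistinguishable"):
            qt.KmerIndex(refs)

    def test_simulated_proportions_recovered(self, refs):
        # 10^4 error-free reads at known proportions: counts land within a
        # generous multinomial envelope of the truth
        rng = np.random.default_rng(17)
        p = np.arange(1, 11, dtype=float)
        p /= p.sum()
        n = 10_000
        draws = rng.multinomial(n, p)
        reads = []
        for ref, k in zip(refs, draws):
            starts = rng.integers(0, len(ref.bases) - 80 + 1, size=k)
            reads.extend(ref.bases[s : s + 80] for s in starts)
        counts, unassigned = qt.assign_reads(reads, refs, k=25)
        assert unassigned == 0
        for ref, k in zip(refs, draws):
            assert counts[ref.id] == k


class TestDemuxDual:
    @pytest.fixture(scope="class")
    def helix_pool(self, ref82):
        protein, cds = ref82
        helix_cds = cds[:60] + "TAA"  # short variable region ending in stop
        cds_by_variant = {}
        rng = np.random.default_rng(43)
        for i in range(6):
            pos = int(rng.integers(0, 20))
            alt = od.CODON_SETS["L"][i]
            var = helix_cds[: 3 * pos] + alt + helix_cds[3 * pos + 3 :]
            cds_by_variant[f"h{i}"] = var
        return cds_by_variant

    def test_barcode_identifies_background(self, helix_pool):
        vid, cds = next(iter(helix_pool.items()))
        read = "GCGC" + cds + "GGA" + "TTTT"
        res = qt.demux_dual(read, helix_pool)
        assert res == qt.DemuxResult(vid, "BMX-H", "ok")

    def test_single_mismatch_barcode_unassigned(self, helix_pool):
        vid, cds = next(iter(helix_pool.items()))
        read = cds + "TTA"  # one mismatch from TTC: no error correction
        res = qt.demux_dual(read, helix_pool)
        assert res.background is None and res.reason == "barcode_unknown"

    def test_round_trip_full_pool_zero_error(self, helix_pool):
        mis = 0
        for vid, cds in helix_pool.items():
            for background, codes in od.BACKGROUND_BARCODES.items():
                for bc in codes:
                    res = qt.demux_dual("AA" + cds + bc + "CCGG", helix_pool)
                    if res.variant_id != vid or res.background != background:
                        mis += 1
        assert mis == 0

    def test_unmatched_read_reported_as_data(self, helix_pool):
        res = qt.demux_dual("A" * 80, helix_pool)
        assert res.reason == "no_variant_match"


class TestInputFilter:
    def test_boundary_convention(self):
        t = _table(
            {("input", 1): [49, 50, 200], ("sort", 1): [10, 10, 10]},
            ["low", "edge", "high"],
        )
        out = qt.filter_min_input(t, cutoff=50)
        assert np.isnan(out.loc["low", ("input", 1)])
        assert out.loc["edge", ("input", 1)] == 50
        assert out.loc["high", ("sort", 1)] == 10

    def test_cutoff_zero_is_identity(self):
        t = _table({("input", 1): [0, 5], ("sort", 1): [1, 1]}, ["a", "b"])
        out = qt.filter_min_input(t, cutoff=0)
        assert out.notna().all().all()

    def test_per_replicate_masking(self):
        t = _table(
            {("input", 1): [100, 100], ("input", 2): [10, 100],
             ("sort", 1): [5, 5], ("sort", 2): [5, 5]},
            ["a", "b"],
        )
        out = qt.filter_min_input(t, cutoff=50)
        assert np.isnan(out.loc["a", ("sort", 2)]) and out.loc["a", ("sort", 1)] == 5


class TestFitness:
    def test_wt_matched_ratio_scores_zero(self):
        t = _table(
            {("input", 1): [100, 100], ("sort", 1): [150, 150]}, ["wt1", "v"]
        )
        scores = qt.fitness(t, ["wt1"])
        assert scores.loc["v", "rep1"] == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        # Sort=200, Input=100 with WT raw mean 0 -> log10(2)
        t = _table(
            {("input", 1): [100, 100], ("sort", 1): [100, 200]}, ["wt1", "v"]
        )
        scores = qt.fitness(t, ["wt1"])
        assert scores.loc["v", "rep1"] == pytest.approx(np.log10(2), abs=1e-12)

    def test_wt_synonym_mean_is_zero_every_replicate(self):
        rng = np.random.default_rng(3)
        variants = [f"wt{i}" for i in range(5)] + [f"v{i}" for i in range(20)]
        data = {}
        for rep in (1, 2, 3):
            data[("input", rep)] = rng.integers(60, 500, len(variants))
            data[("sort", rep)] = rng.integers(60, 500, len(variants))
        scores = qt.fitness(_table(data, variants), [f"wt{i}" for i in range(5)])
        for rep in (1, 2, 3):
            assert scores.loc[[f"wt{i}" for i in range(5)], f"rep{rep}"].mean() == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=2, max_value=1000), st.integers(min_value=2, max_value=1000))
    def test_depth_rescaling_invariance(self, input_scale, sort_scale):
        base = _table(
            {("input", 1): [100, 80, 120], ("sort", 1): [90, 160, 40]},
            ["wt1", "a", "b"],
        )
        scaled = base.copy()
        scaled[("input", 1)] *= input_scale
        scaled[("sort", 1)] *= sort_scale
        s0 = qt.fitness(base, ["wt1"])
        s1 = qt.fitness(scaled, ["wt1"])
        assert np.allclose(s0["rep1"], s1["rep1"], atol=1e-12)

    def test_zero_sort_replaced_by_pseudocount_only(self):
        t = _table(
            {("input", 1): [100, 100, 100], ("sort", 1): [100, 0, 7]},
            ["wt1", "zero", "low"],
        )
        scores = qt.fitness(t, ["wt1"], pseudocount=0.5)
        assert scores.loc["zero", "rep1"] == pytest.approx(np.log10(0.5 / 100), abs=1e-12)
        assert scores.loc["low", "rep1"] == pytest.approx(np.log10(7 / 100), abs=1e-12)

    def test_zero_sort_drop_mode(self):
        t = _table(
            {("input", 1): [100, 100], ("sort", 1): [100, 0]}, ["wt1", "zero"]
        )
        scores = qt.fitness(t, ["wt1"], zero_sort="drop")
        assert np.isnan(scores.loc["zero", "rep1"])

    def test_no_surviving_wt_synonym_errors(self):
        t = _table({("input", 1): [10, 100], ("sort", 1): [5, 50]}, ["wt1", "v"])
        filtered = qt.filter_min_input(t, cutoff=50)
        with pytest.raises(ValueError, match="wild-type"):
            qt.fitness(filtered, ["wt1"])

    def test_missing_replicates_adjust_n(self):
        t = _table(
            {("input", 1): [100, 100], ("input", 2): [100, 10],
             ("sort", 1): [100, 50], ("sort", 2): [100, 50]},
            ["wt1", "v"],
        )
        scores = qt.fitness(qt.filter_min_input(t, 50), ["wt1"])
        assert scores.loc["v", "n"] == 1 and scores.loc["wt1", "n"] == 2


class TestCollapseSynonyms:
    def test_equal_synonyms_collapse_to_same_value(self):
        scores = pd.DataFrame(
            {"rep1": [0.1, 0.1, 0.1, 0.1], "rep2": [0.2, 0.2, 0.2, 0.2]},
            index=[f"p|syn{i}" for i in range(1, 5)],
        )
        out = qt.collapse_synonyms(scores, {f"p|syn{i}": "p" for i in range(1, 5)})
        assert out.loc["p", "rep1"] == pytest.approx(0.1)

    def test_filtered_synonym_mean_over_remaining(self):
        scores = pd.DataFrame(
            {"rep1": [0.1, 0.2, np.nan]}, index=["s1", "s2", "s3"]
        )
        out = qt.collapse_synonyms(scores, {s: "p" for s in ["s1", "s2", "s3"]})
        assert out.loc["p", "rep1"] == pytest.approx(0.15)

    def test_protein_level_rmse_beats_nucleotide_level(self):
        cfg = sd.SimConfig(n_variants=120, n_wt_synonyms=10, replicates=4,
                           input_depth=200_000, sort_depth=200_000, seed=29)
        truth = sd.make_ground_truth(cfg)
        # 4 synonyms per protein share the protein's g
        syn_truth = truth.loc[truth.index.repeat(4)].copy()
        syn_truth.index = [f"{v}|syn{i%4+1}" for i, v in enumerate(syn_truth.index)]
        table = sd.simulate_experiment(syn_truth, cfg)
        wt = [v for v in syn_truth.index if v.startswith("wt_syn")]
        scores = qt.fitness(qt.filter_min_input(table, 50), wt)
        protein_map = {v: v.split("|")[0] for v in syn_truth.index}
        collapsed = qt.collapse_synonyms(scores, protein_map)
        nuc_err = (scores["mean"] - syn_truth["g"]).dropna()
        prot_err = (collapsed["mean"] - truth["g"]).dropna()
        assert np.sqrt((prot_err ** 2).mean()) < np.sqrt((nuc_err ** 2).mean())


class TestBackgroundDifference:
    def _scores(self, means, sems, ids):
        return pd.DataFrame({"mean": means, "sem": sems}, index=ids)

    def test_identical_tables_give_zero_delta(self):
        s = self._scores([0.1, -0.2], [0.03, 0.05], ["a", "b"])
        diff = qt.background_difference(s, s)
        assert (diff["delta"] == 0).all()
        assert diff["se"].tolist() == pytest.approx([0.03 * np.sqrt(2), 0.05 * np.sqrt(2)])

    def test_three_four_five(self):
        a = self._scores([0.0], [0.03], ["v"])
        b = self._scores([0.5], [0.04], ["v"])
        diff = qt.background_difference(b, a)
        assert diff.loc["v", "se"] == pytest.approx(0.05, abs=1e-15)
        assert diff.loc["v", "delta"] == pytest.approx(0.5)

    def test_restricts_to_intersection(self):
        a = self._scores([0.0, 1.0], [0.1, 0.1], ["v", "only_a"])
        b = self._scores([0.5, 2.0], [0.1, 0.1], ["v", "only_b"])
        diff = qt.background_difference(b, a)
        assert list(diff.index) == ["v"]

    def test_planted_background_effect_recovered(self):
        # same variants in two backgrounds; background B shifts a subset by +0.4
        cfg_a = sd.SimConfig(n_variants=100, n_wt_synonyms=10, replicates=4,
                             input_depth=500_000, sort_depth=500_000, seed=61)
        truth_a = sd.make_ground_truth(cfg_a)
        truth_b = truth_a.copy()
        shifted = truth_b.index[20:50]
        truth_b.loc[shifted, "g"] += 0.4
        cfg_b = sd.SimConfig(n_variants=100, n_wt_synonyms=10, replicates=4,
                             input_depth=500_000, sort_depth=500_000, seed=62)
        wt = [v for v in truth_a.index if v.startswith("wt_syn")]
        s_a = qt.fitness(qt.filter_min_input(sd.simulate_experiment(truth_a, cfg_a), 50), wt)
        s_b = qt.fitness(qt.filter_min_input(sd.simulate_experiment(truth_b, cfg_b), 50), wt)
        diff = qt.background_difference(s_b, s_a)
        planted = truth_b["g"] - truth_a["g"]
        # the SE is itself estimated from 4 replicates (3 df per background),
        # so +-2 SE covers well under 95%; 3 SE restores nominal coverage
        # under the matching t distribution
        within = (np.abs(diff["delta"] - planted) <= 3 * diff["se"]).mean()
        assert within >= 0.95
        # and the planted shift is recovered on average
        assert diff.loc[shifted, "delta"].mean() == pytest.approx(0.4, abs=0.05)


class TestReplicateCorrelation:
    def test_self_correlation_is_one(self):
        scores = pd.DataFrame({"rep1": [0.1, 0.5, -0.2], "rep2": [0.1, 0.4, -0.1]})
        corr = qt.replicate_correlation(scores)
        assert corr.loc["rep1", "rep1"] == pytest.approx(1.0)

    def test_anticorrelated_toy_vectors(self):
        scores = pd.DataFrame({"rep1": [1.0, 2.0, 3.0], "rep2": [3.0, 2.0, 1.0]})
        corr = qt.replicate_correlation(scores)
        assert corr.loc["rep1", "rep2"] == pytest.approx(-1.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            qt.replicate_correlation(pd.DataFrame({"rep1": [1.0, 2.0]}))


class TestCountTableIO:
    def test_round_trip(self, tmp_path):
        t = _table(
            {("input", 1): [1, 2], ("sort", 1): [3, 4]}, ["a", "b"]
        )
        path = tmp_path / "c.tsv"
        qt.write_count_table(t, path)
        back = qt.read_count_table(path)
        assert (back == t).all().all()
        assert list(back.columns) == list(t.columns)
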