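"""Fitness math: closed-form examples, an independent literal oracle, and
algebraic invariants (reference-zero, depth invariance, monotonicity,
weighted-mean boundedness)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from barseqfit.errors import InputError
from barseqfit.fitness import (
    FitnessParams,
    center_fitness,
    gene_fitness,
    strain_fitness,
)

# ------------------------------------------------------------------ oracle
# A literal, loop-based evaluation of the fitness definitions, independent of
# the vectorized implementation.  Used here and by the acceptance suite.


def oracle_strain_fitness(counts: pd.DataFrame, ref_samples, ps: float):
    B = counts.shape[0]
    depths = {s: counts[s].sum() for s in counts.columns}
    d0 = sum(depths[s] for s in ref_samples)
    out = {}
    for barcode in counts.index:
        n0 = sum(counts.loc[barcode, s] for s in ref_samples)
        for s in counts.columns:
            if s in ref_samples:
                continue
            f = math.log2((counts.loc[barcode, s] + ps) / (depths[s] + ps * B)) - math.log2(
                (n0 + ps) / (d0 + ps * B)
            )
            out[(barcode, s)] = f
    return out


def oracle_gene_fitness(counts, ref_samples, pool, params: FitnessParams):
    ps = params.pseudocount
    strains = oracle_strain_fitness(counts, ref_samples, ps)
    lo, hi = params.central_window
    out = {}
    for locus in sorted(set(pool["locus"]) - {"intergenic"}):
        rows = pool[pool["locus"] == locus]
        for s in counts.columns:
            if s in ref_samples:
                continue
            num = den = 0.0
            for _, row in rows.iterrows():
                barcode = row["barcode"]
                n0 = sum(counts.loc[barcode, r] for r in ref_samples)
                if n0 < params.min_reference_count:
                    continue
                if not (lo <= row["orf_fraction"] <= hi):
                    continue
                if params.weighting == "uniform":
                    w = 1.0
                elif params.weighting == "reference_count":
                    w = n0 + ps
                else:
                    w = 1.0 / (1.0 / (counts.loc[barcode, s] + ps) + 1.0 / (n0 + ps))
                num += w * strains[(barcode, s)]
                den += w
            if den > 0:
                out[(locus, s)] = num / den
    return out


def _sheet(ref_samples, all_samples):
    return pd.DataFrame(
        {
            "sample_id": all_samples,
            "condition": "control",
            "passage": [1 if s in ref_samples else 2 for s in all_samples],
            "replicate": [f"R{i}" for i in range(len(all_samples))],
            "is_reference": [s in ref_samples for s in all_samples],
        }
    )


def _random_table(rng, n_barcodes=10, n_samples=4):
    counts = pd.DataFrame(
        rng.integers(0, 200, size=(n_barcodes, n_samples)),
        index=pd.Index([f"bc{i:02d}" for i in range(n_barcodes)], name="barcode"),
        columns=[f"s{i}" for i in range(n_samples)],
    )
    counts.iloc[0] += 1  # keep all depths positive
    pool = pd.DataFrame(
        {
            "barcode": counts.index,
            "scaffold": "chr1",
            "strand": "+",
            "position": np.arange(1, n_barcodes + 1),
            "locus": [f"gene{i % 3}" if i % 4 else "intergenic" for i in range(n_barcodes)],
            "orf_fraction": [
                None if i % 4 == 0 else round(float(rng.uniform(0, 1)), 3)
                for i in range(n_barcodes)
            ],
        }
    )
    return counts, pool


class TestStrainFitness:
    def test_sample_equal_to_pooled_reference_is_zero(self):
        rng = np.random.default_rng(0)
        counts, _ = _random_table(rng)
        ref = ["s0", "s1", "s2"]
        pooled = counts[ref].sum(axis=1)
        counts["s3"] = pooled  # depth equals D0 as well
        for ps in (0.0, 0.5, 2.0):
            params = FitnessParams(pseudocount=ps)
            result = strain_fitness(counts, _sheet(ref, list(counts.columns)), params)
            assert np.allclose(result.fitness["s3"], 0.0, atol=1e-12)

    def test_fourfold_change_without_pseudocount(self):
        counts = pd.DataFrame(
            {"ref": [10, 990], "s": [40, 960]},
            index=pd.Index(["bcA", "bcB"], name="barcode"),
        )
        params = FitnessParams(pseudocount=0.0)
        result = strain_fitness(counts, _sheet(["ref"], ["ref", "s"]), params)
        assert result.fitness.loc["bcA", "s"] == pytest.approx(2.0, abs=1e-12)

    def test_pseudocount_example_closed_form(self):
        # n=40 vs n0=10 at depth 1000 each, B=100, ps=1 -> log2(41/11)
        counts = pd.DataFrame(
            {"ref": [10] + [10] * 99, "s": [40] + [0] * 99},
            index=pd.Index([f"bc{i:03d}" for i in range(100)], name="barcode"),
        )
        counts.loc["bc001":"bc099", "ref"] = 10  # depth 1000
        counts.loc["bc001":"bc099", "s"] = 960 // 99
        counts.iloc[1:, 1] = [960 // 99] * 99
        counts.iloc[99, 1] += 960 - (960 // 99) * 99
        assert counts["ref"].sum() == 1000 and counts["s"].sum() == 1000
        params = FitnessParams(pseudocount=1.0)
        result = strain_fitness(counts, _sheet(["ref"], ["ref", "s"]), params)
        assert result.fitness.loc["bc000", "s"] == pytest.approx(
            math.log2(41 / 11), abs=1e-12
        )

    def test_usability_threshold_on_reference_counts(self):
        counts = pd.DataFrame(
            {"ref": [2, 50], "s": [5, 40]},
            index=pd.Index(["low", "high"], name="barcode"),
        )
        result = strain_fitness(counts, _sheet(["ref"], ["ref", "s"]), FitnessParams())
        assert not result.usable["low"] and result.usable["high"]

    def test_no_reference_samples_is_error(self):
        counts = pd.DataFrame(
            {"a": [1], "b": [2]}, index=pd.Index(["x"], name="barcode")
        )
        sheet = _sheet([], ["a", "b"])
        with pytest.raises(InputError):
            strain_fitness(counts, sheet, FitnessParams())

    @given(st.integers(min_value=0, max_value=500), st.integers(min_value=1, max_value=400))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_sample_count(self, n, delta):
        counts = pd.DataFrame(
            {"ref": [50, 50], "s": [n, 100]},
            index=pd.Index(["a", "b"], name="barcode"),
        )
        bumped = counts.copy()
        bumped.loc["a", "s"] = n + delta
        params = FitnessParams(pseudocount=0.5)
        sheet = _sheet(["ref"], ["ref", "s"])
        f1 = strain_fitness(counts, sheet, params).fitness.loc["a", "s"]
        f2 = strain_fitness(bumped, sheet, params).fitness.loc["a", "s"]
        assert f2 > f1

    @given(st.integers(min_value=2, max_value=50), st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_depth_invariance_without_pseudocount(self, scale, seed):
        rng = np.random.default_rng(seed)
        counts, _ = _random_table(rng)
        counts += 1  # ps=0 needs positive counts for finite logs
        sheet = _sheet(["s0", "s1"], list(counts.columns))
        params = FitnessParams(pseudocount=0.0)
        base = strain_fitness(counts, sheet, params).fitness
        scaled_counts = counts.copy()
        scaled_counts["s3"] = counts["s3"] * scale
        scaled = strain_fitness(scaled_counts, sheet, params).fitness
        assert np.allclose(base["s3"], scaled["s3"], atol=1e-9)


class TestGeneFitness:
    @staticmethod
    def _compute(counts, pool, params):
        sheet = _sheet(["s0"], list(counts.columns))
        strains = strain_fitness(counts, sheet, params)
        return gene_fitness(strains, counts, pool, params)

    def _two_strain_setup(self, orf_fractions, sample_counts):
        counts = pd.DataFrame(
            {"s0": [100, 100, 100], "s1": list(sample_counts) + [100]},
            index=pd.Index(["a", "b", "filler"], name="barcode"),
        )
        pool = pd.DataFrame(
            {
                "barcode": ["a", "b", "filler"],
                "scaffold": "chr1",
                "strand": "+",
                "position": [1, 2, 3],
                "locus": ["gX", "gX", "gY"],
                "orf_fraction": list(orf_fractions) + [0.5],
            }
        )
        return counts, pool

    @pytest.mark.parametrize("weighting", ["precision", "reference_count", "uniform"])
    def test_single_central_strain_passes_through(self, weighting):
        counts, pool = self._two_strain_setup([0.5, 0.95], [400, 100])
        params = FitnessParams(weighting=weighting)
        genes = self._compute(counts, pool, params)
        sheet = _sheet(["s0"], list(counts.columns))
        strains = strain_fitness(counts, sheet, params)
        assert genes.fitness.loc["gX", "s1"] == pytest.approx(
            strains.fitness.loc["a", "s1"]
        )
        assert genes.n_strains_used["gX"] == 1

    def test_equal_weights_average(self):
        # identical counts -> equal precision weights -> plain average (here 0)
        counts, pool = self._two_strain_setup([0.3, 0.7], [100, 100])
        genes = self._compute(counts, pool, FitnessParams())
        assert genes.fitness.loc["gX", "s1"] == pytest.approx(0.0, abs=1e-12)
        assert genes.n_strains_used["gX"] == 2
        # unequal strain fitness with uniform weights -> arithmetic mean
        counts, pool = self._two_strain_setup([0.3, 0.7], [400, 100])
        params = FitnessParams(weighting="uniform")
        sheet = _sheet(["s0"], list(counts.columns))
        strains = strain_fitness(counts, sheet, params)
        genes = gene_fitness(strains, counts, pool, params)
        expected = strains.fitness.loc[["a", "b"], "s1"].mean()
        assert genes.fitness.loc["gX", "s1"] == pytest.approx(expected, abs=1e-12)

    def test_peripheral_insertion_excluded(self):
        counts, pool = self._two_strain_setup([0.05, 0.50], [100 * 2**10, 200])
        genes = self._compute(counts, pool, FitnessParams(pseudocount=0.0))
        # the orf_fraction=0.05 strain (huge apparent fitness) must not count
        f = genes.fitness.loc["gX", "s1"]
        depth_term = math.log2(counts["s1"].sum() / counts["s0"].sum())
        assert f == pytest.approx(1.0 - depth_term, abs=1e-9)
        assert genes.n_strains_used["gX"] == 1

    def test_window_endpoints_inclusive(self):
        counts, pool = self._two_strain_setup([0.10, 0.90], [100, 100])
        genes = self._compute(counts, pool, FitnessParams())
        assert genes.n_strains_used["gX"] == 2

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_weighted_mean_within_strain_range(self, seed):
        rng = np.random.default_rng(seed)
        counts, pool = _random_table(rng, n_barcodes=12)
        sheet = _sheet(["s0"], list(counts.columns))
        params = FitnessParams(
            weighting=["precision", "reference_count", "uniform"][seed % 3],
            min_reference_count=0,
        )
        strains = strain_fitness(counts, sheet, params)
        genes = gene_fitness(strains, counts, pool, params)
        lo, hi = params.central_window
        meta = pool.set_index("barcode")
        for locus in genes.fitness.index:
            members = meta[(meta["locus"] == locus)]
            central = members[members["orf_fraction"].between(lo, hi)]
            for s in genes.fitness.columns:
                vals = strains.fitness.loc[central.index, s]
                assert vals.min() - 1e-12 <= genes.fitness.loc[locus, s] <= vals.max() + 1e-12

    @pytest.mark.parametrize("weighting", ["precision", "reference_count", "uniform"])
    def test_matches_literal_oracle(self, weighting):
        rng = np.random.default_rng(123)
        params = FitnessParams(weighting=weighting)
        for _ in range(10):
            counts, pool = _random_table(rng)
            sheet = _sheet(["s0", "s1"], list(counts.columns))
            strains = strain_fitness(counts, sheet, params)
            genes = gene_fitness(strains, counts, pool, params)
            expected = oracle_gene_fitness(counts, ["s0", "s1"], pool, params)
            for (locus, s), value in expected.items():
                assert genes.fitness.loc[locus, s] == pytest.approx(value, abs=1e-9)


class TestCenterFitness:
    @staticmethod
    def _genes(values):
        from barseqfit.fitness import GeneFitness

        df = pd.DataFrame({"s1": values}, index=[f"g{i}" for i in range(len(values))])
        return GeneFitness(fitness=df, n_strains_used=pd.Series(1, index=df.index))

    def test_median_subtraction(self):
        centered = center_fitness(self._genes([1.0, 2.0, 9.0]), "median")
        assert list(centered.fitness["s1"]) == [-1.0, 0.0, 7.0]

    def test_none_is_identity(self):
        genes = self._genes([1.0, 2.0, 9.0])
        assert center_fitness(genes, "none") is genes

    def test_idempotent(self):
        once = center_fitness(self._genes([1.0, 2.0, 9.0]), "median")
        twice = center_fitness(once, "median")
        pd.testing.assert_frame_equal(once.fitness, twice.fitness)

    def test_too_few_genes_rejected(self):
        with pytest.raises(InputError):
            center_fitness(self._genes([1.0, 2.0]), "median")
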