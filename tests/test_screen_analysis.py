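import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bivalentia.genome_model import ValidationError
from bivalentia.screen_analysis import (
    Guide,
    GuideLibrary,
    ScreenCounts,
    count_guides,
    guide_enrichment,
    intersect_screens,
    read_guide_library,
    rsa_rank,
    tier_hits,
    write_guide_library,
)


def rsa_oracle(scores: dict[str, float], gene_guides: dict[str, list[str]]) -> dict[str, Fraction]:
    """Exact-rational RSA: enumerate hypergeometric tail terms directly."""
    order = sorted(scores, key=lambda g: (-scores[g], g))
    rank = {g: i + 1 for i, g in enumerate(order)}
    n_total = len(order)
    out = {}
    for gene, gids in gene_guides.items():
        ranks = sorted(rank[g] for g in gids)
        k = len(ranks)
        best = Fraction(1)
        for j, r in enumerate(ranks, start=1):
            tail = sum(
                Fraction(comb(k, i) * comb(n_total - k, r - i), comb(n_total, r))
                for i in range(j, min(k, r) + 1)
            )
            best = min(best, tail)
        out[gene] = best
    return out


def _library(gene_guides: dict[str, list[str]], n_controls: int = 0) -> GuideLibrary:
    guides = []
    idx = 0
    for gene, gids in gene_guides.items():
        for gid in gids:
            guides.append(Guide(gid, _spacer(idx), gene))
            idx += 1
    for j in range(n_controls):
        guides.append(Guide(f"ntc{j}", _spacer(idx), None, "non_targeting"))
        idx += 1
    return GuideLibrary(guides, "ACCG")


def _spacer(i: int, length: int = 12) -> str:
    bases = "ACGT"
    return "".join(bases[(i >> (2 * k)) & 3] for k in range(length))


class TestGuideLibrary:
    def test_duplicate_guide_id_rejected(self):
        with pytest.raises(ValidationError):
            GuideLibrary(
                [Guide("g", "ACGT", "x"), Guide("g", "TTTT", "y")], ""
            )

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            GuideLibrary([], "")

    def test_bad_spacer_rejected(self):
        with pytest.raises(ValidationError):
            Guide("g", "acgu", "x")

    def test_control_class_has_no_gene(self):
        with pytest.raises(ValidationError):
            Guide("g", "ACGT", "x", "non_targeting")

    def test_tsv_round_trip(self, tmp_path):
        lib = _library({"geneA": ["a1", "a2"]}, n_controls=1)
        write_guide_library(lib, tmp_path / "lib.tsv")
        back = read_guide_library(tmp_path / "lib.tsv", constant_prefix="ACCG")
        assert {g.guide_id for g in back} == {g.guide_id for g in lib}
        assert back.guides["ntc0"].control_class == "non_targeting"


class TestCountGuides:
    def test_exact_match_assigned(self):
        lib = _library({"geneA": ["a1"]})
        spacer = lib.guides["a1"].spacer
        counts = count_guides({"sorted": [f"ACCG{spacer}AAAA"], "unsorted": []}, lib)
        assert counts.counts.loc["a1", "sorted"] == 1
        assert counts.totals["sorted"] == {"assigned": 1, "ambiguous": 0, "unmatched": 0}

    def test_shared_spacer_ambiguous_discarded(self):
        spacer = "ACGTACGTACGT"
        lib = GuideLibrary(
            [Guide("a1", spacer, "geneA"), Guide("b1", spacer, "geneB")], "ACCG"
        )
        counts = count_guides({"sorted": [f"ACCG{spacer}"]}, lib)
        assert counts.counts["sorted"].sum() == 0
        assert counts.totals["sorted"]["ambiguous"] == 1

    def test_missing_prefix_unmatched(self):
        lib = _library({"geneA": ["a1"]})
        spacer = lib.guides["a1"].spacer
        counts = count_guides({"sorted": [f"TTTT{spacer}"]}, lib)
        assert counts.totals["sorted"]["unmatched"] == 1

    def test_prefix_trim_at_first_occurrence(self):
        lib = _library({"geneA": ["a1"]})
        spacer = lib.guides["a1"].spacer
        counts = count_guides({"sorted": [f"GGACCG{spacer}TT"]}, lib)
        assert counts.counts.loc["a1", "sorted"] == 1

    def test_conservation_invariant(self):
        lib = _library({"geneA": ["a1", "a2"]})
        sp = lib.guides["a1"].spacer
        reads = [f"ACCG{sp}", "ACCGAAAAAAAAAAAA", "NOPE"]
        counts = count_guides({"s": reads}, lib)
        t = counts.totals["s"]
        assert t["assigned"] + t["ambiguous"] + t["unmatched"] == len(reads)
        assert counts.counts["s"].sum() == t["assigned"]

    def test_fastq_parsing(self, tmp_path):
        lib = _library({"geneA": ["a1"]})
        spacer = lib.guides["a1"].spacer
        fq = tmp_path / "reads.fastq"
        fq.write_text(f"@r1\nACCG{spacer}\n+\n{'I' * (4 + len(spacer))}\n")
        counts = count_guides({"sorted": str(fq)}, lib)
        assert counts.counts.loc["a1", "sorted"] == 1


class TestGuideEnrichment:
    def _counts(self, sorted_c, unsorted_c):
        df = pd.DataFrame({"sorted": sorted_c, "unsorted": unsorted_c})
        return ScreenCounts(df)

    def test_equal_rpm_zero(self):
        counts = self._counts({"a": 10, "b": 30}, {"a": 20, "b": 60})
        scores = guide_enrichment(counts)
        assert scores["a"] == pytest.approx(0.0)

    def test_arithmetic(self):
        # single-guide contrived RPMs via equal totals
        counts = self._counts({"a": 8, "b": 999992}, {"a": 2, "b": 999998})
        scores = guide_enrichment(counts, pseudocount=0.5)
        assert scores["a"] == pytest.approx(math.log2(8.5 / 2.5))

    def test_absent_in_sorted_negative(self):
        counts = self._counts({"a": 0, "b": 100}, {"a": 10, "b": 90})
        assert guide_enrichment(counts)["a"] < 0

    def test_zero_assigned_rejected(self):
        counts = self._counts({"a": 0}, {"a": 5})
        with pytest.raises(ValidationError):
            guide_enrichment(counts)


class TestRsaRank:
    def test_single_gene_owns_all_guides(self):
        lib = _library({"geneA": [f"a{i}" for i in range(6)]})
        scores = pd.Series({f"a{i}": float(-i) for i in range(6)})
        logp = rsa_rank(scores, lib)
        assert logp["geneA"] == pytest.approx(0.0)

    def test_hand_case_ranks_1_2_of_10(self):
        lib = _library({"geneA": ["a1", "a2"], "filler": [f"f{i}" for i in range(8)]})
        scores = pd.Series(
            {"a1": 10.0, "a2": 9.0, **{f"f{i}": float(-i) for i in range(8)}}
        )
        logp = rsa_rank(scores, lib)
        assert 10 ** logp["geneA"] == pytest.approx(1 / 45, rel=1e-12)

    def test_hand_case_ranks_1_and_10(self):
        lib = _library({"geneA": ["a1", "a2"], "filler": [f"f{i}" for i in range(8)]})
        scores = pd.Series(
            {"a1": 10.0, "a2": -99.0, **{f"f{i}": float(-i) for i in range(8)}}
        )
        logp = rsa_rank(scores, lib)
        assert 10 ** logp["geneA"] == pytest.approx(0.2, rel=1e-12)

    def test_controls_occupy_ranks_but_get_no_p(self):
        lib = _library({"geneA": ["a1"]}, n_controls=5)
        scores = pd.Series({"a1": 1.0, **{f"ntc{j}": 2.0 + j for j in range(5)}})
        logp = rsa_rank(scores, lib)
        assert list(logp.index) == ["geneA"]
        # a1 ranks 6th of 6: p = P[X >= 1 | N=6, K=1, n=6] = 1
        assert logp["geneA"] == pytest.approx(0.0)

    def test_monotone_transform_invariance(self):
        lib = _library({"geneA": ["a1", "a2"], "geneB": ["b1", "b2"]})
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=4), index=["a1", "a2", "b1", "b2"])
        logp1 = rsa_rank(scores, lib)
        logp2 = rsa_rank(np.exp(scores * 3) + 7, lib)
        pd.testing.assert_series_equal(logp1, logp2)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_exact_oracle(self, data):
        n_genes = data.draw(st.integers(1, 5))
        gene_guides = {}
        idx = 0
        for g in range(n_genes):
            k = data.draw(st.integers(1, 6))
            gene_guides[f"gene{g}"] = [f"sg{idx + j}" for j in range(k)]
            idx += k
        n_controls = data.draw(st.integers(0, 30 - idx if idx < 30 else 0))
        lib = _library(gene_guides, n_controls=n_controls)
        all_ids = sorted(lib.guides)
        vals = data.draw(
            st.lists(
                st.floats(-10, 10, allow_nan=False),
                min_size=len(all_ids),
                max_size=len(all_ids),
            )
        )
        scores = pd.Series(vals, index=all_ids)
        logp = rsa_rank(scores, lib)
        oracle = rsa_oracle(scores.to_dict(), gene_guides)
        for gene, frac in oracle.items():
            assert 10 ** logp[gene] == pytest.approx(float(frac), rel=1e-12)


class TestTiers:
    def _results(self, p, n_enriched):
        lib = _library({"geneA": [f"a{i}" for i in range(10)]})
        scores = pd.Series(
            {f"a{i}": (2.0 if i < n_enriched else 0.0) for i in range(10)}
        )
        logp = pd.Series({"geneA": math.log10(p)})
        return tier_hits(logp, scores, lib)

    def test_high(self):
        assert self._results(1e-6, 5).loc["geneA", "tier"] == "high"

    def test_too_few_guides_none(self):
        assert self._results(1e-6, 3).loc["geneA", "tier"] == "none"

    def test_low(self):
        assert self._results(5e-4, 6).loc["geneA", "tier"] == "low"

    def test_moderate(self):
        assert self._results(5e-5, 4).loc["geneA", "tier"] == "moderate"

    def test_boundaries_closed_downward(self):
        # p exactly 1e-5 -> moderate; exactly 1e-4 -> low; exactly 1e-3 -> none
        assert self._results(1e-5, 5).loc["geneA", "tier"] == "moderate"
        assert self._results(1e-4, 5).loc["geneA", "tier"] == "low"
        assert self._results(1e-3, 5).loc["geneA", "tier"] == "none"


class TestIntersect:
    def _df(self, entries):
        df = pd.DataFrame(entries, columns=["gene_id", "logp", "n_enriched", "tier"])
        return df.set_index("gene_id")

    def test_shared_only(self):
        a = self._df([("X", -6.0, 5, "high"), ("Y", -4.5, 5, "moderate")])
        b = self._df([("Y", -5.0, 5, "moderate"), ("Z", -6.0, 5, "high")])
        out = intersect_screens(a, b)
        assert list(out.index) == ["Y"]
        assert out.loc["Y", "worst_logp"] == pytest.approx(-4.5)

    def test_disjoint_empty(self):
        a = self._df([("X", -6.0, 5, "high")])
        b = self._df([("Z", -6.0, 5, "high")])
        assert intersect_screens(a, b).empty

    def test_identical_identity(self):
        a = self._df([("X", -6.0, 5, "high"), ("Y", -3.5, 5, "low")])
        out = intersect_screens(a, a.copy())
        assert set(out.index) == {"X", "Y"}
        assert list(out.index) == ["X", "Y"]  # sorted by worst p

    def test_min_tier_filters(self):
        a = self._df([("X", -3.5, 5, "low")])
        b = self._df([("X", -3.6, 5, "low")])
        assert intersect_screens(a, b, min_tier="moderate").empty
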