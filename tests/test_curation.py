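"""Ortholog harmonization, combined transcriptome, signature subtraction,
Venn partitions."""

import numpy as np
import pandas as pd
import pytest

from xenostroma.curation import (
    DEFAULT_ORDER,
    GeneSignature,
    OrthologMap,
    build_obbmst,
    case_convention_map,
    concordance_r2,
    curate,
    harmonize_symbols,
    venn_partition,
)


class TestHarmonize:
    def test_case_convention_translation(self):
        m = case_convention_map(["Postn", "Aspn", "Fscn1"])
        sig = GeneSignature("s", "mouse", "inflammatory", ("Postn", "Fscn1"))
        out, log = harmonize_symbols(sig, m, "human")
        assert out.symbols == ("POSTN", "FSCN1")
        assert not log.unmapped

    def test_unmapped_symbol_dropped_and_logged(self):
        m = OrthologMap("mouse", "human", {"Postn": "POSTN"})
        sig = GeneSignature("s", "human", "inflammatory", ("POSTN", "MYSTERY1"))
        out, log = harmonize_symbols(sig, m, "mouse")
        assert out.symbols == ("Postn",)
        assert log.unmapped == ["MYSTERY1"]

    def test_collision_resolved_to_single_canonical_pair(self):
        m = case_convention_map(["Abc1", "ABc1"])  # both map to ABC1
        assert list(m.pairs.values()).count("ABC1") == 1
        assert m.collisions == ["ABc1"]
        with pytest.raises(ValueError):
            OrthologMap("mouse", "human", {"A": "X", "B": "X"})

    def test_target_species_must_be_covered(self):
        m = OrthologMap("mouse", "human", {"Postn": "POSTN"})
        sig = GeneSignature("s", "human", "wound", ("POSTN",))
        with pytest.raises(KeyError):
            harmonize_symbols(sig, m, "zebrafish")

    def test_same_species_is_identity(self):
        m = OrthologMap("mouse", "human", {"Postn": "POSTN"})
        sig = GeneSignature("s", "mouse", "wound", ("Postn",))
        out, _ = harmonize_symbols(sig, m, "mouse")
        assert out is sig


def _de_table(genes_lfc: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame({"log2FC": pd.Series(genes_lfc, dtype=float)})


class TestObbmst:
    def test_two_list_partition_arithmetic(self):
        """Two DE lists of 654 and 583 genes sharing 321 leave 333 and 262 unique."""
        a = _de_table({f"g{i}": 1.0 for i in range(654)})
        b = _de_table({f"g{i}": 1.0 for i in range(321)} | {f"h{i}": 1.0 for i in range(262)})
        ob = build_obbmst(a, b)
        assert len(ob.common) == 321
        assert len(ob.unique_a) == 333
        assert len(ob.unique_b) == 262

    def test_identical_lists_are_fully_common_with_r2_one(self):
        rng = np.random.default_rng(0)
        t = _de_table({f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 1.5, 30))})
        ob = build_obbmst(t, t)
        assert ob.common == frozenset(t.index)
        assert not ob.unique_a and not ob.unique_b
        assert ob.concordance.r_squared == pytest.approx(1.0)

    def test_partition_matches_set_oracle_on_random_lists(self):
        rng = np.random.default_rng(5)
        pool = [f"g{i}" for i in range(120)]
        a = set(rng.choice(pool, 50, replace=False))
        b = set(rng.choice(pool, 50, replace=False))
        ob = build_obbmst(_de_table({g: 1.0 for g in a}), _de_table({g: 1.0 for g in b}))
        assert ob.common == frozenset(a & b)
        assert ob.unique_a == frozenset(a - b)
        assert ob.unique_b == frozenset(b - a)
        assert ob.all_genes == frozenset(a | b)

    def test_direction_disagreement_flagged_not_removed(self):
        a = _de_table({"g1": 1.0, "g2": 2.0})
        b = _de_table({"g1": -1.0, "g2": 2.0, "g3": 0.5})
        ob = build_obbmst(a, b)
        assert "g1" in ob.common
        assert ob.discordant == frozenset({"g1"})


class TestConcordance:
    def test_exact_line_gives_r2_one_positive(self):
        pairs = [(x, x) for x in (-2.0, -1.0, 0.5, 2.0)]
        res = concordance_r2(pairs)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope_sign == 1 and not res.discordant

    def test_anti_correlation_flagged_discordant(self):
        pairs = [(x, -x) for x in (-2.0, -1.0, 0.5, 2.0)]
        res = concordance_r2(pairs)
        assert res.r_squared == pytest.approx(1.0)
        assert res.discordant

    def test_shared_response_with_independent_noise_stays_high(self):
        rng = np.random.default_rng(3)
        true = np.where(rng.random(200) < 0.64, 1.0, -1.0) * np.maximum(
            0.5, rng.normal(1.5, 0.3, 200))
        pairs = list(zip(true + rng.normal(0, 0.25, 200), true + rng.normal(0, 0.25, 200)))
        assert concordance_r2(pairs).r_squared >= 0.9

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_r2([(1.0, 1.0), (2.0, 2.0)])


class TestCurate:
    def _registry(self, members: dict[str, tuple[str, ...]]):
        cats = dict(zip(
            ("desmo", "gastric", "mammary"), DEFAULT_ORDER))
        return [GeneSignature(n, "mouse", cats[n], syms) for n, syms in members.items()]

    def test_disjoint_registry_leaves_core_untouched(self):
        genes = {f"Gene{i}" for i in range(10)}
        registry = self._registry({"desmo": ("X1",), "gastric": ("X2",), "mammary": ("X3",)})
        ledger = curate(genes, registry)
        assert ledger.core == frozenset(genes)
        assert all(not s.removed for s in ledger.stages)

    def test_sequential_subtraction_and_conservation(self):
        genes = {"A", "B", "C", "D", "E"}
        registry = self._registry({
            "desmo": ("A", "B"),
            "gastric": ("B", "C"),  # B already removed at stage 1
            "mammary": ("E", "Z"),
        })
        ledger = curate(genes, registry)
        assert [s.category for s in ledger.stages] == list(DEFAULT_ORDER)
        assert ledger.stages[0].removed == frozenset({"A", "B"})
        assert ledger.stages[1].removed == frozenset({"C"})
        assert ledger.stages[2].removed == frozenset({"E"})
        assert ledger.core == frozenset({"D"})
        assert abs(sum(ledger.fractions().values()) - 1.0) < 1e-9
        ledger.check_conservation()

    def test_component_union_is_order_invariant(self):
        rng = np.random.default_rng(11)
        genes = {f"g{i}" for i in range(60)}
        registry = self._registry({
            "desmo": tuple(rng.choice(sorted(genes), 20, replace=False)),
            "gastric": tuple(rng.choice(sorted(genes), 20, replace=False)),
            "mammary": tuple(rng.choice(sorted(genes), 20, replace=False)),
        })
        l1 = curate(genes, registry, order=DEFAULT_ORDER)
        l2 = curate(genes, registry, order=tuple(reversed(DEFAULT_ORDER)))
        removed1 = frozenset().union(*(s.removed for s in l1.stages))
        removed2 = frozenset().union(*(s.removed for s in l2.stages))
        assert removed1 == removed2
        assert l1.core == l2.core

    def test_unknown_category_order_rejected(self):
        with pytest.raises(ValueError):
            curate({"A"}, [], order=("inflammatory", "bogus", "osteotropic-primary"))

    def test_pipeline_ledger_equals_generator_expectation(
        self, small_reference, small_registry
    ):
        """Exact set identity between the curation of the true DE set and the
        generator's independently recorded expectation."""
        from xenostroma.curation import harmonize_symbols as hs

        ortho = case_convention_map(small_reference.mouse_transcripts)
        registry = []
        for name, cat in small_registry.categories.items():
            sig = GeneSignature(name, "human", cat,
                                tuple(small_registry.signatures[name]))
            registry.append(hs(sig, ortho, "mouse")[0])
        ledger = curate(set(small_reference.truth.de_genes), registry)
        for stage in ledger.stages:
            assert stage.removed == frozenset(small_registry.expected_removed[stage.category])
        assert ledger.core == frozenset(small_registry.expected_core)


class TestVenn:
    def test_identical_sets_have_single_region(self):
        counts = venn_partition({"a": {"x", "y"}, "b": {"x", "y"}})
        assert counts == {("a", "b"): 2}

    def test_disjoint_sets_have_singleton_regions(self):
        counts = venn_partition({k: {f"{k}{i}" for i in range(3)} for k in "abcd"})
        assert set(counts) == {("a",), ("b",), ("c",), ("d",)}
        assert all(v == 3 for v in counts.values())

    def test_region_counts_match_membership_tally_and_sum_to_union(self):
        rng = np.random.default_rng(9)
        pool = [f"s{i}" for i in range(60)]
        sets = {k: set(rng.choice(pool, 30, replace=False)) for k in "abcd"}
        counts = venn_partition(sets)
        union = set().union(*sets.values())
        assert sum(counts.values()) == len(union)
        # brute-force membership-vector tally
        tally: dict[tuple[str, ...], int] = {}
        for el in union:
            key = tuple(sorted(k for k in sets if el in sets[k]))
            tally[key] = tally.get(key, 0) + 1
        assert counts == tally

    def test_arity_limits(self):
        with pytest.raises(ValueError):
            venn_partition({"a": {1}})
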