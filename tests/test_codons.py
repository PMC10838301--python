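"""Codon-set deduction, tandem-run scanning, and gene grouping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m2acodon.codons import (
    AlphabetError,
    AnticodonSpec,
    CodonSet,
    Compartment,
    FrameError,
    GeneCds,
    InternalStopError,
    annotate_genes,
    census_tandem_genes,
    chloroplast_codon_set,
    codon_frequency,
    cytosolic_codon_set,
    deduce_codon_set,
    max_tandem_run,
    normalize_cds,
)
from conftest import S1, S3, S4, random_gene

SENSE = [
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in {"UAA", "UAG", "UGA"}
]


class TestNormalize:
    def test_dna_to_rna_uppercase(self):
        assert normalize_cds("atgCGT").sequence == "AUGCGU"

    def test_frame_violation(self):
        with pytest.raises(FrameError):
            normalize_cds("AUGCG", validate=True)

    def test_internal_stop(self):
        with pytest.raises(InternalStopError):
            normalize_cds("AUGUAAAUG", validate=True)

    def test_terminal_stop_allowed(self):
        assert normalize_cds("AUGUAA", validate=True).sequence == "AUGUAA"

    def test_alphabet_error(self):
        with pytest.raises(AlphabetError):
            normalize_cds("AUGNXA")


class TestDeduce:
    def test_arg_icg_wobble(self):
        spec = AnticodonSpec("Arg", "ACG", Compartment.CYTOSOL,
                             position34_as_inosine=True)
        assert deduce_codon_set([spec]).codons == {"CGU", "CGC", "CGA"}

    def test_gln_uug_wobble(self):
        spec = AnticodonSpec("Gln", "UUG", Compartment.CYTOSOL)
        assert deduce_codon_set([spec]).codons == {"CAA", "CAG"}

    def test_gln_uug_never_reads_his_codons(self):
        spec = AnticodonSpec("Gln", "UUG", Compartment.CYTOSOL)
        for rule in ("wobble",):
            assert not {"CAU", "CAC"} & deduce_codon_set([spec], rule).codons

    def test_cytosolic_default(self):
        cs = cytosolic_codon_set()
        assert cs.codons == {"CAA", "CAG", "CGU", "CGC"}
        assert "CGA" in cs.exclusions

    def test_arg_without_inosine_reads_only_u(self):
        spec = AnticodonSpec("Arg", "ACG", Compartment.CYTOSOL,
                             position34_as_inosine=False)
        assert deduce_codon_set([spec]).codons == {"CGU"}

    def test_chloroplast_wobble_and_two_out_of_three(self):
        wob = chloroplast_codon_set("wobble")
        assert wob.codons == {"CGU", "CGC", "CGA", "CAU", "CAC", "AUG",
                              "UCU", "UCC"}
        tot = chloroplast_codon_set("two_out_of_three")
        assert len(tot.codons) == 16
        assert wob.codons < tot.codons

    def test_unknown_rule_rejected(self):
        spec = AnticodonSpec("Gln", "UUG", Compartment.CYTOSOL)
        with pytest.raises(ValueError):
            deduce_codon_set([spec], rule="superwobble")

    def test_non_m2a_anticodon_rejected(self):
        spec = AnticodonSpec("Gln", "UUG", Compartment.CYTOSOL, m2a37=False)
        with pytest.raises(ValueError):
            deduce_codon_set([spec])


def oracle_max_run(gene, codon_set):
    """Exhaustive contiguous-window scan: the longest window whose codons all
    belong to the set."""
    codons = gene.codons
    best = 0
    for i in range(len(codons)):
        for j in range(i + 1, len(codons) + 1):
            if all(c in codon_set.codons for c in codons[i:j]):
                best = max(best, j - i)
    return best


class TestTandemRun:
    def test_reporter_inserts(self, cyto_set):
        assert max_tandem_run(normalize_cds(S3), cyto_set) == 6
        assert max_tandem_run(normalize_cds(S4), cyto_set) == 0

    def test_matches_bruteforce_oracle(self, cyto_set, rng):
        # enriched alphabet so runs actually occur
        codons = SENSE + list(cyto_set.codons) * 12
        for k in range(50):
            gene = random_gene(rng, 60, codons, f"g{k}")
            assert max_tandem_run(gene, cyto_set) == oracle_max_run(gene, cyto_set)

    def test_empty_set_gives_zero(self):
        empty = CodonSet("none", Compartment.CYTOSOL, frozenset())
        assert max_tandem_run(normalize_cds(S3), empty) == 0

    def test_monotone_under_set_enlargement(self, cyto_set, rng):
        larger = CodonSet(
            "larger", Compartment.CYTOSOL,
            frozenset(cyto_set.codons | {"GUG", "ACA"}),
        )
        for k in range(30):
            gene = random_gene(rng, 80, SENSE + list(larger.codons) * 8, f"g{k}")
            assert max_tandem_run(gene, cyto_set) <= max_tandem_run(gene, larger)

    def test_frequency_permutation_invariant_run_is_not(self, cyto_set, rng):
        gene = normalize_cds(S3 + S4)
        codons = gene.codons
        # a permutation that breaks the tandem block apart
        perm = [codons[i] for i in [0, 6, 1, 7, 2, 8, 3, 9, 4, 5]]
        permuted = GeneCds("perm", "".join(perm))
        assert codon_frequency(gene, cyto_set) == pytest.approx(
            codon_frequency(permuted, cyto_set)
        )
        assert max_tandem_run(permuted, cyto_set) < max_tandem_run(gene, cyto_set)


class TestFrequency:
    def test_all_in_set(self, cyto_set):
        assert codon_frequency(normalize_cds(S1), cyto_set) == 1.0

    def test_none_in_set(self, cyto_set):
        assert codon_frequency(normalize_cds(S4), cyto_set) == 0.0

    def test_half(self, cyto_set):
        assert codon_frequency(normalize_cds(S1 + S4), cyto_set) == 0.5

    def test_terminal_stop_excluded_by_default(self, cyto_set):
        gene = normalize_cds(S1 + "TAA")
        assert codon_frequency(gene, cyto_set) == 1.0
        assert codon_frequency(gene, cyto_set, exclude_terminal_stop=False) \
            == pytest.approx(4 / 5)

    def test_empty_gene_rejected(self, cyto_set):
        with pytest.raises(ValueError):
            codon_frequency(GeneCds("x", ""), cyto_set)


class TestAnnotate:
    def make_population(self, cyto_set, rng, n=200):
        codons = SENSE + list(cyto_set.codons) * 6
        return [random_gene(rng, 100, codons, f"g{k}") for k in range(n)]

    def test_partition_exhaustive_and_exclusive(self, cyto_set, rng):
        genes = self.make_population(cyto_set, rng)
        ann = annotate_genes(genes, cyto_set)
        assert len(ann) == len(genes)
        assert {a.group for a in ann} <= set("ABCD")
        for a in ann:
            tandem = a.max_tandem_run >= 3
            expected = {(False, False): "A", (True, False): "B",
                        (False, True): "C", (True, True): "D"}[(tandem, a.freq_high)]
            assert a.group == expected

    def test_bin_labels(self, cyto_set, rng):
        genes = self.make_population(cyto_set, rng)
        for a in annotate_genes(genes, cyto_set):
            if a.max_tandem_run < 3:
                assert a.tandem_bin == "others"
            elif a.max_tandem_run >= 5:
                assert a.tandem_bin == "run5plus"
            else:
                assert a.tandem_bin == f"run{a.max_tandem_run}"

    def test_small_population_warns(self, cyto_set, rng):
        genes = self.make_population(cyto_set, rng, n=5)
        with pytest.warns(UserWarning):
            annotate_genes(genes, cyto_set)

    def test_high_frequency_fraction(self, cyto_set, rng):
        genes = self.make_population(cyto_set, rng, n=500)
        ann = annotate_genes(genes, cyto_set, freq_quantile=0.90)
        n_high = sum(a.freq_high for a in ann)
        # inclusive-at-boundary decile; ties can only enlarge the top bin
        assert n_high >= math.ceil(0.10 * len(genes))
        assert n_high <= 0.2 * len(genes)


class TestCensus:
    def test_threshold_and_sorting(self, cyto_set):
        genes = [
            normalize_cds("GUG" * 5 + "CAA" * 2 + "GUG", gene_id="run2"),
            normalize_cds("GUG" + "CAA" * 3 + "GUG" * 4, gene_id="run3"),
            normalize_cds("CAGCAACGUCAA" + "GUG" * 4, gene_id="run4"),
        ]
        table = census_tandem_genes(genes, cyto_set, min_run=3)
        assert list(table["gene_id"]) == ["run4", "run3"]
        assert list(table["max_tandem_run"]) == [4, 3]
        assert len(census_tandem_genes(genes, cyto_set, min_run=5)) == 0


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGTU", min_size=3, max_size=60))
def test_normalize_is_idempotent(seq):
    once = normalize_cds(seq).sequence
    assert normalize_cds(once).sequence == once
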