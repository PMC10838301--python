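"""Deduce m2A-tRNA-dependent codon sets and annotate CDSs by tandem-codon structure.

The biological question: certain tRNAs carry C2-methyladenosine at position 37
(m2A37), the nucleotide 3' of the anticodon. Codons decoded by those tRNAs —
"m2A-tRNA-dependent codons" — are translated less efficiently when the
modification is lost, and the effect concentrates on genes that carry *runs* of
such codons in tandem. This module derives the codon sets from anticodon
identity (wobble or two-out-of-three pairing), scans coding sequences for
tandem runs and overall codon frequency, and bins genes into the four groups
used for translation-efficiency comparisons:

    A: no tandem run (< 3), low codon frequency
    B: tandem run >= 3, low codon frequency
    C: no tandem run, high codon frequency (top decile)
    D: tandem run >= 3, high codon frequency

Coordinates are 1-based codon indices; scanning is strictly in the annotated
reading frame starting at the first base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Compartment",
    "AnticodonSpec",
    "CodonSet",
    "GeneCds",
    "GeneCodonAnnotation",
    "AlphabetError",
    "FrameError",
    "InternalStopError",
    "normalize_cds",
    "deduce_codon_set",
    "cytosolic_codon_set",
    "chloroplast_codon_set",
    "max_tandem_run",
    "codon_frequency",
    "annotate_genes",
    "census_tandem_genes",
    "CYTOSOLIC_M2A_ANTICODONS",
    "CHLOROPLAST_M2A_ANTICODONS",
]

RNA_ALPHABET = frozenset("ACGU")
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

# Wobble pairing at anticodon position 34 against codon position 3.
# Inosine (I, deaminated A) reads U, C and A; unmodified A reads only U.
WOBBLE_PAIRS: Mapping[str, frozenset[str]] = {
    "I": frozenset("UCA"),
    "G": frozenset("UC"),
    "U": frozenset("AG"),
    "C": frozenset("G"),
    "A": frozenset("U"),
}


class Compartment(str, Enum):
    CYTOSOL = "cytosol"
    CHLOROPLAST = "chloroplast"


class AlphabetError(ValueError):
    """A character outside {A,C,G,T,U} (case-insensitive) was encountered."""


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class InternalStopError(ValueError):
    """A stop codon occurs before the final codon."""


@dataclass(frozen=True)
class AnticodonSpec:
    """One m2A37-modified tRNA identified by its anticodon.

    ``anticodon`` is written 5'->3' (positions 34, 35, 36). When
    ``position34_as_inosine`` is set, an A at position 34 is read as inosine
    for wobble expansion.
    """

    amino_acid: str
    anticodon: str
    compartment: Compartment
    position34_as_inosine: bool = False
    m2a37: bool = True

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or set(self.anticodon) - RNA_ALPHABET:
            raise ValueError(
                f"anticodon must be a 3-mer over A/C/G/U, got {self.anticodon!r}"
            )


@dataclass(frozen=True)
class CodonSet:
    """A named set of codons with a record of how it was deduced."""

    name: str
    compartment: Compartment
    codons: frozenset[str]
    rule: str = "explicit"
    exclusions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.codons:
            if len(c) != 3 or set(c) - RNA_ALPHABET:
                raise ValueError(f"invalid codon {c!r}")
        overlap = set(self.codons) & set(self.exclusions)
        if overlap:
            raise ValueError(f"excluded codons still present: {sorted(overlap)}")

    def __contains__(self, codon: str) -> bool:
        return codon in self.codons

    def to_manifest(self) -> dict:
        """JSON-serializable record of the set and its provenance."""
        return {
            "name": self.name,
            "compartment": self.compartment.value,
            "codons": sorted(self.codons),
            "rule": self.rule,
            "exclusions": dict(self.exclusions),
        }


@dataclass(frozen=True)
class GeneCds:
    """An in-frame coding sequence, RNA alphabet after normalization."""

    gene_id: str
    sequence: str
    compartment: Compartment = Compartment.CYTOSOL

    @property
    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


@dataclass(frozen=True)
class GeneCodonAnnotation:
    gene_id: str
    max_tandem_run: int
    codon_frequency: float
    tandem_bin: str  # others | run3 | run4 | run5plus
    freq_high: bool
    group: str  # A | B | C | D


def normalize_cds(
    raw_sequence: str,
    gene_id: str = "",
    compartment: Compartment = Compartment.CYTOSOL,
    validate: bool = False,
) -> GeneCds:
    """Uppercase, convert T->U, and optionally validate frame and stops.

    DNA input is accepted because reporter inserts are specified as DNA while
    decoding rules operate on the mRNA sense strand.
    """
    if not raw_sequence:
        raise AlphabetError("empty sequence")
    seq = raw_sequence.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    if validate:
        if len(seq) % 3 != 0:
            raise FrameError(f"length {len(seq)} not divisible by 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        for i, codon in enumerate(codons[:-1]):
            if codon in STOP_CODONS:
                raise InternalStopError(f"stop codon {codon} at codon {i + 1}")
    return GeneCds(gene_id=gene_id, sequence=seq, compartment=compartment)


def _codons_for_anticodon(spec: AnticodonSpec, rule: str) -> set[str]:
    # Codon position 1 pairs anticodon position 36, position 2 pairs 35,
    # position 3 pairs the wobble position 34.
    pos34, pos35, pos36 = spec.anticodon
    prefix = _COMPLEMENT[pos36] + _COMPLEMENT[pos35]
    if rule == "two_out_of_three":
        thirds: Iterable[str] = "ACGU"
    else:
        wobble_base = "I" if (pos34 == "A" and spec.position34_as_inosine) else pos34
        if wobble_base not in WOBBLE_PAIRS:
            raise ValueError(f"no wobble pairing rule for base {wobble_base!r}")
        thirds = WOBBLE_PAIRS[wobble_base]
    return {prefix + third for third in thirds}


def deduce_codon_set(
    anticodons: Sequence[AnticodonSpec],
    rule: str = "wobble",
    exclusions: Mapping[str, str] | None = None,
    name: str | None = None,
) -> CodonSet:
    """Deduce the codon repertoire of a collection of m2A37 tRNAs.

    ``rule='wobble'`` expands codon position 3 by the anticodon-34 pairing
    table; ``rule='two_out_of_three'`` lets the first two codon positions
    alone determine decoding, so position 3 expands to all four bases.
    Exclusions (codon -> reason) are removed afterwards and kept on record —
    e.g. CGA, which the inosine-34 arginine tRNA fails to decode when m2A37
    is present.
    """
    if rule not in ("wobble", "two_out_of_three"):
        raise ValueError(f"unknown rule {rule!r}")
    if not anticodons:
        raise ValueError("at least one anticodon is required")
    non_m2a = [a.anticodon for a in anticodons if not a.m2a37]
    if non_m2a:
        raise ValueError(f"anticodons without m2A37 supplied: {non_m2a}")
    compartments = {a.compartment for a in anticodons}
    if len(compartments) > 1:
        raise ValueError("anticodons span multiple compartments")
    exclusions = dict(exclusions or {})
    codons: set[str] = set()
    for spec in anticodons:
        codons |= _codons_for_anticodon(spec, rule)
    codons -= set(exclusions)
    return CodonSet(
        name=name or f"{rule}_set",
        compartment=next(iter(compartments)),
        codons=frozenset(codons),
        rule=rule,
        exclusions=exclusions,
    )


#: The two cytosolic m2A37 tRNAs: arginine with anticodon ACG (A34 read as
#: inosine) and glutamine with anticodon UUG.
CYTOSOLIC_M2A_ANTICODONS: tuple[AnticodonSpec, ...] = (
    AnticodonSpec("Arg", "ACG", Compartment.CYTOSOL, position34_as_inosine=True),
    AnticodonSpec("Gln", "UUG", Compartment.CYTOSOL),
)

#: The four m2A37-modified chloroplast tRNAs.
CHLOROPLAST_M2A_ANTICODONS: tuple[AnticodonSpec, ...] = (
    AnticodonSpec("Arg", "ACG", Compartment.CHLOROPLAST, position34_as_inosine=True),
    AnticodonSpec("His", "GUG", Compartment.CHLOROPLAST),
    AnticodonSpec("Met", "CAU", Compartment.CHLOROPLAST),  # elongator Met
    AnticodonSpec("Ser", "GGA", Compartment.CHLOROPLAST),
)


def cytosolic_codon_set() -> CodonSet:
    """The default cytosolic set {CAA, CAG, CGU, CGC}.

    Wobble expansion of Arg-ACG(I34) and Gln-UUG, with CGA removed: reporter
    assays show CGA decoding is unaffected by m2A loss, consistent with CGA
    being read by a different arginine isoacceptor.
    """
    return deduce_codon_set(
        CYTOSOLIC_M2A_ANTICODONS,
        rule="wobble",
        exclusions={"CGA": "not decoded by the m2A-modified Arg-ICG tRNA"},
        name="cytosolic_m2A_dependent",
    )


def chloroplast_codon_set(rule: str = "wobble") -> CodonSet:
    """Chloroplast m2A-dependent codons under ``wobble`` or ``two_out_of_three``.

    The exact set used for the published chloroplast census is not pinned by
    the main text, so both rule outputs are exposed; callers choose.
    """
    return deduce_codon_set(
        CHLOROPLAST_M2A_ANTICODONS,
        rule=rule,
        name=f"chloroplast_m2A_dependent_{rule}",
    )


def max_tandem_run(gene: GeneCds, codon_set: CodonSet) -> int:
    """Length in codons of the longest run of consecutive in-frame set codons."""
    best = run = 0
    members = codon_set.codons
    for codon in gene.codons:
        if codon in members:
            run += 1
            if run > best:
                best = run
        else:
            run = 0
    return best


def codon_frequency(
    gene: GeneCds, codon_set: CodonSet, exclude_terminal_stop: bool = True
) -> float:
    """Fraction of in-frame codons belonging to the set.

    The terminal stop codon is excluded from the denominator by default since
    it is not decoded by an elongator tRNA.
    """
    codons = gene.codons
    if exclude_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise ValueError(f"gene {gene.gene_id!r} has no codons to count")
    hits = sum(1 for c in codons if c in codon_set.codons)
    return hits / len(codons)


def _tandem_bin(run: int, bins: Sequence[int]) -> str:
    """Map a run length to a bin label: others (< bins[0]), exact bins, and
    an open-ended top bin (``run{max}plus``)."""
    if run < bins[0]:
        return "others"
    top = bins[-1]
    if run >= top:
        return f"run{top}plus"
    return f"run{run}"


def annotate_genes(
    genes: Sequence[GeneCds],
    codon_set: CodonSet,
    freq_quantile: float = 0.90,
    bins: Sequence[int] = (3, 4, 5),
    exclude_terminal_stop: bool = True,
) -> list[GeneCodonAnnotation]:
    """Annotate a gene population with tandem bins, frequency decile and group.

    ``freq_high`` is population-relative: frequency >= the empirical
    ``freq_quantile`` over the supplied genes (ties at the boundary count as
    high). Group A/B/C/D crosses (tandem run >= bins[0]) with freq_high.
    """
    if not genes:
        raise ValueError("empty gene population")
    if not 0 < freq_quantile < 1:
        raise ValueError("freq_quantile must be in (0, 1)")
    if len(genes) < 10:
        warnings.warn(
            f"quantile grouping over only {len(genes)} genes is unstable",
            stacklevel=2,
        )
    runs = [max_tandem_run(g, codon_set) for g in genes]
    freqs = [
        codon_frequency(g, codon_set, exclude_terminal_stop=exclude_terminal_stop)
        for g in genes
    ]
    threshold = float(np.quantile(freqs, freq_quantile))
    out = []
    for gene, run, freq in zip(genes, runs, freqs):
        high = freq >= threshold
        tandem = run >= bins[0]
        group = {(False, False): "A", (True, False): "B",
                 (False, True): "C", (True, True): "D"}[(tandem, high)]
        out.append(
            GeneCodonAnnotation(
                gene_id=gene.gene_id,
                max_tandem_run=run,
                codon_frequency=freq,
                tandem_bin=_tandem_bin(run, bins),
                freq_high=high,
                group=group,
            )
        )
    return out


def annotations_to_frame(annotations: Sequence[GeneCodonAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in annotations],
            "max_tandem_run": [a.max_tandem_run for a in annotations],
            "codon_frequency": [a.codon_frequency for a in annotations],
            "tandem_bin": [a.tandem_bin for a in annotations],
            "freq_high": [a.freq_high for a in annotations],
            "group": [a.group for a in annotations],
        }
    )


def census_tandem_genes(
    genes: Sequence[GeneCds], codon_set: CodonSet, min_run: int
) -> pd.DataFrame:
    """Table of genes whose max tandem run reaches ``min_run``.

    Sorted by run descending, then gene_id — the form used for the
    chloroplast tandem-gene census.
    """
    rows = [
        (g.gene_id, max_tandem_run(g, codon_set))
        for g in genes
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "max_tandem_run"])
    df = df[df["max_tandem_run"] >= min_run]
    return df.sort_values(
        ["max_tandem_run", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
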