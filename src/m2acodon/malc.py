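"""Malc: nuclease-protection probe design and single-nucleotide modification
quantification.

The assay localizes and quantifies a base modification (here m2A) at a
candidate adenosine position X of a target RNA. Three biotinylated antisense
DNA probes share a 5' end (covering the target up to a 3' boundary E) and
step back one nucleotide at a time at their 3' end, so that after
single-strand-specific nuclease digestion the protected fragments F_{X-1},
F_X, F_{X+1} have 5' boundaries X-1, X, X+1 and are strictly nested:

    F_{X+1}  subset of  F_X  subset of  F_{X-1}

The modification signal appears in exactly the fragments whose span contains
X, which pins the position. The modified fraction is recovered from the
measured modified/unmodified mole ratio R of a fragment containing X:

    R_m = A * R / (1 + R)

where A is the count of adenosines in the fragment that report as A when
unmodified (stoichiometrically modified positions such as m1A58 of cytosolic
tRNA are excluded, since they never contribute to the A signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "TargetRna",
    "Probe",
    "ProbeSet",
    "ProtectedFragment",
    "MalcMeasurement",
    "MalcResult",
    "design_probes",
    "predict_fragment",
    "modification_fraction",
    "localize",
    "quantify",
    "DEFAULT_LOD",
]

_RNA_TO_DNA_ANTISENSE = {"A": "T", "C": "G", "G": "C", "U": "A"}

#: Default limit of detection on the measured mole ratio R.
DEFAULT_LOD = 1e-3


@dataclass(frozen=True)
class TargetRna:
    """Target RNA with a candidate modified adenosine at 1-based position X.

    ``known_non_a_positions`` lists adenosine positions that never report as
    unmodified A in digestion (e.g. the stoichiometric m1A58 of cytosolic
    tRNA) and are excluded from effective A counts.
    """

    rna_id: str
    sequence: str
    position: int  # X, 1-based
    known_non_a_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seq = self.sequence
        if set(seq) - set("ACGU"):
            raise ValueError("target sequence must be RNA over A/C/G/U")
        if not 1 <= self.position <= len(seq):
            raise ValueError(f"position {self.position} outside 1..{len(seq)}")
        if seq[self.position - 1] != "A":
            raise ValueError(
                f"base at position {self.position} is {seq[self.position - 1]}, not A"
            )
        for p in self.known_non_a_positions:
            if not 1 <= p <= len(seq) or seq[p - 1] != "A":
                raise ValueError(f"known non-A-reporting position {p} is not an A")


@dataclass(frozen=True)
class Probe:
    """Antisense DNA probe protecting target span [start, end], 1-based."""

    name: str
    start: int  # fragment 5' boundary n
    end: int  # shared 3' boundary E
    sequence: str  # DNA, written 5'->3'


@dataclass(frozen=True)
class ProbeSet:
    target: TargetRna
    end: int  # E
    probes: tuple[Probe, Probe, Probe]  # F_{X-1}, F_X, F_{X+1} order

    def __iter__(self):
        return iter(self.probes)


@dataclass(frozen=True)
class ProtectedFragment:
    """Protected fragment F_n spanning [start, end] on the target."""

    name: str
    start: int
    end: int
    sequence: str  # RNA, target sense
    effective_a: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class MalcMeasurement:
    fragment: str  # e.g. "F_X-1"
    ratio: float  # measured modified/A mole ratio R
    detected: bool = True

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("mole ratio R must be non-negative")

    @property
    def effective_ratio(self) -> float:
        return self.ratio if self.detected else 0.0


@dataclass(frozen=True)
class MalcResult:
    rna_id: str
    called_position: int | None
    fraction: float | None  # R_m
    quantification_fragment: str | None
    status: str  # called | no_modification | inconclusive | inconsistent


def fragment_name(target: TargetRna, start: int) -> str:
    offset = start - target.position
    if offset == 0:
        return "F_X"
    return f"F_X{offset:+d}"


def _antisense_dna(rna: str) -> str:
    """Reverse-complement into DNA, 5'->3'."""
    return "".join(_RNA_TO_DNA_ANTISENSE[b] for b in reversed(rna))


def design_probes(target: TargetRna, end: int | None = None) -> ProbeSet:
    """Design the probe trio for position X with shared protected 3' end E.

    Probes are the antisense DNA of target[n..E] for n in {X-1, X, X+1};
    they share their 5' end (complementary to E) and differ by one
    nucleotide at the 3' end. Default E = X + 8, leaving a 3' flank of eight
    protected nucleotides beyond X.
    """
    x = target.position
    if end is None:
        end = x + 8
    if x - 1 < 1:
        raise ValueError("position X is at the 5' edge; probe X-1 impossible")
    if end <= x + 1:
        raise ValueError(f"protected 3' boundary E={end} must exceed X+1={x + 1}")
    if end > len(target.sequence):
        raise ValueError(f"E={end} beyond target length {len(target.sequence)}")
    probes = tuple(
        Probe(
            name=f"Probe_{fragment_name(target, n)[2:]}",
            start=n,
            end=end,
            sequence=_antisense_dna(target.sequence[n - 1 : end]),
        )
        for n in (x - 1, x, x + 1)
    )
    return ProbeSet(target=target, end=end, probes=probes)


def predict_fragment(target: TargetRna, start: int, end: int) -> ProtectedFragment:
    """Protected fragment [start, end] with its effective adenosine count.

    ``effective_a`` counts A positions in the span minus the target's known
    non-A-reporting positions. The candidate position X itself counts: when
    unmodified it reports as A, when modified as the modified nucleoside.
    """
    if not 1 <= start <= end <= len(target.sequence):
        raise ValueError(f"span [{start}, {end}] outside target")
    seq = target.sequence[start - 1 : end]
    eff = sum(
        1
        for i, b in enumerate(seq, start=start)
        if b == "A" and i not in target.known_non_a_positions
    )
    return ProtectedFragment(
        name=fragment_name(target, start),
        start=start,
        end=end,
        sequence=seq,
        effective_a=eff,
    )


def predict_fragments(probe_set: ProbeSet) -> list[ProtectedFragment]:
    return [
        predict_fragment(probe_set.target, p.start, p.end) for p in probe_set.probes
    ]


def modification_fraction(effective_a: int, ratio: float) -> float:
    """Invert the mole ratio into the modified fraction: R_m = A*R/(1+R).

    One fragment molecule with modified fraction f at position X contributes
    f moles of modified nucleoside and (A - f) moles of A, so the measured
    ratio is R = f / (A - f); this inverts it. Noise can push R above the
    algebraic bound R = 1/(A-1); the result is then clipped to 1 with a
    warning rather than rejected.
    """
    if effective_a < 0:
        raise ValueError("effective_a must be non-negative")
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if effective_a == 0:
        if ratio > 0:
            raise ValueError(
                "measured modification signal from a fragment with no reporting A"
            )
        return 0.0
    if ratio == float("inf"):  # fully modified single-A fragment: R -> inf
        rm = float(effective_a)
    else:
        rm = effective_a * ratio / (1.0 + ratio)
    if rm > 1.0:
        warnings.warn(
            f"ratio {ratio:.4g} implies fraction {rm:.4g} > 1; clipping",
            stacklevel=2,
        )
        rm = 1.0
    return rm


def localize(
    target: TargetRna,
    measurements: Mapping[str, MalcMeasurement] | Sequence[MalcMeasurement],
    lod: float = DEFAULT_LOD,
) -> MalcResult:
    """Call the modified position from the nested detection pattern.

    The fragments are nested, so a consistent signal pattern is monotone
    along F_{X-1}, F_X, F_{X+1}:

        (det, det, not) -> modification at X
        (det, not, not) -> modification at X-1
        (not, not, not) -> none in the window
        (det, det, det) -> inconclusive (modification 3' of X+1 or beyond window)

    Any pattern where an inner fragment shows signal that an enclosing one
    lacks is physically impossible and flagged inconsistent. The call is a
    pure function of the detection pattern; R magnitudes are ignored here.
    """
    meas = _as_mapping(measurements)
    required = ["F_X-1", "F_X", "F_X+1"]
    missing = [n for n in required if n not in meas]
    if missing:
        raise ValueError(f"measurements missing for fragments: {missing}")
    det = [
        meas[n].detected and meas[n].effective_ratio > lod for n in required
    ]
    x = target.position
    if det == [True, True, False]:
        return MalcResult(target.rna_id, x, None, None, "called")
    if det == [True, False, False]:
        return MalcResult(target.rna_id, x - 1, None, None, "called")
    if det == [False, False, False]:
        return MalcResult(target.rna_id, None, None, None, "no_modification")
    # signal in an inner fragment without the enclosing one -> impossible
    if (det[1] and not det[0]) or (det[2] and not det[1]):
        return MalcResult(target.rna_id, None, None, None, "inconsistent")
    return MalcResult(target.rna_id, None, None, None, "inconclusive")


def quantify(
    target: TargetRna,
    measurements: Mapping[str, MalcMeasurement] | Sequence[MalcMeasurement],
    fragment_choice: str = "F_X-1",
    end: int | None = None,
    lod: float = DEFAULT_LOD,
) -> MalcResult:
    """Estimate the modified fraction from a chosen fragment's measurement.

    Defaults to F_{X-1}; overridable to F_{X-2} or F_{X-3} for targets whose
    F_X fragment carries an A/U-rich end, where residual double-strand
    nuclease activity trims the fragment and biases the ratio low.
    """
    allowed = {"F_X-1", "F_X-2", "F_X-3", "F_X"}
    if fragment_choice not in allowed:
        raise ValueError(f"fragment_choice must be one of {sorted(allowed)}")
    meas = _as_mapping(measurements)
    if fragment_choice not in meas:
        raise KeyError(f"no measurement for {fragment_choice}")
    m = meas[fragment_choice]
    if not m.detected or m.effective_ratio <= lod:
        raise ValueError(f"chosen fragment {fragment_choice} not detected")
    x = target.position
    offset = 0 if fragment_choice == "F_X" else int(fragment_choice.split("X")[1])
    start = x + offset
    if end is None:
        end = x + 8
    frag = predict_fragment(target, start, end)
    loc = localize(target, meas, lod=lod) if all(
        n in meas for n in ("F_X-1", "F_X", "F_X+1")
    ) else None
    rm = modification_fraction(frag.effective_a, m.effective_ratio)
    return MalcResult(
        rna_id=target.rna_id,
        called_position=loc.called_position if loc else x,
        fraction=rm,
        quantification_fragment=fragment_choice,
        status=loc.status if loc else "called",
    )


def _as_mapping(
    measurements: Mapping[str, MalcMeasurement] | Sequence[MalcMeasurement],
) -> dict[str, MalcMeasurement]:
    if isinstance(measurements, Mapping):
        return dict(measurements)
    return {m.fragment: m for m in measurements}
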