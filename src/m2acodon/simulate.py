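"""Synthetic data with ground truth for the codon/TE/Malc pipeline.

Emulates the statistical structure of the study design the pipeline consumes:
a nuclear gene population with controlled tandem-codon architecture, FPKM
tables for a two-genotype x two-replicate x {mRNA input, ribosome footprint}
design with codon-dependent translation-efficiency effects, and noisy
nuclease-protection (Malc) mole-ratio measurements. Every routine is a pure
function of (config, seed).

The expression model is multiplicative on the FPKM scale: per-gene baseline
log10 FPKM ~ Normal(1, 0.5); footprint FPKM = input x TE x noise; in the
mutant the TE of a gene is scaled by a per-tandem-bin multiplier delta in
(0, 1] (delta = 1: no effect; delta = 0.5: twofold TE loss). Noise is
log-normal with median 1 and configurable CV, so the median observed TE fold
change of a bin equals its delta. A negative-binomial count-level mode is
available for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import (
    Compartment,
    CodonSet,
    GeneCds,
    STOP_CODONS,
    codon_frequency,
    cytosolic_codon_set,
    max_tandem_run,
)
from .malc import DEFAULT_LOD, TargetRna, fragment_name, predict_fragment
from .te import ExpressionTable

__all__ = ["SimConfig", "simulate_transcriptome", "simulate_expression",
           "simulate_malc"]

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generators.

    ``tandem_design`` maps designed run length -> number of genes (run 0
    means no implanted run; background never reaches run 3 by construction).
    ``delta`` maps tandem bin label (others/run3/run4/run5plus) -> mutant TE
    multiplier.
    """

    n_genes: int = 1000
    length_codons: tuple[int, int] = (150, 450)  # uniform range, inclusive
    tandem_design: Mapping[int, int] = field(
        default_factory=lambda: {0: 700, 3: 100, 4: 100, 6: 100}
    )
    set_codon_proportion: tuple[float, float] = (0.02, 0.25)  # per-gene uniform
    baseline_log10_fpkm: tuple[float, float] = (1.0, 0.5)  # mean, sd
    te_log10: tuple[float, float] = (0.0, 0.15)  # baseline wild-type TE
    delta: Mapping[str, float] = field(
        default_factory=lambda: {"others": 1.0, "run3": 1.0, "run4": 1.0,
                                 "run5plus": 1.0}
    )
    noise_cv: float = 0.2
    noise_model: str = "lognormal"  # or "negative_binomial"
    nb_dispersion: float = 0.05
    nb_library_size: float = 2e7
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.tandem_design.values()) != self.n_genes:
            raise ValueError(
                "tandem_design gene counts must sum to n_genes "
                f"({sum(self.tandem_design.values())} != {self.n_genes})"
            )
        for d in self.delta.values():
            if not 0 < d <= 1:
                raise ValueError("delta multipliers must lie in (0, 1]")
        if self.noise_model not in ("lognormal", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.replicates < 2:
            raise ValueError("at least two replicates are required for the SNR filter")


def _bin_label(run: int) -> str:
    if run < 3:
        return "others"
    if run >= 5:
        return "run5plus"
    return f"run{run}"


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _sample_codons(
    rng: np.random.Generator,
    n: int,
    set_codons: Sequence[str],
    other_codons: Sequence[str],
    p_set: float,
    max_background_run: int = 2,
    initial_run: int = 0,
) -> list[str]:
    """Background codons with set-codon proportion ~p_set, runs capped.

    Whenever ``max_background_run`` consecutive set codons have been laid
    down, the next draw is forced outside the set, so background never forms
    a tandem run of 3 — implanted runs alone determine the max run.
    ``initial_run`` accounts for set codons immediately upstream (the AUG
    start codon belongs to some chloroplast sets).
    """
    out: list[str] = []
    run = initial_run
    for _ in range(n):
        if run >= max_background_run:
            out.append(other_codons[rng.integers(len(other_codons))])
            run = 0
        elif rng.random() < p_set:
            out.append(set_codons[rng.integers(len(set_codons))])
            run += 1
        else:
            out.append(other_codons[rng.integers(len(other_codons))])
            run = 0
    return out


def simulate_transcriptome(
    config: SimConfig, codon_set: CodonSet | None = None
) -> tuple[list[GeneCds], pd.DataFrame]:
    """Generate a gene population with designed tandem-run structure.

    Each gene starts with AUG, ends with a stop, and has no internal stop.
    A designed run of length L >= 3 of set codons is implanted at a random
    in-frame position with non-set guard codons at both flanks, so the
    realized max tandem run equals L exactly. Returns the genes and a truth
    table (gene_id, designed_run, max_tandem_run, tandem_bin,
    codon_frequency, baseline_fpkm, te_wildtype, delta), with the scanner
    columns recomputed from the emitted sequences.
    """
    if codon_set is None:
        codon_set = cytosolic_codon_set()
    rng = np.random.default_rng(config.seed)
    set_codons = sorted(codon_set.codons)
    other_codons = [c for c in SENSE_CODONS if c not in codon_set.codons]
    lo, hi = config.length_codons
    p_lo, p_hi = config.set_codon_proportion

    designs: list[int] = []
    for run_len, count in sorted(config.tandem_design.items()):
        designs.extend([run_len] * count)
    rng.shuffle(designs)

    genes: list[GeneCds] = []
    rows = []
    width = len(str(config.n_genes))
    for i, run_len in enumerate(designs):
        n_body = int(rng.integers(lo, hi + 1))  # codons between AUG and stop
        if run_len and run_len + 2 > n_body:
            raise ValueError(
                f"designed run {run_len} (+2 guards) exceeds gene body {n_body}"
            )
        p_set = float(rng.uniform(p_lo, p_hi))
        body = _sample_codons(
            rng, n_body, set_codons, other_codons, p_set,
            initial_run=1 if "AUG" in codon_set.codons else 0,
        )
        if run_len:
            pos = int(rng.integers(0, n_body - run_len - 1))  # leave room for guards
            implant = [set_codons[rng.integers(len(set_codons))] for _ in range(run_len)]
            guard_l = other_codons[rng.integers(len(other_codons))]
            guard_r = other_codons[rng.integers(len(other_codons))]
            body = body[:pos] + [guard_l] + implant + [guard_r] + body[pos:]
            body = body[: n_body + run_len + 2]
        stop = ("UAA", "UAG", "UGA")[rng.integers(3)]
        seq = "AUG" + "".join(body) + stop
        gene = GeneCds(
            gene_id=f"SYNG{i:0{width}d}", sequence=seq, compartment=codon_set.compartment
        )
        genes.append(gene)
        run = max_tandem_run(gene, codon_set)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "designed_run": run_len,
                "max_tandem_run": run,
                "tandem_bin": _bin_label(run),
                "codon_frequency": codon_frequency(gene, codon_set),
                "baseline_fpkm": float(
                    10.0
                    ** rng.normal(config.baseline_log10_fpkm[0],
                                  config.baseline_log10_fpkm[1])
                ),
                "te_wildtype": float(
                    10.0 ** rng.normal(config.te_log10[0], config.te_log10[1])
                ),
            }
        )
    truth = pd.DataFrame(rows).set_index("gene_id")
    truth["delta"] = truth["tandem_bin"].map(dict(config.delta)).astype(float)
    if truth["delta"].isna().any():
        raise ValueError("config.delta missing a tandem bin present in the design")
    return genes, truth


def _noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(shape)
    return rng.lognormal(mean=0.0, sigma=_lognormal_sigma(cv), size=shape)


def _nb_fpkm(
    rng: np.random.Generator, fpkm: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Count-level mode: NB counts at mean proportional to FPKM, back to FPKM."""
    scale = config.nb_library_size / 1e6  # per-kb transcript, 1-kb convention
    mu = fpkm * scale
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(n=r, p=r / (r + np.maximum(mu, 1e-12)))
    return counts / scale


def simulate_expression(
    truth: pd.DataFrame, config: SimConfig
) -> ExpressionTable:
    """FPKM tables for the two-condition, replicated input/footprint design.

    Input FPKM = baseline x noise per replicate; footprint FPKM = the same
    replicate's input signal x condition TE x noise, with mutant TE =
    wild-type TE x delta(bin). Column names carry assay, condition and
    replicate; the sample sheet is built alongside.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(truth)
    baseline = truth["baseline_fpkm"].to_numpy()
    te_wt = truth["te_wildtype"].to_numpy()
    delta = truth["delta"].to_numpy()
    te = {"wildtype": te_wt, "mutant": te_wt * delta}

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for cond in ("wildtype", "mutant"):
        for rep in range(1, config.replicates + 1):
            inp = baseline * _noise(rng, n, config.noise_cv)
            rpf = inp * te[cond] * _noise(rng, n, config.noise_cv)
            if config.noise_model == "negative_binomial":
                inp = _nb_fpkm(rng, inp, config)
                rpf = _nb_fpkm(rng, rpf, config)
            for assay, vals in (("input_mrna", inp), ("ribo_footprint", rpf)):
                name = f"{assay}_{cond}_rep{rep}"
                columns[name] = vals
                sheet_rows.append(
                    {"sample": name, "assay": assay, "condition": cond,
                     "replicate": rep}
                )
    values = pd.DataFrame(columns, index=truth.index)
    return ExpressionTable(values, pd.DataFrame(sheet_rows))


def simulate_malc(
    targets: Sequence[tuple[TargetRna, float]],
    noise_cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    end: int | None = None,
    end_bias: float = 1.0,
    lod: float = DEFAULT_LOD,
    fragments: Sequence[int] = (-1, 0, 1),
) -> pd.DataFrame:
    """Noisy Malc mole-ratio measurements for (target, true fraction) pairs.

    For fragment F_n the true ratio is R = f / (A_n - f) when the span
    [n, E] contains the modified position, else 0; measured R is true R
    times log-normal noise with the given CV. ``end_bias`` < 1 models the
    partial double-strand nuclease trimming of A/U-rich-ended fragments by
    scaling the F_X ratio only. ``fragments`` lists 5' offsets from X
    (e.g. -1, 0, 1 for the standard trio). Columns: rna_id, replicate,
    fragment, true_fraction, ratio, detected.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for target, f in targets:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"true fraction {f} outside [0, 1]")
        x = target.position
        e = end if end is not None else x + 8
        for offset in fragments:
            frag = predict_fragment(target, x + offset, e)
            if frag.contains(x) and f > 0:
                true_r = f / (frag.effective_a - f)
            else:
                true_r = 0.0
            if offset == 0:
                true_r *= end_bias
            for rep in range(1, replicates + 1):
                measured = float(true_r * _noise(rng, (), noise_cv))
                rows.append(
                    {
                        "rna_id": target.rna_id,
                        "replicate": rep,
                        "fragment": fragment_name(target, x + offset),
                        "true_fraction": f,
                        "ratio": measured,
                        "detected": measured > lod,
                    }
                )
    return pd.DataFrame(rows)
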