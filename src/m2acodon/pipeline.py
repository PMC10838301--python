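"""End-to-end driver: simulate (or load) -> scan -> TE -> group comparison.

`run_pipeline` executes the full analysis on a validated configuration and
writes TSV/JSON outputs plus a machine-readable manifest recording the
package version, seed, a hash of the semantically meaningful configuration
fields, and per-stage row counts. All outputs are deterministic functions of
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codons import (
    CodonSet,
    annotate_genes,
    annotations_to_frame,
    chloroplast_codon_set,
    cytosolic_codon_set,
)
from .simulate import SimConfig, simulate_expression, simulate_transcriptome
from .tables import read_cds_fasta, read_expression, write_cds_fasta, write_table
from .te import compare_groups, compute_te, cumulative_summary, te_fold_change

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration.

    Either ``simulate=True`` (inputs generated from ``sim``) or paths to a
    CDS FASTA plus expression/sample-sheet TSVs. ``codon_set`` names a
    built-in set (``cytosolic``, ``chloroplast_wobble``,
    ``chloroplast_two_out_of_three``) — explicit sets can be passed to the
    underlying functions directly.
    """

    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    cds_fasta: str | None = None
    expression_tsv: str | None = None
    sample_sheet_tsv: str | None = None
    codon_set: str = "cytosolic"
    freq_quantile: float = 0.90
    fc_cutoff: float = 2.0
    alpha: float = 0.05
    snr_cutoff: float = 1.0
    min_group_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.freq_quantile < 1:
            raise ValueError("freq_quantile must be in (0, 1)")
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must exceed 1")
        if self.snr_cutoff < 0:
            raise ValueError("snr_cutoff must be non-negative")
        if not self.simulate:
            missing = [
                n
                for n, v in (
                    ("cds_fasta", self.cds_fasta),
                    ("expression_tsv", self.expression_tsv),
                    ("sample_sheet_tsv", self.sample_sheet_tsv),
                )
                if v is None
            ]
            if missing:
                raise ValueError(f"simulate=False requires paths: {missing}")

    def resolve_codon_set(self) -> CodonSet:
        if self.codon_set == "cytosolic":
            return cytosolic_codon_set()
        if self.codon_set == "chloroplast_wobble":
            return chloroplast_codon_set("wobble")
        if self.codon_set == "chloroplast_two_out_of_three":
            return chloroplast_codon_set("two_out_of_three")
        raise ValueError(f"unknown codon_set {self.codon_set!r}")

    def config_hash(self) -> str:
        blob = json.dumps(self._payload(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def _payload(self) -> dict:
        payload = asdict(self)
        payload["sim"]["tandem_design"] = {
            str(k): v for k, v in payload["sim"]["tandem_design"].items()
        }
        return payload

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._payload(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        sim = payload.pop("sim", {})
        sim["tandem_design"] = {
            int(k): v for k, v in sim.get("tandem_design", {}).items()
        }
        sim["length_codons"] = tuple(sim["length_codons"])
        sim["set_codon_proportion"] = tuple(sim["set_codon_proportion"])
        sim["baseline_log10_fpkm"] = tuple(sim["baseline_log10_fpkm"])
        sim["te_log10"] = tuple(sim["te_log10"])
        return cls(sim=SimConfig(**sim), **payload)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run scan -> TE -> group comparison; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    codon_set = config.resolve_codon_set()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "codon_set": codon_set.to_manifest(),
        "stages": {},
    }

    if config.simulate:
        sim = SimConfig(**{**asdict(config.sim), "seed": config.seed})
        genes, truth = simulate_transcriptome(sim, codon_set)
        expr = simulate_expression(truth, sim)
        write_cds_fasta(genes, outdir / "genes.fa")
        write_table(truth.reset_index(), outdir / "truth.tsv")
    else:
        genes = read_cds_fasta(config.cds_fasta)
        expr = read_expression(config.expression_tsv, config.sample_sheet_tsv)
    manifest["stages"]["inputs"] = {"genes": len(genes),
                                    "samples": len(expr.samples)}

    annotations = annotate_genes(genes, codon_set,
                                 freq_quantile=config.freq_quantile)
    annot = annotations_to_frame(annotations).set_index("gene_id")
    write_table(annot.reset_index(), outdir / "annotations.tsv")
    manifest["stages"]["scan"] = {"genes": len(annot)}

    te_table = compute_te(expr)
    write_table(te_table.rename_axis("gene_id").reset_index(), outdir / "te.tsv")
    fc = te_fold_change(te_table)
    manifest["stages"]["te"] = {
        "genes": len(te_table),
        "translated": int(te_table["translated"].sum()),
    }

    reports = {}
    for label_col in ("tandem_bin", "group"):
        labels = annot[label_col].reindex(fc.index).dropna()
        comparison = compare_groups(
            fc.reindex(labels.index), labels,
            alpha=config.alpha, min_group_size=config.min_group_size,
        )
        reports[label_col] = comparison.to_dict()
        cdf = cumulative_summary(fc.reindex(labels.index), labels)
        write_table(cdf, outdir / f"cdf_{label_col}.tsv")
    with open(outdir / "group_comparison.json", "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)
    manifest["stages"]["compare"] = {
        k: {"kruskal_p": v["kruskal_p"]} for k, v in reports.items()
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
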