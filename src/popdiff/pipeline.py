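"""End-to-end orchestration: filter -> outlier scan -> differentiation layers
-> fixed differences -> ecotype contrasts -> enrichment.

Every stage is a pure function of (inputs, config, seed); the bundle is
written as plain tabular/JSON artifacts plus a manifest with SHA-256
checksums, so a rerun with the same configuration and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import annotation_enrichment as enrich
from . import ecotype_contrast as contrast
from . import fixed_diff, genotype_io, outlier_scan, popgen_stats, synthetic_data

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception, written: list[str]):
        super().__init__(f"pipeline stage {stage!r} failed: {original} (artifacts so far: {written})")
        self.stage = stage
        self.original = original
        self.written = written


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "results/run"
    # either real inputs ...
    vcf: Optional[str] = None
    popmap: Optional[str] = None
    genes: Optional[str] = None
    gene_terms: Optional[str] = None
    # ... or a synthetic dataset
    sim: Optional[synthetic_data.SimulationConfig] = None
    simulate_annotation: bool = True
    # filter thresholds
    min_dp: float = 20.0
    min_gq: float = 20.0
    keep_missing: bool = False
    # scan parameters
    n_sims: int = 50_000
    fdr: float = 0.1
    n_bins: int = 50
    seed: int = 0
    # ecotype grouping (population labels); empty -> derived from ecotype column
    residents: list[str] = field(default_factory=list)
    transients: list[str] = field(default_factory=list)
    outgroups: list[str] = field(default_factory=list)
    # enrichment
    link_window: int = 5000
    enrich_alpha: float = 0.05
    n_control_lists: int = 10

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat key = value text configuration."""
        kwargs: dict = {}
        sim_kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            target = sim_kwargs if key.startswith("sim.") else kwargs
            name = key[4:] if key.startswith("sim.") else key
            target[name] = _coerce(name, value)
        if sim_kwargs or kwargs.pop("synthetic", False):
            kwargs["sim"] = synthetic_data.SimulationConfig(**sim_kwargs)
        return cls(**kwargs)


def _coerce(name: str, value: str):
    if name in ("residents", "transients", "outgroups", "samples_per_population"):
        items = [v.strip() for v in value.split(",") if v.strip()]
        return [int(v) if v.isdigit() else v for v in items]
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _groups(config: RunConfig, popmap: genotype_io.PopulationMap):
    """Resolve (residents, transients, outgroups) population lists."""
    if config.residents and config.transients:
        return list(config.residents), list(config.transients), list(config.outgroups)
    ecos = popmap.ecotypes()
    res = popmap.populations_of_ecotype(ecos[0]) if len(ecos) > 0 else []
    tra = popmap.populations_of_ecotype(ecos[1]) if len(ecos) > 1 else []
    out = [p for e in ecos[2:] for p in popmap.populations_of_ecotype(e)]
    return res, tra, out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    notes: list[str] = []

    def emit_frame(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
        written.append(name)

    stage = "input"
    try:
        annotation = None
        truth = None
        if config.sim is not None:
            sim_cfg = dataclasses.replace(config.sim, seed=config.sim.seed or config.seed)
            matrix, popmap, truth = synthetic_data.simulate_dataset(sim_cfg)
            if config.simulate_annotation:
                annotation = synthetic_data.simulate_annotation(
                    matrix, truth, seed=sim_cfg.seed + 1
                )
            truth.rename_axis("id").to_frame().to_csv(out / "truth.tsv", sep="\t")
            written.append("truth.tsv")
        else:
            if not config.vcf or not config.popmap:
                raise ValueError("config needs either a synthetic section or vcf+popmap paths")
            matrix = genotype_io.read_vcf(config.vcf)
            popmap = genotype_io.read_popmap(config.popmap, matrix)
            if config.genes and config.gene_terms:
                annotation = enrich.AnnotationTrack.read(config.genes, config.gene_terms)

        stage = "filter"
        matrix, ledger = genotype_io.filter_snps(
            matrix,
            min_mean_coverage=config.min_dp,
            min_genotype_quality=config.min_gq,
            drop_missing=not config.keep_missing,
        )
        _write_json({"removed": ledger, "kept": matrix.n_loci, "seed": config.seed}, out / "filter_ledger.json")
        written.append("filter_ledger.json")

        stage = "scan"
        cls, baseline = outlier_scan.iterate_baseline(
            matrix,
            popmap,
            fdr=config.fdr,
            n_sims=config.n_sims,
            seed=config.seed,
            n_bins=config.n_bins,
        )
        emit_frame(cls.table, "classification.tsv")
        _write_json(
            {
                "baseline_mean_fst": baseline,
                "iterations": cls.iterations,
                "converged": cls.converged,
                "counts": {k: int(v) for k, v in cls.counts().items()},
                "fdr": config.fdr,
                "n_sims": config.n_sims,
                "seed": config.seed,
            },
            out / "scan_summary.json",
        )
        written.append("scan_summary.json")

        stage = "layers"
        neutral_idx = matrix.locus_index(cls.ids_with_label("neutral"))
        positive_idx = matrix.locus_index(cls.ids_with_label("positive"))
        layers: dict[str, dict[str, popgen_stats.PairwiseLayer]] = {}
        for label, idx in (("neutral", neutral_idx), ("outlier", positive_idx)):
            if len(idx) == 0:
                notes.append(f"no {label} loci; differentiation layers skipped for that set")
                continue
            fst = popgen_stats.pairwise_fst(matrix, popmap, locus_idx=idx)
            fst.label = label
            diff = popgen_stats.allelic_difference_matrix(matrix, popmap, locus_idx=idx)
            diff.label = label
            diff_norm = popgen_stats.allelic_difference_matrix(
                matrix, popmap, locus_idx=idx, normalize=True
            )
            layers[label] = {"fst": fst, "diff": diff}
            emit_frame(fst.to_frame(), f"fst_{label}.tsv", index=True)
            emit_frame(diff.to_frame(), f"alleldiff_{label}.tsv", index=True)
            emit_frame(diff_norm.to_frame(), f"alleldiff_perlocus_{label}.tsv", index=True)

        stage = "fixed"
        table = fixed_diff.pairwise_fixed_table(
            matrix, popmap, neutral_idx=neutral_idx, outlier_idx=positive_idx
        )
        emit_frame(table, "fixed_differences.tsv", index=True)

        stage = "contrast"
        residents, transients, outgroups = _groups(config, popmap)
        contrasts: dict = {"residents": residents, "transients": transients, "outgroups": outgroups}
        can_ratio = (len(residents) >= 2 or len(transients) >= 2) and residents and transients
        if {"neutral", "outlier"} <= set(layers) and can_ratio:
            rs = {
                label: contrast.ratio_set(layers[label]["fst"], residents, transients)
                for label in ("neutral", "outlier")
            }
            mw = contrast.mann_whitney(rs["neutral"].ratios, rs["outlier"].ratios)
            contrasts["ratio"] = {
                label: {"n": r.n, "mean": r.mean, "min": r.min, "max": r.max}
                for label, r in rs.items()
            }
            contrasts["mann_whitney"] = {"u": mw.u, "z": mw.z, "p": mw.p, "method": mw.method}
            c1 = contrast.chi2_contrast(
                layers["neutral"]["diff"], layers["outlier"]["diff"], residents, transients
            )
            contrasts["between_within"] = {
                "table": c1.table.tolist(),
                "fold_ratios": list(c1.fold_ratios),
                "chi2": c1.chi2,
                "p": c1.p,
            }
            if outgroups:
                c2 = contrast.outgroup_contrast(
                    layers["neutral"]["diff"], layers["outlier"]["diff"],
                    residents, transients, outgroups,
                )
                contrasts["outgroup"] = {
                    "table": c2.table.tolist(),
                    "fold_ratios": list(c2.fold_ratios),
                    "chi2": c2.chi2,
                    "p": c2.p,
                }
        else:
            notes.append("ecotype contrasts skipped (insufficient groups or locus sets)")
        _write_json(contrasts, out / "contrasts.json")
        written.append("contrasts.json")

        stage = "enrich"
        if annotation is not None and len(annotation.genes):
            links = enrich.link_snps_to_genes(matrix.loci, annotation, window=config.link_window)
            strong = list(
                cls.table.loc[cls.table["best_supported"], "id"]
            )
            fixed_any: set[str] = set()
            pops = popmap.populations
            for i in range(len(pops)):
                for j in range(i + 1, len(pops)):
                    fixed_any |= set(fixed_diff.find_fixed(matrix, popmap, pops[i], pops[j]))
            candidates = enrich.genes_linked(links, set(strong) | fixed_any)
            background = enrich.genes_linked(links, matrix.loci["id"])
            if candidates:
                result = enrich.fisher_enrichment(candidates, background, annotation)
                emit_frame(result, "enrichment.tsv")
                neutral_genes = enrich.genes_linked(links, cls.ids_with_label("neutral"))
                if len(neutral_genes) >= len(candidates):
                    n_sig, min_p = enrich.neutral_control_summary(
                        neutral_genes, len(candidates), background, annotation,
                        n_lists=config.n_control_lists, seed=config.seed + 7,
                        alpha=config.enrich_alpha,
                    )
                    _write_json(
                        {"lists_with_significant_term": n_sig, "min_p_adj": min_p},
                        out / "neutral_control.json",
                    )
                    written.append("neutral_control.json")
                else:
                    notes.append("neutral gene pool smaller than candidate list; control skipped")
            else:
                notes.append("no candidate genes within the linkage window; enrichment skipped")
        else:
            notes.append("no annotation supplied; enrichment stage skipped")
            logger.info("no annotation supplied; enrichment stage skipped")
    except Exception as exc:
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc, written) from exc

    manifest = {
        "seed": config.seed,
        "notes": notes,
        "artifacts": {name: _sha256(out / name) for name in sorted(written)},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
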