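"""End-to-end orchestration: simulate -> DE -> union set -> discover ->
evaluate -> enrich -> associate, driven by one config with a single seed.

Each stage derives its own deterministic substream from the global seed and
its stage name, so toggling one stage never perturbs another's randomness.
Outputs are plain-text TSV/JSON; a manifest records input checksums, stage
seeds, and per-stage outputs, and replaying the same config reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import allelic_association, filter_significant, read_genotype_tsv
from .discovery import (
    RFEConfig,
    rfe,
    select_parsimonious_signature,
    selection_frequency_weights,
)
from .enrich import hypergeometric_enrichment, read_gmt
from .evaluate import CVConfig, pca_projection, repeated_stratified_cv
from .expression import (
    filter_sex_chromosomes,
    read_expression_matrix,
    read_gene_annotation,
    read_phenotypes,
)
from .sam import DEConfig, differential_expression, union_analysis_set
from .simulate import ExpressionSimConfig, GenotypeSimConfig, simulate_expression_cohort, simulate_genotypes

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_demo_workspace", "stage_seed"]


class PipelineError(RuntimeError):
    """One or more pipeline stages failed; the manifest holds details."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Inputs, contrasts, per-stage parameters, and stage toggles."""

    expression: str = "expression.tsv"
    phenotypes: str = "phenotypes.tsv"
    annotation: str = "annotation.tsv"
    gene_sets: str = "genesets.gmt"
    genotypes: str = "genotypes.tsv"
    genotype_status: str = "genotype_status.tsv"
    out_dir: str = "results"
    seed: int = 0
    # contrasts: DE runs complicated-vs-control per population; discovery
    # pools all sarcoidosis (US+CS) vs HC across populations
    de_case_classes: tuple = ("CS",)
    de_control_classes: tuple = ("HC",)
    discovery_case_classes: tuple = ("US", "CS")
    n_permutations: int = 200
    rfe_drop_fraction: float = 0.1
    rfe_cv_repeats: int = 3
    cv_repetitions: int = 200
    cv_folds: int = 5
    weight_resamples: int = 50
    association_p_threshold: float = 0.01
    association_window: int = 10_000
    stages: tuple = (
        "differential_expression",
        "discovery",
        "evaluation",
        "enrichment",
        "association",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("de_case_classes", "de_control_classes", "discovery_case_classes", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self, base: Path) -> None:
        needed = [self.expression, self.phenotypes, self.annotation]
        if "enrichment" in self.stages:
            needed.append(self.gene_sets)
        if "association" in self.stages:
            needed += [self.genotypes, self.genotype_status]
        missing = [str(p) for p in needed if not (base / p).is_file()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, base_dir=".") -> dict:
    """Execute the configured stages in dependency order; returns the manifest.

    A failing stage aborts its dependents but independent stages still run;
    if anything failed a :class:`PipelineError` is raised after the manifest
    is written.
    """
    base = Path(base_dir)
    cfg.validate(base)
    out = base / cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    for name in ("expression", "phenotypes", "annotation", "gene_sets", "genotypes", "genotype_status"):
        p = base / getattr(cfg, name)
        if p.is_file():
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    annotation = read_gene_annotation(base / cfg.annotation)
    matrix = read_expression_matrix(base / cfg.expression, annotation)
    phenotypes = read_phenotypes(base / cfg.phenotypes)
    matrix = filter_sex_chromosomes(matrix)
    universe = matrix.gene_ids

    failed: dict[str, str] = {}
    de_lists: dict[str, list[str]] = {}
    analysis_set: list[str] | None = None
    signature = None

    def record(stage, t0, outputs):
        manifest["stages"][stage] = {
            "seed": stage_seed(cfg.seed, stage),
            "seconds": round(time.monotonic() - t0, 3),
            "outputs": [str(p.name) for p in outputs],
        }
        for p in outputs:
            manifest["outputs"][p.name] = _sha256(p)

    # --- differential expression per population -------------------------
    if "differential_expression" in cfg.stages:
        t0 = time.monotonic()
        try:
            outputs = []
            for pop in ("AA", "EA"):
                samples = phenotypes.select_samples(
                    classes=list(cfg.de_case_classes) + list(cfg.de_control_classes),
                    population=pop,
                )
                sub = matrix.subset_samples(samples)
                y = phenotypes.binary_labels(
                    samples, list(cfg.de_case_classes), list(cfg.de_control_classes)
                )
                de = differential_expression(
                    sub,
                    y,
                    DEConfig(
                        n_permutations=cfg.n_permutations,
                        seed=stage_seed(cfg.seed, f"de_{pop}"),
                    ),
                )
                path = out / f"de_{pop}.tsv"
                de.round(6).to_csv(path, sep="\t")
                outputs.append(path)
                de_lists[pop] = de.index[de["selected"]].tolist()
            analysis_set = union_analysis_set(*de_lists.values())
            path = out / "analysis_set.txt"
            path.write_text("\n".join(analysis_set) + "\n")
            outputs.append(path)
            record("differential_expression", t0, outputs)
        except Exception as exc:  # noqa: BLE001 - stage isolation
            failed["differential_expression"] = repr(exc)

    # --- signature discovery --------------------------------------------
    if "discovery" in cfg.stages and "differential_expression" not in failed:
        t0 = time.monotonic()
        try:
            if not analysis_set:
                raise RuntimeError("empty analysis set; nothing to discover on")
            disc_samples = phenotypes.select_samples(
                classes=list(cfg.discovery_case_classes) + list(cfg.de_control_classes)
            )
            disc_samples = [s for s in disc_samples if s in matrix.sample_ids]
            sub = matrix.subset_samples(disc_samples).subset_genes(analysis_set)
            y = phenotypes.binary_labels(
                disc_samples,
                list(cfg.discovery_case_classes),
                list(cfg.de_control_classes),
            )
            rfe_cfg = RFEConfig(
                drop_fraction=cfg.rfe_drop_fraction,
                cv_repeats_per_round=cfg.rfe_cv_repeats,
                cv_folds=cfg.cv_folds,
                seed=stage_seed(cfg.seed, "discovery"),
            )
            trace = rfe(sub, y, rfe_cfg)
            sig = select_parsimonious_signature(trace, sub, y)
            weights = selection_frequency_weights(
                sub,
                y,
                sig.size,
                n_resamples=cfg.weight_resamples,
                cfg=rfe_cfg,
                seed=stage_seed(cfg.seed, "weights"),
            )
            signature = sig
            trace_path = out / "rfe_trace.tsv"
            trace.summary().round(6).to_csv(trace_path, sep="\t", index=False)
            sig_path = out / "signature.tsv"
            weights.round(6).rename_axis("gene").to_csv(sig_path, sep="\t")
            genes_path = out / "signature_genes.txt"
            genes_path.write_text("\n".join(sig.genes) + "\n")
            record("discovery", t0, [trace_path, sig_path, genes_path])
        except Exception as exc:  # noqa: BLE001
            failed["discovery"] = repr(exc)

    # --- evaluation ------------------------------------------------------
    if "evaluation" in cfg.stages and "discovery" not in failed and signature is not None:
        t0 = time.monotonic()
        try:
            outputs = []
            contrasts = {
                "all_vs_hc": (["US", "CS"], ["HC"], None),
                "cs_vs_us": (["CS"], ["US"], None),
                "all_vs_hc_AA": (["US", "CS"], ["HC"], "AA"),
                "all_vs_hc_EA": (["US", "CS"], ["HC"], "EA"),
            }
            summaries = {}
            for name, (case, ctrl, pop) in contrasts.items():
                samples = phenotypes.select_samples(classes=case + ctrl, population=pop)
                samples = [s for s in samples if s in matrix.sample_ids]
                y = phenotypes.binary_labels(samples, case, ctrl)
                counts = pd.Series(y).value_counts()
                if counts.min() < cfg.cv_folds:
                    summaries[name] = {"skipped": f"class smaller than k={cfg.cv_folds}"}
                    continue
                report = repeated_stratified_cv(
                    matrix.subset_samples(samples),
                    y,
                    list(signature.genes),
                    CVConfig(
                        n_folds=cfg.cv_folds,
                        n_repetitions=cfg.cv_repetitions,
                        seed=stage_seed(cfg.seed, f"eval_{name}"),
                    ),
                )
                summaries[name] = report.summary()
                acc_path = out / f"accuracy_{name}.tsv"
                pd.DataFrame(
                    {
                        "accuracy": report.accuracy_samples,
                        "sensitivity": report.sensitivity_samples,
                        "specificity": report.specificity_samples,
                    }
                ).round(6).to_csv(acc_path, sep="\t", index=False)
                outputs.append(acc_path)
            eval_path = out / "evaluation.json"
            eval_path.write_text(json.dumps(summaries, indent=2, sort_keys=True))
            outputs.append(eval_path)
            # PCA coordinates of the signature submatrix, all samples
            proj = pca_projection(matrix, list(signature.genes))
            pca_path = out / "pca_signature.tsv"
            coords = proj.coordinates.round(6).copy()
            coords["disease_class"] = phenotypes.classes_for(coords.index.tolist()).to_numpy()
            coords.rename_axis("sample_id").to_csv(pca_path, sep="\t")
            outputs.append(pca_path)
            record("evaluation", t0, outputs)
        except Exception as exc:  # noqa: BLE001
            failed["evaluation"] = repr(exc)

    # --- pathway enrichment ----------------------------------------------
    if "enrichment" in cfg.stages and "differential_expression" not in failed:
        t0 = time.monotonic()
        try:
            sets = read_gmt(base / cfg.gene_sets)
            outputs = []
            for pop, genes in de_lists.items():
                res = hypergeometric_enrichment(genes, universe, sets)
                path = out / f"enrichment_{pop}.tsv"
                res.round(6).to_csv(path, sep="\t", index=False)
                outputs.append(path)
            record("enrichment", t0, outputs)
        except Exception as exc:  # noqa: BLE001
            failed["enrichment"] = repr(exc)

    # --- SNP association --------------------------------------------------
    if "association" in cfg.stages:
        t0 = time.monotonic()
        try:
            genotypes = read_genotype_tsv(base / cfg.genotypes)
            status = (
                pd.read_csv(base / cfg.genotype_status, sep="\t", dtype=str)
                .set_index("sample_id")["status"]
            )
            sig_ann = annotation
            if signature is not None:
                in_sig = annotation.index.isin(signature.genes)
                if in_sig.any():
                    sig_ann = annotation[in_sig]
            assoc = allelic_association(
                genotypes, status, sig_ann, window=cfg.association_window
            )
            assoc_path = out / "association.tsv"
            assoc.round(6).to_csv(assoc_path, sep="\t")
            hits = filter_significant(
                assoc, cfg.association_p_threshold, contrast="case_vs_control"
            )
            hits_path = out / "association_significant.tsv"
            hits.round(6).to_csv(hits_path, sep="\t")
            record("association", t0, [assoc_path, hits_path])
        except Exception as exc:  # noqa: BLE001
            failed["association"] = repr(exc)

    manifest["failed_stages"] = failed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if failed:
        raise PipelineError(f"stage failure(s): {failed}")
    return manifest


def make_demo_workspace(directory, seed: int = 0, force: bool = False) -> Path:
    """Write a small self-contained synthetic workspace for demos and tests.

    Emulates the study's shape: ~2,000 autosomal-plus-sex-chromosome genes
    over 35 HC / 17 US / 22 CS samples in two populations with a planted
    20-gene signature, a genotype panel with planted associated SNPs near
    signature genes, a BED-like gene annotation, a toy GMT collection, and a
    ready-to-run ``config.yaml``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} exists and is not empty (use force=True)")
    directory.mkdir(parents=True, exist_ok=True)

    expr_cfg = ExpressionSimConfig(
        n_genes=2000,
        n_signature=20,
        n_per_class={"HC": 35, "US": 17, "CS": 22},
        delta=1.0,
        additive_factor=2.0,
        frac_down=0.9,
        noise_sd=0.5,
        pop_shift_sd=0.1,
        seed=stage_seed(seed, "demo_expression"),
    )
    matrix, phenotypes, truth = simulate_expression_cohort(expr_cfg)
    matrix.to_tsv(directory / "expression.tsv")
    phenotypes.to_tsv(directory / "phenotypes.tsv")
    truth.signature.to_csv(directory / "ground_truth_signature.tsv", sep="\t")

    # annotation: genes on chr1..22 round-robin, last 60 genes on X/Y so the
    # sex-chromosome filter has work to do; signature genes stay autosomal
    genes = matrix.gene_ids
    rng = np.random.default_rng(stage_seed(seed, "demo_annotation"))
    rows = []
    for i, g in enumerate(genes):
        if i >= len(genes) - 60:
            chrom = "X" if i % 2 else "Y"
        else:
            chrom = str(1 + i % 22)
        start = 100_000 + 50_000 * (i // 22)
        rows.append((g, chrom, start, start + int(rng.integers(5_000, 30_000))))
    ann = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    ann.to_csv(directory / "annotation.tsv", sep="\t", index=False, header=False)

    # toy GMT: one set enriched in signature genes plus background sets
    sig_genes = truth.signature_genes
    non_sig = [g for g in genes[:1900] if g not in sig_genes]
    with open(directory / "genesets.gmt", "w") as fh:
        fh.write(
            "PLANTED_SIGNALING\tsynthetic set overlapping the planted signature\t"
            + "\t".join(sig_genes[:15] + non_sig[:10])
            + "\n"
        )
        for k in range(5):
            members = non_sig[10 + 30 * k : 10 + 30 * (k + 1)]
            fh.write(f"BACKGROUND_{k}\tsynthetic background set\t" + "\t".join(members) + "\n")

    # genotypes: SNPs positioned inside/near the first few signature genes,
    # planted ORs in the range reported for severity-associated variants
    geno_cfg = GenotypeSimConfig(
        n_snps=300,
        n_cases=200,
        n_controls=200,
        planted=((0, 2.710, 0.2), (1, 1.645, 0.3), (2, 0.475, 0.25)),
        seed=stage_seed(seed, "demo_genotypes"),
    )
    genotypes, status, geno_truth = simulate_genotypes(geno_cfg)
    ann_idx = ann.set_index("gene")
    positions = genotypes.positions.copy()
    for i, snp in enumerate(genotypes.snp_ids):
        g = ann_idx.loc[genes[i % 40]]
        positions.loc[snp, "chrom"] = str(g["chrom"])
        positions.loc[snp, "pos"] = int((g["start"] + g["end"]) // 2)
    from .association import GenotypeMatrix

    genotypes = GenotypeMatrix(dosages=genotypes.dosages, positions=positions)
    genotypes.to_tsv(directory / "genotypes.tsv")
    status.rename_axis("sample_id").to_frame().to_csv(
        directory / "genotype_status.tsv", sep="\t"
    )
    geno_truth.planted_snps.to_csv(
        directory / "ground_truth_snps.tsv", sep="\t", index=False
    )

    cfg = RunConfig(seed=seed)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "expression": cfg.expression,
                "phenotypes": cfg.phenotypes,
                "annotation": cfg.annotation,
                "gene_sets": cfg.gene_sets,
                "genotypes": cfg.genotypes,
                "genotype_status": cfg.genotype_status,
                "out_dir": cfg.out_dir,
                "seed": seed,
            },
            fh,
        )
    return directory
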