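"""Synthetic cohorts with known ground truth.

Two generators emulate the statistical structure of a blood-transcriptome
severity study so that every downstream stage is testable without external
downloads:

* :func:`simulate_expression_cohort` draws a three-class cohort (healthy
  control, uncomplicated, complicated disease) across two populations with a
  planted gene signature following an additive severity pattern — the
  complicated-disease effect is a multiple of the uncomplicated effect, and
  most signature genes are down-regulated, mirroring the predominance of
  down-regulation in severe granulomatous disease.
* :func:`simulate_genotypes` draws case/control allele dosages with planted
  allele-frequency differences at specified odds ratios, under
  Hardy-Weinberg sampling within each group.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, PhenotypeTable

__all__ = [
    "ExpressionSimConfig",
    "GenotypeSimConfig",
    "GroundTruth",
    "simulate_expression_cohort",
    "simulate_genotypes",
    "case_frequency_from_or",
]


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the planted-signature expression cohort.

    ``delta`` is the uncomplicated-vs-control log2 effect; the complicated
    class shows ``additive_factor * delta`` (default 2, i.e. the severity
    effect continues additively past the uncomplicated level).  A fraction
    ``frac_down`` of the signature is down-regulated (default 0.9, matching
    the 18-of-20 down-regulated pattern typical of severe disease).  Noise is
    Gaussian in log2 space; ``pop_shift_sd`` adds a per-gene, per-population
    baseline shift, and ``pop_effect_multiplier`` optionally scales the
    signature effect per population (for testing population discordance).
    """

    n_genes: int = 2000
    n_signature: int = 20
    n_per_class: dict = field(
        default_factory=lambda: {"HC": 35, "US": 17, "CS": 22}
    )
    populations: dict = field(default_factory=lambda: {"AA": 0.5, "EA": 0.5})
    delta: float = 1.0
    additive_factor: float = 2.0
    frac_down: float = 0.9
    noise_sd: float = 0.5
    pop_shift_sd: float = 0.0
    pop_effect_multiplier: dict | None = None  # e.g. {"AA": 1.0, "EA": 0.5}
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature exceeds n_genes")
        if not 0 <= self.frac_down <= 1:
            raise ValueError("frac_down must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be nonnegative")
        total = sum(self.populations.values())
        if not np.isclose(total, 1.0):
            raise ValueError("population fractions must sum to 1")


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Parameters of the case/control genotype panel.

    ``planted`` lists ``(snp_index, target_or, control_maf)`` triples; the
    case allele frequency is derived from the control frequency and the
    target odds ratio.  Unplanted SNPs share one frequency between groups,
    drawn uniformly over ``maf_range``.
    """

    n_snps: int = 1300
    n_cases: int = 500
    n_controls: int = 500
    planted: tuple = ()
    maf_range: tuple = (0.1, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for idx, target_or, maf in self.planted:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"planted SNP index {idx} out of range")
            if target_or <= 0:
                raise ValueError("target odds ratio must be positive")
            if not 0 < maf <= 0.5:
                raise ValueError("control MAF must lie in (0, 0.5]")
            p1 = case_frequency_from_or(maf, target_or)
            if p1 >= 1:
                raise ValueError(
                    f"planted SNP {idx}: case frequency {p1} >= 1 is unreachable"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for simulated data.

    ``signature`` has one row per signature gene (columns ``direction`` in
    {up, down} and ``effect`` in log2 units, the uncomplicated-vs-control
    shift).  ``planted_snps`` has one row per planted SNP (columns
    ``target_or``, ``control_maf``, ``case_maf``).
    """

    signature: pd.DataFrame | None = None
    planted_snps: pd.DataFrame | None = None

    @property
    def signature_genes(self) -> list[str]:
        if self.signature is None:
            return []
        return self.signature.index.tolist()


def case_frequency_from_or(p0: float, odds_ratio: float) -> float:
    """Case allele frequency implied by a control frequency and an odds ratio.

    Inverts OR = [p1/(1-p1)] / [p0/(1-p0)]:  p1 = OR*p0 / (1 - p0 + OR*p0).
    """
    return odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)


def simulate_expression_cohort(
    cfg: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, PhenotypeTable, GroundTruth]:
    """Draw one cohort from the planted-signature model.

    Non-signature genes are baseline + Normal(0, noise_sd) in every class.
    Signature gene g has class means baseline (HC), baseline +/- delta (US),
    baseline +/- additive_factor*delta (CS), with the sign determined by
    ``frac_down`` (the first ``round(frac_down * n_signature)`` signature
    genes go down).  Population membership is assigned deterministically in
    proportion to ``cfg.populations`` within each class; each population
    carries its own per-gene baseline shift ~ Normal(0, pop_shift_sd).
    """
    rng = np.random.default_rng(cfg.seed)
    classes = ["HC", "US", "CS"]
    for c in classes:
        if cfg.n_per_class.get(c, 0) == 0:
            warnings.warn(
                f"class {c} has zero samples; downstream contrasts using it "
                "will fail",
                stacklevel=2,
            )

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sig_genes = genes[: cfg.n_signature]
    n_down = int(round(cfg.frac_down * cfg.n_signature))
    directions = np.where(np.arange(cfg.n_signature) < n_down, -1.0, 1.0)

    sample_ids: list[str] = []
    sample_class: list[str] = []
    sample_pop: list[str] = []
    pops = list(cfg.populations)
    for c in classes:
        n_c = cfg.n_per_class.get(c, 0)
        # deterministic largest-remainder split of the class across populations
        quotas = {p: cfg.populations[p] * n_c for p in pops}
        counts = {p: int(np.floor(quotas[p])) for p in pops}
        leftover = n_c - sum(counts.values())
        for p in sorted(pops, key=lambda p: quotas[p] - counts[p], reverse=True):
            if leftover <= 0:
                break
            counts[p] += 1
            leftover -= 1
        for p in pops:
            for j in range(counts[p]):
                sample_ids.append(f"{c}_{p}_{j:03d}")
                sample_class.append(c)
                sample_pop.append(p)

    n_samples = len(sample_ids)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    pop_shift = {
        p: rng.normal(0.0, cfg.pop_shift_sd, size=cfg.n_genes)
        if cfg.pop_shift_sd > 0
        else np.zeros(cfg.n_genes)
        for p in pops
    }

    class_multiplier = {"HC": 0.0, "US": 1.0, "CS": cfg.additive_factor}
    pop_mult = cfg.pop_effect_multiplier or {}
    mean = np.tile(baseline[:, None], (1, n_samples))
    for j, (c, p) in enumerate(zip(sample_class, sample_pop)):
        mean[:, j] += pop_shift[p]
        mean[: cfg.n_signature, j] += (
            directions * class_multiplier[c] * cfg.delta * pop_mult.get(p, 1.0)
        )
    values = mean + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids)
    )
    phenotypes = PhenotypeTable(
        pd.DataFrame(
            {"disease_class": sample_class, "population": sample_pop},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = GroundTruth(
        signature=pd.DataFrame(
            {
                "direction": np.where(directions < 0, "down", "up"),
                "effect": directions * cfg.delta,
            },
            index=pd.Index(sig_genes, name="gene"),
        )
    )
    return matrix, phenotypes, truth


def simulate_genotypes(cfg: GenotypeSimConfig):
    """Draw a case/control allele-dosage panel with planted associations.

    Returns ``(genotypes, status, truth)`` where ``genotypes`` is a
    :class:`sarcsig.association.GenotypeMatrix`, ``status`` is a pandas
    Series of "case"/"control" per sample, and ``truth`` records the planted
    SNPs.  Dosages count minor alleles: Binomial(2, p) per individual
    (Hardy-Weinberg within group).
    """
    from .association import GenotypeMatrix  # deferred: avoid import cycle

    rng = np.random.default_rng(cfg.seed)
    p_control = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    p_case = p_control.copy()
    planted_rows = []
    for idx, target_or, maf in cfg.planted:
        p_control[idx] = maf
        p_case[idx] = case_frequency_from_or(maf, target_or)
        planted_rows.append(
            {
                "snp_index": idx,
                "target_or": target_or,
                "control_maf": maf,
                "case_maf": p_case[idx],
            }
        )

    case_dos = rng.binomial(2, p_case[:, None], size=(cfg.n_snps, cfg.n_cases))
    ctrl_dos = rng.binomial(
        2, p_control[:, None], size=(cfg.n_snps, cfg.n_controls)
    )
    dosages = np.concatenate([case_dos, ctrl_dos], axis=1)

    snp_ids = [f"rs{i:06d}" for i in range(cfg.n_snps)]
    sample_ids = [f"case_{i:04d}" for i in range(cfg.n_cases)] + [
        f"ctrl_{i:04d}" for i in range(cfg.n_controls)
    ]
    # SNPs placed on one synthetic chromosome at 10 kb spacing
    positions = pd.DataFrame(
        {"chrom": "1", "pos": 10_000 * (1 + np.arange(cfg.n_snps))},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    genotypes = GenotypeMatrix(
        dosages=pd.DataFrame(dosages, index=snp_ids, columns=sample_ids),
        positions=positions,
    )
    status = pd.Series(
        ["case"] * cfg.n_cases + ["control"] * cfg.n_controls,
        index=sample_ids,
        name="status",
    )
    truth = GroundTruth(
        planted_snps=pd.DataFrame(
            planted_rows,
            columns=["snp_index", "target_or", "control_maf", "case_maf"],
        ).assign(snp_id=lambda d: [snp_ids[i] for i in d["snp_index"]])
        if planted_rows
        else pd.DataFrame(
            columns=["snp_index", "target_or", "control_maf", "case_maf", "snp_id"]
        )
    )
    return genotypes, status, truth
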