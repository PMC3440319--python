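"""Case-control allelic association of SNPs mapped to signature-gene regions.

For each SNP a 2x2 allele-count table is built (rows case/control, columns
minor/major allele; allele totals are twice the sample counts) and tested by
the 1-df chi-square without continuity correction, falling back to Fisher's
exact test when any expected cell is below 5.  The odds ratio is
(a*d)/(b*c) with the Haldane-Anscombe +0.5 correction when any cell is zero.
SNPs are annotated to nearby genes: inside the gene span -> intron, within a
window 5' of the start -> upstream, within a window 3' of the end ->
downstream (nearest gene wins ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "read_genotype_tsv",
    "read_vcf_dosages",
    "map_snps_to_genes",
    "allelic_association",
    "filter_significant",
]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Minor-allele dosages (SNPs x samples, values 0/1/2) with positions."""

    dosages: pd.DataFrame
    positions: pd.DataFrame  # index snp_id, columns chrom, pos

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates:
            dup = self.dosages.index[self.dosages.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate SNP id(s): {dup}")
        if self.dosages.columns.has_duplicates:
            dup = self.dosages.columns[self.dosages.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dup}")
        arr = self.dosages.to_numpy()
        if arr.size and not np.isin(arr, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1, or 2")
        missing = self.dosages.index.difference(self.positions.index)
        if len(missing):
            raise ValueError(f"SNP(s) lacking positions: {missing.tolist()}")

    @property
    def snp_ids(self) -> list[str]:
        return self.dosages.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.dosages.columns.tolist()

    def to_tsv(self, path) -> None:
        out = self.positions.loc[self.dosages.index, ["chrom", "pos"]].join(
            self.dosages
        )
        out.index.name = "snp_id"
        out.to_csv(path, sep="\t")


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read a genotype TSV: snp_id, chrom, pos, then one dosage column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.set_index("snp_id")
    positions = df[["chrom", "pos"]]
    dosages = df.drop(columns=["chrom", "pos"]).astype(int)
    return GenotypeMatrix(dosages=dosages, positions=positions)


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Minimal VCF reader: GT field of biallelic records -> ALT-allele dosage.

    Multi-allelic records and records with missing genotypes are skipped.
    The ALT allele plays the "minor allele" role downstream.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, ids, chroms, poss = [], [], [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        dosage = []
        ok = True
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                ok = False
                break
            dosage.append(sum(1 for a in gt if a == 1))
        if not ok:
            continue
        rows.append(dosage)
        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        chroms.append(str(rec.chrom))
        poss.append(int(rec.pos))
    vf.close()
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    idx = pd.Index(ids, name="snp_id")
    return GenotypeMatrix(
        dosages=pd.DataFrame(rows, index=idx, columns=samples),
        positions=pd.DataFrame({"chrom": chroms, "pos": poss}, index=idx),
    )


def map_snps_to_genes(
    positions: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    window: int = 10_000,
) -> pd.DataFrame:
    """Assign each SNP a (gene, relationship) by genomic proximity.

    ``relationship`` is "intron" inside the gene span (exon structure is not
    modeled), "upstream" within ``window`` bp 5' of the start, "downstream"
    within ``window`` bp 3' of the end, else "none".  The nearest gene wins
    ties; chromosome mismatch means no assignment.  Annotation uses 0-based
    half-open [start, end) coordinates; SNP positions are 1-based bp.
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    out = pd.DataFrame(
        {"gene": pd.NA, "relationship": "none"}, index=positions.index
    )
    ann = gene_annotation
    for snp_id, row in positions.iterrows():
        same_chr = ann[ann["chrom"].astype(str) == str(row["chrom"])]
        best_gene, best_rel, best_dist = None, "none", None
        pos0 = int(row["pos"]) - 1  # to 0-based
        for gene, g in same_chr.iterrows():
            if g["start"] <= pos0 < g["end"]:
                rel, dist = "intron", 0
            elif g["start"] - window <= pos0 < g["start"]:
                rel, dist = "upstream", g["start"] - pos0
            elif g["end"] <= pos0 < g["end"] + window:
                rel, dist = "downstream", pos0 - g["end"] + 1
            else:
                continue
            if best_dist is None or dist < best_dist:
                best_gene, best_rel, best_dist = gene, rel, dist
        out.loc[snp_id, ["gene", "relationship"]] = (best_gene, best_rel)
    return out


def _chi2_no_correction(a, b, c, d):
    """1-df Pearson chi-square on the 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    return chi2, stats.chi2.sf(chi2, df=1)


def allelic_association(
    g: GenotypeMatrix,
    status: pd.Series,
    gene_annotation: pd.DataFrame | None = None,
    window: int = 10_000,
) -> pd.DataFrame:
    """Allele-frequency test of every SNP between cases and controls.

    ``status`` maps sample id -> "case"/"control".  Returns a per-SNP frame
    with the 2x2 allele counts (a = case minor, b = case major, c = control
    minor, d = control major), p_value, odds_ratio, the test used, and a
    ``monomorphic`` flag (such SNPs get p = 1, OR = 1).  With
    ``gene_annotation`` the gene/relationship mapping columns are included.
    """
    status = status.loc[g.sample_ids]
    is_case = (status == "case").to_numpy()
    is_ctrl = (status == "control").to_numpy()
    if not is_case.any() or not is_ctrl.any():
        raise ValueError("both cases and controls are required")
    unknown = status[~(is_case | is_ctrl)]
    if len(unknown):
        raise ValueError(f"samples with unknown status: {unknown.index.tolist()}")

    D = g.dosages.to_numpy()
    a = D[:, is_case].sum(axis=1)
    b = 2 * is_case.sum() - a
    c = D[:, is_ctrl].sum(axis=1)
    d = 2 * is_ctrl.sum() - c

    monomorphic = ((a + c) == 0) | ((b + d) == 0)
    chi2, p_chi = _chi2_no_correction(a, b, c, d)

    # expected counts decide between chi-square and Fisher
    n = a + b + c + d
    expected_min = np.minimum.reduce(
        [
            (a + b) * (a + c) / n,
            (a + b) * (b + d) / n,
            (c + d) * (a + c) / n,
            (c + d) * (b + d) / n,
        ]
    )
    use_fisher = (expected_min < 5) & ~monomorphic
    p = p_chi.copy()
    test = np.where(use_fisher, "fisher", "chi2")
    for i in np.flatnonzero(use_fisher):
        p[i] = stats.fisher_exact(
            [[a[i], b[i]], [c[i], d[i]]], alternative="two-sided"
        )[1]

    zero_cell = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    af, bf, cf, df_ = (
        np.where(zero_cell, x + 0.5, x).astype(float) for x in (a, b, c, d)
    )
    odds_ratio = (af * df_) / (bf * cf)

    p[monomorphic] = 1.0
    odds_ratio[monomorphic] = 1.0
    test = np.where(monomorphic, "none", test)

    out = pd.DataFrame(
        {
            "chrom": g.positions.loc[g.snp_ids, "chrom"].to_numpy(),
            "pos": g.positions.loc[g.snp_ids, "pos"].to_numpy(),
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "p_value": np.clip(p, 0.0, 1.0),
            "odds_ratio": odds_ratio,
            "test": test,
            "monomorphic": monomorphic,
        },
        index=pd.Index(g.snp_ids, name="snp_id"),
    )
    if gene_annotation is not None:
        mapping = map_snps_to_genes(g.positions, gene_annotation, window)
        out = out.join(mapping)
    else:
        out["gene"] = pd.NA
        out["relationship"] = "none"
    return out


def filter_significant(
    results: pd.DataFrame, p_threshold: float = 0.01, contrast: str | None = None
) -> pd.DataFrame:
    """Rows below the nominal p threshold, sorted ascending by p.

    No multiple-testing correction is applied at this stage (the nominal
    threshold convention); apply :func:`sarcsig.enrich.bh_adjust` to
    ``results["p_value"]`` first if adjusted filtering is wanted.
    """
    out = results[results["p_value"] < p_threshold].sort_values(
        ["p_value", "chrom", "pos"], kind="stable"
    )
    out = out.copy()
    if contrast is not None:
        out.insert(0, "contrast", contrast)
    return out
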