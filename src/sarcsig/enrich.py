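"""Pathway over-representation: hypergeometric test with BH adjustment.

Gene lists (e.g. the differentially expressed genes of one contrast) are
tested against a GMT collection of pathway gene sets.  The universe is the
analysis set the list was drawn from (all genes surviving QC and the
sex-chromosome filter), and each set is intersected with the universe before
testing.  Only over-representation (upper tail) is tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeometric_enrichment",
    "bh_adjust",
]


class GeneSetCollection(dict):
    """Mapping of set name -> frozenset of gene symbols, plus source metadata."""

    def __init__(self, sets: dict | None = None, source: str = ""):
        super().__init__()
        self.source = source
        for name, members in (sets or {}).items():
            self.add(name, members)

    def add(self, name: str, members) -> None:
        if name in self:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        members = frozenset(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self[name] = members


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line name, description, then member symbols.

    Duplicate members within one line are collapsed; a line with fewer than
    three tab-separated fields is a parse error naming its line number.
    """
    coll = GeneSetCollection(source=str(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, _description, *members = fields
            members = [g for g in members if g]
            coll.add(name, members)
    return coll


def hypergeometric_enrichment(
    gene_list,
    universe,
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric P(X >= overlap) per gene set.

    Population size = |universe|, successes = |set ∩ universe|, draws =
    |gene_list|.  The list must be a subset of the universe; sets that do not
    intersect the universe are skipped (recorded in ``DataFrame.attrs``).
    Returns a frame sorted by adjusted then raw p, with columns overlap,
    set_size_in_universe, p_raw, p_adjusted.
    """
    universe = list(dict.fromkeys(universe))
    universe_set = set(universe)
    gene_list = list(dict.fromkeys(gene_list))
    offenders = [g for g in gene_list if g not in universe_set]
    if offenders:
        raise ValueError(f"gene list not a subset of the universe: {offenders}")
    n_universe = len(universe_set)
    n_draws = len(gene_list)
    list_set = set(gene_list)

    rows, skipped = [], []
    for name, members in sets.items():
        in_universe = members & universe_set
        if not in_universe:
            skipped.append(name)
            continue
        overlap = len(in_universe & list_set)
        # P(X >= overlap) under Hypergeom(N=universe, K=set, n=draws)
        p_raw = float(
            stats.hypergeom.sf(overlap - 1, n_universe, len(in_universe), n_draws)
        )
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size_in_universe": len(in_universe),
                "p_raw": min(p_raw, 1.0),
            }
        )
    result = pd.DataFrame(rows, columns=["set", "overlap", "set_size_in_universe", "p_raw"])
    if len(result):
        result["p_adjusted"] = bh_adjust(result["p_raw"].to_numpy())
        result = result.sort_values(
            ["p_adjusted", "p_raw", "set"], kind="stable"
        ).reset_index(drop=True)
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
    result.attrs["skipped_sets"] = skipped
    result.attrs["n_universe"] = n_universe
    result.attrs["n_list"] = n_draws
    return result


def bh_adjust(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
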