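"""Metabolite-to-gene expansion and hypergeometric pathway enrichment.

Significant metabolites are expanded to genes via a user-supplied
mapping table (top 50 genes per metabolite by mapping score, ties at
the boundary kept), a background is built from the full measured panel
with the same criteria, and per-pathway over-representation is tested
with the one-sided hypergeometric distribution, BH-adjusted within each
phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from metabaxes.mwas import bh_adjust

TOP_K_DEFAULT = 50
TOP_N_DEFAULT = 3


class EnrichmentError(ValueError):
    pass


@dataclass
class MappingTable:
    """Metabolite->gene mapping scores plus pathway membership."""

    mapping: pd.DataFrame   # metabolite_id, gene_id, mapping_score
    pathways: pd.DataFrame  # pathway_id, gene_id [, pathway_name]

    def __post_init__(self) -> None:
        need = {"metabolite_id", "gene_id", "mapping_score"}
        if not need.issubset(self.mapping.columns):
            raise EnrichmentError(f"mapping table needs columns {sorted(need)}")
        if self.mapping.duplicated(["metabolite_id", "gene_id"]).any():
            raise EnrichmentError("duplicate (metabolite, gene) mapping records")
        if not (self.mapping["mapping_score"] >= 0).all():
            raise EnrichmentError("mapping scores must be non-negative and finite")
        need_p = {"pathway_id", "gene_id"}
        if not need_p.issubset(self.pathways.columns):
            raise EnrichmentError(f"pathway table needs columns {sorted(need_p)}")
        sizes = self.pathways.groupby("pathway_id").size()
        if (sizes == 0).any():
            raise EnrichmentError("empty pathways present")

    def pathway_genes(self) -> dict[str, set[str]]:
        return {
            str(pid): set(grp["gene_id"].astype(str))
            for pid, grp in self.pathways.groupby("pathway_id")
        }


def expand_to_genes(
    metabolites: set[str] | list[str],
    mapping: MappingTable,
    top_k: int = TOP_K_DEFAULT,
) -> set[str]:
    """Union of each metabolite's top-k genes by mapping score.

    Score ties at the k-th position keep all tied records (logged).
    Metabolites absent from the mapping are skipped with a warning.
    """
    wanted = set(map(str, metabolites))
    if not wanted:
        return set()
    sub = mapping.mapping[mapping.mapping["metabolite_id"].astype(str).isin(wanted)]
    absent = wanted - set(sub["metabolite_id"].astype(str))
    if absent:
        warnings.warn(
            f"{len(absent)} metabolites missing from mapping table: "
            f"{sorted(absent)[:5]}",
            stacklevel=2,
        )
    genes: set[str] = set()
    for met, grp in sub.groupby("metabolite_id"):
        scores = grp.sort_values("mapping_score", ascending=False)["mapping_score"]
        if len(scores) > top_k:
            cutoff = scores.iloc[top_k - 1]
            keep = grp[grp["mapping_score"] >= cutoff]
        else:
            keep = grp
        genes.update(keep["gene_id"].astype(str))
    return genes


def build_background(
    measured_metabolites: set[str] | list[str],
    mapping: MappingTable,
    top_k: int = TOP_K_DEFAULT,
) -> set[str]:
    """Expand the full measured panel with the same top-k criteria."""
    measured = set(map(str, measured_metabolites))
    if not measured:
        raise EnrichmentError("measured metabolite panel is empty")
    return expand_to_genes(measured, mapping, top_k)


def enrich(
    target_genes: set[str],
    mapping: MappingTable,
    background: set[str],
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway.

    Population = background, successes = pathway ∩ background, draws =
    target.  P is the upper tail P(overlap >= observed).  BH adjustment
    is applied across pathways.
    """
    if not target_genes <= background:
        extra = sorted(target_genes - background)
        raise EnrichmentError(f"target genes outside background: {extra[:5]}")
    rows = []
    M = len(background)
    N = len(target_genes)
    for pid, genes in mapping.pathway_genes().items():
        in_bg = genes & background
        overlap = len(in_bg & target_genes)
        if N == 0:
            p = 1.0
        else:
            # P(X >= overlap), X ~ Hypergeom(M, |pathway ∩ bg|, N)
            p = float(stats.hypergeom.sf(overlap - 1, M, len(in_bg), N))
        rows.append(
            {
                "pathway_id": pid,
                "overlap": overlap,
                "target_size": N,
                "pathway_size": len(in_bg),
                "background_size": M,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).sort_values("pathway_id", ignore_index=True)
    if len(out):
        q, flags = bh_adjust(out["p"], fdr_level)
        out["q"] = q
        out["significant"] = flags
    return out


def enrich_per_phenotype(
    significant: pd.DataFrame,
    measured_metabolites: list[str],
    mapping: MappingTable,
    top_k: int = TOP_K_DEFAULT,
    fdr_level: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Run enrichment per phenotype from a long MWAS result table.

    Phenotypes with no significant metabolites are omitted.
    """
    background = build_background(measured_metabolites, mapping, top_k)
    sig = significant[significant["significant"]]
    out: dict[str, pd.DataFrame] = {}
    for phen, grp in sig.groupby("phenotype_id"):
        mets = set(grp["metabolite_id"].astype(str))
        if not mets:
            continue
        genes = expand_to_genes(mets, mapping, top_k)
        out[str(phen)] = enrich(genes, mapping, background, fdr_level)
    return out


def top_pathways(
    per_phenotype: dict[str, pd.DataFrame], n: int = TOP_N_DEFAULT
) -> pd.DataFrame:
    """Top-n smallest-p pathways per phenotype (heatmap row set).

    Ties on p break toward the larger overlap, then the pathway id.
    Phenotypes absent from ``per_phenotype`` (no significant
    metabolites) simply do not appear.
    """
    rows = []
    for phen in sorted(per_phenotype):
        res = per_phenotype[phen]
        ranked = res.sort_values(
            ["p", "overlap", "pathway_id"], ascending=[True, False, True]
        ).head(n)
        for rank, (_, r) in enumerate(ranked.iterrows(), start=1):
            rows.append(
                {
                    "phenotype_id": phen,
                    "pathway_id": r["pathway_id"],
                    "rank": rank,
                    "overlap": int(r["overlap"]),
                    "target_size": int(r["target_size"]),
                    "pathway_size": int(r["pathway_size"]),
                    "background_size": int(r["background_size"]),
                    "p": float(r["p"]),
                    "q": float(r["q"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype_id",
            "pathway_id",
            "rank",
            "overlap",
            "target_size",
            "pathway_size",
            "background_size",
            "p",
            "q",
        ],
    )
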