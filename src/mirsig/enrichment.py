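"""miRNA-target summaries and pathway enrichment.

Works from a validated miRNA->gene edge table (miRTarBase-style TSV) whose
full gene universe serves as the enrichment background: multi-targeted gene
identification, Deduced Expression Effect (DEE) scores, one-sided
hypergeometric pathway enrichment with BH adjustment, and cross-signature
pathway intersection (Venn regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .survstats import bh_fdr


@dataclass
class TargetMap:
    """Validated miRNA->gene edges with a background gene universe.

    ``edges`` has columns ``mirna_id``, ``gene_id``, ``support_type``;
    duplicate (mirna, gene) pairs are collapsed.  The background is every
    gene with at least one validated edge.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edge table needs columns {sorted(required)}")
        if "support_type" not in self.edges.columns:
            self.edges = self.edges.assign(support_type="unknown")
        self.edges = self.edges.drop_duplicates(subset=["mirna_id", "gene_id"]).reset_index(
            drop=True
        )

    @property
    def background(self) -> set[str]:
        return set(self.edges["gene_id"])

    @property
    def mirnas(self) -> set[str]:
        return set(self.edges["mirna_id"])

    def targets_of(self, mirnas) -> set[str]:
        mirnas = {normalize_mirna_id(m) for m in mirnas}
        norm = self.edges["mirna_id"].map(normalize_mirna_id)
        return set(self.edges.loc[norm.isin(mirnas), "gene_id"])

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TargetMap":
        return cls(pd.read_csv(path, sep="\t"))


def normalize_mirna_id(mirna: str, strip_species_prefix: bool = True) -> str:
    """Exact mature-name matching with case-folding and optional removal of
    the species prefix ('hsa-miR-140-5p' == 'miR-140-5p')."""
    m = str(mirna).strip().lower()
    if strip_species_prefix and m.startswith("hsa-"):
        m = m[4:]
    return m


def multi_targeted_genes(target_map: TargetMap, mirnas, min_support: int = 2) -> list[str]:
    """Genes targeted by at least ``min_support`` distinct query miRNAs."""
    mirnas = list(mirnas)
    if not mirnas:
        raise ValueError("empty miRNA query")
    norm_query = {normalize_mirna_id(m) for m in mirnas}
    edges = target_map.edges
    norm = edges["mirna_id"].map(normalize_mirna_id)
    sub = edges.loc[norm.isin(norm_query)]
    counts = sub.groupby("gene_id")["mirna_id"].nunique()
    return sorted(counts.index[counts >= min_support])


def compute_dee(target_map: TargetMap, mirna_directions: dict[str, int]) -> pd.DataFrame:
    """Deduced Expression Effect per gene.

    ``mirna_directions`` maps each query miRNA to its direction of
    association with the endpoint: +1 = positively associated with distant
    metastasis, -1 = negatively associated.  DEE(g) = (# targeting miRNAs
    negatively associated) - (# positively associated); since miRNAs repress
    their targets, a positive DEE predicts up-regulation of g in high-risk
    patients.  Genes untouched by the query set are omitted.
    """
    if not mirna_directions:
        raise ValueError("no query miRNAs")
    directions = {normalize_mirna_id(m): int(d) for m, d in mirna_directions.items()}
    if any(d not in (-1, 1) for d in directions.values()):
        raise ValueError("directions must be +1 or -1")
    edges = target_map.edges.copy()
    edges["_norm"] = edges["mirna_id"].map(normalize_mirna_id)
    sub = edges[edges["_norm"].isin(directions)]
    rows = []
    for gene, grp in sub.groupby("gene_id"):
        ds = [directions[m] for m in grp["_norm"].unique()]
        neg = sum(1 for d in ds if d == -1)
        pos = sum(1 for d in ds if d == +1)
        rows.append(
            {
                "gene_id": gene,
                "dee": neg - pos,
                "n_negative": neg,
                "n_positive": pos,
                "mirnas": ";".join(sorted(grp["mirna_id"].unique())),
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "dee", "n_negative", "n_positive", "mirnas"])
    return out.sort_values("gene_id").reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = [g for g in parts[2:] if g]
    return pathways


def write_gmt(pathways: dict[str, list[str]], path, descriptions: dict[str, str] | None = None):
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def pathway_enrichment(
    query_genes, pathways: dict[str, list[str]], background
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment against a custom background.

    For each pathway (intersected with the background first) the p-value is
    P(overlap >= observed) drawing |query| genes from the background;
    BH-adjusted q across tested pathways.  Pathways with empty background
    intersection are skipped.
    """
    query = set(query_genes)
    background = set(background)
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")
    N = len(background)
    n = len(query)
    rows = []
    for name, genes in pathways.items():
        pw = set(genes) & background
        K = len(pw)
        if K == 0:
            continue
        overlap = len(pw & query)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        rows.append(
            {
                "pathway": name,
                "overlap": overlap,
                "pathway_size": K,
                "query_size": n,
                "background_size": N,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values("p").reset_index(drop=True)
    return out


def pathway_intersection(
    enriched_tables: list[pd.DataFrame] | list[set],
    q_threshold: float = 0.05,
    labels: list[str] | None = None,
) -> dict:
    """Venn-region counts and the common set across >= 2 enrichment results.

    Accepts either EnrichmentResult tables (thresholded at q < q_threshold)
    or pre-made pathway-ID sets.  Returns region counts keyed by label
    combinations plus the full intersection members.
    """
    if len(enriched_tables) < 2:
        raise ValueError("need >= 2 sets to intersect")
    sets = []
    for item in enriched_tables:
        if isinstance(item, pd.DataFrame):
            if len(item):
                sets.append(set(item.loc[item["q"] < q_threshold, "pathway"]))
            else:
                sets.append(set())
        else:
            sets.append(set(item))
    k = len(sets)
    labels = labels or [f"set{i + 1}" for i in range(k)]
    regions = {}
    union = set().union(*sets)
    for r in range(1, k + 1):
        for combo in combinations(range(k), r):
            inside = set.intersection(*(sets[i] for i in combo))
            outside = set().union(*(sets[i] for i in range(k) if i not in combo)) if r < k else set()
            exclusive = inside - outside
            regions["&".join(labels[i] for i in combo)] = len(exclusive)
    common = set.intersection(*sets)
    return {
        "regions": regions,
        "common": sorted(common),
        "union_size": len(union),
        "labels": labels,
    }
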