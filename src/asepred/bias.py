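"""Gene-function bias diagnostic for ASE predictors.

A prediction model might preferentially recover ASE variants in genes of
particular molecular functions.  The diagnostic maps a model's correctly
predicted ASE-SNVs to genes, ranks gene-set terms by hypergeometric
over-representation (the enrichment profile), and compares the observed
top-term ranks against rank distributions obtained by repeatedly drawing
random ASE-SNV subsets of the same size from the full ASE-SNV set.
Observed ranks falling inside the resampled rank distributions indicate
no functional bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (term, description, tab-separated genes)."""
    gene_sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            gene_sets[parts[0]] = [g for g in parts[2:] if g]
    return gene_sets


def write_gmt(gene_sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in gene_sets:
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *gene_sets[term]]) + "\n")


def read_gene_map(path) -> dict[str, str]:
    """Read a ``locus_id<TAB>gene`` mapping table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"locus_id", "gene"} <= set(df.columns):
        raise ValueError("gene map requires columns locus_id and gene")
    return dict(zip(df["locus_id"], df["gene"]))


def snvs_to_genes(snvs, gene_map: dict[str, str]) -> list[str]:
    """Deduplicated, sorted genes for a list of SNV ids (many-to-one)."""
    snvs = list(snvs)
    if not snvs:
        raise ValueError("empty SNV list")
    unmapped = [s for s in snvs if s not in gene_map]
    if unmapped:
        logger.warning("dropping %d SNV(s) without a gene mapping", len(unmapped))
    genes = sorted({gene_map[s] for s in snvs if s in gene_map})
    if not genes:
        raise ValueError("no SNV could be mapped to a gene")
    return genes


@dataclass
class EnrichmentProfile:
    """Ranked over-representation of gene-set terms for a query gene list."""

    table: pd.DataFrame  # term, overlap, term_size, p_value, rank

    def rank_of(self, term: str) -> int | None:
        hit = self.table.loc[self.table["term"] == term, "rank"]
        return int(hit.iloc[0]) if len(hit) else None

    @property
    def n_terms(self) -> int:
        return len(self.table)


def enrich_profile(query_genes, gene_sets: dict[str, list[str]],
                   background_genes) -> EnrichmentProfile:
    """Hypergeometric over-representation profile of ``query_genes``.

    For each term the upper-tail probability of observing at least the
    realised overlap is computed within ``background_genes``; terms are
    ranked ascending by p-value with ties broken by larger overlap, then
    term id.  Term membership outside the background is ignored.
    """
    if not gene_sets:
        raise ValueError("gene-set collection is empty")
    background = set(background_genes)
    query = set(query_genes)
    outside = sorted(query - background)
    if outside:
        raise ValueError(f"query gene(s) outside the background universe: {outside[:10]}")
    N = len(background)
    q = len(query)
    rows = []
    for term, members in gene_sets.items():
        in_bg = background.intersection(members)
        K = len(in_bg)
        x = len(query & in_bg)
        # P(X >= x) for X ~ Hypergeom(N, K, q)
        p = float(hypergeom.sf(x - 1, N, K, q)) if K else 1.0
        rows.append((term, x, K, min(1.0, p)))
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_value"])
    df = df.sort_values(["p_value", "overlap", "term"],
                        ascending=[True, False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return EnrichmentProfile(df.reset_index(drop=True))


@dataclass
class BiasReport:
    """Observed vs resampled ranks of the observed profile's top terms."""

    observed: EnrichmentProfile
    top_terms: list[str]
    observed_ranks: dict[str, int]
    resampled_ranks: dict[str, list[int]]  # rank T+1 flags a term absent from a resample
    absent_flags: dict[str, list[bool]]
    n_resamples: int
    subset_size: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Long format: term, source (observed / resample_i), rank."""
        rows = [(t, "observed", self.observed_ranks[t],
                 float(self.observed.table.set_index("term").loc[t, "p_value"]))
                for t in self.top_terms]
        for t in self.top_terms:
            for i, r in enumerate(self.resampled_ranks[t]):
                rows.append((t, f"resample_{i}", r, float("nan")))
        return pd.DataFrame(rows, columns=["term", "source", "rank", "p_value"])


def rank_resampling_test(predicted_snvs, full_ase_snvs, gene_map: dict[str, str],
                         gene_sets: dict[str, list[str]], background_genes,
                         n_resamples: int = 10, top_k: int = 10,
                         seed: int = 0) -> BiasReport:
    """Compare observed enrichment-term ranks with random-resample ranks.

    The observed profile comes from the genes of ``predicted_snvs``; each
    of ``n_resamples`` draws samples ``len(predicted_snvs)`` SNVs without
    replacement from ``full_ase_snvs`` and profiles them identically.
    For the observed profile's ``top_k`` terms the report records the
    observed rank and the term's rank in every resample (a term missing
    from a resample profile is assigned rank T+1 and flagged).
    """
    predicted = list(dict.fromkeys(predicted_snvs))
    full = list(dict.fromkeys(full_ase_snvs))
    if not set(predicted) <= set(full):
        raise ValueError("predicted SNVs must be a subset of the full ASE-SNV set")
    if len(predicted) > len(full):
        raise ValueError("predicted subset larger than the full ASE-SNV set")
    observed = enrich_profile(snvs_to_genes(predicted, gene_map), gene_sets,
                              background_genes)
    top = observed.table.head(top_k)["term"].tolist()
    observed_ranks = {t: int(observed.rank_of(t)) for t in top}

    rng = np.random.default_rng(seed)
    resampled = {t: [] for t in top}
    absent = {t: [] for t in top}
    full_arr = np.array(full, dtype=object)
    for _ in range(n_resamples):
        draw = rng.choice(full_arr, size=len(predicted), replace=False)
        profile = enrich_profile(snvs_to_genes(draw.tolist(), gene_map), gene_sets,
                                 background_genes)
        for t in top:
            r = profile.rank_of(t)
            if r is None:
                resampled[t].append(profile.n_terms + 1)
                absent[t].append(True)
            else:
                resampled[t].append(int(r))
                absent[t].append(False)
    return BiasReport(observed=observed, top_terms=top, observed_ranks=observed_ranks,
                      resampled_ranks=resampled, absent_flags=absent,
                      n_resamples=n_resamples, subset_size=len(predicted), seed=seed)
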