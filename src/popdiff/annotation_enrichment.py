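"""SNP-to-gene linkage and functional-term enrichment.

Candidate loci are linked to genes whose span lies within a fixed
linkage window (default 5 kb, closed intervals on both sides) of the
SNP position.  Term overrepresentation in a candidate gene list against
a background list is tested per term with a two-tailed Fisher's exact
test and Benjamini-Hochberg correction across terms.  A negative
control draws random gene lists of the same length from the
neutral-locus genes and reports how many produce any significant term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class AnnotationTrack:
    """Gene spans (1-based, inclusive) plus a gene -> term mapping."""

    genes: pd.DataFrame  # columns: gene, contig, start, end
    gene2term: pd.DataFrame  # columns: gene, term

    def __post_init__(self) -> None:
        if len(self.genes):
            if not {"gene", "contig", "start", "end"}.issubset(self.genes.columns):
                raise ValueError("gene table needs columns gene, contig, start, end")
            if (self.genes["start"] > self.genes["end"]).any():
                raise ValueError("gene spans must satisfy start <= end")
            if self.genes["gene"].duplicated().any():
                raise ValueError("gene ids must be unique")

    def terms_of(self, gene: str) -> set[str]:
        return set(self.gene2term.loc[self.gene2term["gene"] == gene, "term"])

    @classmethod
    def read(cls, genes_path, terms_path) -> "AnnotationTrack":
        genes = pd.read_csv(genes_path, sep="\t")
        terms = pd.read_csv(terms_path, sep="\t")
        return cls(genes=genes, gene2term=terms)


def link_snps_to_genes(
    loci: pd.DataFrame,
    track: AnnotationTrack,
    window: int = 5000,
) -> dict[str, set[str]]:
    """Map locus id -> genes within ``window`` bases of the SNP.

    A gene is linked when at most ``window`` bases separate the SNP
    position from the gene span (the distance counts the intervening
    bases, so a SNP at 10,000 is exactly 5,000 bases from a span
    starting at 15,001 and is linked at window 5,000, while 15,002 is
    not); a SNP inside the span is linked at any window.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in track.genes.itertuples():
        # half-open tree interval covering the closed gene span
        trees.setdefault(row.contig, IntervalTree())[row.start : row.end + 1] = row.gene

    links: dict[str, set[str]] = {}
    for row in loci.itertuples():
        tree = trees.get(row.contig)
        if tree is None:
            links[row.id] = set()
            continue
        lo = max(1, row.pos - window - 1)
        hits = tree[lo : row.pos + window + 2]
        links[row.id] = {h.data for h in hits}
    return links


def genes_linked(links: dict[str, set[str]], locus_ids: Iterable[str]) -> list[str]:
    """Deduplicated, sorted union of genes linked to the given loci."""
    out: set[str] = set()
    for lid in locus_ids:
        out |= links.get(lid, set())
    return sorted(out)


def fisher_enrichment(
    candidate_genes: Sequence[str],
    background_genes: Sequence[str],
    track: AnnotationTrack,
) -> pd.DataFrame:
    """Two-tailed Fisher enrichment of each term, BH-corrected across terms.

    For a term with K carriers among the N background genes and k among
    the n candidates, the 2x2 table is
    [[k, n - k], [K - k, (N - n) - (K - k)]] (candidates must be a
    subset of the background).  Results are sorted by adjusted p.
    """
    from scipy.stats import fisher_exact
    from statsmodels.stats.multitest import multipletests

    cand = sorted(set(candidate_genes))
    bg = sorted(set(background_genes))
    if not cand:
        raise ValueError("empty candidate gene list")
    missing = set(cand) - set(bg)
    if missing:
        raise ValueError(f"candidate genes not in background: {sorted(missing)}")

    g2t = track.gene2term[track.gene2term["gene"].isin(bg)]
    term_genes = g2t.groupby("term")["gene"].apply(set)
    n, N = len(cand), len(bg)
    cand_set = set(cand)

    rows = []
    for term, carriers in term_genes.items():
        K = len(carriers)
        k = len(carriers & cand_set)
        table = [[k, n - k], [K - k, (N - n) - (K - k)]]
        _, p = fisher_exact(table, alternative="two-sided")
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": p})
    result = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(result):
        result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
        result = result.sort_values(["p_adj", "p", "term"]).reset_index(drop=True)
    else:
        result["p_adj"] = pd.Series(dtype=float)
    return result


def random_neutral_control(
    neutral_genes: Sequence[str],
    list_length: int,
    n_lists: int = 10,
    seed: int = 0,
) -> list[list[str]]:
    """Seed-reproducible random gene lists sampled without replacement."""
    pool = sorted(set(neutral_genes))
    if list_length > len(pool):
        raise ValueError(
            f"cannot draw {list_length} genes from a pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    return [sorted(rng.choice(pool, size=list_length, replace=False)) for _ in range(n_lists)]


def neutral_control_summary(
    neutral_genes: Sequence[str],
    list_length: int,
    background_genes: Sequence[str],
    track: AnnotationTrack,
    n_lists: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[int, list[float]]:
    """Run the enrichment test on each random neutral list.

    Returns the number of lists with any term significant after BH at
    ``alpha``, and the minimum adjusted p per list.
    """
    lists = random_neutral_control(neutral_genes, list_length, n_lists, seed)
    n_significant = 0
    min_p_adj = []
    for genes in lists:
        res = fisher_enrichment(genes, background_genes, track)
        best = float(res["p_adj"].min()) if len(res) else 1.0
        min_p_adj.append(best)
        if best <= alpha:
            n_significant += 1
    return n_significant, min_p_adj
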