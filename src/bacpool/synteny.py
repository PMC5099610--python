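"""Homolog hit counting and microsynteny block detection.

Works from a best-hit homology table: one row per query gene per model
species, carrying the query gene's rank along the target region (grouped by
the FPC contig it was assembled in) and the hit's chromosome, position and
rank on that chromosome.  Homologous chromosomes are called by hit count
(argmax plus any chromosome above a fraction of the maximum, which captures
the two-chromosome pattern seen against zebrafish-like karyotypes).

A microsynteny block is a run of genes adjacent in the query (same contig,
small rank gaps) whose hits co-locate in a small window of one target
chromosome *irrespective of their order there* -- conserved co-location,
not collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HOMOLOGY_COLUMNS",
    "SyntenyBlock",
    "count_hits_per_chromosome",
    "call_homologous_chromosomes",
    "detect_microsynteny",
    "block_span_summary",
    "simulate_homology_table",
]

HOMOLOGY_COLUMNS = [
    "query_gene_id",
    "query_contig_id",
    "query_rank",
    "species",
    "chromosome",
    "position_bp",
    "target_rank",
]


@dataclass
class SyntenyBlock:
    species: str
    chromosome: str
    query_contig_id: str
    gene_ids: list[str]
    query_rank_span: tuple[int, int]
    target_span_bp: tuple[int, int]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def count_hits_per_chromosome(table: pd.DataFrame, species: str) -> dict[str, int]:
    """Hit counts per chromosome for one species (descending)."""
    sub = table[table["species"] == species]
    counts = sub.groupby("chromosome").size().sort_values(ascending=False)
    return {str(k): int(v) for k, v in counts.items()}


def call_homologous_chromosomes(
    table: pd.DataFrame, species: str, secondary_frac: float = 0.25
) -> list[tuple[str, int]]:
    """Homolog call: the argmax chromosome plus all >= ``secondary_frac`` of it."""
    counts = count_hits_per_chromosome(table, species)
    if not counts:
        return []
    top = max(counts.values())
    return [(c, n) for c, n in counts.items() if n >= secondary_frac * top]


def detect_microsynteny(
    table: pd.DataFrame,
    species: str,
    min_genes: int = 2,
    max_query_gap: int = 1,
    max_target_gap_genes: int = 5,
    max_target_gap_bp: int = 1_000_000,
) -> list[SyntenyBlock]:
    """Maximal order-free co-location blocks per (query contig, chromosome).

    Genes of one contig with hits on one chromosome are walked in query-rank
    order; a gene extends the open block when its query-rank gap is within
    ``max_query_gap`` missing genes and its target rank/position lies within
    ``max_target_gap_genes`` ranks / ``max_target_gap_bp`` of some block
    member.  Blocks shorter than ``min_genes`` are discarded.
    """
    sub = table[table["species"] == species]
    blocks: list[SyntenyBlock] = []
    for (contig, chrom), grp in sub.groupby(["query_contig_id", "chromosome"], sort=True):
        grp = grp.sort_values("query_rank")
        open_rows: list[pd.Series] = []
        for _, row in grp.iterrows():
            if open_rows:
                q_gap = row["query_rank"] - open_rows[-1]["query_rank"] - 1
                t_rank_gap = min(
                    abs(row["target_rank"] - r["target_rank"]) for r in open_rows
                ) - 1
                t_bp_gap = min(
                    abs(row["position_bp"] - r["position_bp"]) for r in open_rows
                )
                if (
                    q_gap <= max_query_gap
                    and t_rank_gap <= max_target_gap_genes
                    and t_bp_gap <= max_target_gap_bp
                ):
                    open_rows.append(row)
                    continue
                blocks.extend(
                    _close(open_rows, species, str(chrom), str(contig), min_genes)
                )
                open_rows = []
            open_rows.append(row)
        blocks.extend(_close(open_rows, species, str(chrom), str(contig), min_genes))
    return blocks


def _close(rows, species, chrom, contig, min_genes) -> list[SyntenyBlock]:
    if len(rows) < min_genes:
        return []
    return [
        SyntenyBlock(
            species,
            chrom,
            contig,
            [r["query_gene_id"] for r in rows],
            (int(min(r["query_rank"] for r in rows)), int(max(r["query_rank"] for r in rows))),
            (int(min(r["position_bp"] for r in rows)), int(max(r["position_bp"] for r in rows))),
        )
    ]


def block_span_summary(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """Per-species totals: block count, distinct genes, summed target Mb."""
    if not blocks:
        return pd.DataFrame(columns=["species", "n_blocks", "n_genes", "target_mb"])
    rows = {}
    for b in blocks:
        rec = rows.setdefault(b.species, {"n_blocks": 0, "genes": set(), "bp": 0})
        rec["n_blocks"] += 1
        rec["genes"].update(b.gene_ids)
        rec["bp"] += b.target_span_bp[1] - b.target_span_bp[0]
    return pd.DataFrame(
        [
            (sp, r["n_blocks"], len(r["genes"]), round(r["bp"] / 1e6, 1))
            for sp, r in sorted(rows.items())
        ],
        columns=["species", "n_blocks", "n_genes", "target_mb"],
    )


def blocks_frame(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                b.species,
                b.chromosome,
                b.query_contig_id,
                b.n_genes,
                ";".join(b.gene_ids),
                *b.query_rank_span,
                *b.target_span_bp,
            )
            for b in blocks
        ],
        columns=[
            "species", "chromosome", "query_contig_id", "n_genes", "gene_ids",
            "query_rank_start", "query_rank_end", "target_start_bp", "target_end_bp",
        ],
    )


# ---------------------------------------------------------------------------
# synthetic homology tables


def simulate_homology_table(
    n_blocks: int = 8,
    genes_per_block: int = 6,
    noise_frac: float = 0.1,
    species: str = "modelfish",
    n_chromosomes: int = 10,
    gene_spacing_bp: int = 60_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Homology table with planted co-location blocks plus uniform noise.

    Each planted block is a contig whose genes hit a compact, possibly
    shuffled run of target ranks on one chromosome.  A ``noise_frac``
    fraction of extra genes with uniform random best hits is interleaved
    into the contigs, emulating spurious best hits.  Returns the table and
    the planted-block truth records.
    """
    rng = np.random.default_rng(seed)
    chrom_len_genes = 200
    n_planted = n_blocks * genes_per_block
    n_noise = int(round(noise_frac * n_planted))
    # per-contig gene payloads, planted hits first
    payloads: list[list[tuple[str, int, int] | None]] = []
    truth = []
    for b in range(n_blocks):
        chrom = f"chr{int(rng.integers(1, n_chromosomes + 1))}"
        t_start = int(rng.integers(0, chrom_len_genes - genes_per_block))
        t_ranks = t_start + rng.permutation(genes_per_block)
        payloads.append([(chrom, int(t), 1) for t in t_ranks])
        truth.append({"contig": f"qctg{b:03d}", "chromosome": chrom, "genes": []})
    for _ in range(n_noise):  # insert spurious best hits at random slots
        b = int(rng.integers(0, n_blocks))
        pos = int(rng.integers(0, len(payloads[b]) + 1))
        chrom = f"chr{int(rng.integers(1, n_chromosomes + 1))}"
        payloads[b].insert(pos, (chrom, int(rng.integers(0, chrom_len_genes)), 0))
    rows = []
    q_rank = 0
    for b, payload in enumerate(payloads):
        contig = f"qctg{b:03d}"
        for chrom, tr, planted in payload:
            q_rank += 1
            gid = f"g{q_rank:04d}"
            if planted:
                truth[b]["genes"].append(gid)
            rows.append(
                (gid, contig, q_rank, species, chrom, tr * gene_spacing_bp, tr)
            )
    return pd.DataFrame(rows, columns=HOMOLOGY_COLUMNS), truth
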