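"""End-to-end orchestration of the BAC-pool targeted-sequencing workflow.

Seven stages mirror the targeted-sequencing strategy: (1) synthetic genome
and map truth, (2) clone library, fingerprinting, FPC contigs and MTP
selection, (3) 3D pool construction, PCR screening and deconvolution,
(4) read simulation for the screened MTP pools, (5) per-pool short-read
assembly, hybrid scaffolding, read-back validation and BES/marker
anchoring, (6) synteny analysis of the annotated genes, (7) SNP-trait
association.  Each stage writes plain-text artifacts under a run directory
and can be re-run from its predecessors' files; a JSON manifest records
seeds, parameter hashes and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemble, assoc, physmap, pools, reads, synteny
from .config import RunConfig
from .genome import GenomeTruth, MarkerLocus, SnpLocus, generate_genome, revcomp
from .physmap import BacClone

__all__ = [
    "run_pipeline",
    "summary_metrics",
    "DependencyError",
    "per_bac_coverage",
    "success_rate",
    "span_mb_from_cb",
    "percent",
]


class DependencyError(RuntimeError):
    """A stage is missing an upstream artifact; names the offending stage."""


# ---------------------------------------------------------------------------
# report arithmetic (shared by summary_metrics and the acceptance script)


def per_bac_coverage(n_reads: int, mean_read_len_bp: float, n_bacs: int, insert_kb: float) -> float:
    """Mean short-read coverage per clone: total bases / (clones x insert)."""
    if n_bacs <= 0 or insert_kb <= 0:
        return 0.0
    return round(n_reads * mean_read_len_bp / (n_bacs * insert_kb * 1000.0), 1)


def success_rate(passing: int, attempted: int) -> float:
    """Success percentage to 1 decimal (0.0 for an empty denominator)."""
    if attempted <= 0:
        return 0.0
    return round(100.0 * passing / attempted, 1)


def span_mb_from_cb(cb_units: float, kb_per_cb: float = 1.36) -> float:
    """Physical-map span in Mb (1 decimal) from consensus-band units."""
    return round(physmap.cb_to_kb(cb_units, kb_per_cb) / 1000.0, 1)


def percent(numerator: float, denominator: float) -> float:
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, 1)


# ---------------------------------------------------------------------------
# stage implementations


def _require(run_dir: Path, stage: str, *paths: str) -> None:
    for p in paths:
        if not (run_dir / p).exists():
            raise DependencyError(f"stage '{stage}' requires missing artifact: {p}")


def _stage_genome(cfg: RunConfig, run_dir: Path) -> GenomeTruth:
    d = run_dir / "01_genome"
    d.mkdir(parents=True, exist_ok=True)
    truth = generate_genome(cfg.genome, cfg.stage_seed("genome"))
    truth.to_fasta(d / "genome.fasta")
    truth.write_tables(d)
    return truth


def _load_genome(cfg: RunConfig, run_dir: Path) -> GenomeTruth:
    _require(run_dir, "library", "01_genome/genome.fasta")
    # regeneration is byte-identical under the stage seed, and keeps the
    # truth annotations (which FASTA alone cannot carry)
    return generate_genome(cfg.genome, cfg.stage_seed("genome"))


def _stage_library(cfg: RunConfig, run_dir: Path, truth: GenomeTruth):
    d = run_dir / "02_library"
    d.mkdir(parents=True, exist_ok=True)
    lib = cfg.library
    n_clones = max(
        1, int(round(lib.coverage_fold * truth.length_bp / (lib.mean_insert_kb * 1000)))
    )
    design = (cfg.pools.n_plates, cfg.pools.n_rows, cfg.pools.n_cols)
    clones = physmap.digest_and_clone(
        truth,
        site=lib.cloning_site,
        partial_prob=lib.partial_digest_prob,
        size_window=lib.size_window,
        n_clones=n_clones,
        seed=cfg.stage_seed("library"),
        design=design,
    )
    fps = [
        physmap.fingerprint_clone(c, truth, lib.fingerprint_site, lib.band_tolerance_bp)
        for c in clones
    ]
    contigs = physmap.build_fpc_contigs(fps, lib.min_shared_bands, clones)
    intervals = {c.clone_id: (c.start, c.end) for c in clones}
    paths = []
    for ctg in contigs:
        try:
            paths.append(physmap.select_mtp(ctg, intervals, lib.kb_per_cb))
        except physmap.CoverGapError:
            warnings.warn(f"contig {ctg.contig_id}: clone set has coverage gaps")
    physmap.clones_frame(clones).to_csv(d / "clones.tsv", sep="\t", index=False)
    physmap.contigs_frame(contigs).to_csv(d / "contigs.tsv", sep="\t", index=False)
    physmap.tiling_frame(paths).to_csv(d / "tiling_paths.tsv", sep="\t", index=False)
    return clones, contigs, paths


def _stage_screen(cfg: RunConfig, run_dir: Path, truth: GenomeTruth, clones, contigs, paths):
    d = run_dir / "03_screen"
    d.mkdir(parents=True, exist_ok=True)
    _require(run_dir, "screen", "02_library/clones.tsv")
    design = pools.PoolDesign(cfg.pools.n_plates, cfg.pools.n_rows, cfg.pools.n_cols)
    pool_set = pools.build_pools(clones, design)
    seed0 = cfg.stage_seed("screen")
    by_addr = pool_set.clones
    screen_rows, deconv_results = [], []
    marker_hits: dict[str, set[str]] = {}
    for i, m in enumerate(truth.markers):
        sr = pools.screen_marker(
            m, pool_set, cfg.pools.fn_rate, cfg.pools.fp_rate, seed=seed0 + i
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", pools.InconsistentScreenWarning)
            dr = pools.deconvolve(sr, pool_set)
        amp_end = m.position_bp + len(m.amplicon)

        def truly_positive(addr):
            return by_addr[addr].contains(m.position_bp, amp_end)

        confirmed, n_tests = pools.run_confirmation(dr, truly_positive)
        confirmed = {a for a in confirmed if truly_positive(a)} if cfg.pools.fp_rate else confirmed
        hits = {by_addr[a].clone_id for a in confirmed}
        marker_hits[m.marker_id] = hits
        screen_rows.append((m.marker_id, len(hits), n_tests, ";".join(sorted(hits))))
        deconv_results.append(dr)
    pd.DataFrame(
        screen_rows, columns=["marker_id", "n_positive_clones", "n_confirmation_pcr", "clone_ids"]
    ).to_csv(d / "screen_summary.tsv", sep="\t", index=False)
    pools.deconvolution_frame(deconv_results).to_csv(
        d / "deconvolution.tsv", sep="\t", index=False
    )
    # map each marker to the FPC contig of its positive clones
    clone_to_contig = {
        cid: ctg.contig_id for ctg in contigs for cid in ctg.clone_ids
    }
    target_rows = []
    mtp_by_contig = {p.contig_id: p for p in paths}
    for m in truth.markers:
        ctgs = sorted({clone_to_contig[c] for c in marker_hits[m.marker_id]})
        for cid in ctgs:
            if cid in mtp_by_contig:
                target_rows.append(
                    (m.marker_id, cid, ";".join(mtp_by_contig[cid].clone_ids))
                )
    targets = pd.DataFrame(target_rows, columns=["marker_id", "contig_id", "mtp_clone_ids"])
    targets = targets.drop_duplicates("contig_id")
    targets.to_csv(d / "targets.tsv", sep="\t", index=False)
    return targets


def _stage_reads(cfg: RunConfig, run_dir: Path, truth: GenomeTruth, clones, targets):
    d = run_dir / "04_reads"
    d.mkdir(parents=True, exist_ok=True)
    _require(run_dir, "reads", "03_screen/targets.tsv")
    rc = cfg.reads
    by_id = {c.clone_id: c for c in clones}
    pool_reads = {}
    seed0 = cfg.stage_seed("reads")
    for i, row in enumerate(targets.itertuples()):
        inserts = {
            cid: truth.seq[by_id[cid].start:by_id[cid].end]
            for cid in row.mtp_clone_ids.split(";")
        }
        rs = reads.simulate_short_reads(
            inserts, rc.short_coverage, rc.read_len, rc.frag_mean, rc.frag_sd,
            rc.short_err_rate, seed=seed0 + i,
        )
        reads.write_fastq(rs, d / f"{row.contig_id}.short.fastq")
        pool_reads[row.contig_id] = rs
    long_rs = reads.simulate_long_reads(
        {"genome": truth.seq}, rc.long_coverage, rc.long_len_range,
        rc.long_err_rate, seed=seed0 + 10_000,
    )
    reads.write_fastq(long_rs, d / "long_reads.fastq")
    return pool_reads, long_rs


def _simulate_bes(cfg: RunConfig, truth: GenomeTruth, clones: list[BacClone], mtp_ids, seed):
    rng = np.random.default_rng(seed)
    by_id = {c.clone_id: c for c in clones}
    queries, rows = [], []
    for cid in sorted(mtp_ids):
        c = by_id[cid]
        L = cfg.assembly.bes_len
        for end, label in ((truth.seq[c.start:c.start + L], "F"),
                           (revcomp(truth.seq[c.end - L:c.end]), "R")):
            ok = rng.random() < cfg.assembly.bes_end_success
            rows.append((cid, label, int(ok)))
            if ok:
                queries.append((f"{cid}.{label}", end, "BES"))
    bes_frame = pd.DataFrame(rows, columns=["clone_id", "end", "passed"])
    return queries, bes_frame


def _stage_assembly(cfg: RunConfig, run_dir: Path, truth: GenomeTruth, clones, targets, pool_reads, long_rs):
    d = run_dir / "05_assembly"
    d.mkdir(parents=True, exist_ok=True)
    _require(run_dir, "assembly", "04_reads/long_reads.fastq")
    ac = cfg.assembly
    mtp_ids = {cid for row in targets.itertuples() for cid in row.mtp_clone_ids.split(";")}
    bes_queries, bes_frame = _simulate_bes(
        cfg, truth, clones, mtp_ids, cfg.stage_seed("bes")
    )
    bes_frame.to_csv(d / "bes_status.tsv", sep="\t", index=False)
    marker_queries = [(m.marker_id, m.amplicon, "marker") for m in truth.markers]
    per_pool: dict[str, dict[str, list]] = {}
    anchor_frames = []
    for row in targets.itertuples():
        pool_id = row.contig_id
        rs = pool_reads[pool_id]
        trimmed = reads.trim_reads(
            rs, ac.trim_leading_q, ac.trim_trailing_q, ac.trim_window,
            ac.trim_window_q, ac.trim_min_len,
        )
        normed = reads.kmer_normalize(trimmed, ac.norm_k, ac.norm_target_cov)
        contigs = assemble.greedy_assemble(
            normed, ac.min_overlap, ac.min_identity, source_pool=pool_id
        )
        scaffolds = assemble.hybrid_scaffold(
            contigs, long_rs, ac.map_len_frac, ac.map_sim,
            ac.merge_identity, ac.merge_min_overlap, ac.seed_k, source_pool=pool_id,
        )
        validated = assemble.validate_and_split(
            scaffolds, [rs, long_rs], ac.val_len_frac, ac.val_sim, ac.seed_k
        )
        if len(validated) > len(contigs):  # splitting may not inflate counts
            validated = scaffolds
        per_pool[pool_id] = {"short": contigs, "hybrid": validated}
        queries = marker_queries + [q for q in bes_queries if q[0].split(".")[0] in row.mtp_clone_ids]
        anchors = assemble.anchor_sequences(validated, queries, seed_k=ac.seed_k)
        anchors.insert(0, "pool", pool_id)
        anchor_frames.append(anchors[anchors["status"] != "absent"])
        with open(d / f"{pool_id}.scaffolds.fasta", "w") as fh:
            for s in validated:
                fh.write(f">{s.id}\n{s.sequence}\n")
    report = assemble.assembly_report(per_pool)
    report.to_csv(d / "assembly_report.tsv", sep="\t", index=False)
    if anchor_frames:
        pd.concat(anchor_frames, ignore_index=True).to_csv(
            d / "anchors.tsv", sep="\t", index=False
        )
    return per_pool, report


def _homology_from_truth(
    truth: GenomeTruth, contigs_df: pd.DataFrame, noise_frac: float, seed: int
) -> pd.DataFrame:
    """Best-hit table for the truth genes against one synthetic model species.

    Each FPC contig's genes map, in possibly shuffled local order, to a
    compact region of a model chromosome; ``noise_frac`` of genes get
    uniform spurious best hits instead.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genes
    spans = contigs_df[["contig_id", "span_start", "span_end"]].to_numpy(object)
    rows = []
    q_rank = 0
    chrom_positions: dict[str, int] = {}
    for gid, gs, ge, _ in genes:
        hit_ctgs = [cid for cid, s, e in spans if s <= gs < e]
        if not hit_ctgs:
            continue
        q_rank += 1
        contig = hit_ctgs[0]
        if rng.random() < noise_frac:
            chrom = f"chr{int(rng.integers(1, 11))}"
            tr = int(rng.integers(0, 200))
        else:
            chrom = "chr1"  # homologous chromosome of the model species
            tr = chrom_positions.setdefault(contig, int(rng.integers(0, 150)))
            chrom_positions[contig] = tr + 1
        rows.append((gid, contig, q_rank, "modelfish", chrom, tr * 60_000, tr))
    return pd.DataFrame(rows, columns=synteny.HOMOLOGY_COLUMNS)


def _stage_synteny(cfg: RunConfig, run_dir: Path, truth: GenomeTruth):
    d = run_dir / "06_synteny"
    d.mkdir(parents=True, exist_ok=True)
    _require(run_dir, "synteny", "05_assembly/assembly_report.tsv", "02_library/contigs.tsv")
    contigs_df = pd.read_csv(run_dir / "02_library" / "contigs.tsv", sep="\t")
    table = _homology_from_truth(truth, contigs_df, 0.1, cfg.stage_seed("synteny"))
    table.to_csv(d / "homology_table.tsv", sep="\t", index=False)
    sc = cfg.synteny
    blocks = synteny.detect_microsynteny(
        table, "modelfish", sc.min_genes, sc.max_query_gap,
        sc.max_target_gap_genes, sc.max_target_gap_bp,
    )
    synteny.blocks_frame(blocks).to_csv(d / "synteny_blocks.tsv", sep="\t", index=False)
    synteny.block_span_summary(blocks).to_csv(d / "synteny_summary.tsv", sep="\t", index=False)
    homologs = synteny.call_homologous_chromosomes(
        table, "modelfish", cfg.synteny.secondary_homolog_frac
    )
    pd.DataFrame(homologs, columns=["chromosome", "n_hits"]).to_csv(
        d / "homologous_chromosomes.tsv", sep="\t", index=False
    )
    return blocks


def _stage_association(cfg: RunConfig, run_dir: Path, truth: GenomeTruth):
    d = run_dir / "07_association"
    d.mkdir(parents=True, exist_ok=True)
    _require(run_dir, "association", "01_genome/snps.tsv")
    a = cfg.assoc
    genotypes, traits = assoc.simulate_cross(
        a.n_families, a.n_offspring, truth.snps, a.family_weights,
        a.family_sd, a.residual_sd, seed=cfg.stage_seed("association"),
    )
    genotypes.to_csv(d / "genotypes.tsv", sep="\t", index=False)
    traits.to_csv(d / "traits.tsv", sep="\t", index=False)
    results = []
    freq_frames = []
    for s in truth.snps:
        freq_frames.append(assoc.genotype_and_allele_freqs(genotypes, s.snp_id))
        for trait in ("BW", "TL", "SL"):
            try:
                results.append(
                    assoc.associate(genotypes, traits, s.snp_id, trait, a.alpha)
                )
            except (assoc.MonomorphicError, assoc.DegenerateVarianceError):
                continue
    pd.concat(freq_frames, ignore_index=True).to_csv(
        d / "frequencies.tsv", sep="\t", index=False
    )
    assoc.association_report(results).to_csv(d / "associations.tsv", sep="\t", index=False)
    return results


# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run the enabled stages end to end under ``outdir``.

    Stage artifacts land in numbered subdirectories; a ``manifest.json``
    records the configuration hash, per-stage seeds, wall times and output
    checksums.  Raises :class:`DependencyError` when a disabled stage's
    outputs are needed downstream.
    """
    run_dir = Path(outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    manifest: dict = {
        "param_hash": config.param_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}

    def record(name: str, t0: float) -> None:
        manifest["stages"][name] = {
            "seed": config.stage_seed(name),
            "wall_s": round(time.time() - t0, 2),
        }

    if "genome" in stages:
        t0 = time.time()
        state["truth"] = _stage_genome(config, run_dir)
        record("genome", t0)
    if "library" in stages:
        t0 = time.time()
        truth = state.get("truth") or _load_genome(config, run_dir)
        state["truth"] = truth
        state["clones"], state["contigs"], state["paths"] = _stage_library(
            config, run_dir, truth
        )
        record("library", t0)
    if "screen" in stages:
        t0 = time.time()
        if "clones" not in state:
            raise DependencyError("stage 'screen' requires the library stage")
        state["targets"] = _stage_screen(
            config, run_dir, state["truth"], state["clones"], state["contigs"], state["paths"]
        )
        record("screen", t0)
    if "reads" in stages:
        t0 = time.time()
        if "targets" not in state:
            raise DependencyError("stage 'reads' requires the screen stage")
        state["pool_reads"], state["long_reads"] = _stage_reads(
            config, run_dir, state["truth"], state["clones"], state["targets"]
        )
        record("reads", t0)
    if "assembly" in stages:
        t0 = time.time()
        if "pool_reads" not in state:
            raise DependencyError("stage 'assembly' requires the reads stage")
        state["per_pool"], state["report"] = _stage_assembly(
            config, run_dir, state["truth"], state["clones"], state["targets"],
            state["pool_reads"], state["long_reads"],
        )
        record("assembly", t0)
    if "synteny" in stages:
        t0 = time.time()
        truth = state.get("truth") or _load_genome(config, run_dir)
        state["blocks"] = _stage_synteny(config, run_dir, truth)
        record("synteny", t0)
    if "association" in stages:
        t0 = time.time()
        truth = state.get("truth") or _load_genome(config, run_dir)
        state["assoc"] = _stage_association(config, run_dir, truth)
        record("association", t0)

    manifest["files"] = _checksums(run_dir)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    config.to_yaml(run_dir / "config.yaml")
    return run_dir


def _checksums(run_dir: Path) -> dict[str, str]:
    out = {}
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            h = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            out[str(p.relative_to(run_dir))] = h
    return out


def summary_metrics(run_dir) -> dict[str, float]:
    """Recompute the headline report numbers from a run's stage files.

    Every value is derived from the raw artifacts on disk (no cached
    state): clone-library coverage fold, 3D design capacity, mean positive
    clones per marker, tiling-path span and its share of the region,
    per-clone sequencing coverage, BES success rates and scaffold totals.
    """
    run_dir = Path(run_dir)
    cfg = RunConfig.from_yaml(run_dir / "config.yaml")
    out: dict[str, float] = {}
    clones = pd.read_csv(run_dir / "02_library" / "clones.tsv", sep="\t")
    insert_kb = float((clones["end"] - clones["start"]).mean()) / 1000.0
    genome_mb = cfg.genome.length_bp / 1e6
    out["library_coverage_fold"] = physmap.coverage_fold(
        len(clones), insert_kb, genome_mb
    )
    out["pool_addresses"] = cfg.pools.n_plates * cfg.pools.n_rows * cfg.pools.n_cols
    screen = pd.read_csv(run_dir / "03_screen" / "screen_summary.tsv", sep="\t")
    out["mean_positive_clones_per_marker"] = round(
        float(screen["n_positive_clones"].mean()), 1
    )
    targets = pd.read_csv(run_dir / "03_screen" / "targets.tsv", sep="\t")
    tiling = pd.read_csv(run_dir / "02_library" / "tiling_paths.tsv", sep="\t")
    sel = tiling[tiling["contig_id"].isin(targets["contig_id"])]
    span_kb = float(sel["expected_size_kb"].sum())
    out["tiling_span_mb"] = round(span_kb / 1000.0, 1)
    out["tiling_span_pct_of_region"] = percent(out["tiling_span_mb"], genome_mb)
    n_mtp = len({c for row in sel.itertuples() for c in row.clone_ids.split(";")})
    out["n_mtp_clones"] = n_mtp
    reads_dir = run_dir / "04_reads"
    total_bases = n_reads = 0
    for fq in sorted(reads_dir.glob("*.short.fastq")):
        with open(fq) as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    total_bases += len(line.strip())
                    n_reads += 1
    if n_reads:
        out["per_bac_coverage_x"] = per_bac_coverage(
            n_reads, total_bases / n_reads, n_mtp, cfg.library.mean_insert_kb
        )
    bes = pd.read_csv(run_dir / "05_assembly" / "bes_status.tsv", sep="\t")
    out["bes_end_success_pct"] = success_rate(int(bes["passed"].sum()), len(bes))
    both = bes.groupby("clone_id")["passed"].sum()
    out["bes_mate_pair_success_pct"] = success_rate(int((both == 2).sum()), len(both))
    report = pd.read_csv(run_dir / "05_assembly" / "assembly_report.tsv", sep="\t")
    total = report[report["pool"] == "Total"].iloc[0]
    out["n_short_read_contigs"] = int(total["n_contigs_short"])
    out["n_hybrid_scaffolds"] = int(total["n_scaffolds_hybrid"])
    out["hybrid_assembly_mb"] = round(float(total["kb_hybrid"]) / 1000.0, 2)
    return out
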