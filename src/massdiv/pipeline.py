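"""End-to-end orchestration: simulate/load -> QC -> screen -> cluster ->
diversity -> community.

Every stage writes its outputs and ledgers under the configured output
directory and contributes read counts plus file checksums to a run
manifest, so a rerun with the same config and seeds is byte-reproducible
and count conservation (input = pass + rejects at each stage) can be
audited.  With ``resume=True`` existing stage outputs are loaded instead
of recomputed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import community as communitymod
from . import diversity as diversitymod
from . import io as iomod
from .otucluster import (build_otu_table, cluster_otus, distance_matrix,
                         extract_regions)
from .orfscreen import default_panel, screen
from .readqc import QCParams, demultiplex, filter_reads
from .seqsim import CommunitySpec, ErrorModel, default_references, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run."""

    output_dir: str
    reads_path: str | None = None         # load instead of simulate
    barcode_map_path: str | None = None
    community: CommunitySpec = field(default_factory=CommunitySpec)
    error: ErrorModel = field(default_factory=ErrorModel)
    qc: QCParams = field(default_factory=QCParams)
    threshold: float = 0.04               # species-level distance cutoff
    linkage: str = "nearest"
    subsample_depth: int | None = None    # None -> smallest site total
    min_sites_cosmopolitan: int = 10
    nmds_starts: int = 20
    seed: int = 0
    resume: bool = False


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written as JSON).

    The manifest carries, per stage, the input/output read counts and the
    sha256 checksum of every file the stage wrote.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.seed}

    def record(stage: str, counts: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "counts": counts,
            "files": {f.name: _sha256(f) for f in files},
        }

    # ---- stage: reads (simulate or load) -------------------------------
    reads_fq = out / "reads.fastq"
    barcodes_tsv = out / "barcodes.tsv"
    truth_tsv = out / "truth.tsv"
    if config.reads_path:
        reads = iomod.read_fastq(config.reads_path)
        barcode_map = (iomod.read_barcode_map(config.barcode_map_path)
                       if config.barcode_map_path else {})
        files = []
    elif config.resume and reads_fq.exists() and barcodes_tsv.exists():
        reads = iomod.read_fastq(reads_fq)
        barcode_map = iomod.read_barcode_map(barcodes_tsv)
        files = [reads_fq, barcodes_tsv]
    else:
        spec = config.community
        references = default_references(spec.n_otus, seed=spec.seed)
        reads, truth = generate_dataset(spec, config.error, references)
        barcodes = truth.attrs["barcodes"]
        iomod.write_fastq(reads, reads_fq)
        iomod.write_barcode_map(barcodes, barcodes_tsv)
        iomod.write_truth(truth, truth_tsv)
        barcode_map = {bc: site for site, bc in barcodes.items()}
        files = [reads_fq, barcodes_tsv, truth_tsv]
    record("reads", {"raw": len(reads)}, files)

    # ---- stage: qc ------------------------------------------------------
    if barcode_map:
        reads = demultiplex(reads, barcode_map)
    kept, qc_report = filter_reads(reads, config.qc)
    qc_tsv = out / "qc_report.tsv"
    pd.Series(qc_report.verdicts, name="verdict").rename_axis("read_id") \
        .to_csv(qc_tsv, sep="\t")
    counts = dict(qc_report.counts)
    if sum(counts.values()) != len(reads):
        raise RuntimeError("QC ledger does not reconcile with input count")
    record("qc", {"in": len(reads), **counts}, [qc_tsv])

    # ---- stage: screen --------------------------------------------------
    panel = default_panel()
    accepted, screen_report = screen(kept, panel)
    screen_tsv = out / "screen_ledger.tsv"
    pd.Series(screen_report.verdicts, name="verdict").rename_axis("read_id") \
        .to_csv(screen_tsv, sep="\t")
    accepted_fa = out / "accepted_proteins.fasta"
    iomod.write_fasta({t.read_id: t.protein for t in accepted}, accepted_fa)
    record("screen", {"in": len(kept), **dict(screen_report.counts)},
           [screen_tsv, accepted_fa])

    # ---- stage: cluster -------------------------------------------------
    extracts, dropped = extract_regions(accepted)
    if not extracts:
        raise RuntimeError("cluster stage: no sequences cover the region")
    dm, rep, _mult = distance_matrix(extracts)
    assignment = cluster_otus(dm, config.threshold, config.linkage)
    table = build_otu_table(assignment, [e.site for e in extracts], rep,
                            dm_labels=dm.labels)
    table_tsv = out / "otu_table.tsv"
    iomod.write_otu_table(table, table_tsv)
    record("cluster", {"in": len(accepted), "region_dropped": len(dropped),
                       "clustered": len(extracts),
                       "otus": int(table.shape[1])}, [table_tsv])

    # ---- stage: diversity ----------------------------------------------
    report = diversitymod.table_report(table, config.subsample_depth,
                                       seed=config.seed)
    report_tsv = out / "diversity_report.tsv"
    report.to_csv(report_tsv, sep="\t")
    occupancy = diversitymod.classify_occupancy(
        table, config.min_sites_cosmopolitan) if len(table.index) >= 2 else {}
    occ_tsv = out / "occupancy.tsv"
    pd.Series(occupancy, name="class").rename_axis("otu").to_csv(occ_tsv, sep="\t")
    record("diversity", {"sites": int(table.shape[0])}, [report_tsv, occ_tsv])

    # ---- stage: community ----------------------------------------------
    files = []
    if len(table.index) >= 3:
        bc = communitymod.bray_curtis(table)
        bc_tsv = out / "bray_curtis.tsv"
        bc.to_dataframe().to_csv(bc_tsv, sep="\t")
        ordination = communitymod.nmds(bc, n_starts=config.nmds_starts,
                                       seed=config.seed)
        nmds_tsv = out / "nmds.tsv"
        ordination.coordinates.assign(stress=ordination.stress) \
            .to_csv(nmds_tsv, sep="\t")
        dendro = communitymod.ward_cluster(bc)
        nwk = out / "dendrogram.nwk"
        nwk.write_text(dendro.to_newick() + "\n")
        cooc = communitymod.cooccurrence(table)
        cooc_tsv = out / "cooccurrence.tsv"
        cooc.to_csv(cooc_tsv, sep="\t")
        files = [bc_tsv, nmds_tsv, nwk, cooc_tsv]
        record("community", {"sites": int(table.shape[0]),
                             "nmds_stress": ordination.stress}, files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
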