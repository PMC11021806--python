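"""End-to-end pipeline: extraction -> distances -> clustering -> consensus
-> QC flags, plus report generation.

The pipeline is deterministic: identical inputs (in any read order) produce
byte-identical outputs, and chunked (multi-process) extraction produces the
same result as single-process extraction because per-read results are
collected in input order and all downstream tie-breaks are explicit.
"""

from __future__ import annotations

import json
import multiprocessing
import sys
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from . import __version__
from .clustering import Cluster, build_seed_clusters, merge_all
from .consensus import FinalCluster, finalize_cluster
from .design_io import (
    CLUSTER_COLUMNS,
    LibraryDesign,
    LongRead,
    Params,
    read_clusters_table,
    read_long_reads,
    write_clusters_table,
)
from .distance import build_neighbor_index
from .errors import SchemaError
from .extraction import (
    ExtractedRead,
    ReadRejection,
    align_read,
    extract,
    parse_nt_string,
    passes_barcode_quality,
)
from .qc_flags import (
    BarcodeCollisionReport,
    ChimeraSet,
    detect_chimeras,
    detect_nonunique,
    homopolymer_flag,
)

_WORKER_STATE: dict = {}


def _init_worker(design, params, try_reverse):
    _WORKER_STATE["args"] = (design, params, try_reverse)


def _extract_one_global(read: LongRead):
    design, params, try_reverse = _WORKER_STATE["args"]
    return _extract_one(read, design, params, try_reverse)


def _extract_one(
    read: LongRead, design: LibraryDesign, params: Params, try_reverse: bool
) -> Union[ExtractedRead, ReadRejection]:
    aln = align_read(read, design, try_reverse=try_reverse)
    if isinstance(aln, ReadRejection):
        return aln
    er = extract(aln, design)
    if isinstance(er, ReadRejection):
        return er
    if not passes_barcode_quality(er, params):
        return ReadRejection(read.read_id, "low_barcode_qual")
    return er


@dataclass
class PipelineResult:
    final_clusters: list[FinalCluster]
    collision_reports: list[BarcodeCollisionReport]
    chimera_sets: list[ChimeraSet]
    rejected: list[ReadRejection]
    cluster_rows: list[dict]
    manifest: dict

    @property
    def clusters_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.cluster_rows, columns=CLUSTER_COLUMNS)


def run_pipeline(
    reads: Union[str, Path, Iterable[LongRead]],
    design: LibraryDesign,
    params: Params = Params(),
    *,
    virtual_barcodes: bool = True,
    threads: int = 1,
    try_reverse: bool = True,
    out_dir: Optional[Union[str, Path]] = None,
    audit: Optional[list] = None,
) -> PipelineResult:
    """Run the full pipeline over a FASTQ path or an iterable of reads."""
    if isinstance(reads, (str, Path)):
        read_list = list(read_long_reads(reads))
        input_path = str(reads)
    else:
        read_list = list(reads)
        input_path = "<in-memory>"

    if threads > 1:
        ctx = multiprocessing.get_context("fork")
        with ctx.Pool(
            threads, initializer=_init_worker, initargs=(design, params, try_reverse)
        ) as pool:
            results = pool.map(_extract_one_global, read_list, chunksize=64)
    else:
        results = [_extract_one(r, design, params, try_reverse) for r in read_list]

    rejected = [r for r in results if isinstance(r, ReadRejection)]
    retained = [r for r in results if isinstance(r, ExtractedRead)]

    if virtual_barcodes:
        key_of = lambda er: er.virtual_barcode  # noqa: E731
    else:
        key_of = lambda er: er.barcodes[0]  # noqa: E731

    groups: dict[str, list[ExtractedRead]] = {}
    for er in retained:
        groups.setdefault(key_of(er), []).append(er)

    seeds: list[Cluster] = []
    for key in sorted(groups):
        seeds.extend(
            build_seed_clusters(groups[key], params, key, id_start=len(seeds))
        )

    index = build_neighbor_index(groups.keys(), max(params.max_ed, 1))
    final = merge_all(seeds, index, params, audit=audit)

    final_clusters = [
        finalize_cluster(c, design, params, virtual_barcodes=virtual_barcodes)
        for c in final
    ]
    collision_reports = detect_nonunique(final_clusters, params)
    status_of = {
        cid: rep.status for rep in collision_reports for cid in rep.cluster_ids
    }
    chimera_sets: list[ChimeraSet] = []
    if design.n_loci == 2 and virtual_barcodes:
        chimera_sets = detect_chimeras(final_clusters, params)
    elif design.n_loci == 2 and not virtual_barcodes:
        print(
            "warning: virtual barcodes disabled; chimera detection skipped",
            file=sys.stderr,
        )
    chimeric = {cid for cs in chimera_sets for cid in cs.cluster_ids}

    # public ids follow the output row order (descending size, then barcode)
    ordered = sorted(
        final_clusters,
        key=lambda fc: (
            -fc.size,
            fc.clustering_barcode,
            fc.cluster.reads[0].read_id,
        ),
    )
    public_id = {
        fc.cluster.cluster_id: f"c{i + 1:05d}" for i, fc in enumerate(ordered)
    }
    rows = []
    for fc in ordered:
        nt = ";".join(v.nt_string() for v in fc.consensus.genotype_nt) or "="
        rows.append(
            {
                "cluster_id": public_id[fc.cluster.cluster_id],
                "consensus_barcode": fc.clustering_barcode,
                "up_barcode": fc.up_barcode,
                "down_barcode": fc.down_barcode,
                "virtual_barcode": fc.virtual_barcode,
                "size": fc.size,
                "reads": ",".join(r.read_id for r in fc.cluster.reads),
                "genotype_nt": nt,
                "genotype_aa": ";".join(fc.consensus.genotype_aa),
                "collision": status_of[fc.cluster.cluster_id],
                "chimera": int(fc.cluster.cluster_id in chimeric),
            }
        )

    n_retained = len(retained)
    size_sum = sum(fc.size for fc in final_clusters)
    if size_sum != n_retained:
        raise AssertionError(
            f"clusters do not partition retained reads ({size_sum} != {n_retained})"
        )
    reject_counts: dict[str, int] = {}
    for r in rejected:
        reject_counts[r.reason] = reject_counts.get(r.reason, 0) + 1
    manifest = {
        "version": __version__,
        "input": input_path,
        "params": asdict(params),
        "virtual_barcodes": virtual_barcodes,
        "threads": threads,
        "counts": {
            "input_reads": len(read_list),
            "rejected": len(rejected),
            "rejected_by_reason": dict(sorted(reject_counts.items())),
            "retained": n_retained,
            "seed_clusters": len(seeds),
            "final_clusters": len(final_clusters),
            "cluster_size_sum": size_sum,
        },
    }

    result = PipelineResult(
        final_clusters=final_clusters,
        collision_reports=collision_reports,
        chimera_sets=chimera_sets,
        rejected=rejected,
        cluster_rows=rows,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), public_id)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path, public_id: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_clusters_table(result.cluster_rows, out_dir / "clusters.tsv")
    with open(out_dir / "collisions.tsv", "w") as fh:
        fh.write("barcode\tstatus\ttotal_reads\tdominant_fraction\tcluster_ids\n")
        for rep in result.collision_reports:
            ids = ",".join(public_id[c] for c in rep.cluster_ids)
            fh.write(
                f"{rep.barcode}\t{rep.status}\t{rep.total_reads}\t"
                f"{rep.dominant_fraction:.6g}\t{ids}\n"
            )
    with open(out_dir / "chimeras.tsv", "w") as fh:
        fh.write("upstream_barcode\toverlap_kind\tcluster_ids\n")
        for cs in result.chimera_sets:
            ids = ",".join(public_id[c] for c in cs.cluster_ids)
            fh.write(f"{cs.upstream_barcode}\t{cs.overlap_kind}\t{ids}\n")
    with open(out_dir / "rejected.tsv", "w") as fh:
        fh.write("read_id\treason\n")
        for r in result.rejected:
            fh.write(f"{r.read_id}\t{r.reason}\n")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report(
    clusters_tsv: Union[str, Path], design: Optional[LibraryDesign] = None
) -> dict:
    """Deterministic summary of a clusters table.

    Includes the cluster-size histogram, the distribution of variant counts
    per cluster, collision and chimera tallies, and — when a design is
    supplied — the fraction of frameshift indel calls sitting at the 5' end
    of reference homopolymer runs (length >= 4).
    """
    df = read_clusters_table(clusters_tsv)
    try:
        sizes = df["size"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"column 'size' is not integer: {exc}")
    size_hist = dict(sorted(sizes.value_counts().items()))
    n_variants = [
        0 if nt == "=" else len(nt.split(";")) for nt in df["genotype_nt"]
    ]
    var_hist: dict[int, int] = {}
    for n in n_variants:
        var_hist[n] = var_hist.get(n, 0) + 1
    collision_tally = dict(sorted(df["collision"].value_counts().items()))
    summary = {
        "n_clusters": int(len(df)),
        "cluster_size_histogram": {int(k): int(v) for k, v in size_hist.items()},
        "variant_count_distribution": dict(sorted(var_hist.items())),
        "collision_tally": {str(k): int(v) for k, v in collision_tally.items()},
        "n_chimeric_clusters": int(df["chimera"].astype(int).sum()),
    }
    if design is not None:
        fs_total = 0
        fs_homopolymer = 0
        for nt in df["genotype_nt"]:
            if nt == "=":
                continue
            for vs in nt.split(";"):
                v = parse_nt_string(vs)
                if v.vtype == "SNV":
                    continue
                indel_len = len(v.ref_allele) or len(v.alt_allele)
                if indel_len % 3 == 0 or not design.orf.overlaps(v.ref_pos, max(v.end, v.ref_pos + 1)):
                    continue
                fs_total += 1
                if homopolymer_flag(v, design.reference_seq):
                    fs_homopolymer += 1
        summary["frameshift_calls"] = fs_total
        summary["frameshift_homopolymer_fraction"] = (
            fs_homopolymer / fs_total if fs_total else 0.0
        )
    return summary
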