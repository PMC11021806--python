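"""Library design, run parameters, and the standard file formats.

A *library design* ties together the reference amplicon sequence, the
coordinates of one or two barcode loci, and the coordinates of the
mutagenized ORF.  All coordinates are 0-based half-open internally;
human-readable variant strings are 1-based (see :mod:`barclust.extraction`).

The design file is a small flat YAML document::

    reference: myAmplicon          # optional, must match the FASTA id if given
    barcode_upstream: [20, 45]     # 0-based half-open; "20-45" also accepted
    barcode_downstream: [400, 425] # optional second locus
    orf: [60, 393]
    orf_strand: "+"                # forward only

Cluster tables are plain TSV with a fixed, documented column set
(:data:`CLUSTER_COLUMNS`) and a deterministic row order (descending size,
then lexicographic consensus barcode).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import (
    ConfigError,
    DesignError,
    DesignOverlapError,
    FastqFormatError,
    IntervalBoundsError,
    LocusOrderError,
    MultiRecordFastaError,
    OrfFrameError,
    ReverseStrandError,
    SchemaError,
)

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"

#: Column order of the clusters TSV.
CLUSTER_COLUMNS = [
    "cluster_id",
    "consensus_barcode",
    "up_barcode",
    "down_barcode",
    "virtual_barcode",
    "size",
    "reads",
    "genotype_nt",
    "genotype_aa",
    "collision",
    "chimera",
]


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on the reference."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise IntervalBoundsError(f"bad interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class LibraryDesign:
    """Reference amplicon plus barcode-locus and ORF coordinates."""

    reference_seq: str
    barcode_loci: tuple[Interval, ...]  # locus order: upstream [, downstream]
    orf: Interval
    orf_strand: str = "+"
    name: str = "reference"

    def __post_init__(self):
        seq = self.reference_seq.upper()
        object.__setattr__(self, "reference_seq", seq)
        if not seq or set(seq) - set("ACGT"):
            bad = sorted(set(seq) - set("ACGT"))
            raise DesignError(
                f"reference must be non-empty ACGT (offending characters: {bad})"
            )
        n = len(seq)
        if self.orf_strand != "+":
            raise ReverseStrandError(
                "only forward-strand ORFs are supported (got "
                f"{self.orf_strand!r})"
            )
        if not 1 <= len(self.barcode_loci) <= 2:
            raise ConfigError("designs need 1 or 2 barcode loci")
        for iv in (*self.barcode_loci, self.orf):
            if iv.end > n:
                raise IntervalBoundsError(
                    f"interval [{iv.start},{iv.end}) exceeds reference length {n}"
                )
        if len(self.orf) % 3 != 0:
            raise OrfFrameError(
                f"orf length not divisible by 3 (length {len(self.orf)})"
            )
        ivs = [*self.barcode_loci, self.orf]
        for i, a in enumerate(ivs):
            for b in ivs[i + 1 :]:
                if a.overlaps(b.start, b.end):
                    raise DesignOverlapError(
                        f"intervals [{a.start},{a.end}) and [{b.start},{b.end}) overlap"
                    )
        if len(self.barcode_loci) == 2:
            up, down = self.barcode_loci
            if not up.start < down.start:
                raise LocusOrderError("upstream locus must start before downstream")

    @property
    def n_loci(self) -> int:
        return len(self.barcode_loci)

    @property
    def locus_tags(self) -> tuple[str, ...]:
        return (UPSTREAM,) if self.n_loci == 1 else (UPSTREAM, DOWNSTREAM)

    def in_barcode_locus(self, pos: int) -> bool:
        return any(iv.contains(pos) for iv in self.barcode_loci)


@dataclass(frozen=True)
class Params:
    """Tunable thresholds of the clustering pipeline.

    min_barcode_qual
        Reads whose minimum phred quality inside the barcode loci falls below
        this are dropped (default Q62; far above single-pass accuracy, so any
        doubtful barcode base disqualifies the read).
    max_ed
        Maximum barcode edit distance considered during cluster merging.
    jaccard_min
        Minimum Jaccard index of candidate-variant sets for reads/clusters to
        be considered genotype-coherent (inclusive).
    min_var_qual
        A candidate variant seen in only one read is discarded unless its
        quality reaches this threshold.
    remediable_fraction
        A nonunique barcode is *remediable* when a single clone holds strictly
        more than this fraction of the barcode's reads.
    chimera_downstream_min_ed
        Minimum downstream-barcode edit distance for two clusters to count as
        "entirely different"; defaults to ``max_ed + 1`` (beyond merge range).
    """

    min_barcode_qual: int = 62
    max_ed: int = 2
    jaccard_min: float = 0.2
    min_var_qual: int = 90
    remediable_fraction: float = 2.0 / 3.0
    chimera_downstream_min_ed: int | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.min_barcode_qual < 0 or self.min_var_qual < 0:
            raise ConfigError("phred thresholds must be >= 0")
        if self.max_ed < 0:
            raise ConfigError("max_ed must be >= 0")
        if not 0.0 <= self.jaccard_min <= 1.0:
            raise ConfigError("jaccard_min must be in [0,1]")
        if not 0.0 < self.remediable_fraction < 1.0:
            raise ConfigError("remediable_fraction must be in (0,1)")
        if self.chimera_downstream_min_ed is None:
            object.__setattr__(self, "chimera_downstream_min_ed", self.max_ed + 1)
        elif self.chimera_downstream_min_ed < 1:
            raise ConfigError("chimera_downstream_min_ed must be >= 1")


@dataclass(frozen=True)
class LongRead:
    """One sequencing read with Sanger/phred+33 qualities (0..93)."""

    read_id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self):
        if len(self.seq) != len(self.quals):
            raise ConfigError("sequence/quality length mismatch")


def _parse_interval(value, key: str) -> Interval:
    if isinstance(value, str):
        try:
            lo, hi = value.replace(":", "-").split("-")
            return Interval(int(lo), int(hi))
        except (ValueError, IntervalBoundsError) as exc:
            if isinstance(exc, IntervalBoundsError):
                raise
            raise ConfigError(f"cannot parse interval for {key!r}: {value!r}")
    if isinstance(value, Sequence) and len(value) == 2:
        try:
            return Interval(int(value[0]), int(value[1]))
        except (TypeError, ValueError):
            raise ConfigError(f"cannot parse interval for {key!r}: {value!r}")
    raise ConfigError(f"cannot parse interval for {key!r}: {value!r}")


def load_design(reference_path, design_path) -> LibraryDesign:
    """Load and validate a library design from a FASTA + YAML config pair."""
    reference_path = Path(reference_path)
    design_path = Path(design_path)
    records = list(SeqIO.parse(str(reference_path), "fasta"))
    if len(records) != 1:
        raise MultiRecordFastaError(
            f"{reference_path} must contain exactly one record, found {len(records)}"
        )
    with open(design_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{design_path} is not a key-value design file")
    known = {"reference", "barcode_upstream", "barcode_downstream", "orf", "orf_strand"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown design keys: {sorted(unknown)}")
    if "barcode_upstream" not in cfg or "orf" not in cfg:
        raise ConfigError("design file needs 'barcode_upstream' and 'orf'")
    name = str(cfg.get("reference", records[0].id))
    if cfg.get("reference") is not None and name != records[0].id:
        raise ConfigError(
            f"design names reference {name!r} but FASTA record is {records[0].id!r}"
        )
    loci = [_parse_interval(cfg["barcode_upstream"], "barcode_upstream")]
    if cfg.get("barcode_downstream") is not None:
        loci.append(_parse_interval(cfg["barcode_downstream"], "barcode_downstream"))
    return LibraryDesign(
        reference_seq=str(records[0].seq).upper(),
        barcode_loci=tuple(loci),
        orf=_parse_interval(cfg["orf"], "orf"),
        orf_strand=str(cfg.get("orf_strand", "+")),
        name=records[0].id,
    )


def write_design(design: LibraryDesign, reference_path, design_path) -> None:
    """Write the FASTA + YAML pair read back by :func:`load_design`."""
    with open(reference_path, "w") as fh:
        fh.write(f">{design.name}\n")
        seq = design.reference_seq
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    cfg = {
        "reference": design.name,
        "barcode_upstream": [design.barcode_loci[0].start, design.barcode_loci[0].end],
        "orf": [design.orf.start, design.orf.end],
        "orf_strand": design.orf_strand,
    }
    if design.n_loci == 2:
        cfg["barcode_downstream"] = [
            design.barcode_loci[1].start,
            design.barcode_loci[1].end,
        ]
    with open(design_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _open_maybe_gzip(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_long_reads(path) -> Iterator[LongRead]:
    """Stream reads from a FASTQ(.gz) file in file order.

    Qualities are decoded as Sanger/phred+33 (values up to 93 accepted).
    A malformed record aborts with :class:`FastqFormatError` naming the
    0-based index of the offending record.
    """
    index = 0
    with _open_maybe_gzip(path) as fh:
        parser = SeqIO.parse(fh, "fastq")
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(index, str(exc)) from exc
            yield LongRead(
                read_id=rec.id,
                seq=str(rec.seq).upper(),
                quals=tuple(rec.letter_annotations["phred_quality"]),
            )
            index += 1


def write_long_reads(reads: Iterable[LongRead], path) -> None:
    """Write FASTQ (phred+33); gzipped when *path* ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")


def write_clusters_table(rows: Sequence[Mapping], path) -> None:
    """Write the clusters TSV.

    Rows are sorted by descending size, then lexicographic consensus barcode,
    then cluster_id, so output is deterministic regardless of input order.
    """
    df = pd.DataFrame(list(rows), columns=CLUSTER_COLUMNS)
    if len(df):
        df = df.sort_values(
            by=["size", "consensus_barcode", "cluster_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
    df.to_csv(path, sep="\t", index=False)


def read_clusters_table(path) -> pd.DataFrame:
    """Read a clusters TSV back; string columns stay strings bit-exactly."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clusters table missing columns: {missing}")
    df["size"] = df["size"].astype(int)
    df["chimera"] = df["chimera"].astype(int)
    return df
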