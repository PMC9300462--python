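"""Readers and writers for the interchange formats used by the pipeline.

Formats are deliberately plain: GFF3/BED for gene models, 12-column BLAST
tabular (outfmt-6 dialect: ``qseqid sseqid pident length mismatch gapopen
qstart qend sstart send evalue bitscore``) for protein hits, newick for
trees and TSV for matrices.  BLAST hit coordinates are 1-based inclusive
on disk and converted to 0-based half-open in memory.

All functions are free of randomness; read-write-read round-trips are
identity at the dialect level.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, List, Tuple

import dendropy
import pandas as pd

from amkarya.genome import GeneModel, Genome

logger = logging.getLogger("amkarya")

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path, species: str | None = None) -> Genome:
    """Read a GFF3 file with one ``gene`` feature per gene.

    The ``ID`` attribute is the gene id.  Order indices are recomputed
    from start coordinates; unsorted input is accepted and logged.
    """
    path = Path(path)
    if species is None:
        species = path.stem
    records: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "gene":
                continue
            gid = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gid = item[3:]
                    break
            if gid is None:
                raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
            records.append(
                GeneModel(
                    id=gid,
                    species=species,
                    chrom=chrom,
                    start=int(start) - 1,  # GFF3 is 1-based inclusive
                    end=int(end),
                    strand=strand,
                    order=0,
                )
            )
    if not records:
        logger.warning("read_gff3: %s contains no gene features", path)
    return Genome.from_records(species, records)


def write_gff3(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genome.genes():
            fh.write(
                f"{gene.chrom}\tamkarya\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.id}\n"
            )


def read_bed(path: str | Path, species: str | None = None) -> Genome:
    """Read a 6-column BED file of gene models (0-based half-open)."""
    path = Path(path)
    if species is None:
        species = path.stem
    records: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom, start, end, name, _, strand = fields[:6]
            records.append(
                GeneModel(
                    id=name,
                    species=species,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    order=0,
                )
            )
    if not records:
        logger.warning("read_bed: %s contains no intervals", path)
    return Genome.from_records(species, records)


def write_bed(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genome.genes():
            fh.write(
                f"{gene.chrom}\t{gene.start}\t{gene.end}\t{gene.id}\t0\t{gene.strand}\n"
            )


def read_intervals_bed(path: str | Path) -> pd.DataFrame:
    """Read a >=3-column BED of plain intervals (e.g. TE annotations)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            rows.append((fields[0], int(fields[1]), int(fields[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_intervals_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BLAST tabular hits
# ---------------------------------------------------------------------------


def read_hits(path: str | Path, drop_self: bool = True) -> pd.DataFrame:
    """Read a 12-column BLAST tabular file into a DataFrame.

    Self hits (query == subject) are excluded by default and counted in
    the log.  Query/subject coordinates stay 1-based inclusive in the
    returned frame, matching the on-disk dialect; downstream code
    converts where needed.
    """
    path = Path(path)
    rows = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            if drop_self and fields[0] == fields[1]:
                n_self += 1
                continue
            rows.append(fields)
    if n_self:
        logger.info("read_hits: excluded %d self hits from %s", n_self, path)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if len(df):
        df = df.astype(
            {
                "pident": float,
                "length": int,
                "mismatch": int,
                "gapopen": int,
                "qstart": int,
                "qend": int,
                "sstart": int,
                "send": int,
                "evalue": float,
                "bitscore": float,
            }
        )
    return df


def write_hits(df: pd.DataFrame, path: str | Path) -> None:
    out = df[HIT_COLUMNS].copy()
    out["pident"] = out["pident"].map(lambda v: f"{v:.2f}")
    out["evalue"] = out["evalue"].map(lambda v: f"{v:.2e}")
    out["bitscore"] = out["bitscore"].map(lambda v: f"{v:.1f}")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# trees and matrices
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="force-rooted"
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse newick file {path}: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labelled numeric TSV matrix (rows x columns)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# event logs
# ---------------------------------------------------------------------------


def read_event_log(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def write_event_log(records: Iterable[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(list(records), fh, indent=1)


def hits_coords_to_internal(qstart: int, qend: int) -> Tuple[int, int]:
    """Convert 1-based inclusive hit coordinates to 0-based half-open."""
    if qend < qstart:
        qstart, qend = qend, qstart
    return qstart - 1, qend
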