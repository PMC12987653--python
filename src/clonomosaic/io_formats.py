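"""Readers and writers for the standard file formats the pipeline touches.

Every external format (AIRR-C rearrangement TSV, 10x-style contig CSV, SAM,
GMT, MatrixMarket) is normalized here into the internal data model so the
analysis modules never see raw files.  Coordinates are 1-based inclusive on
the way in (SAM convention) and converted to 0-based only inside arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

CHAINS = ("TRA", "TRB")

#: mandatory AIRR-C rearrangement columns for single-cell V(D)J data
AIRR_COLUMNS = (
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "duplicate_count",
    "productive",
)

TENX_COLUMNS = (
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "umis",
    "productive",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One TCR contig observed in one cell."""

    cell_barcode: str
    chain: str  # "TRA" | "TRB"
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    umi_count: int
    productive: bool

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        if self.umi_count < 0:
            raise ValueError("umi_count must be non-negative")


@dataclass(frozen=True)
class CellAnnotation:
    """Per-cell metadata: which sample/tissue/type/group a barcode belongs to."""

    cell_barcode: str
    sample_id: str
    tissue: str  # "blood" | "gut"
    cell_type: str
    group: str


@dataclass(frozen=True)
class VariantLocus:
    """A single-nucleotide variant locus on the alignment reference (1-based)."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @classmethod
    def from_string(cls, spec: str, label: str = "") -> "VariantLocus":
        """Parse ``contig:pos:REF:ALT`` (e.g. ``chr1:115256530:G:A``)."""
        parts = spec.split(":")
        if len(parts) != 4:
            raise FormatError(f"locus spec must be contig:pos:REF:ALT, got {spec!r}")
        contig, pos, ref, alt = parts
        return cls(contig, int(pos), ref.upper(), alt.upper(), label or spec)


class RecordList(list):
    """A list of ClonotypeRecords carrying parse bookkeeping."""

    def __init__(self, records=(), n_malformed: int = 0, n_dropped_chain: int = 0):
        super().__init__(records)
        self.n_malformed = n_malformed
        self.n_dropped_chain = n_dropped_chain


_TRUE = {"t", "true", "1", "yes"}
_FALSE = {"f", "false", "0", "no", "none", ""}


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"unparseable boolean {value!r}")


def read_airr(path: str | Path) -> RecordList:
    """Read an AIRR-C rearrangement TSV into ClonotypeRecords.

    Non-productive rows are retained but flagged; rows whose locus is not
    TRA/TRB are dropped (counted); malformed rows are skipped (counted).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("empty AIRR file %s", path)
        return RecordList()
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"AIRR file {path} missing mandatory column(s): {', '.join(missing)}")
    records = RecordList()
    for row in df.itertuples(index=False):
        if row.locus not in CHAINS:
            records.n_dropped_chain += 1
            continue
        try:
            records.append(
                ClonotypeRecord(
                    cell_barcode=row.cell_id,
                    chain=row.locus,
                    v_gene=row.v_call,
                    j_gene=row.j_call,
                    cdr3_nt=row.junction,
                    cdr3_aa=row.junction_aa,
                    umi_count=int(float(row.duplicate_count)) if row.duplicate_count else 0,
                    productive=_parse_bool(row.productive),
                )
            )
        except (ValueError, TypeError):
            records.n_malformed += 1
    if records.n_malformed:
        logger.warning("%s: skipped %d malformed rows", path, records.n_malformed)
    if records.n_dropped_chain:
        logger.info("%s: dropped %d non-TRA/TRB rows", path, records.n_dropped_chain)
    if not records:
        logger.warning("no usable rows in %s", path)
    return records


def write_airr(records, path: str | Path) -> None:
    """Write ClonotypeRecords as an AIRR-C rearrangement TSV (round-trips read_airr)."""
    rows = [
        {
            "cell_id": r.cell_barcode,
            "locus": r.chain,
            "v_call": r.v_gene,
            "j_call": r.j_gene,
            "junction": r.cdr3_nt,
            "junction_aa": r.cdr3_aa,
            "duplicate_count": r.umi_count,
            "productive": "T" if r.productive else "F",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(AIRR_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_10x_contigs(path: str | Path) -> RecordList:
    """Read a 10x-style filtered_contig_annotations.csv.

    Chains other than TRA/TRB (e.g. IGH) are dropped with a logged count.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TENX_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig CSV {path} missing mandatory column(s): {', '.join(missing)}")
    records = RecordList()
    for row in df.itertuples(index=False):
        if row.chain not in CHAINS:
            records.n_dropped_chain += 1
            continue
        try:
            records.append(
                ClonotypeRecord(
                    cell_barcode=row.barcode,
                    chain=row.chain,
                    v_gene=row.v_gene,
                    j_gene=row.j_gene,
                    cdr3_nt=row.cdr3_nt,
                    cdr3_aa=row.cdr3,
                    umi_count=int(float(row.umis)) if row.umis else 0,
                    productive=_parse_bool(row.productive),
                )
            )
        except (ValueError, TypeError):
            records.n_malformed += 1
    if records.n_dropped_chain:
        logger.info("%s: dropped %d non-TCR-chain contigs", path, records.n_dropped_chain)
    return records


# --- SAM: per-read allele extraction at a locus ---------------------------

# CIGAR op codes: M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_CONSUMES_BOTH = {0, 7, 8}
_CONSUMES_REF_ONLY = {2, 3}
_CONSUMES_QUERY_ONLY = {1, 4}


def allele_at(cigartuples, reference_start: int, query_sequence: str, pos0: int) -> str | None:
    """Resolve the read base aligned to 0-based reference position ``pos0``.

    Walks the CIGAR explicitly: a deletion (D) spanning the position yields
    ``"del"``; a reference skip (N, splice) means the read does not cover the
    position and yields None; insertions consume query only and never map to
    a reference position.
    """
    rpos = reference_start
    qpos = 0
    for op, length in cigartuples:
        if op in _CONSUMES_BOTH:
            if rpos <= pos0 < rpos + length:
                return query_sequence[qpos + (pos0 - rpos)].upper()
            rpos += length
            qpos += length
        elif op == 2:  # deletion from the reference
            if rpos <= pos0 < rpos + length:
                return "del"
            rpos += length
        elif op == 3:  # reference skip (splice): not covered
            if rpos <= pos0 < rpos + length:
                return None
            rpos += length
        elif op in _CONSUMES_QUERY_ONLY:
            qpos += length
        # H (5) and P (6) consume neither
    return None


def read_tagged_alignments(
    path: str | Path,
    locus: VariantLocus,
    cb_tag: str = "CB",
    ub_tag: str = "UB",
) -> Iterator[tuple[str, str, str]]:
    """Stream (cell_barcode, umi, allele_observed) for reads spanning the locus.

    Only primary, mapped, non-duplicate alignments on the locus contig whose
    aligned span covers the position are yielded.  Reads lacking the barcode
    or UMI tag, or with unusable CIGARs, are skipped and counted (logged).
    """
    pos0 = locus.position - 1
    n_skipped_tags = n_skipped_cigar = n_yielded = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            if aln.reference_name != locus.contig:
                continue
            if aln.cigartuples is None or aln.query_sequence is None:
                n_skipped_cigar += 1
                continue
            if not (aln.reference_start <= pos0 < aln.reference_end):
                continue
            if not (aln.has_tag(cb_tag) and aln.has_tag(ub_tag)):
                n_skipped_tags += 1
                continue
            allele = allele_at(aln.cigartuples, aln.reference_start, aln.query_sequence, pos0)
            if allele is None:
                continue
            n_yielded += 1
            yield str(aln.get_tag(cb_tag)), str(aln.get_tag(ub_tag)), allele
    if n_skipped_tags:
        logger.info("%s: skipped %d reads lacking %s/%s tags", path, n_skipped_tags, cb_tag, ub_tag)
    if n_skipped_cigar:
        logger.info("%s: skipped %d reads with unusable CIGAR/sequence", path, n_skipped_cigar)
    if n_yielded == 0:
        logger.warning("%s: no usable alignments span %s:%d", path, locus.contig, locus.position)


# --- GMT gene sets --------------------------------------------------------


def read_gene_sets(path: str | Path, min_size: int = 1) -> dict[str, set[str]]:
    """Read a GMT gene-set collection; sets smaller than min_size are excluded."""
    sets: dict[str, set[str]] = {}
    n_excluded = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has {len(fields)} fields (need >= 3)")
            name, _desc, *genes = fields
            genes = {g for g in genes if g}
            if len(genes) < min_size:
                n_excluded += 1
                continue
            sets[name] = genes
    if n_excluded:
        logger.info("%s: excluded %d gene sets smaller than %d", path, n_excluded, min_size)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, "na", *sorted(sets[name])]) + "\n")


# --- MatrixMarket count matrices ------------------------------------------


def _read_sidecar(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts_mtx(
    matrix: str | Path, barcodes: str | Path, features: str | Path
) -> pd.DataFrame:
    """Read an MTX count matrix with barcode/feature sidecars as cells x genes.

    On-disk orientation is detected by matching dimensions to the sidecar
    lengths; a square matrix with equal-length sidecars is ambiguous and
    rejected.
    """
    mat = scipy.io.mmread(str(matrix))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    cells = _read_sidecar(barcodes)
    genes = _read_sidecar(features)
    nb, nf = len(cells), len(genes)
    if mat.shape == (nb, nf) and nb == nf:
        raise FormatError(
            f"square {mat.shape} matrix with {nb} barcodes and {nf} features: orientation ambiguous"
        )
    if mat.shape == (nb, nf):
        pass
    elif mat.shape == (nf, nb):
        mat = mat.T
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {nb} barcodes x {nf} features nor its transpose"
        )
    return pd.DataFrame(np.asarray(mat).astype(np.int64), index=cells, columns=genes)


def write_counts_mtx(
    counts: pd.DataFrame, matrix: str | Path, barcodes: str | Path, features: str | Path
) -> None:
    """Write a cells x genes count table as genes x cells MTX (CellRanger layout)."""
    sparse = scipy.sparse.csr_matrix(counts.to_numpy().T)
    scipy.io.mmwrite(str(matrix), sparse, field="integer")
    Path(barcodes).write_text("".join(f"{b}\n" for b in counts.index))
    Path(features).write_text("".join(f"{g}\n" for g in counts.columns))


# --- cell annotations ------------------------------------------------------

ANNOTATION_COLUMNS = ("cell_barcode", "sample_id", "tissue", "cell_type", "group")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-cell annotation TSV with (sample_id, cell_barcode) unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file {path} missing column(s): {', '.join(missing)}")
    if df.duplicated(subset=["sample_id", "cell_barcode"]).any():
        raise FormatError(f"annotation file {path}: duplicate (sample_id, cell_barcode) pairs")
    return df
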