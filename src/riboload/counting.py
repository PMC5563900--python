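"""Read-to-region assignment, count matrices, RPKM/densities and QC.

Reads are handled as a pandas DataFrame with one row per aligned read and
columns ``sample``, ``assay`` (RPF or mRNA), ``transcript``, ``start``
(1-based transcript coordinate of the 5' end) and ``length``. A read is
assigned to the region (5'UTR, CDS or 3'UTR) containing its 5'-end base,
so boundary-spanning reads are attributed unambiguously.

Normalisation follows the standard RPKM convention: reads per kilobase of
feature per million mapped reads, with the per-library total of assigned
reads as the "mapped reads" normalisation factor. Region densities use the
same count / length / library-size form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

logger = logging.getLogger(__name__)

READ_COLUMNS = ["sample", "assay", "transcript", "start", "length"]
REGION_ORDER = ["utr5", "cds", "utr3", "intron", "gene_total"]

#: pseudocount (in RPKM units) added before log2 for correlation QC
LOG_PSEUDOCOUNT = 1e-2


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read in transcript space."""

    sample_id: str
    assay: str  # "RPF" or "mRNA"
    transcript_id: str
    start: int  # 1-based transcript coordinate of the read 5' end
    length: int


def reads_to_frame(reads) -> pd.DataFrame:
    """Build the canonical read table from AlignedRead records or tuples."""
    rows = [
        (r.sample_id, r.assay, r.transcript_id, r.start, r.length)
        if isinstance(r, AlignedRead)
        else tuple(r)
        for r in reads
    ]
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["length"] = df["length"].astype(np.int64)
    return df


def read_alignment_tsv(path: str) -> pd.DataFrame:
    """Read the 5-column alignment TSV dialect.

    The identifier columns are loaded as categoricals: alignment tables
    run to millions of rows with only a handful of distinct samples.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample": "category", "assay": "category", "transcript": "category"},
    )
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[(df["start"] < 1) | (df["length"] < 1)]
    if len(bad):
        raise ValueError(
            f"{path}: {len(bad)} record(s) with non-positive start or length "
            f"(first at row {bad.index[0] + 2})"
        )
    return df[READ_COLUMNS].copy()


def write_alignment_tsv(reads: pd.DataFrame, path: str) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_alignment_sam(
    path: str,
    sample: str,
    assay: str,
    models: dict[str, TranscriptModel] | None = None,
) -> pd.DataFrame:
    """Read alignments from SAM/BAM into the canonical read table.

    Reference names are transcript ids by default. When ``models`` is
    given and reference names are chromosomes, genomic alignments are
    projected into transcript space through exon blocks (the 5' end of a
    minus-strand transcript alignment is the genomic end coordinate).
    Query names aligned to transcripts of more than one gene are discarded
    as gene-ambiguous.
    """
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    rows: list[tuple] = []
    by_query: dict[str, set[str]] = {}
    genomic = models is not None
    chrom_index: dict[str, list[TranscriptModel]] = {}
    if genomic:
        for m in models.values():
            chrom_index.setdefault(m.chrom, []).append(m)
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            ref = aln.reference_name
            length = aln.query_length or aln.infer_read_length() or 0
            if genomic and ref in chrom_index:
                hit = None
                for m in chrom_index[ref]:
                    gpos = (
                        aln.reference_start + 1
                        if m.strand == "+"
                        else aln.reference_end
                    )
                    try:
                        tpos = m.genomic_to_transcript(gpos)
                    except ValueError:
                        continue
                    hit = (m, tpos)
                    break
                if hit is None:
                    continue
                m, tpos = hit
                rows.append((sample, assay, m.transcript_id, tpos, length))
                by_query.setdefault(aln.query_name, set()).add(m.gene_id)
            else:
                rows.append((sample, assay, ref, aln.reference_start + 1, length))
                if models:
                    m = models.get(ref)
                    if m is not None:
                        by_query.setdefault(aln.query_name, set()).add(m.gene_id)
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    ambiguous = {q for q, genes in by_query.items() if len(genes) > 1}
    if ambiguous:
        logger.info("%d gene-ambiguous query name(s) discarded", len(ambiguous))
    return df


# ---------------------------------------------------------------------------
# counting


@dataclass
class CountMatrix:
    """Region x library count matrix.

    ``counts`` is indexed by (gene_id, region) with one column per
    (assay, sample) library; ``library_size`` maps each library to its
    total of assigned reads; ``rejected`` tallies off-transcript reads.
    """

    counts: pd.DataFrame
    library_size: pd.Series
    rejected: pd.Series

    def region(self, region: str) -> pd.DataFrame:
        return self.counts.xs(region, level="region")


def count_reads(
    reads: pd.DataFrame,
    models: dict[str, TranscriptModel],
) -> CountMatrix:
    """Assign reads to gene regions by 5'-end containment and tally.

    Reads referencing transcripts absent from ``models`` are ignored;
    reads whose span leaves the transcript are rejected and counted. The
    per-library size is the total of reads assigned to any gene, matching
    the total-mapped-reads normalisation convention.
    """
    if len(reads) == 0:
        idx = pd.MultiIndex.from_product(
            [[], REGION_ORDER], names=["gene_id", "region"]
        )
        return CountMatrix(
            counts=pd.DataFrame(index=idx),
            library_size=pd.Series(dtype=np.int64),
            rejected=pd.Series(dtype=np.int64),
        )

    # vectorise the per-transcript lookups through categorical codes so a
    # multi-million-row table never materialises duplicated strings
    tr = reads["transcript"].astype("category")
    cats = tr.cat.categories
    known = np.array([t in models for t in cats])
    gene_of = np.array(
        [models[t].gene_id if t in models else "" for t in cats], dtype=object
    )
    tlen = np.array([models[t].transcript_length if t in models else 0 for t in cats])
    utr5_len = np.array([models[t].utr5_len if t in models else 0 for t in cats])
    cds_end = np.array(
        [models[t].utr5_len + models[t].cds_len if t in models else 0 for t in cats]
    )
    codes = tr.cat.codes.to_numpy()
    in_annot = known[codes]

    start = reads["start"].to_numpy()
    end = start + reads["length"].to_numpy() - 1
    ok = in_annot & (start >= 1) & (end <= tlen[codes])
    off = in_annot & ~ok
    rejected = (
        pd.DataFrame(
            {"assay": reads["assay"][off], "sample": reads["sample"][off]}
        )
        .groupby(["assay", "sample"], observed=True)
        .size()
        .astype(np.int64)
    )
    n_rej = int(off.sum())
    if n_rej:
        logger.info("%d read(s) rejected as off-transcript", n_rej)

    region = np.where(
        start <= utr5_len[codes],
        "utr5",
        np.where(start <= cds_end[codes], "cds", "utr3"),
    )
    df = pd.DataFrame(
        {
            "gene_id": pd.Categorical(gene_of[codes[ok]]),
            "region": pd.Categorical(region[ok]),
            "assay": reads["assay"][ok].to_numpy(),
            "sample": reads["sample"][ok].to_numpy(),
        }
    )
    grouped = (
        df.groupby(["gene_id", "region", "assay", "sample"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    for col in ("gene_id", "region", "assay", "sample"):
        grouped[col] = grouped[col].astype(str)
    counts = grouped.pivot_table(
        index=["gene_id", "region"],
        columns=["assay", "sample"],
        values="n",
        fill_value=0,
        aggfunc="sum",
    ).astype(np.int64)

    totals = counts.groupby(level="gene_id").sum()
    totals.index = pd.MultiIndex.from_arrays(
        [totals.index, ["gene_total"] * len(totals)], names=["gene_id", "region"]
    )
    counts = pd.concat([counts, totals]).sort_index()

    # complete missing regions with zeros so every gene has all rows
    genes = counts.index.get_level_values("gene_id").unique()
    full = pd.MultiIndex.from_product(
        [genes, REGION_ORDER], names=["gene_id", "region"]
    )
    counts = counts.reindex(full, fill_value=0)

    library_size = (
        counts.xs("gene_total", level="region").sum(axis=0).astype(np.int64)
    )
    rejected = rejected.reindex(library_size.index, fill_value=0)
    return CountMatrix(counts=counts, library_size=library_size, rejected=rejected)


# ---------------------------------------------------------------------------
# normalisation


def compute_rpkm(count, feature_length_nt, mapped_reads):
    """RPKM = count / (length/1000) / (mapped/1e6). Vectorises over arrays."""
    length = np.asarray(feature_length_nt, dtype=float)
    mapped = np.asarray(mapped_reads, dtype=float)
    if np.any(mapped <= 0):
        raise ValueError("empty library: mapped_reads must be > 0")
    if np.any(length <= 0):
        raise ValueError("feature_length_nt must be > 0 (exclude zero-length features)")
    return np.asarray(count, dtype=float) / (length / 1e3) / (mapped / 1e6)


def region_density(count, region_length_nt, library_size, scale: float = 1e9):
    """Normalised read density: count / region length / library size x scale.

    With the default scale of 1e9 the units coincide with RPKM.
    """
    length = np.asarray(region_length_nt, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("empty library: library_size must be > 0")
    if np.any(length <= 0):
        raise ValueError("zero-length region is excluded from density")
    return np.asarray(count, dtype=float) / length / lib * scale


def rpkm_table(
    cm: CountMatrix, models: dict[str, TranscriptModel]
) -> pd.DataFrame:
    """Per-gene RPKM (gene_total counts over transcript length) per library."""
    counts = cm.counts.xs("gene_total", level="region")
    canon = {}
    for m in models.values():
        cur = canon.get(m.gene_id)
        if cur is None or m.transcript_length > cur.transcript_length:
            canon[m.gene_id] = m
    lengths = pd.Series(
        {g: canon[g].transcript_length for g in counts.index}, name="length"
    )
    out = {}
    for col in counts.columns:
        out[col] = compute_rpkm(
            counts[col].to_numpy(), lengths.to_numpy(), cm.library_size[col]
        )
    return pd.DataFrame(out, index=counts.index)


def region_density_table(
    cm: CountMatrix, models: dict[str, TranscriptModel], scale: float = 1e9
) -> pd.DataFrame:
    """Region x library normalised densities; zero-length regions are NaN."""
    canon: dict[str, TranscriptModel] = {}
    for m in models.values():
        cur = canon.get(m.gene_id)
        if cur is None or m.cds_len > cur.cds_len:
            canon[m.gene_id] = m
    rows = []
    for (gene, region), row in cm.counts.iterrows():
        if region == "gene_total":
            continue
        m = canon.get(gene)
        if m is None:
            continue
        length = {
            "utr5": m.utr5_len,
            "cds": m.cds_len,
            "utr3": m.utr3_len,
            "intron": m.intron_len,
        }[region]
        if length <= 0:
            continue
        dens = {
            col: region_density(row[col], length, cm.library_size[col], scale)
            for col in cm.counts.columns
        }
        rows.append({"gene_id": gene, "region": region, **dens})
    return pd.DataFrame(rows).set_index(["gene_id", "region"]) if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# QC


def read_length_histogram(reads: pd.DataFrame) -> pd.Series:
    """Read-length -> count map (RPF libraries peak in the 28-32 nt band)."""
    return reads.groupby("length").size().sort_index()


def replicate_correlation(
    x, y, pseudocount: float = LOG_PSEUDOCOUNT
) -> float:
    """Pearson r between two libraries on the log2(RPKM + pseudocount) scale."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expect two equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    lx = np.log2(x + pseudocount)
    ly = np.log2(y + pseudocount)
    return float(np.corrcoef(lx, ly)[0, 1])
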