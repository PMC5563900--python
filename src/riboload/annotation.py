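"""Transcript annotation, canonical-isoform selection and region extraction.

Coordinates are 1-based closed intervals throughout. Transcript space (the
spliced mRNA, position 1 at the 5' cap) is the primary analysis space;
genomic alignments are projected through the exon blocks of a transcript.

A transcript partitions into three transcript-space regions:

    [1, utr5_len]                         5'UTR
    [utr5_len+1, utr5_len+cds_len]        CDS (start through stop codon)
    [utr5_len+cds_len+1, length]          3'UTR

Introns live only in genomic space: they are the gaps between consecutive
exons. For translation-level metrics (5' loading ratio, TE) one canonical
isoform per gene is used — the transcript with the longest CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger(__name__)

REGIONS = ("utr5", "cds", "utr3")


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are genomic 1-based closed intervals ordered 5'->3' in
    transcript orientation (descending genomic coordinate on the minus
    strand). ``cds_span`` is the genomic interval from start codon through
    stop codon, or ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons {s1}-{e1}, {s2}-{e2}"
                )
        expected = tuple(genomic) if self.strand == "+" else tuple(genomic[::-1])
        if tuple(self.exons) != expected:
            raise AnnotationError(
                f"{self.transcript_id}: exons not ordered 5'->3' in transcript orientation"
            )
        if self.cds_span is not None:
            # both CDS endpoints must land on exons; interior containment
            # follows because exons are disjoint and the CDS is spliced
            for pos in self.cds_span:
                if not any(s <= pos <= e for s, e in self.exons):
                    raise AnnotationError(
                        f"{self.transcript_id}: CDS endpoint {pos} outside exons"
                    )

    # -- derived lengths ---------------------------------------------------

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def intron_len(self) -> int:
        genomic = sorted(self.exons)
        return sum(s2 - e1 - 1 for (_, e1), (s2, _) in zip(genomic, genomic[1:]))

    @property
    def cds_interval_t(self) -> tuple[int, int] | None:
        """CDS as a transcript-space interval, or None for non-coding."""
        if self.cds_span is None:
            return None
        a = self.genomic_to_transcript(self.cds_span[0])
        b = self.genomic_to_transcript(self.cds_span[1])
        return (min(a, b), max(a, b))

    @property
    def utr5_len(self) -> int:
        iv = self.cds_interval_t
        return 0 if iv is None else iv[0] - 1

    @property
    def cds_len(self) -> int:
        iv = self.cds_interval_t
        return 0 if iv is None else iv[1] - iv[0] + 1

    @property
    def utr3_len(self) -> int:
        iv = self.cds_interval_t
        return 0 if iv is None else self.transcript_length - iv[1]

    @property
    def cds_frame_ok(self) -> bool:
        """True when the annotated CDS length is a multiple of 3.

        Real annotations contain ragged CDS ends; this is a flag, not an
        error.
        """
        return self.cds_len % 3 == 0

    # -- coordinate projection ---------------------------------------------

    def genomic_to_transcript(self, gpos: int) -> int:
        """Project a genomic position (1-based) onto transcript space."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos <= e:
                within = (gpos - s) if self.strand == "+" else (e - gpos)
                return offset + within + 1
            offset += e - s + 1
        raise ValueError(
            f"{self.transcript_id}: genomic position {gpos} not exonic"
        )

    def transcript_to_genomic(self, tpos: int) -> int:
        """Project a transcript-space position (1-based) onto the genome."""
        if not 1 <= tpos <= self.transcript_length:
            raise ValueError(
                f"{self.transcript_id}: transcript position {tpos} out of "
                f"range 1..{self.transcript_length}"
            )
        offset = 0
        for s, e in self.exons:
            n = e - s + 1
            if tpos <= offset + n:
                within = tpos - offset - 1
                return s + within if self.strand == "+" else e - within
            offset += n
        raise AssertionError("unreachable")

    def region_of(self, tpos: int) -> str:
        """Region ('utr5'/'cds'/'utr3') containing a transcript position."""
        iv = self.cds_interval_t
        if iv is None:
            raise ValueError(f"{self.transcript_id}: non-coding transcript")
        if tpos < iv[0]:
            return "utr5"
        if tpos <= iv[1]:
            return "cds"
        return "utr3"


def extract_regions(model: TranscriptModel) -> dict:
    """Partition a coding transcript into 5'UTR/CDS/3'UTR plus introns.

    Returns transcript-space 1-based closed intervals (``None`` for an
    empty region, e.g. a CDS touching the transcript end) and the genomic
    intron intervals. The three transcript-space regions partition
    ``[1, transcript_length]`` exactly.
    """
    iv = model.cds_interval_t
    if iv is None:
        raise ValueError(f"{model.transcript_id}: no CDS annotated")
    cs, ce = iv
    L = model.transcript_length
    genomic = sorted(model.exons)
    introns = [
        (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(genomic, genomic[1:])
    ]
    return {
        "utr5": (1, cs - 1) if cs > 1 else None,
        "cds": (cs, ce),
        "utr3": (ce + 1, L) if ce < L else None,
        "introns": introns,
    }


def select_canonical(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """Pick a gene's canonical isoform: the transcript with the longest CDS.

    Ties break to the longest transcript, then lexicographically smallest
    transcript_id, making the choice deterministic and order-independent.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(gene_ids)}")
    coding = [t for t in transcripts if t.cds_span is not None]
    if not coding:
        raise NoCodingTranscript(transcripts[0].gene_id)
    return min(
        coding,
        key=lambda t: (-t.cds_len, -t.transcript_length, t.transcript_id),
    )


class NoCodingTranscript(Exception):
    """Signals a gene with no CDS on any isoform (excluded, not fatal)."""

    def __init__(self, gene_id: str):
        self.gene_id = gene_id
        super().__init__(f"gene {gene_id} has no coding transcript")


def canonical_transcripts(
    models: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Map gene_id -> canonical TranscriptModel, dropping non-coding genes.

    Genes whose every isoform lacks a CDS are excluded from footprint
    analyses (5'LR and TE are CDS-defined) and logged.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    out: dict[str, TranscriptModel] = {}
    dropped = []
    for gid in sorted(by_gene):
        try:
            out[gid] = select_canonical(by_gene[gid])
        except NoCodingTranscript:
            dropped.append(gid)
    if dropped:
        logger.warning(
            "%d gene(s) without a coding transcript dropped from CDS-level "
            "analyses: %s%s",
            len(dropped), ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    return out


# ---------------------------------------------------------------------------
# element table


@dataclass
class ElementTable:
    """Per-gene presence of 5'UTR regulatory elements (uORF, IRES, 5'TOP)."""

    flags: dict[str, tuple[bool, bool, bool]] = field(default_factory=dict)

    COLUMNS = ("has_uORF", "has_IRES", "has_5TOP")

    def get(self, gene_id: str) -> tuple[bool, bool, bool]:
        return self.flags.get(gene_id, (False, False, False))

    def has_element(self, gene_id: str, element: str) -> bool:
        idx = {"uORF": 0, "IRES": 1, "5TOP": 2}[element]
        return self.get(gene_id)[idx]

    def genes_with(self, element: str) -> set[str]:
        idx = {"uORF": 0, "IRES": 1, "5TOP": 2}[element]
        return {g for g, f in self.flags.items() if f[idx]}


_TRUTHY = {"1", "true", "yes", "t", "y"}
_FALSY = {"0", "false", "no", "f", "n"}


def _parse_bool(token: str, path: str, lineno: int) -> bool:
    t = token.strip().lower()
    if t in _TRUTHY:
        return True
    if t in _FALSY:
        return False
    raise AnnotationError(f"{path}:{lineno}: not a boolean: {token!r}")


def load_element_table(
    path: str, annotation_genes: Iterable[str] | None = None
) -> ElementTable:
    """Load the 4-column element TSV (gene_id, has_uORF, has_IRES, has_5TOP).

    When ``annotation_genes`` is given, flagged genes absent from the
    annotation raise an error; annotation genes absent from the table
    default to all-false with a logged warning.
    """
    flags: dict[str, tuple[bool, bool, bool]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4:
            raise AnnotationError(f"{path}:1: expected 4 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise AnnotationError(f"{path}:{lineno}: expected 4 columns")
            gid = parts[0]
            flags[gid] = tuple(_parse_bool(p, path, lineno) for p in parts[1:4])
    if annotation_genes is not None:
        known = set(annotation_genes)
        unknown = sorted(set(flags) - known)
        if unknown:
            raise AnnotationError(
                f"{path}: element table references genes absent from the "
                f"annotation: {', '.join(unknown[:5])}"
            )
        missing = sorted(known - set(flags))
        if missing:
            logger.warning(
                "%d annotated gene(s) missing from element table; defaulting "
                "to no elements", len(missing),
            )
            for g in missing:
                flags[g] = (False, False, False)
    return ElementTable(flags)


def write_element_table(table: ElementTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\thas_uORF\thas_IRES\thas_5TOP\n")
        for gid in sorted(table.flags):
            u, i, t = table.flags[gid]
            fh.write(f"{gid}\t{int(u)}\t{int(i)}\t{int(t)}\n")


# ---------------------------------------------------------------------------
# annotation readers / writers


def load_annotation(path: str, dialect: str = "gtf") -> list[TranscriptModel]:
    """Read transcript models from GTF (Ensembl-style attributes) or BED12."""
    if dialect == "gtf":
        return _load_gtf(path)
    if dialect == "bed12":
        return _load_bed12(path)
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def _load_gtf(path: str) -> list[TranscriptModel]:
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: {feat.featuretype} record at {feat.seqid}:"
                f"{feat.start} missing {exc} attribute"
            ) from None
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))
    models = []
    for tid in sorted(meta):
        gid, chrom, strand = meta[tid]
        ex = sorted(exons.get(tid, []))
        if not ex:
            raise AnnotationError(f"{path}: transcript {tid} has no exons")
        if strand == "-":
            ex = ex[::-1]
        span = None
        if tid in cds:
            blocks = cds[tid]
            span = (min(s for s, _ in blocks), max(e for _, e in blocks))
        models.append(
            TranscriptModel(tid, gid, chrom, strand, tuple(ex), span)
        )
    return models


def _load_bed12(path: str) -> list[TranscriptModel]:
    """BED12: 0-based half-open on disk, converted to 1-based closed.

    The name field carries ``gene_id|transcript_id`` (pipe-separated); a
    bare name is used for both ids.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: BED12 requires 12 columns, got {len(parts)}"
                )
            try:
                chrom = parts[0]
                chrom_start = int(parts[1])
                name = parts[3]
                strand = parts[5]
                thick_start, thick_end = int(parts[6]), int(parts[7])
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(
                    f"{path}:{lineno}: blockCount disagrees with block lists"
                )
            if "|" in name:
                gid, tid = name.split("|", 1)
            else:
                gid = tid = name
            ex = [
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            if strand == "-":
                ex = ex[::-1]
            span = None
            if thick_end > thick_start:
                span = (thick_start + 1, thick_end)
            models.append(
                TranscriptModel(tid, gid, chrom, strand, tuple(ex), span)
            )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str, source: str = "riboload") -> None:
    """Write models as Ensembl-attribute GTF (exon + CDS features)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, min(s for s, _ in m.exons), m.transcript_id)):
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_span is not None:
                cs, ce = m.cds_span
                for s, e in sorted(m.exons):
                    os_, oe = max(s, cs), min(e, ce)
                    if os_ <= oe:
                        fh.write(
                            f"{m.chrom}\t{source}\tCDS\t{os_}\t{oe}\t.\t{m.strand}\t.\t{attrs}\n"
                        )


def write_bed12(models: Iterable[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, min(s for s, _ in m.exons), m.transcript_id)):
            genomic = sorted(m.exons)
            chrom_start = genomic[0][0] - 1
            chrom_end = genomic[-1][1]
            if m.cds_span is not None:
                thick = (m.cds_span[0] - 1, m.cds_span[1])
            else:
                thick = (chrom_start, chrom_start)
            sizes = ",".join(str(e - s + 1) for s, e in genomic)
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in genomic)
            fh.write(
                "\t".join(
                    [
                        m.chrom, str(chrom_start), str(chrom_end),
                        f"{m.gene_id}|{m.transcript_id}", "0", m.strand,
                        str(thick[0]), str(thick[1]), "0",
                        str(len(genomic)), sizes, starts,
                    ]
                )
                + "\n"
            )


def write_regions_bed6(models: Iterable[TranscriptModel], path: str) -> None:
    """Export genomic footprints of 5'UTR/CDS/3'UTR as BED6 (0-based half-open)."""
    rows = []
    for m in models:
        if m.cds_span is None:
            continue
        regions = extract_regions(m)
        for region in REGIONS:
            iv = regions[region]
            if iv is None:
                continue
            # project the transcript interval back through exons block by block
            for gs, ge in _transcript_interval_to_genomic_blocks(m, iv):
                rows.append((m.chrom, gs - 1, ge, f"{m.gene_id}|{region}", 0, m.strand))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, name, score, strand in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}\n")


def _transcript_interval_to_genomic_blocks(
    model: TranscriptModel, iv: tuple[int, int]
) -> list[tuple[int, int]]:
    """Split a transcript-space interval into genomic exon-block intervals."""
    blocks = []
    offset = 0
    for s, e in model.exons:
        n = e - s + 1
        lo = max(iv[0], offset + 1)
        hi = min(iv[1], offset + n)
        if lo <= hi:
            if model.strand == "+":
                blocks.append((s + (lo - offset - 1), s + (hi - offset - 1)))
            else:
                blocks.append((e - (hi - offset - 1), e - (lo - offset - 1)))
        offset += n
    return sorted(blocks)
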