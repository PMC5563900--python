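"""Synthetic Ribo-seq/RNA-seq data with known ground truth.

The generator emulates a two-assay hypoxia time-course experiment: a
normoxic control ("0h") and hypoxic stress conditions ("1h", "2h", "4h"),
each with replicate RPF (ribosome footprint) and mRNA libraries over a
synthetic transcriptome.

Per gene g and condition c the expected library fraction is proportional
to abundance_g for mRNA and abundance_g x TE_g(c) for RPF; observed gene
read totals are negative-binomial around that expectation with a shared
size (dispersion) parameter, so replicates over-disperse relative to
Poisson the way sequencing libraries do. mRNA read 5' ends are uniform
over the transcript (fixed 50-nt reads); RPF reads are placed by first
drawing an A-site position on the CDS — with relative density ``ramp_rho``
on CDS bases 16-195 for ramp-affected genes under affected conditions and
uniform elsewhere — then subtracting the length-dependent A-site offset,
with footprint lengths drawn from a 25-35 nt distribution peaked at
28-32 nt.

uORF-flagged genes can carry two hypoxia effects: a multiplicative TE
change (``te_fc_uorf``) and the 5'-window ramp (``ramp_rho``). Everything
is reproducible from a single seed via named substreams per stage.

What this emulates and what it does not: gene-level abundance/TE effects,
replicate dispersion, footprint length structure and the 5' ramp are
modelled; sequence content, rRNA contamination, positional biases beyond
the ramp, and mechanistic uORF scanning/reinitiation are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .annotation import ElementTable, TranscriptModel
from .asite import _OFFSETS
from .counting import READ_COLUMNS

CONDITIONS = ("0h", "1h", "2h", "4h")

#: footprint length distribution over 25..35 nt, mode at 29
RPF_LENGTHS = np.arange(25, 36)
RPF_LENGTH_PROBS = np.array(
    [0.01, 0.02, 0.05, 0.20, 0.22, 0.20, 0.15, 0.08, 0.04, 0.02, 0.01]
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Lengths are uniform over the stated ranges (CDS rounded to a multiple
    of 3); abundance and baseline TE are log-normal; gene totals are
    negative-binomial with ``dispersion`` as the size parameter. Element
    prevalences approximate human 5'UTR annotation (uORFs common, IRES
    and 5'TOP rarer). Effects apply to hypoxic conditions listed in
    ``effect_conditions``.
    """

    n_genes: int = 500
    utr5_range: tuple[int, int] = (100, 300)
    cds_range: tuple[int, int] = (300, 3000)
    utr3_range: tuple[int, int] = (200, 800)
    frac_multi_exon: float = 0.5
    max_extra_exons: int = 3
    intron_range: tuple[int, int] = (80, 2000)
    p_uorf: float = 0.35
    p_ires: float = 0.10
    p_5top: float = 0.05
    log_abundance_mu: float = 0.0
    log_abundance_sigma: float = 1.0
    log_te_sigma: float = 0.35
    te_fc_uorf: float = 2.0  # multiplicative TE change for uORF genes
    ramp_rho: float = 1.2  # relative A-site density on CDS bases 16-195
    ramp_affected_fraction: float = 1.0  # fraction of uORF genes ramped
    effect_conditions: tuple[str, ...] = ("1h", "2h")
    conditions: tuple[str, ...] = CONDITIONS
    n_replicates: int = 2
    dispersion: float = 20.0  # NB size; larger -> closer to Poisson
    library_size_rpf: int = 1_000_000
    library_size_mrna: int = 1_000_000
    mrna_read_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_uorf", "p_ires", "p_5top", "frac_multi_exon",
                     "ramp_affected_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("te_fc_uorf", "ramp_rho", "dispersion",
                     "log_abundance_sigma", "log_te_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        unknown = set(self.effect_conditions) - set(self.conditions)
        if unknown:
            raise ValueError(f"effect_conditions not in conditions: {unknown}")


def save_config(config: SimulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def load_config(path: str) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("utr5_range", "cds_range", "utr3_range", "intron_range",
                "effect_conditions", "conditions"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    cfg = SimulationConfig(**data)
    cfg.validate()
    return cfg


def _rng_for(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Named substream: independent generator per pipeline stage.

    The stage key is hashed with CRC32 so streams are stable across
    processes and Python versions.
    """
    import zlib

    ss = np.random.SeedSequence(
        config.seed, spawn_key=(zlib.crc32(stage.encode()) % (2**31),)
    )
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# annotation + truth


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], ElementTable]:
    """Draw a synthetic transcriptome: single- and multi-exon coding genes
    on both strands, plus element flags per prevalence."""
    config.validate()
    rng = _rng_for(config, "annotation")
    models = []
    flags = {}
    cursor = 1000  # genomic coordinate cursor, genes laid end to end
    width = max(4, len(str(max(config.n_genes, 1))))
    for i in range(config.n_genes):
        gid = f"G{i:0{width}d}"
        tid = f"{gid}.t1"
        utr5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        cds = int(rng.integers(config.cds_range[0], config.cds_range[1] + 1))
        cds -= cds % 3
        utr3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        tlen = utr5 + cds + utr3
        strand = "+" if rng.random() < 0.5 else "-"

        if rng.random() < config.frac_multi_exon:
            n_exons = int(rng.integers(2, config.max_extra_exons + 2))
        else:
            n_exons = 1
        # split [1, tlen] into n_exons transcript segments
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(2, tlen), size=n_exons - 1, replace=False))
            bounds = [1, *cuts.tolist(), tlen + 1]
        else:
            bounds = [1, tlen + 1]
        seg_lens = [bounds[j + 1] - bounds[j] for j in range(n_exons)]
        introns = (
            rng.integers(config.intron_range[0], config.intron_range[1] + 1,
                         size=n_exons - 1).tolist()
            if n_exons > 1 else []
        )

        # lay exons on the genome in transcript order; on the minus strand
        # the 5'-most exon is genomically rightmost
        gstart = cursor
        glen = sum(seg_lens) + sum(introns)
        exons_plus = []
        pos = gstart
        for j, sl in enumerate(seg_lens):
            exons_plus.append((pos, pos + sl - 1))
            pos += sl
            if j < len(introns):
                pos += introns[j]
        if strand == "+":
            exons = tuple(exons_plus)
        else:
            exons = tuple(exons_plus[::-1])
        model_noncds = TranscriptModel(tid, gid, "chrS", strand, exons)
        cds_t = (utr5 + 1, utr5 + cds)
        g1 = model_noncds.transcript_to_genomic(cds_t[0])
        g2 = model_noncds.transcript_to_genomic(cds_t[1])
        span = (min(g1, g2), max(g1, g2))
        models.append(TranscriptModel(tid, gid, "chrS", strand, exons, span))
        cursor = gstart + glen + int(rng.integers(500, 2000))

        flags[gid] = (
            bool(rng.random() < config.p_uorf),
            bool(rng.random() < config.p_ires),
            bool(rng.random() < config.p_5top),
        )
    return models, ElementTable(flags)


def simulate_truth(
    config: SimulationConfig,
    models: list[TranscriptModel],
    elements: ElementTable,
) -> pd.DataFrame:
    """Per-gene ground truth: abundance, per-condition TE, effect flags."""
    rng = _rng_for(config, "truth")
    genes = sorted({m.gene_id for m in models})
    n = len(genes)
    abundance = rng.lognormal(config.log_abundance_mu, config.log_abundance_sigma, n)
    te0 = rng.lognormal(0.0, config.log_te_sigma, n)
    uorf = np.array([elements.has_element(g, "uORF") for g in genes])
    ramp_affected = uorf & (rng.random(n) < config.ramp_affected_fraction)

    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "abundance": abundance,
            "has_uORF": uorf,
            "has_IRES": [elements.has_element(g, "IRES") for g in genes],
            "has_5TOP": [elements.has_element(g, "5TOP") for g in genes],
            "ramp_affected": ramp_affected,
        }
    ).set_index("gene_id")
    for c in config.conditions:
        te_c = te0.copy()
        if c in config.effect_conditions:
            te_c = te_c * np.where(uorf, config.te_fc_uorf, 1.0)
        truth[f"te_{c}"] = te_c
        truth[f"ramp_rho_{c}"] = np.where(
            ramp_affected & (c in config.effect_conditions), config.ramp_rho, 1.0
        )
    return truth


def export_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", float_format="%.8g")


# ---------------------------------------------------------------------------
# reads


def _nb_counts(rng, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative-binomial draws parameterised by mean and size (dispersion)."""
    mean = np.maximum(mean, 1e-12)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _sample_rpf_positions(
    rng, n: int, cds_len: int, rho: float
) -> np.ndarray:
    """A-site CDS positions with relative density rho on bases 16-195."""
    lo, hi = 16, 195
    w_len = hi - lo + 1
    if cds_len <= hi or rho == 1.0:
        return rng.integers(1, cds_len + 1, size=n)
    p_window = rho * w_len / (rho * w_len + (cds_len - w_len))
    in_window = rng.random(n) < p_window
    pos = np.empty(n, dtype=np.int64)
    k = int(in_window.sum())
    pos[in_window] = rng.integers(lo, hi + 1, size=k)
    # outside: bases 1..15 and 196..cds_len, sampled uniformly
    n_out = n - k
    u = rng.integers(0, cds_len - w_len, size=n_out)
    pos[~in_window] = np.where(u < lo - 1, u + 1, u + w_len + 1)
    return pos


def simulate_reads(
    config: SimulationConfig,
    models: list[TranscriptModel],
    truth: pd.DataFrame,
) -> pd.DataFrame:
    """Emit the aligned-read table for every sample/assay/condition/replicate.

    Sample ids are ``{condition}_rep{r}``. Gene totals are NB around the
    expected library share; read placement follows the positional model in
    the module docstring. All emitted reads satisfy the transcript-space
    invariants by construction.
    """
    config.validate()
    rng = _rng_for(config, "reads")
    by_gene = {m.gene_id: m for m in models}
    genes = truth.index.to_numpy()
    abundance = truth["abundance"].to_numpy()

    frames = []
    offsets = np.array([_OFFSETS[l] for l in RPF_LENGTHS])
    for c in config.conditions:
        te_c = truth[f"te_{c}"].to_numpy()
        rho_c = truth[f"ramp_rho_{c}"].to_numpy()
        w_mrna = abundance / abundance.sum()
        w_rpf_raw = abundance * te_c
        w_rpf = w_rpf_raw / w_rpf_raw.sum()
        for rep in range(1, config.n_replicates + 1):
            sample = f"{c}_rep{rep}"
            n_mrna = _nb_counts(rng, w_mrna * config.library_size_mrna, config.dispersion)
            n_rpf = _nb_counts(rng, w_rpf * config.library_size_rpf, config.dispersion)
            for gi, gene in enumerate(genes):
                m = by_gene[gene]
                tlen = m.transcript_length
                cds_start = m.utr5_len + 1
                cds_len = m.cds_len
                # mRNA: uniform 5' ends, fixed read length
                nm = int(n_mrna[gi])
                if nm > 0:
                    rl = min(config.mrna_read_length, tlen)
                    starts = rng.integers(1, tlen - rl + 2, size=nm)
                    frames.append(pd.DataFrame({
                        "sample": sample, "assay": "mRNA",
                        "transcript": m.transcript_id,
                        "start": starts, "length": rl,
                    }))
                # RPF: A-site positional model, then back out the 5' end
                nr = int(n_rpf[gi])
                if nr > 0:
                    apos = _sample_rpf_positions(rng, nr, cds_len, float(rho_c[gi]))
                    li = rng.choice(len(RPF_LENGTHS), size=nr, p=RPF_LENGTH_PROBS)
                    lens = RPF_LENGTHS[li]
                    starts = cds_start + apos - 1 - offsets[li]
                    ok = (starts >= 1) & (starts + lens - 1 <= tlen)
                    frames.append(pd.DataFrame({
                        "sample": sample, "assay": "RPF",
                        "transcript": m.transcript_id,
                        "start": starts[ok], "length": lens[ok],
                    }))
    if not frames:
        return pd.DataFrame(columns=READ_COLUMNS)
    reads = pd.concat(frames, ignore_index=True)
    reads["start"] = reads["start"].astype(np.int64)
    reads["length"] = reads["length"].astype(np.int64)
    return reads[READ_COLUMNS]


def condition_of_sample(config: SimulationConfig) -> dict[str, str]:
    return {
        f"{c}_rep{r}": c
        for c in config.conditions
        for r in range(1, config.n_replicates + 1)
    }


def write_sam(
    reads: pd.DataFrame,
    models: list[TranscriptModel],
    path: str,
    genomic: bool = False,
) -> None:
    """Write reads as SAM, either against transcript references or
    projected through exon blocks onto the genome (split reads get N
    operations in the CIGAR)."""
    import pysam

    by_tid = {m.transcript_id: m for m in models}
    header: dict = {"HD": {"VN": "1.6", "SO": "unknown"}}
    if genomic:
        chroms = sorted({m.chrom for m in models})
        ends = {
            ch: max(max(e for _, e in m.exons) for m in models if m.chrom == ch)
            for ch in chroms
        }
        header["SQ"] = [{"SN": ch, "LN": ends[ch] + 1000} for ch in chroms]
        refmap = {ch: i for i, ch in enumerate(chroms)}
    else:
        tids = sorted(by_tid)
        header["SQ"] = [
            {"SN": t, "LN": by_tid[t].transcript_length} for t in tids
        ]
        refmap = {t: i for i, t in enumerate(tids)}

    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment()
            a.query_name = f"{row.sample}.{row.assay}.{i}"
            a.query_sequence = "N" * int(row.length)
            a.mapping_quality = 255
            m = by_tid[row.transcript]
            if genomic:
                tstart, tend = int(row.start), int(row.start) + int(row.length) - 1
                gpositions = sorted(
                    m.transcript_to_genomic(t) for t in range(tstart, tend + 1)
                )
                a.reference_id = refmap[m.chrom]
                a.reference_start = gpositions[0] - 1
                a.is_reverse = m.strand == "-"
                cigar = []
                run_start = gpositions[0]
                prev = gpositions[0]
                for g in gpositions[1:]:
                    if g == prev + 1:
                        prev = g
                        continue
                    cigar.append((0, prev - run_start + 1))
                    cigar.append((3, g - prev - 1))
                    run_start = g
                    prev = g
                cigar.append((0, prev - run_start + 1))
                a.cigartuples = cigar
            else:
                a.reference_id = refmap[row.transcript]
                a.reference_start = int(row.start) - 1
                a.cigartuples = [(0, int(row.length))]
            out.write(a)
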