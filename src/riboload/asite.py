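"""A-site assignment and 5' loading ratios for ribosome footprints.

Footprint reads are attributed to the ribosomal A-site with a
length-dependent offset from the read's 5' end:

    length 25-28 nt -> +14      length 31-33 nt -> +16
    length 29-30 nt -> +15      length 34-35 nt -> +17

Reads shorter than 25 nt or longer than 35 nt are excluded. The offset is
a 0-based displacement: a 28-nt read whose 5' end sits at transcript
position p has its A-site at p + 14.

The 5' loading ratio (5'LR) of a gene compares footprint density in the
early-elongation window of the CDS — bases 16 to 195, i.e. codons 6-65 —
to the density over the remaining downstream CDS:

    5'LR = (n_window / 180) / (n_downstream / (cds_len - 195))

and the relative 5' loading ratio r5'LR is the stress-to-control ratio of
a gene's 5'LR. An r5'LR above 1 means ribosomes pile up behind the start
codon under stress relative to control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

# numerator window of the 5' loading ratio, in CDS base coordinates
WINDOW_START = 16
WINDOW_END = 195
WINDOW_LEN = WINDOW_END - WINDOW_START + 1  # 180 nt, codons 6-65

#: length-band -> A-site offset lookup (0-based displacement from 5' end)
_OFFSETS = {}
for _l in range(25, 29):
    _OFFSETS[_l] = 14
for _l in range(29, 31):
    _OFFSETS[_l] = 15
for _l in range(31, 34):
    _OFFSETS[_l] = 16
for _l in range(34, 36):
    _OFFSETS[_l] = 17


def a_site_offset(read_length: int) -> int | None:
    """A-site offset for a footprint of the given length, or None if the
    read falls outside the accepted 25-35 nt range."""
    if read_length <= 0:
        raise ValueError("read_length must be a positive integer")
    return _OFFSETS.get(int(read_length))


@dataclass
class FootprintProfile:
    """Per-base A-site counts over CDS positions 1..cds_len of one gene."""

    gene_id: str
    condition: str
    counts: np.ndarray  # int64, length == cds_len
    dropped_length: int = 0  # reads outside the 25-35 nt band
    dropped_outside: int = 0  # A-sites landing off the CDS

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def assign_a_sites(
    reads: pd.DataFrame,
    model: TranscriptModel,
    condition: str = "",
) -> FootprintProfile:
    """Build the A-site profile of one gene from its RPF reads.

    ``reads`` rows must belong to the model's transcript; each retained
    read adds 1 at CDS position (start + offset - cds_start + 1). Reads
    with out-of-band lengths and A-sites falling outside [1, cds_len] are
    dropped and tallied separately.
    """
    iv = model.cds_interval_t
    if iv is None:
        raise ValueError(f"{model.transcript_id}: non-coding transcript")
    cds_start, _ = iv
    cds_len = model.cds_len
    counts = np.zeros(cds_len, dtype=np.int64)
    if len(reads) == 0:
        return FootprintProfile(model.gene_id, condition, counts)
    if not (reads["transcript"] == model.transcript_id).all():
        raise ValueError("reads from a different transcript")

    lengths = reads["length"].to_numpy()
    starts = reads["start"].to_numpy()
    offsets = np.array([_OFFSETS.get(int(l), -1) for l in lengths])
    keep = offsets >= 0
    dropped_length = int((~keep).sum())

    apos = starts[keep] + offsets[keep] - cds_start + 1  # CDS coordinates
    inside = (apos >= 1) & (apos <= cds_len)
    dropped_outside = int((~inside).sum())
    np.add.at(counts, apos[inside].astype(np.int64) - 1, 1)
    return FootprintProfile(
        model.gene_id, condition, counts, dropped_length, dropped_outside
    )


@dataclass
class LoadingRatioConfig:
    """Eligibility guards for the 5' loading ratio.

    A gene enters the analysis only when its CDS extends well past the
    numerator window and carries enough footprint signal for a stable
    density ratio.
    """

    min_cds_len: int = 300
    min_total_counts: int = 10
    min_downstream_counts: int = 1


DEFAULT_LR_CONFIG = LoadingRatioConfig()


def loading_ratio_5(
    profile: FootprintProfile,
    config: LoadingRatioConfig = DEFAULT_LR_CONFIG,
) -> tuple[float | None, str | None]:
    """5'LR of one profile, or (None, reason) when the gene is ineligible.

    Reasons: "short CDS", "low counts", "no downstream signal".
    """
    cds_len = len(profile.counts)
    if cds_len < max(config.min_cds_len, WINDOW_END + 1):
        return None, "short CDS"
    num_count = int(profile.counts[WINDOW_START - 1 : WINDOW_END].sum())
    den_count = int(profile.counts[WINDOW_END:].sum())
    if num_count + den_count < config.min_total_counts:
        return None, "low counts"
    if den_count < config.min_downstream_counts:
        return None, "no downstream signal"
    num_density = num_count / WINDOW_LEN
    den_density = den_count / (cds_len - WINDOW_END)
    return num_density / den_density, None


def relative_5lr(lr5_stress: float, lr5_control: float) -> float:
    """r5'LR: ratio of a gene's 5'LR under stress to its control 5'LR."""
    if lr5_stress is None or lr5_control is None:
        raise ValueError("both 5'LR values must be defined")
    if lr5_stress <= 0 or lr5_control <= 0:
        raise ValueError("5'LR values must be positive")
    return lr5_stress / lr5_control


def build_profiles(
    rpf_reads: pd.DataFrame,
    models: dict[str, TranscriptModel],
    condition_of_sample: dict[str, str],
) -> dict[tuple[str, str], FootprintProfile]:
    """Pooled A-site profiles per (gene, condition).

    Replicate reads of a condition are summed into one profile before any
    ratio is formed, which stabilises the denominator of sparse genes.
    """
    canon = {m.transcript_id: m for m in models.values()}
    rpf = rpf_reads[rpf_reads["assay"] == "RPF"]
    rpf = rpf[rpf["transcript"].isin(canon)]
    profiles: dict[tuple[str, str], FootprintProfile] = {}
    cond = rpf["sample"].astype(str).map(condition_of_sample)
    for (tid, condition), grp in rpf.groupby(
        [rpf["transcript"], cond], sort=True, observed=True
    ):
        tid = str(tid)
        model = canon[tid]
        if model.cds_span is None:
            continue
        profiles[(model.gene_id, condition)] = assign_a_sites(
            grp, model, condition
        )
    return profiles


def loading_ratio_table(
    profiles: dict[tuple[str, str], FootprintProfile],
    comparisons: list[tuple[str, str]],
    config: LoadingRatioConfig = DEFAULT_LR_CONFIG,
) -> pd.DataFrame:
    """Per-gene 5'LR per condition and r5'LR per (stress, control) pair.

    Genes failing an eligibility guard in a condition get NaN there and an
    exclusion reason; an r5'LR is defined only when both of its conditions
    pass.
    """
    genes = sorted({g for g, _ in profiles})
    conditions = sorted({c for _, c in profiles})
    rows = []
    for gene in genes:
        row: dict = {"gene_id": gene}
        reasons = []
        lr = {}
        for c in conditions:
            prof = profiles.get((gene, c))
            if prof is None:
                lr[c] = None
                reasons.append(f"{c}:no reads")
                continue
            value, reason = loading_ratio_5(prof, config)
            lr[c] = value
            row[f"lr5_{c}"] = np.nan if value is None else value
            if reason:
                reasons.append(f"{c}:{reason}")
        for stress, control in comparisons:
            key = f"r5lr_{stress}_vs_{control}"
            if lr.get(stress) and lr.get(control):
                row[key] = relative_5lr(lr[stress], lr[control])
            else:
                row[key] = np.nan
        row["exclusion_reason"] = ";".join(reasons)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()


def profiles_to_frame(
    profiles: dict[tuple[str, str], FootprintProfile]
) -> pd.DataFrame:
    """Long-format export: gene, condition, cds_position, count (non-zero)."""
    rows = []
    for (gene, condition), prof in sorted(profiles.items()):
        nz = np.nonzero(prof.counts)[0]
        for i in nz:
            rows.append((gene, condition, int(i) + 1, int(prof.counts[i])))
    return pd.DataFrame(
        rows, columns=["gene_id", "condition", "cds_position", "count"]
    )
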