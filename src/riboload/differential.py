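"""Translation efficiency, fold changes and threshold-based DE calling.

Translation efficiency (TE) of a gene is the ratio of its normalised
footprint abundance to its normalised mRNA abundance,

    TE = RPF_RPKM / mRNA_RPKM,

so on the log2 scale the TE fold change decomposes exactly into
log2FC(TE) = log2FC(RPF) - log2FC(mRNA) whenever both levels are defined
from the same RPKMs.

Calling is threshold-based, not test-based:

* DEG / DTG: |log2FC| >= 1 (inclusive) and mean log2(RPKM) of the two
  conditions >= 3.3, applied at the mRNA level (DEG) and RPF level (DTG).
* DTE: fold change strictly > 2 (|log2FC(TE)| > 1) and mean RPKM
  strictly > 5 on the linear scale.

Both guards are configurable. Because calls are deterministic functions
of fold change and abundance, no multiple-testing correction applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats

#: RPKM pseudocount applied before log2 fold changes (guards zeros)
FC_PSEUDOCOUNT = 1e-2

#: genes with mRNA RPKM at or below this floor have undefined TE
TE_FLOOR = 0.0


def translation_efficiency(rpf_rpkm, mrna_rpkm, floor: float = TE_FLOOR):
    """TE = RPF RPKM / mRNA RPKM; NaN where the mRNA signal is at/below floor."""
    rpf = np.asarray(rpf_rpkm, dtype=float)
    mrna = np.asarray(mrna_rpkm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(mrna > floor, rpf / np.where(mrna > floor, mrna, 1.0), np.nan)
    if te.ndim == 0:
        return float(te)
    return te


def log2_fold_change(value_t, value_0, pseudocount: float = FC_PSEUDOCOUNT):
    """log2((x_t + pc) / (x_0 + pc)) on replicate-averaged RPKMs."""
    a = np.asarray(value_t, dtype=float) + pseudocount
    b = np.asarray(value_0, dtype=float) + pseudocount
    return np.log2(a) - np.log2(b)


def call_deg(log2fc, mean_log2_rpkm, fc_thresh: float = 1.0, abund_thresh: float = 3.3):
    """DEG/DTG call: |log2FC| >= fc_thresh and mean log2(RPKM) >= abund_thresh.

    Both comparisons are inclusive. Vectorises over arrays.
    """
    fc = np.abs(np.asarray(log2fc, dtype=float))
    ab = np.asarray(mean_log2_rpkm, dtype=float)
    out = (fc >= fc_thresh) & (ab >= abund_thresh)
    return bool(out) if out.ndim == 0 else out


def call_dte(log2fc_te, mean_rpkm, fc_thresh: float = 1.0, abund_thresh: float = 5.0):
    """DTE call: |log2FC(TE)| strictly > fc_thresh and mean RPKM strictly >
    abund_thresh (linear scale)."""
    fc = np.abs(np.asarray(log2fc_te, dtype=float))
    ab = np.asarray(mean_rpkm, dtype=float)
    out = (fc > fc_thresh) & (ab > abund_thresh)
    return bool(out) if out.ndim == 0 else out


@dataclass
class Thresholds:
    deg_fc: float = 1.0
    deg_abund: float = 3.3  # mean log2(RPKM)
    dte_fc: float = 1.0
    dte_abund: float = 5.0  # mean RPKM, linear
    pseudocount: float = FC_PSEUDOCOUNT
    te_floor: float = TE_FLOOR


def condition_means(
    rpkm: pd.DataFrame, condition_of_sample: dict[str, str]
) -> pd.DataFrame:
    """Average replicate RPKM columns into one column per condition."""
    cond = pd.Index(
        [condition_of_sample[s] for s in rpkm.columns], name="condition"
    )
    return rpkm.T.groupby(cond).mean().T


def gene_metrics(
    mrna_rpkm: pd.DataFrame,
    rpf_rpkm: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-gene TE, log2 fold changes and DEG/DTG/DTE flags.

    Inputs are replicate-averaged RPKM tables with one column per
    condition (see :func:`condition_means`); comparisons are (stress,
    control) condition pairs. Genes absent from either assay are dropped.
    """
    th = thresholds or Thresholds()
    genes = mrna_rpkm.index.intersection(rpf_rpkm.index).sort_values()
    mrna = mrna_rpkm.loc[genes]
    rpf = rpf_rpkm.loc[genes]

    out = pd.DataFrame(index=genes)
    for c in mrna.columns:
        out[f"mrna_rpkm_{c}"] = mrna[c]
        out[f"rpf_rpkm_{c}"] = rpf[c]
        out[f"te_{c}"] = translation_efficiency(
            rpf[c].to_numpy(), mrna[c].to_numpy(), th.te_floor
        )
    for stress, control in comparisons:
        tag = f"{stress}_vs_{control}"
        fc_m = log2_fold_change(mrna[stress], mrna[control], th.pseudocount)
        fc_r = log2_fold_change(rpf[stress], rpf[control], th.pseudocount)
        out[f"log2fc_mrna_{tag}"] = fc_m
        out[f"log2fc_rpf_{tag}"] = fc_r
        out[f"log2fc_te_{tag}"] = fc_r - fc_m

        mean_log2_mrna = 0.5 * (
            np.log2(mrna[stress] + th.pseudocount)
            + np.log2(mrna[control] + th.pseudocount)
        )
        mean_log2_rpf = 0.5 * (
            np.log2(rpf[stress] + th.pseudocount)
            + np.log2(rpf[control] + th.pseudocount)
        )
        out[f"deg_{tag}"] = call_deg(fc_m, mean_log2_mrna, th.deg_fc, th.deg_abund)
        out[f"dtg_{tag}"] = call_deg(fc_r, mean_log2_rpf, th.deg_fc, th.deg_abund)
        mean_rpkm = 0.25 * (
            mrna[stress] + mrna[control] + rpf[stress] + rpf[control]
        )
        out[f"dte_{tag}"] = call_dte(
            out[f"log2fc_te_{tag}"], mean_rpkm, th.dte_fc, th.dte_abund
        )
    return out


def overlap_sets(sets: dict[str, set]) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a 3-set Venn diagram.

    Keys are membership patterns over the input order, e.g. '110' for
    elements in the first two sets only. Region counts sum to the union.
    """
    if len(sets) != 3:
        raise ValueError("expect exactly 3 named sets")
    names = list(sets)
    a, b, c = (set(sets[n]) for n in names)
    universe = a | b | c
    out = {f"{i}{j}{k}": 0 for i in (0, 1) for j in (0, 1) for k in (0, 1)}
    del out["000"]
    for x in universe:
        key = f"{int(x in a)}{int(x in b)}{int(x in c)}"
        out[key] += 1
    return out


def fc_correlation(
    metrics: pd.DataFrame, genes, comparison: str
) -> tuple[float, float]:
    """Pearson r (and p) between mRNA and RPF log2 fold changes of a gene set."""
    idx = metrics.index.intersection(pd.Index(genes))
    if len(idx) < 3:
        raise ValueError("need at least 3 genes")
    x = metrics.loc[idx, f"log2fc_mrna_{comparison}"]
    y = metrics.loc[idx, f"log2fc_rpf_{comparison}"]
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
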