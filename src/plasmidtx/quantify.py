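"""Expression quantification (RPKM, TPM) and floor-plus-quartile tiering.

Genes below an expression floor (default 1.5 RPKM) are classed silent;
quartiles of the remaining (expressed) genes split them into low (<= Q1),
medium (Q1..Q3] and high (> Q3) transcription tiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TIER_ORDER = {"silent": 0, "low": 1, "medium": 2, "high": 3}
DEFAULT_FLOOR = 1.5


def rpkm(num_reads, gene_length, total_num_reads):
    """Reads per kilobase of gene per million mapped reads.

    rpkm = numReads / ((geneLength / 1e3) * (totalNumReads / 1e6))
    """
    gene_length = np.asarray(gene_length, dtype=float)
    total = float(total_num_reads)
    if np.any(gene_length <= 0):
        raise ValueError("gene length must be > 0")
    if total <= 0:
        raise ValueError("total mapped reads must be > 0")
    return np.asarray(num_reads, dtype=float) / ((gene_length / 1e3) * (total / 1e6))


def tpm(counts, lengths):
    """Transcripts per million: per-gene rate count/length scaled to 1e6.

    Raises on an all-zero sample (TPM undefined).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be > 0")
    rates = counts / lengths
    total = rates.sum()
    if total <= 0:
        raise ValueError("all-zero sample: TPM undefined")
    return 1e6 * rates / total


@dataclass
class TierThresholds:
    floor: float
    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.q2 <= self.q3:
            raise ValueError("quartiles must be ordered")


def assign_tiers(rpkm_values, floor: float = DEFAULT_FLOOR):
    """Assign silent/low/medium/high tiers from RPKM values.

    Quartiles are computed on expressed genes only (rpkm >= floor) with
    linear-interpolation (type-7) quantiles.  Returns (TierThresholds,
    array of tier labels).
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    vals = np.asarray(rpkm_values, dtype=float)
    expressed = vals[vals >= floor]
    if len(expressed) < 4:
        raise ValueError("fewer than 4 expressed genes: quartiles undefined")
    q1, q2, q3 = np.quantile(expressed, [0.25, 0.5, 0.75])
    thresholds = TierThresholds(floor=floor, q1=q1, q2=q2, q3=q3)
    labels = np.full(len(vals), "medium", dtype=object)
    labels[vals < floor] = "silent"
    labels[(vals >= floor) & (vals <= q1)] = "low"
    labels[vals > q3] = "high"
    return thresholds, labels


def expression_table(
    counts: pd.DataFrame, lengths: pd.Series, floor: float = DEFAULT_FLOOR
) -> pd.DataFrame:
    """Per-gene expression summary across samples.

    RPKM and TPM are computed per sample and averaged; the tier is assigned
    on the mean RPKM so each gene carries a single tier.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise KeyError(f"no length for genes {missing[:5]}")
    rpkm_mat = pd.DataFrame(
        {
            s: rpkm(counts[s].to_numpy(), lengths.to_numpy(), counts[s].sum())
            for s in counts.columns
        },
        index=counts.index,
    )
    tpm_mat = pd.DataFrame(
        {s: tpm(counts[s].to_numpy(), lengths.to_numpy()) for s in counts.columns},
        index=counts.index,
    )
    mean_rpkm = rpkm_mat.mean(axis=1)
    _, tiers = assign_tiers(mean_rpkm.to_numpy(), floor=floor)
    out = counts.copy()
    out["length"] = lengths
    out["rpkm"] = mean_rpkm
    out["tpm"] = tpm_mat.mean(axis=1)
    out["tier"] = tiers
    return out
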