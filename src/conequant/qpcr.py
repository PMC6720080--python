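"""Efficiency-corrected comparative-Ct relative quantification.

Relative expression of a target gene in a sample versus a calibrator
group, corrected per gene for amplification efficiency E and normalized
to the geometric mean of two endogenous reference genes:

    RQ_sample = E_target^(Ct_cal - Ct_sample)  /  NF_sample
    NF_sample = geomean over refs of E_ref^(Ct_cal,ref - Ct_sample,ref)

with the calibrator-group mean Ct as the anchor for every gene.  Group
summaries are arithmetic means of per-sample RQ, renormalized so the
calibrator group is exactly 1.  Efficiencies come from dilution-series
slopes, E = 10^(-1/slope); an unmeasured efficiency defaults to 2
(perfect doubling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from conequant.qpcr_synth import CtTable


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Amplification efficiency from a dilution series."""

    efficiency: float
    slope: float
    r_squared: float
    gene: str | None = None


class EfficiencyError(ValueError):
    """Dilution series cannot yield a valid efficiency."""


def estimate_efficiency(
    quantities: np.ndarray,
    cts: np.ndarray,
    gene: str | None = None,
) -> EfficiencyEstimate:
    """Least-squares fit of Ct against log10 input quantity.

    A perfect doubling assay loses 1 cycle per 2-fold input increase,
    i.e. slope -3.3219 per decade and E = 2.
    """
    q = np.asarray(quantities, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if q.shape != ct.shape:
        raise ValueError("quantities and cts must have the same length")
    if np.unique(q).size < 3:
        raise ValueError("need at least 3 distinct dilutions")
    if np.any(q <= 0):
        raise ValueError("input quantities must be positive")
    x = np.log10(q)
    slope, intercept = np.polyfit(x, ct, 1)
    if slope >= 0:
        raise EfficiencyError(
            f"non-negative dilution slope ({slope:.3f}); Ct must fall with input"
        )
    pred = slope * x + intercept
    ss_res = float(np.sum((ct - pred) ** 2))
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    e = float(10.0 ** (-1.0 / slope))
    return EfficiencyEstimate(e, float(slope), r2, gene)


def _calibrator_means(
    table: CtTable, calibrator_group: str
) -> dict[str, float]:
    df = table.data
    cal = df[df["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} absent from table")
    return cal.groupby("gene")["ct"].mean().to_dict()


def _efficiency(table: CtTable, gene: str) -> float:
    return table.efficiencies.get(gene, 2.0)


def normalization_factor(
    table: CtTable,
    calibrator_group: str,
    reference_genes: tuple[str, str] = ("GAPDH", "cyclophilin"),
) -> pd.DataFrame:
    """Per-sample reference-gene normalization factor.

    For each sample (group, replicate) and reference gene r the factor
    ``E_r^(Ct_cal,r - Ct_sample,r)`` measures apparent input abundance
    vs the calibrator; the pooled factor is the geometric mean over the
    two reference genes.  Returns columns group, replicate, nf.
    """
    df = table.data
    cal_means = _calibrator_means(table, calibrator_group)
    for ref in reference_genes:
        if ref not in set(df["gene"]):
            raise ValueError(f"reference gene {ref!r} missing from table")
        if ref not in cal_means:
            raise ValueError(
                f"reference gene {ref!r} missing from calibrator group"
            )
    logs = []
    for ref in reference_genes:
        sub = df[df["gene"] == ref].set_index(["group", "replicate"])
        log_factor = np.log(_efficiency(table, ref)) * (
            cal_means[ref] - sub["ct"]
        )
        logs.append(log_factor)
    pooled = sum(logs) / len(logs)
    out = np.exp(pooled).rename("nf").reset_index()
    return out


def relative_expression(
    table: CtTable,
    gene: str,
    calibrator_group: str,
    reference_genes: tuple[str, str] = ("GAPDH", "cyclophilin"),
) -> pd.DataFrame:
    """Group-level relative expression of one target gene.

    Returns one row per group with columns ``group, rq, sem, n``; the
    calibrator group has rq exactly 1 by construction.
    """
    df = table.data
    target = df[df["gene"] == gene]
    if target.empty:
        raise ValueError(f"gene {gene!r} absent from table")
    cal_means = _calibrator_means(table, calibrator_group)
    if gene not in cal_means:
        raise ValueError(f"gene {gene!r} missing from calibrator group")
    e_t = _efficiency(table, gene)
    nf = normalization_factor(table, calibrator_group, reference_genes)
    sub = target.merge(nf, on=["group", "replicate"], how="left")
    if sub["nf"].isna().any():
        bad = sub[sub["nf"].isna()][["group", "replicate"]].values.tolist()
        raise ValueError(f"samples lacking reference-gene Cts: {bad}")
    sub["rq_sample"] = (
        e_t ** (cal_means[gene] - sub["ct"]) / sub["nf"]
    )
    grouped = sub.groupby("group")["rq_sample"]
    summary = grouped.agg(rq="mean", n="count")
    sd = grouped.std(ddof=1)
    summary["sem"] = sd / np.sqrt(summary["n"])
    cal_rq = summary.loc[calibrator_group, "rq"]
    if cal_rq <= 0:
        raise ValueError("calibrator mean RQ is non-positive")
    summary["rq"] = summary["rq"] / cal_rq
    summary["sem"] = summary["sem"] / cal_rq
    if summary["n"].lt(1).any():
        raise ValueError("empty group in relative expression summary")
    return summary.reset_index()[["group", "rq", "sem", "n"]]
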