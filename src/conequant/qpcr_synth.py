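"""Simulate qPCR Ct tables under an exponential amplification model.

A transcript present at relative level L (vs the calibrator condition)
crosses the detection threshold ``log_E(L)`` cycles earlier than the
calibrator, so ``Ct = baseline_Ct(gene) - log_E(L) + noise``.  Reference
genes are simulated at constant level 1 in every group.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from conequant.presets import REFERENCE_GENES

#: typical threshold cycles at calibrator level for each assay
DEFAULT_BASELINE_CT = {
    "GAPDH": 18.0,
    "cyclophilin": 20.0,
    "S-opsin": 24.0,
    "ML-opsin": 26.0,
}


@dataclass
class CtTable:
    """Long-format Ct records plus per-gene amplification efficiencies.

    ``data`` columns: gene, group, replicate, ct.  Each (gene, group)
    cell must hold at least two replicates and all Ct values must lie in
    the instrument's usable range (5, 40).
    """

    data: pd.DataFrame
    efficiencies: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene", "group", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        ct = self.data["ct"]
        if not ((ct > 5) & (ct < 40)).all():
            raise ValueError("Ct values must lie in (5, 40)")
        counts = self.data.groupby(["gene", "group"]).size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"fewer than 2 replicates for {bad}")
        for gene, e in self.efficiencies.items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency for {gene} must be in (1, 2]")

    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())


def simulate_ct_table(
    expression: dict[str, dict[str, float]],
    group_ns: dict[str, int],
    efficiencies: dict[str, float],
    rng: np.random.Generator,
    noise_sd: float = 0.15,
    baseline_ct: dict[str, float] | None = None,
) -> CtTable:
    """Draw a Ct table from per-gene relative expression levels.

    ``expression[gene][group]`` is the relative level (> 0) of that gene
    in that group; reference genes default to level 1 everywhere if not
    listed.  ``group_ns[group]`` biological replicates are drawn per
    group, each contributing one Ct per gene.
    """
    baselines = dict(DEFAULT_BASELINE_CT)
    if baseline_ct:
        baselines.update(baseline_ct)
    rows = []
    genes = list(expression)
    for gene in genes:
        e = efficiencies[gene]
        if not 1.0 < e <= 2.0:
            raise ValueError(f"efficiency for {gene} must be in (1, 2]")
        log_e = np.log(e)
        for group, n in group_ns.items():
            level = expression[gene].get(
                group, 1.0 if gene in REFERENCE_GENES else None
            )
            if level is None:
                raise ValueError(f"no expression level for {gene} in {group}")
            if level <= 0:
                raise ValueError(
                    f"relative level must be positive ({gene}/{group}: {level})"
                )
            base = baselines.get(gene, 25.0)
            ct0 = base - np.log(level) / log_e
            noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
            for rep in range(n):
                rows.append((gene, group, rep + 1, ct0 + noise[rep]))
    df = pd.DataFrame(rows, columns=["gene", "group", "replicate", "ct"])
    return CtTable(df, dict(efficiencies))
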