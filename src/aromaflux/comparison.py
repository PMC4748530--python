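"""Strain comparison by final-concentration ratios across paired conditions.

For each compound, the final liquid-phase concentration of the evolved
strain is divided by that of the ancestral strain under the same
fermentation condition. The per-condition ratios are summarised by their
median with a percentile-bootstrap confidence interval over conditions;
a compound counts as overproduced when the whole interval lies above 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_BOOT_DEFAULT = 10_000
LEVEL_DEFAULT = 0.95


@dataclass
class PairedFinals:
    """Final concentrations of one compound under one paired condition."""

    compound: str
    condition_id: str
    final_evolved: float
    final_ancestral: float

    def __post_init__(self):
        if self.final_evolved < 0 or self.final_ancestral < 0:
            raise ValueError("final concentrations must be nonnegative")


@dataclass
class RatioSummary:
    compound: str
    ratios: np.ndarray
    median_ratio: float
    ci_low: float
    ci_high: float
    overproduced: bool
    n_conditions: int
    excluded_conditions: list[str] = field(default_factory=list)


def ratio_summary(
    pairs: list[PairedFinals],
    n_boot: int = N_BOOT_DEFAULT,
    level: float = LEVEL_DEFAULT,
    seed: int | np.random.Generator = 0,
) -> RatioSummary:
    """Median evolved/ancestral ratio with a percentile bootstrap CI.

    Conditions with a zero ancestral final are excluded with a warning
    (their ratio is undefined). At least 3 usable paired conditions are
    required. A fixed seed makes the interval reproducible bit-for-bit.
    """
    compounds = {p.compound for p in pairs}
    if len(compounds) != 1:
        raise ValueError("ratio_summary expects pairs for a single compound")
    (compound,) = compounds
    excluded = [p.condition_id for p in pairs if p.final_ancestral == 0]
    if excluded:
        warnings.warn(
            f"{compound}: excluded conditions with zero ancestral final: {excluded}"
        )
    usable = [p for p in pairs if p.final_ancestral > 0]
    if len(usable) < 3:
        raise ValueError("need at least 3 paired conditions with positive ancestral finals")
    ratios = np.array([p.final_evolved / p.final_ancestral for p in usable])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, ratios.size, size=(n_boot, ratios.size))
    boot_medians = np.median(ratios[idx], axis=1)
    alpha = 1.0 - level
    ci_low = float(np.quantile(boot_medians, alpha / 2))
    ci_high = float(np.quantile(boot_medians, 1 - alpha / 2))
    med = float(np.median(ratios))
    return RatioSummary(
        compound=compound,
        ratios=ratios,
        median_ratio=med,
        ci_low=min(ci_low, med),
        ci_high=max(ci_high, med),
        overproduced=ci_low > 1.0,
        n_conditions=ratios.size,
        excluded_conditions=excluded,
    )


def summarize_finals_table(
    finals: pd.DataFrame,
    evolved_label: str,
    ancestral_label: str,
    n_boot: int = N_BOOT_DEFAULT,
    level: float = LEVEL_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Ratio summaries for every compound in a long finals table.

    Expects columns ``compound, condition_id, strain, final_mg_per_l``.
    Returns one row per compound: n, median_ratio, ci_low, ci_high,
    overproduced.
    """
    required = {"compound", "condition_id", "strain", "final_mg_per_l"}
    missing = required - set(finals.columns)
    if missing:
        raise ValueError(f"finals table missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for compound, sub in finals.groupby("compound", sort=True):
        wide = sub.pivot_table(
            index="condition_id", columns="strain", values="final_mg_per_l"
        )
        if evolved_label not in wide.columns or ancestral_label not in wide.columns:
            raise ValueError(f"{compound}: missing strain {evolved_label!r} or {ancestral_label!r}")
        wide = wide.dropna(subset=[evolved_label, ancestral_label])
        pairs = [
            PairedFinals(
                compound=str(compound),
                condition_id=str(cond),
                final_evolved=float(row[evolved_label]),
                final_ancestral=float(row[ancestral_label]),
            )
            for cond, row in wide.iterrows()
        ]
        s = ratio_summary(pairs, n_boot=n_boot, level=level, seed=rng)
        rows.append(
            {
                "compound": s.compound,
                "n": s.n_conditions,
                "median_ratio": s.median_ratio,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "overproduced": s.overproduced,
            }
        )
    return pd.DataFrame(rows)
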