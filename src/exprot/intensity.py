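"""Cross-intensity set partitioning and intensity-dependence classification.

Significant proteins (BH q below alpha) at the two intensities are split
into moderate-only, high-only and shared sets. Shared proteins are
checked for directional concordance and classified by how much more they
change at high intensity: with the magnitude ratio r defined so that
r > 1 always means a larger change at high intensity (FC_H/FC_M for
increasing proteins, FC_M/FC_H for decreasing ones), a protein is

- ``dependent``    if r >= 1.25 (changes at least 25% more at high),
- ``independent``  if FC_H is within 5% of FC_M (relative to FC_M),
- ``intermediate`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IntensityPartition",
    "partition_by_intensity",
    "check_concordance",
    "classify_intensity_dependence",
    "volcano_table",
]

DEPENDENT_RATIO_THRESHOLD = 1.25
INDEPENDENT_RELATIVE_GAP = 0.05


@dataclass(frozen=True)
class IntensityPartition:
    """Disjoint significant-protein sets across the two intensities."""

    moderate_only: frozenset
    high_only: frozenset
    shared: frozenset

    @property
    def n_moderate_only(self) -> int:
        return len(self.moderate_only)

    @property
    def n_high_only(self) -> int:
        return len(self.high_only)

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_moderate_total(self) -> int:
        return len(self.moderate_only) + len(self.shared)

    @property
    def n_high_total(self) -> int:
        return len(self.high_only) + len(self.shared)

    @property
    def n_union(self) -> int:
        return self.n_moderate_only + self.n_high_only + self.n_shared

    def counts(self) -> dict[str, int]:
        return {
            "moderate_only": self.n_moderate_only,
            "high_only": self.n_high_only,
            "shared": self.n_shared,
            "moderate_total": self.n_moderate_total,
            "high_total": self.n_high_total,
            "union": self.n_union,
        }


def partition_by_intensity(
    res_moderate: pd.DataFrame, res_high: pd.DataFrame, alpha: float = 0.05
) -> IntensityPartition:
    """Partition proteins by where they are significant (q < alpha).

    Both result tables must cover the same protein universe.
    """
    univ_m = set(res_moderate["protein_id"])
    univ_h = set(res_high["protein_id"])
    if univ_m != univ_h:
        diff = sorted(univ_m.symmetric_difference(univ_h))
        raise ValueError(
            f"result tables cover different protein universes; symmetric "
            f"difference: {diff[:10]}{'...' if len(diff) > 10 else ''}"
        )
    sig_m = set(res_moderate.loc[res_moderate["q_value"] < alpha, "protein_id"])
    sig_h = set(res_high.loc[res_high["q_value"] < alpha, "protein_id"])
    return IntensityPartition(
        moderate_only=frozenset(sig_m - sig_h),
        high_only=frozenset(sig_h - sig_m),
        shared=frozenset(sig_m & sig_h),
    )


def check_concordance(shared_results: pd.DataFrame) -> list[str]:
    """Return the shared proteins whose directions disagree across
    intensities.

    Expects columns ``protein_id``, ``direction_moderate`` and
    ``direction_high``; an empty list means full concordance.
    """
    req = {"protein_id", "direction_moderate", "direction_high"}
    missing = req - set(shared_results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = shared_results["direction_moderate"] != shared_results["direction_high"]
    return sorted(shared_results.loc[bad, "protein_id"])


def classify_intensity_dependence(shared: pd.DataFrame) -> pd.DataFrame:
    """Classify shared proteins by the 25%/5% fold-change rules.

    ``shared`` needs columns ``protein_id``, ``fc_moderate``, ``fc_high``
    and ``direction`` (up/down, concordant across intensities). Returns
    one row per protein with the magnitude ratio ``r`` and ``klass``.
    When the dependence and independence rules could both fire, the
    dependence call wins.
    """
    df = shared.copy()
    fc_m = df["fc_moderate"].to_numpy(dtype=float)
    fc_h = df["fc_high"].to_numpy(dtype=float)
    if (fc_m <= 0).any() or (fc_h <= 0).any():
        raise ValueError("fold changes must be strictly positive")
    up = df["direction"].to_numpy() == "up"
    r = np.where(up, fc_h / fc_m, fc_m / fc_h)
    rel_gap = np.abs(fc_h - fc_m) / fc_m
    klass = np.where(
        r >= DEPENDENT_RATIO_THRESHOLD,
        "dependent",
        np.where(rel_gap <= INDEPENDENT_RELATIVE_GAP, "independent", "intermediate"),
    )
    return pd.DataFrame(
        {
            "protein_id": df["protein_id"].to_numpy(),
            "fc_moderate": fc_m,
            "fc_high": fc_h,
            "direction": df["direction"].to_numpy(),
            "magnitude_ratio": r,
            "klass": klass,
        }
    )


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot export: protein, log2 fold change, -log10 q, direction,
    ordered by protein id."""
    out = pd.DataFrame(
        {
            "protein_id": results["protein_id"].to_numpy(),
            "log2_fc": results["log2_fc"].to_numpy(dtype=float),
            "neg_log10_q": -np.log10(results["q_value"].to_numpy(dtype=float)),
            "direction": results["direction"].to_numpy(),
        }
    )
    return out.sort_values("protein_id", kind="stable").reset_index(drop=True)
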