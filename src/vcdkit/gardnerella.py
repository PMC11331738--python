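"""Redistribute genus-level Gardnerella reads onto genomospecies.

Short-read profilers typically collapse all Gardnerella reads onto a
single species label, while direct mapping against one reference genome
per genomospecies resolves them. This module moves the genus-level count
of each sample onto species in proportion to their mapped reads,
conserving the per-sample total exactly. When nothing maps, reads stay
as "<genus> (unassigned)" rather than being split uniformly, which would
fabricate species evidence.
"""

from __future__ import annotations

import math
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "largest_remainder",
    "redistribute_genus_reads",
    "redistribute_table",
    "unassigned_row_name",
]


def unassigned_row_name(genus_id: str) -> str:
    return f"{genus_id} (unassigned)"


def largest_remainder(total: int, weights: Sequence[float], tie_order: Sequence[str]) -> np.ndarray:
    """Hamilton apportionment of ``total`` units proportionally to weights.

    Ties in the fractional remainders are broken by position in
    ``tie_order`` (ascending identifier), for determinism.
    """
    weights = np.asarray(weights, dtype=float)
    if total != int(total) or total < 0:
        raise ValueError("largest-remainder apportionment needs a non-negative integer total")
    total = int(total)
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    quota = total * weights / wsum
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = total - int(base.sum())
    # Sort by descending remainder, then ascending identifier.
    order = sorted(range(len(weights)), key=lambda i: (-remainder[i], str(tie_order[i])))
    for i in order[:short]:
        base[i] += 1
    return base


def redistribute_genus_reads(
    genus_count: float,
    species_mapped: pd.Series,
    rounding: str = "real",
) -> Tuple[pd.Series, float]:
    """Split one sample's genus count across species by mapping proportions.

    Returns ``(per_species_counts, unassigned)`` with
    ``counts.sum() + unassigned == genus_count`` exactly. With zero total
    mapping everything is unassigned. ``rounding="largest_remainder"``
    yields integers conserving an integer total.
    """
    if genus_count < 0:
        raise ValueError("genus_count must be >= 0")
    mapped = pd.Series(species_mapped, dtype=float)
    if (mapped < 0).any():
        raise ValueError("mapped counts must be >= 0")
    if rounding not in ("real", "largest_remainder"):
        raise ValueError(f"unknown rounding mode {rounding!r}")

    total_mapped = mapped.sum()
    if total_mapped == 0:
        return pd.Series(0.0, index=mapped.index), float(genus_count)

    if rounding == "real":
        out = genus_count * mapped / total_mapped
        # Absorb the float summation residual into the largest share so
        # the per-sample total is conserved exactly, not just to 1 ulp.
        top = int(np.argmax(out.to_numpy()))
        for _ in range(5):
            residual = genus_count - math.fsum(out.to_numpy())
            if residual == 0.0:
                break
            out.iloc[top] += residual
        return out, 0.0
    counts = largest_remainder(genus_count, mapped.to_numpy(), list(mapped.index))
    return pd.Series(counts, index=mapped.index, dtype=float), 0.0


def redistribute_table(
    profile_table: pd.DataFrame,
    mapping_table: pd.DataFrame,
    genus_id: str,
    rounding: str = "real",
) -> pd.DataFrame:
    """Replace a genus row of a taxa-by-samples profile with species rows.

    ``mapping_table`` is species x samples mapped-read counts. Samples
    absent from the mapping table fall under the zero-mapping policy
    (their genus count moves to the unassigned row). Column sums are
    conserved exactly; the genus row is kept at zero so the operation is
    idempotent.
    """
    if genus_id not in profile_table.index:
        raise KeyError(f"unknown genus_id {genus_id!r} in profile table")
    out = profile_table.astype(float).copy()
    species = list(mapping_table.index)
    unassigned = unassigned_row_name(genus_id)
    for row in [*species, unassigned]:
        if row not in out.index:
            out.loc[row] = 0.0

    for sample in out.columns:
        genus_count = float(profile_table.loc[genus_id, sample])
        if sample in mapping_table.columns:
            mapped = mapping_table[sample]
        else:
            mapped = pd.Series(0.0, index=species)
        per_species, left = redistribute_genus_reads(genus_count, mapped, rounding)
        out.loc[species, sample] += per_species.to_numpy()
        out.loc[unassigned, sample] += left
        out.loc[genus_id, sample] = 0.0
    return out
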