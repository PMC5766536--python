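"""Per-genome ECRT counts, densities and the OTU distribution matrix.

Densities are ECRT loci per megabase of ungapped assembly (runs of N
are excluded from the denominator), and the count-vs-size trend is an
ordinary least squares fit of the per-genome count on log10 of the
ungapped size in Mb — the "logarithmic trendline" convention, with a
log-log alternative behind a flag.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats


def compute_density(count: int, assembly_length: int, gap_length: int) -> float | None:
    """ECRTs per Mb of ungapped assembly; ``None`` if no ungapped sequence.

    Exact rational arithmetic is used before the final float conversion.
    """
    if gap_length < 0 or assembly_length < gap_length:
        raise ValueError("need assembly_length >= gap_length >= 0")
    ungapped = assembly_length - gap_length
    if ungapped == 0:
        return None
    return float(Fraction(count) / (Fraction(ungapped) / 1_000_000))


def genome_stats_table(
    counts: dict[str, int],
    assembly_lengths: dict[str, int],
    gap_lengths: dict[str, int],
) -> pd.DataFrame:
    rows = []
    for gid in sorted(counts):
        ungapped = assembly_lengths[gid] - gap_lengths[gid]
        rows.append(
            {
                "genome_id": gid,
                "assembly_length": assembly_lengths[gid],
                "gap_length": gap_lengths[gid],
                "ungapped_mb": ungapped / 1e6,
                "ecrt_count": counts[gid],
                "density_per_mb": compute_density(
                    counts[gid], assembly_lengths[gid], gap_lengths[gid]
                ),
            }
        )
    return pd.DataFrame(rows)


def log_trend_fit(
    counts: list[int] | np.ndarray,
    sizes_mb: list[float] | np.ndarray,
    log_counts: bool = False,
) -> tuple[float, float, float]:
    """OLS fit of count on log10(size in Mb): (slope, intercept, R^2).

    ``log_counts=True`` switches to a log-log fit (log10 of counts as the
    response), which requires strictly positive counts.
    """
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes_mb, dtype=float)
    if len(counts) < 3:
        raise ValueError("need >= 3 genomes for a trend fit")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    x = np.log10(sizes)
    if np.allclose(x, x[0]):
        raise ValueError("sizes are constant; fit undefined")
    y = np.log10(counts) if log_counts else counts
    res = stats.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:  # constant response: nothing to explain
        return float(res.slope), float(res.intercept), 0.0
    pred = res.slope * x + res.intercept
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    return float(res.slope), float(res.intercept), r2


def build_distribution(
    placements: list,
    species_map: dict[str, str],
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Species x OTU locus-count matrix with per-OTU totals and presence.

    ``placements`` are classified placement results (``query_id``,
    ``otu_label``); ``species_map`` sends each locus id to its species.
    Returns (matrix, per-OTU totals, per-OTU species-presence counts).
    """
    unmapped = [p.query_id for p in placements if p.query_id not in species_map]
    if unmapped:
        raise ValueError(f"loci without a species: {unmapped}")
    df = pd.DataFrame(
        {
            "species": [species_map[p.query_id] for p in placements],
            "otu": [p.otu_label for p in placements],
        }
    )
    if df.empty:
        matrix = pd.DataFrame()
    else:
        matrix = (
            df.groupby(["species", "otu"]).size().unstack(fill_value=0).sort_index()
        )
        matrix = matrix[sorted(matrix.columns)]
    totals = matrix.sum(axis=0) if not matrix.empty else pd.Series(dtype=int)
    presence = (matrix > 0).sum(axis=0) if not matrix.empty else pd.Series(dtype=int)
    return matrix, totals, presence
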