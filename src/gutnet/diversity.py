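"""Alpha diversity from first principles: richness, Shannon entropy, rarefaction.

Shannon diversity is reported in nats by default, H = -sum p_i ln p_i over
taxa with positive counts.  Rarefaction uses the exact hypergeometric
expectation of richness in a random subsample without replacement,

    E[S_d] = S - sum_i C(N - N_i, d) / C(N, d),

evaluated in log-gamma space so large counts do not overflow.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .table import AbundanceTable


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if arr.size and arr.min() < 0:
        raise ValueError("counts must be non-negative")
    return arr


def richness(counts) -> int:
    """Number of taxa with strictly positive count."""
    return int(np.count_nonzero(_as_counts(counts) > 0))


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity of a count vector (natural log unless ``base`` set)."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total <= 0:
        raise ValueError("Shannon diversity is undefined for an all-zero vector")
    p = arr[arr > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def _log_choose(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(k + 1) - gammaln(np.asarray(n) - k + 1)


def rarefaction_expected_richness(counts, depth: int) -> float:
    """Expected richness of a uniform subsample of ``depth`` reads."""
    arr = _as_counts(counts)
    arr = arr[arr > 0]
    if not float(arr.sum()).is_integer() or (arr != np.round(arr)).any():
        raise ValueError("rarefaction requires integer counts")
    total = int(arr.sum())
    if depth < 1 or depth > total:
        raise ValueError(f"depth must be in [1, {total}], got {depth}")
    s = arr.size
    rest = total - arr
    miss = np.zeros(s)
    ok = rest >= depth  # taxa that can be absent from the subsample
    if ok.any():
        miss[ok] = np.exp(_log_choose(rest[ok], depth) - _log_choose(total, depth))
    return float(s - miss.sum())


def rarefaction_curve(counts, depths: Sequence[int] | None = None,
                      n_points: int = 20) -> pd.DataFrame:
    """Expected richness at increasing depths (defaults to an even grid)."""
    arr = _as_counts(counts)
    total = int(arr.sum())
    if depths is None:
        depths = np.unique(np.linspace(1, total, min(n_points, total)).astype(int))
    depths = [int(d) for d in depths]
    if any(d < 1 or d > total for d in depths) or sorted(depths) != depths:
        raise ValueError("depths must be increasing integers within [1, total]")
    values = [rarefaction_expected_richness(arr, d) for d in depths]
    return pd.DataFrame({"depth": depths, "expected_richness": values})


def sample_diversity(table: AbundanceTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample richness and Shannon diversity for a whole table."""
    records = []
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        records.append({"sample_id": sid, "richness": richness(col),
                        "shannon": shannon(col, base=base)})
    return pd.DataFrame(records)


def rarefaction_table(table: AbundanceTable, n_points: int = 20) -> pd.DataFrame:
    """Long-format rarefaction curves (sample_id, depth, expected_richness)."""
    frames = []
    for sid in table.sample_ids:
        curve = rarefaction_curve(table.counts[sid].to_numpy(), n_points=n_points)
        curve.insert(0, "sample_id", sid)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)
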