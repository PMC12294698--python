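"""Pseudotime-binned regulatory dynamics along a supplied cell ordering.

Pseudotime is an input (trajectory inference is out of scope). Cells are
ranked by pseudotime and partitioned into equal-count bins (default 100);
per-bin means are z-scaled across the trajectory. Equal-count bins make the
binning invariant to any strictly monotone transform of pseudotime; an
equal-width option is available. Cross-modality coordination (TF motif
deviation vs TF expression, peak vs linked gene) is the Pearson correlation
between scaled binned profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TrajectoryProfile:
    feature_id: str
    modality: str                 # gene | peak | motif
    binned: np.ndarray            # per-bin means
    scaled: np.ndarray            # z-scored across bins (zeros if constant)
    constant: bool
    interpolated_bins: list[int]  # bins that were empty and filled by interpolation


def _bin_assignment(pseudotime: np.ndarray, n_bins: int,
                    equal_count: bool) -> np.ndarray:
    if equal_count:
        order = np.argsort(pseudotime, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(order))
        return (ranks * n_bins) // len(order)
    lo, hi = pseudotime.min(), pseudotime.max()
    return np.clip(((pseudotime - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)


def bin_trajectory(values: np.ndarray, pseudotime: np.ndarray,
                   n_bins: int = 100, feature_id: str = "feature",
                   modality: str = "gene",
                   equal_count: bool = True) -> TrajectoryProfile:
    """Bin one feature's per-cell values along pseudotime.

    Cells are ranked by pseudotime into ``n_bins`` equal-count bins (sizes
    differ by at most 1); per-bin means are z-scaled across bins. Empty bins
    (possible with ties or few cells) are linearly interpolated and flagged.
    A constant feature scales to all zeros with ``constant=True``.
    """
    values = np.asarray(values, dtype=float)
    pseudotime = np.asarray(pseudotime, dtype=float)
    if not np.isfinite(pseudotime).all():
        raise ValueError("pseudotime must be finite for every cell")
    if np.ptp(pseudotime) == 0:
        raise ValueError("all pseudotime values identical; cannot order cells")
    bins = _bin_assignment(pseudotime, n_bins, equal_count)
    sums = np.bincount(bins, weights=values, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    binned = np.full(n_bins, np.nan)
    nz = counts > 0
    binned[nz] = sums[nz] / counts[nz]
    empty = np.flatnonzero(~nz)
    if len(empty):
        binned = np.interp(np.arange(n_bins), np.flatnonzero(nz), binned[nz])
    sd = binned.std()
    constant = sd == 0
    scaled = np.zeros(n_bins) if constant else (binned - binned.mean()) / sd
    return TrajectoryProfile(feature_id, modality, binned, scaled,
                             bool(constant), empty.tolist())


def bin_trajectories(X: np.ndarray, pseudotime: np.ndarray, feature_ids,
                     modality: str, n_bins: int = 100,
                     equal_count: bool = True) -> list[TrajectoryProfile]:
    """Vectorized :func:`bin_trajectory` over the columns of a
    cells-by-features matrix."""
    X = np.asarray(X, dtype=float)
    return [bin_trajectory(X[:, j], pseudotime, n_bins, str(f), modality,
                           equal_count)
            for j, f in enumerate(feature_ids)]


def correlate_trajectories(profiles_a: dict[str, TrajectoryProfile],
                           profiles_b: dict[str, TrajectoryProfile],
                           pairs: list[tuple[str, str]],
                           r_cut: float = 0.5) -> pd.DataFrame:
    """Pearson correlation between scaled binned profiles of named pairs.

    ``pairs`` lists (key in profiles_a, key in profiles_b), e.g. TF motif
    vs TF gene, or peak vs linked gene. Pairs with r > ``r_cut`` are flagged
    ``coordinated``.
    """
    rows = []
    for ka, kb in pairs:
        a = profiles_a[ka]
        b = profiles_b[kb]
        if len(a.scaled) != len(b.scaled):
            raise ValueError("profiles have mismatched bin counts")
        if a.constant or b.constant:
            r = np.nan
        else:
            r = float(np.corrcoef(a.scaled, b.scaled)[0, 1])
        rows.append({"feature_a": ka, "modality_a": a.modality,
                     "feature_b": kb, "modality_b": b.modality,
                     "r": r, "coordinated": bool(np.isfinite(r) and r > r_cut)})
    return pd.DataFrame(rows)


def profiles_frame(profiles: list[TrajectoryProfile]) -> pd.DataFrame:
    """Feature-by-bin table of scaled profiles (on-disk schema)."""
    df = pd.DataFrame({f"{p.modality}:{p.feature_id}": p.scaled for p in profiles}).T
    df.columns = [f"bin{i}" for i in range(df.shape[1])]
    df.insert(0, "modality", [p.modality for p in profiles])
    df.insert(1, "feature", [p.feature_id for p in profiles])
    df.index.name = "profile_id"
    return df
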