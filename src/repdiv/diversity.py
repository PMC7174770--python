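"""Hill-diversity and evenness-profile mathematics.

The Hill diversity of order alpha of a clonal frequency vector f is

    D_a(f) = (sum_i f_i^a)^(1/(1-a)),

with the analytic limit D_1 = exp(H), the exponential of Shannon entropy,
at a = 1, and D_0 = n (richness) at a = 0. The evenness profile evaluates
the normalized diversity E_a = D_a / D_1 on a grid of alpha values
(default 0 to 10 in steps of 0.2, 51 points), giving a low-dimensional,
scale-free summary of a clonal frequency distribution: E is identically 1
for a perfectly even repertoire and decays with alpha as clonal expansion
concentrates frequency mass.

Computations run in log space (logsumexp over alpha * log f) so large
alpha never underflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .repertoire import FrequencyVector


@dataclass(frozen=True)
class AlphaGrid:
    """Ordered, strictly increasing grid of Hill orders alpha."""

    alphas: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))
        if self.alphas.size == 0:
            raise ValueError("alpha grid must be non-empty")
        if (self.alphas < 0).any():
            raise ValueError("alpha must be non-negative")
        if (np.diff(self.alphas) <= 0).any():
            raise ValueError("alpha grid must be strictly increasing")

    @classmethod
    def default(cls) -> "AlphaGrid":
        """alpha = 0, 0.2, ..., 10.0 — the 51-point grid."""
        return cls(np.round(np.arange(0, 10.2, 0.2), 10))

    def __len__(self) -> int:
        return int(self.alphas.size)


@dataclass
class EvennessProfile:
    grid: AlphaGrid
    diversity: np.ndarray
    evenness: np.ndarray
    sample_id: str | None = None
    cluster_id: str | None = None

    def __len__(self) -> int:
        return len(self.grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "cluster": self.cluster_id,
                "alpha": self.grid.alphas,
                "diversity": self.diversity,
                "evenness": self.evenness,
            }
        )


def _as_freqs(f) -> np.ndarray:
    if isinstance(f, FrequencyVector):
        return f.f
    return FrequencyVector(np.asarray(f, dtype=float)).f


def hill_diversity(f, alpha) -> float | np.ndarray:
    """Hill diversity D_a(f); vectorized over alpha.

    Returns richness n at a=0 and exp(Shannon entropy) at a=1 (the
    analytic limit). Raises on negative alpha.
    """
    freqs = _as_freqs(f)
    alpha_arr = np.asarray(alpha, dtype=float)
    if (alpha_arr < 0).any():
        raise ValueError("alpha must be non-negative")
    log_f = np.log(freqs)
    a = np.atleast_1d(alpha_arr)
    log_d = np.empty(a.shape)
    at_one = np.isclose(a, 1.0)
    if at_one.any():
        log_d[at_one] = -np.sum(freqs * log_f)  # Shannon entropy
    rest = ~at_one
    if rest.any():
        # log D = logsumexp(a * log f) / (1 - a)
        lse = logsumexp(a[rest, None] * log_f[None, :], axis=1)
        log_d[rest] = lse / (1.0 - a[rest])
    d = np.exp(log_d)
    return float(d[0]) if alpha_arr.ndim == 0 else d


def evenness_profile(f, grid: AlphaGrid | None = None,
                     normalize_at: float = 1.0,
                     sample_id: str | None = None,
                     cluster_id: str | None = None) -> EvennessProfile:
    """Evenness profile E_a = D_a / D_{normalize_at} over the grid.

    The default normalizes by D at alpha = 1 so E_1 == 1 exactly;
    ``normalize_at=0`` gives the richness-normalized variant.
    """
    grid = grid or AlphaGrid.default()
    diversity = np.atleast_1d(hill_diversity(f, grid.alphas))
    denom = hill_diversity(f, normalize_at)
    return EvennessProfile(grid=grid, diversity=diversity,
                           evenness=diversity / denom,
                           sample_id=sample_id, cluster_id=cluster_id)


def profiles_for_sample_and_clusters(sample_table: pd.DataFrame,
                                     cluster_tables: dict[str, pd.DataFrame],
                                     grid: AlphaGrid | None = None,
                                     sample_id: str = "sample") -> list[EvennessProfile]:
    """One profile for the pooled sample plus one per cluster, each from its
    own frequency vector (clusters are treated as independent samples)."""
    from .repertoire import frequency_vector

    grid = grid or AlphaGrid.default()
    profiles = [
        evenness_profile(frequency_vector(sample_table), grid,
                         sample_id=sample_id)
    ]
    for cluster, table in cluster_tables.items():
        if cluster == "unlabeled" or table.empty:
            continue
        profiles.append(
            evenness_profile(frequency_vector(table), grid,
                             sample_id=sample_id, cluster_id=cluster)
        )
    return profiles


@dataclass
class ProfileComparison:
    table: pd.DataFrame      # alpha, evenness_a, evenness_b, difference
    dominant: str | None     # "a", "b" or None
    fraction_a_below_b: float


def compare_profiles(a: EvennessProfile, b: EvennessProfile) -> ProfileComparison:
    """Elementwise evenness difference a - b with a dominance summary.

    Profile a dominates b when its evenness is >= b's at every alpha > 1
    and strictly greater somewhere; dominance at alpha > 1 is where clonal
    expansion shows, since both profiles are pinned to 1 at alpha = 1.
    """
    if len(a.grid) != len(b.grid) or not np.allclose(a.grid.alphas, b.grid.alphas):
        raise ValueError("profiles are on different alpha grids")
    alphas = a.grid.alphas
    diff = a.evenness - b.evenness
    table = pd.DataFrame({"alpha": alphas, "evenness_a": a.evenness,
                          "evenness_b": b.evenness, "difference": diff})
    tail = alphas > 1
    dominant = None
    if tail.any():
        d = diff[tail]
        if (d >= 0).all() and (d > 0).any():
            dominant = "a"
        elif (d <= 0).all() and (d < 0).any():
            dominant = "b"
    return ProfileComparison(
        table=table,
        dominant=dominant,
        fraction_a_below_b=float(np.mean(diff < 0)),
    )
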