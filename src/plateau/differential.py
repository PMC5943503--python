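"""Two-group differential presentation testing.

The procedure follows the moderated-t / permutation-FDR construction used
for label-free proteomics matrices: intensities are log2-transformed,
missing cells are imputed with the global minimum observed log2 value, and
each item (epitope or peptide) is scored with a SAM-style statistic

    t = (mean(b) - mean(a)) / (se + s0)

where ``se`` is the Welch standard error and ``s0`` (default 0.2) a fuzz
constant that de-emphasizes small absolute differences.  Significance is
calibrated by permuting group labels jointly across all items: an item is
called at FDR ``q`` when its |t| exceeds the smallest cutoff at which the
mean number of permutation exceedances per round, divided by the number of
observed exceedances, stays below ``q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DifferentialConfig:
    s0: float = 0.2
    fdr: float = 0.01
    n_permutations: int = 1000
    seed: int | None = None
    imputation: str = "global_min"

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.imputation != "global_min":
            raise ValueError(f"unknown imputation {self.imputation!r}")


@dataclass
class DifferentialResult:
    item_id: str
    diff: float  # log2 fold change, group b minus group a
    t: float
    p: float
    neg_log10_p: float
    significant: bool
    direction: str  # "up" (b > a), "down", or "none"


def log2_impute(matrix: pd.DataFrame, config: DifferentialConfig) -> pd.DataFrame:
    """Log2-transform observed values; impute missing cells with the global minimum.

    The minimum is a single scalar over the whole matrix (the literal
    "minimum observed value"), not per column.  Observed values are never
    altered beyond the transform.
    """
    arr = matrix.to_numpy(dtype=float)
    if np.all(np.isnan(arr)):
        raise ValueError("matrix has no observed values")
    if np.nanmin(arr) <= 0:
        raise ValueError("observed intensities must be positive for log2")
    mask = ~np.isnan(arr)
    logged = np.full_like(arr, np.nan)
    logged[mask] = np.log2(arr[mask])
    logged[~mask] = logged[mask].min()
    return pd.DataFrame(logged, index=matrix.index, columns=matrix.columns)


def _moderated_t(
    x: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized SAM-moderated Welch statistic per matrix row.

    Returns (t, p, diff).  With s0 = 0 this is exactly the Welch t-test.
    """
    a, b = x[:, idx_a], x[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = mb - ma
    sem2 = va / na + vb / nb
    se = np.sqrt(sem2)
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
        # Welch-Satterthwaite degrees of freedom; pooled df when variance-free
        num = sem2**2
        den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        df = np.where(den > 0, num / den, na + nb - 2)
    df = np.maximum(df, 1.0)
    p = np.where(
        se > 0,
        2.0 * stats.t.sf(np.abs(np.where(se > 0, diff / np.maximum(se, 1e-300), 0.0)), df),
        np.where(diff == 0, 1.0, 0.0),
    )
    return t, p, diff


def s0_ttest(
    group_a: Sequence[float], group_b: Sequence[float], s0: float = 0.2
) -> tuple[float, float, float]:
    """Moderated two-sample test on one item: returns (t, p, diff).

    ``diff`` is mean(group_b) - mean(group_a).  Each group needs at least
    two values for a variance estimate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    x = np.concatenate([a, b])[None, :]
    idx_a = np.arange(a.size)
    idx_b = np.arange(a.size, a.size + b.size)
    t, p, diff = _moderated_t(x, idx_a, idx_b, s0)
    return float(t[0]), float(p[0]), float(diff[0])


def _fdr_cutoff(
    t_obs_abs: np.ndarray, t_perm_abs: np.ndarray, q: float
) -> float | None:
    """Smallest |t| cutoff whose estimated FDR is <= q; None if none qualifies.

    Estimated FDR at cutoff c = (mean permutation count of |t| >= c) /
    (observed count of |t| >= c).  Candidates are the observed |t| values.
    """
    candidates = np.unique(t_obs_abs)
    perm_sorted = np.sort(t_perm_abs.ravel())
    n_perm = t_perm_abs.shape[0]
    obs_sorted = np.sort(t_obs_abs)
    n_obs = t_obs_abs.size - np.searchsorted(obs_sorted, candidates, side="left")
    n_fp = (
        perm_sorted.size - np.searchsorted(perm_sorted, candidates, side="left")
    ) / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_obs > 0, n_fp / np.maximum(n_obs, 1), np.inf)
    ok = np.nonzero(fdr <= q)[0]
    if ok.size == 0:
        return None
    return float(candidates[ok[0]])  # lowest qualifying cutoff -> largest call set


def permutation_fdr(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    config: DifferentialConfig = DifferentialConfig(),
) -> list[DifferentialResult]:
    """Moderated t-test with permutation-calibrated FDR over a dense matrix.

    ``matrix`` is items x runs (already log2-imputed); ``group_a`` /
    ``group_b`` name its columns.  Group labels are shuffled jointly across
    all items, preserving inter-item correlation.  A seed is mandatory:
    silent irreproducibility is worse than an extra flag.
    """
    if config.seed is None:
        raise ValueError("DifferentialConfig.seed must be set for permutation FDR")
    cols = list(group_a) + list(group_b)
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks run columns {missing}")
    x = matrix[cols].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; apply log2_impute first")
    na, nb = len(group_a), len(group_b)
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + nb)
    t_obs, p_obs, diff = _moderated_t(x, idx_a, idx_b, config.s0)

    rng = np.random.default_rng(config.seed)
    t_perm = np.empty((config.n_permutations, x.shape[0]))
    order = np.arange(na + nb)
    for k in range(config.n_permutations):
        perm = rng.permutation(order)
        t_perm[k], _, _ = _moderated_t(x, perm[:na], perm[na:], config.s0)

    cutoff = _fdr_cutoff(np.abs(t_obs), np.abs(t_perm), config.fdr)
    results: list[DifferentialResult] = []
    for i, item in enumerate(matrix.index):
        sig = cutoff is not None and abs(t_obs[i]) >= cutoff
        direction = "none"
        if sig:
            direction = "up" if diff[i] > 0 else "down"
        p = float(p_obs[i])
        results.append(
            DifferentialResult(
                item_id=str(item),
                diff=float(diff[i]),
                t=float(t_obs[i]),
                p=p,
                neg_log10_p=float(-np.log10(max(p, 1e-300))),
                significant=bool(sig),
                direction=direction,
            )
        )
    return results


def results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Volcano table: id, diff, t, p, -log10 p, significance flag."""
    return pd.DataFrame(
        {
            "item_id": [r.item_id for r in results],
            "diff": [r.diff for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
            "neg_log10_p": [r.neg_log10_p for r in results],
            "significant": ["+" if r.significant else "" for r in results],
            "direction": [r.direction for r in results],
        }
    )
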