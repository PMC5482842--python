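"""Predictive validation by repeated random splits and spatial residual
diagnostics (Moran's I correlograms, experimental semivariograms)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .gamm import FitError, GAMMSpec, fit

logger = logging.getLogger(__name__)


@dataclass
class ValidationSummary:
    runs: pd.DataFrame           # run, seed, train_frac, r2, rmse
    r2_median: float
    r2_iqr: tuple
    rmse_median: float
    rmse_iqr: tuple

    def to_json_dict(self) -> dict:
        return {"r2_median": self.r2_median, "r2_iqr": list(self.r2_iqr),
                "rmse_median": self.rmse_median,
                "rmse_iqr": list(self.rmse_iqr),
                "n_runs": int(len(self.runs))}


def _r2_pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation; 0 if the correlation is undefined."""
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def _r2_ss(pred: np.ndarray, obs: np.ndarray) -> float:
    """1 - SSE/SST alternative convention (may be negative)."""
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        return 0.0
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def _valid_split(table: pd.DataFrame, train_idx: np.ndarray,
                 spec: GAMMSpec) -> bool:
    train = table.iloc[train_idx]
    if spec.random and train["plot_id"].nunique() < 2:
        return False
    if spec.landform and (set(table["landform"].astype(str).unique())
                          - set(train["landform"].astype(str).unique())):
        return False
    return True


def split_validate(table: pd.DataFrame, spec: GAMMSpec | None = None, *,
                   n_runs: int = 100, train_frac: float = 0.75,
                   seed: int = 0, r2_convention: str = "pearson",
                   max_redraws: int = 50) -> ValidationSummary:
    """Repeated random-split validation.

    Each run fits on a random ``train_frac`` of rows and scores the held
    out rows with fixed effects plus the random intercepts of groups seen
    in training.  Splits leaving fewer than two training plots, a missing
    landform level, or a constant test response are redrawn (logged).
    Fully reproducible from ``seed``.
    """
    spec = spec or GAMMSpec()
    r2_fn = _r2_pearson if r2_convention == "pearson" else _r2_ss
    rng = np.random.default_rng(seed)
    n = len(table)
    n_train = int(round(train_frac * n))
    rows = []
    for run in range(n_runs):
        for attempt in range(max_redraws):
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            test = table.iloc[test_idx]
            if not _valid_split(table, train_idx, spec):
                logger.info("run %d: invalid split redrawn", run)
                continue
            if test[spec.response].nunique() <= 1:
                logger.info("run %d: degenerate test set redrawn", run)
                continue
            try:
                m = fit(table.iloc[train_idx], spec)
            except FitError as exc:
                logger.warning("run %d: fit failed (%s); split redrawn", run, exc)
                continue
            pred = m.predict(test, include_random=True)
            obs = test[spec.response].to_numpy(dtype=float)
            rows.append({"run": run, "train_frac": train_frac,
                         "n_test": len(test_idx),
                         "r2": r2_fn(pred, obs),
                         "rmse": float(np.sqrt(np.mean((pred - obs) ** 2)))})
            break
        else:
            raise RuntimeError(f"run {run}: no valid split after "
                               f"{max_redraws} redraws")
    runs = pd.DataFrame(rows)
    q = runs[["r2", "rmse"]].quantile([0.25, 0.5, 0.75])
    return ValidationSummary(
        runs=runs,
        r2_median=float(q.loc[0.5, "r2"]),
        r2_iqr=(float(q.loc[0.25, "r2"]), float(q.loc[0.75, "r2"])),
        rmse_median=float(q.loc[0.5, "rmse"]),
        rmse_iqr=(float(q.loc[0.25, "rmse"]), float(q.loc[0.75, "rmse"])))


@dataclass
class Correlogram:
    bin_edges: np.ndarray
    statistic: np.ndarray        # Moran's I per bin (NaN for empty bins)
    pair_counts: np.ndarray
    expected: float              # -1/(n-1)
    envelope_low: np.ndarray = None
    envelope_high: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1], "bin_high": self.bin_edges[1:],
            "morans_i": self.statistic, "pairs": self.pair_counts,
            "env_low": self.envelope_low, "env_high": self.envelope_high})


@dataclass
class Semivariogram:
    bin_edges: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1], "bin_high": self.bin_edges[1:],
            "gamma": self.gamma, "pairs": self.pair_counts})


def default_bins(coords: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-width distance bins to half the maximum pairwise distance."""
    dmax = float(pdist(coords).max())
    return np.linspace(0.0, dmax / 2.0, n_bins + 1)


def _morans_i_binned(z: np.ndarray, in_bin_list) -> np.ndarray:
    n = z.size
    s_zz = float(z @ z)
    out = np.empty(len(in_bin_list))
    for bi, (wsum, cross_template) in enumerate(in_bin_list):
        if wsum == 0:
            out[bi] = np.nan
        else:
            cross = float(z @ (cross_template @ z))
            out[bi] = (n / wsum) * cross / s_zz
    return out


def morans_i(values, coords, bin_edges=None, *, n_permutations: int = 199,
             seed: int = 0) -> Correlogram:
    """Moran's I per distance bin with binary weights and a permutation
    envelope (2.5/97.5 percentiles of ``n_permutations`` label shuffles)."""
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = values.size
    if n < 10:
        raise ValueError("need at least 10 points")
    if np.std(values) == 0:
        raise ValueError("zero variance in values; Moran's I undefined")
    if bin_edges is None:
        bin_edges = default_bins(coords)
    bin_edges = np.asarray(bin_edges, dtype=float)

    D = squareform(pdist(coords))
    np.fill_diagonal(D, np.inf)  # exclude self-pairs
    in_bins = []
    counts = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        W = ((D > lo) & (D <= hi)).astype(float)
        in_bins.append((float(W.sum()), W))
        counts.append(int(W.sum() / 2))
    z = values - values.mean()
    stat = _morans_i_binned(z, in_bins)

    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, len(in_bins)))
    for p in range(n_permutations):
        zp = z[rng.permutation(n)]
        perms[p] = _morans_i_binned(zp, in_bins)
    with np.errstate(invalid="ignore"):
        lo_env = np.nanpercentile(perms, 2.5, axis=0)
        hi_env = np.nanpercentile(perms, 97.5, axis=0)
    return Correlogram(bin_edges=bin_edges, statistic=stat,
                       pair_counts=np.asarray(counts),
                       expected=-1.0 / (n - 1),
                       envelope_low=lo_env, envelope_high=hi_env)


def semivariogram(values, coords, bin_edges=None) -> Semivariogram:
    """Experimental semivariogram: gamma(b) = mean squared difference / 2
    over point pairs whose separation falls in bin b."""
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if bin_edges is None:
        bin_edges = default_bins(coords)
    bin_edges = np.asarray(bin_edges, dtype=float)
    d = pdist(coords)
    dv2 = pdist(values[:, None], metric="sqeuclidean")
    gamma = np.full(len(bin_edges) - 1, np.nan)
    counts = np.zeros(len(bin_edges) - 1, dtype=int)
    for bi, (lo, hi) in enumerate(zip(bin_edges[:-1], bin_edges[1:])):
        sel = (d > lo) & (d <= hi)
        counts[bi] = int(sel.sum())
        if counts[bi]:
            gamma[bi] = 0.5 * float(np.mean(dv2[sel]))
    return Semivariogram(bin_edges=bin_edges, gamma=gamma, pair_counts=counts)
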