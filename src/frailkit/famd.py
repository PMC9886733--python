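"""Factor analysis of mixed data (FAMD) with kNN imputation.

Joint decomposition of continuous and categorical columns: continuous columns
are standardised (population SD) as in PCA; each categorical level k is coded
as the centred indicator scaled by 1/sqrt(p_k), as in multiple correspondence
analysis.  The SVD of the combined matrix with uniform row weight 1/n yields
eigenvalues that sum to ``n_continuous + sum_j (k_j - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FAMDModel", "knn_impute", "fit_famd", "select_components", "variable_contributions"]


@dataclass
class FAMDModel:
    cont_cols: list[str]
    cat_cols: list[str]
    cont_mean: np.ndarray          # per continuous column
    cont_sd: np.ndarray
    cat_levels: dict[str, list]    # observed levels per categorical column
    cat_props: dict[str, np.ndarray]
    loadings: pd.DataFrame         # expanded columns x components (unit-norm columns)
    eigenvalues: np.ndarray        # descending
    scores: np.ndarray             # subjects x components; Var(col s) = eigenvalue s
    column_of: list[str]           # source variable of each expanded column

    @property
    def explained(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())


def _check_columns(table: pd.DataFrame, cont_cols, cat_cols) -> None:
    cols = list(cont_cols) + list(cat_cols)
    if not cols:
        raise ValueError("no columns declared")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns absent from table: {missing}")


def knn_impute(
    table: pd.DataFrame,
    cont_cols: Sequence[str],
    cat_cols: Sequence[str],
    k: int = 10,
) -> pd.DataFrame:
    """k-nearest-neighbour imputation for a mixed table.

    Distance between two rows averages, over coordinates observed in both,
    squared differences of standardised continuous values and simple matching
    (0/1) on categorical values.  Continuous gaps take the mean of the k
    nearest neighbours' values; categorical gaps the modal category among
    them, ties broken by row order of the neighbours.
    """
    _check_columns(table, cont_cols, cat_cols)
    if k < 1:
        raise ValueError("k must be >= 1")
    out = table.copy()
    cont = out[list(cont_cols)].to_numpy(dtype=float) if cont_cols else np.empty((len(out), 0))
    cat = out[list(cat_cols)].to_numpy(dtype=object) if cat_cols else np.empty((len(out), 0), dtype=object)
    cat_na = pd.isna(cat) if cat.size else np.empty(cat.shape, dtype=bool)
    if not np.isnan(cont).any() and not cat_na.any():
        return out

    n = len(out)
    if (np.isnan(cont).all(axis=1) & (cat_na.all(axis=1) if cat.size else True)).any():
        raise ValueError("row with no observed value")

    mu = np.nanmean(cont, axis=0) if cont.size else np.empty(0)
    sd = np.nanstd(cont, axis=0) if cont.size else np.empty(0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (cont - mu) / sd

    z_obs = ~np.isnan(z)
    z0 = np.where(z_obs, z, 0.0)
    # pairwise mean over co-observed coordinates of squared std diffs + mismatches
    d2 = np.zeros((n, n))
    cnt = np.zeros((n, n))
    if z.size:
        cnt += z_obs.astype(float) @ z_obs.T.astype(float)
        sq = z0**2
        d2 += (sq @ z_obs.T.astype(float)) + (z_obs.astype(float) @ sq.T) - 2 * (z0 @ z0.T)
    if cat.size:
        for j in range(cat.shape[1]):
            obs_j = ~cat_na[:, j]
            both = np.outer(obs_j, obs_j)
            col = cat[:, j]
            mismatch = (col[:, None] != col[None, :]) & both
            d2 += mismatch.astype(float)
            cnt += both.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(cnt > 0, d2 / cnt, np.inf)
    np.fill_diagonal(dist, np.inf)

    cont_imp = cont.copy()
    for i in range(n):
        need_cont = np.where(np.isnan(cont[i])) [0] if cont.size else []
        need_cat = np.where(cat_na[i])[0] if cat.size else []
        if len(need_cont) == 0 and len(need_cat) == 0:
            continue
        order = np.argsort(dist[i], kind="stable")
        for j in need_cont:
            donors = [r for r in order if np.isfinite(dist[i, r]) and not np.isnan(cont[r, j])]
            if len(donors) < k:
                raise ValueError(f"fewer than k={k} candidate neighbours for row {i}")
            cont_imp[i, j] = float(np.mean([cont[r, j] for r in donors[:k]]))
        for j in need_cat:
            donors = [r for r in order if np.isfinite(dist[i, r]) and not cat_na[r, j]]
            if len(donors) < k:
                raise ValueError(f"fewer than k={k} candidate neighbours for row {i}")
            votes: dict = {}
            for r in donors[:k]:
                votes.setdefault(cat[r, j], 0)
                votes[cat[r, j]] += 1
            best = max(votes.values())
            # deterministic tie-break: first donor (row order among neighbours) holding a modal value
            for r in donors[:k]:
                if votes[cat[r, j]] == best:
                    cat[i, j] = cat[r, j]
                    break
    if cont_cols:
        out[list(cont_cols)] = cont_imp
    if cat_cols:
        out[list(cat_cols)] = cat
    return out


def fit_famd(table: pd.DataFrame, cont_cols: Sequence[str], cat_cols: Sequence[str]) -> FAMDModel:
    """Fit the mixed-data decomposition on a complete table."""
    _check_columns(table, cont_cols, cat_cols)
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    column_of: list[str] = []

    cont = table[list(cont_cols)].to_numpy(dtype=float) if cont_cols else np.empty((n, 0))
    if np.isnan(cont).any():
        raise ValueError("table must be complete; run knn_impute first")
    mu = cont.mean(axis=0) if cont.size else np.empty(0)
    sd = cont.std(axis=0) if cont.size else np.empty(0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cont_cols, sd) if s == 0]
        raise ValueError(f"zero-variance continuous column(s): {bad}")
    if cont.size:
        blocks.append((cont - mu) / sd)
        names.extend(cont_cols)
        column_of.extend(cont_cols)

    cat_levels: dict[str, list] = {}
    cat_props: dict[str, np.ndarray] = {}
    for c in cat_cols:
        col = table[c]
        if col.isna().any():
            raise ValueError("table must be complete; run knn_impute first")
        levels = sorted(pd.unique(col), key=lambda v: str(v))
        if len(levels) < 2:
            raise ValueError(f"categorical column {c!r} has a single level")
        indicator = np.column_stack([(col == lv).to_numpy(dtype=float) for lv in levels])
        p = indicator.mean(axis=0)
        blocks.append((indicator - p) / np.sqrt(p))
        names.extend(f"{c}={lv}" for lv in levels)
        column_of.extend([c] * len(levels))
        cat_levels[c] = list(levels)
        cat_props[c] = p

    Z = np.hstack(blocks) / np.sqrt(n)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eigenvalues = S**2
    V = Vt.T
    # deterministic sign: largest-|loading| entry of each component positive
    for s in range(V.shape[1]):
        idx = int(np.argmax(np.abs(V[:, s])))
        if V[idx, s] < 0:
            V[:, s] = -V[:, s]
            U[:, s] = -U[:, s]
    scores = np.sqrt(n) * U * S  # per-component variance (divisor n) = eigenvalue

    loadings = pd.DataFrame(V, index=names, columns=[f"comp{j+1}" for j in range(V.shape[1])])
    return FAMDModel(
        cont_cols=list(cont_cols),
        cat_cols=list(cat_cols),
        cont_mean=mu,
        cont_sd=sd,
        cat_levels=cat_levels,
        cat_props=cat_props,
        loadings=loadings,
        eigenvalues=eigenvalues,
        scores=scores,
        column_of=column_of,
    )


def select_components(model: FAMDModel, target: float = 0.80) -> int:
    """Smallest m whose cumulative explained-variance share reaches ``target``."""
    if not 0 < target <= 1:
        raise ValueError("target must lie in (0, 1]")
    cum = np.cumsum(model.explained)
    return int(np.searchsorted(cum, target - 1e-12) + 1)


def variable_contributions(model: FAMDModel, component: int | None = None) -> pd.DataFrame:
    """Percentage contribution of each source variable to each component.

    A variable's contribution to component s is 100 x the sum of squared
    loadings of its expanded column(s); categorical variables aggregate over
    their level columns.  Contributions sum to 100 per component.
    """
    n_comp = len(model.eigenvalues)
    if component is not None:
        if not 1 <= component <= n_comp:
            raise IndexError(f"component {component} out of range 1..{n_comp}")
    sq = model.loadings.to_numpy() ** 2 * 100.0
    frame = pd.DataFrame(sq, index=model.column_of, columns=model.loadings.columns)
    contrib = frame.groupby(level=0, sort=False).sum()
    contrib = contrib.loc[list(dict.fromkeys(model.column_of))]
    if component is not None:
        return contrib[[f"comp{component}"]]
    return contrib
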