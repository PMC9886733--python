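"""Per-deficit association with cluster membership, FDR control, selection.

Each screened deficit is regressed on the two-level cluster indicator
(deficit as dependent variable): logistic regression for binary deficits,
proportional-odds ordinal logistic regression for ordinal deficits, linear
regression for continuous deficits.  All p-values come from likelihood-ratio
tests of the cluster term; Benjamini-Hochberg adjustment and a q < alpha
cut emit the refined item list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "RefinedSelection",
    "deficit_cluster_association",
    "bh_adjust",
    "rank_deficits",
    "refine_selection",
]


@dataclass
class AssociationResult:
    name: str
    family: str           # logistic | ordinal-logistic | linear
    effect: float
    p: float
    note: str = ""        # e.g. "exact conditional fallback"


@dataclass
class RefinedSelection:
    items: list[str]      # ordered kept deficits
    alpha: float
    n_kept: int


def _as_binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"labels must have exactly 2 levels, got {len(uniq)}")
    if (labels == uniq[0]).sum() == 0 or (labels == uniq[1]).sum() == 0:
        raise ValueError("one cluster is empty")
    return (labels == uniq[1]).astype(int)


def _logistic_2x2(y: np.ndarray, g: np.ndarray) -> tuple[float, float, str]:
    """Closed-form logistic LRT of binary y on binary g (identical to 2x2 G-test)."""
    a = float(((y == 1) & (g == 1)).sum())
    b = float(((y == 0) & (g == 1)).sum())
    c = float(((y == 1) & (g == 0)).sum())
    d = float(((y == 0) & (g == 0)).sum())
    table = np.array([[a, b], [c, d]])
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    g_stat = 2.0 * terms.sum()
    if min(a, b, c, d) == 0:
        # quasi-complete separation: exact conditional (Fisher) p, Haldane log-OR
        _, p = stats.fisher_exact([[a, b], [c, d]])
        effect = float(np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))))
        return effect, float(p), "exact conditional fallback"
    effect = float(np.log((a * d) / (b * c)))
    p = float(stats.chi2.sf(g_stat, df=1))
    return effect, p, ""


def _linear(y: np.ndarray, g: np.ndarray) -> tuple[float, float, str]:
    """Gaussian LRT of continuous y on the binary indicator: n log(RSS0/RSS1)."""
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    y1, y0 = y[g == 1], y[g == 0]
    rss1 = float(((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum())
    if rss0 <= 0:
        raise ValueError("constant deficit column")
    if rss1 <= 0:
        lrt = np.inf
    else:
        lrt = n * np.log(rss0 / rss1)
    effect = float(y1.mean() - y0.mean())
    return effect, float(stats.chi2.sf(lrt, df=1)), ""


def _ordinal(y: np.ndarray, g: np.ndarray) -> tuple[float, float, str]:
    """Proportional-odds LRT via maximum likelihood; exact fallback on failure."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    levels, counts = np.unique(y, return_counts=True)
    if len(levels) < 2:
        raise ValueError("constant deficit column")
    ll0 = float((counts * np.log(counts / counts.sum())).sum())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(pd.Series(y).astype("category").cat.codes.to_numpy(), g[:, None], distr="logit")
            res = model.fit(method="bfgs", maxiter=200, disp=False)
        if not np.isfinite(res.llf) or abs(res.params[0]) > 25:
            raise RuntimeError("separation suspected")
        lrt = 2.0 * (res.llf - ll0)
        return float(res.params[0]), float(stats.chi2.sf(max(lrt, 0.0), df=1)), ""
    except Exception as exc:  # quasi-complete separation / non-convergence
        logger.warning("ordinal fit failed (%s); exact conditional fallback", exc)
        yb = (y > levels[0]).astype(int)
        effect, p, _ = _logistic_2x2(yb, g)
        return effect, p, "exact conditional fallback"


def deficit_cluster_association(deficit_column, labels, kind: str) -> AssociationResult:
    """Likelihood-ratio association between one deficit and cluster membership."""
    y_raw = pd.Series(deficit_column)
    name = y_raw.name if y_raw.name is not None else "deficit"
    mask = y_raw.notna().to_numpy()
    g = _as_binary_labels(np.asarray(labels)[mask])
    y = y_raw[mask].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"{name}: constant deficit column")
    if kind == "binary":
        y = np.asarray(y, dtype=float).astype(int)
        effect, p, note = _logistic_2x2(y, g)
        family = "logistic"
    elif kind == "ordinal":
        effect, p, note = _ordinal(np.asarray(y, dtype=float), g)
        family = "ordinal-logistic"
    elif kind == "continuous":
        effect, p, note = _linear(np.asarray(y, dtype=float), g)
        family = "linear"
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return AssociationResult(name=str(name), family=family, effect=effect, p=p, note=note)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def rank_deficits(
    matrix: pd.DataFrame,
    labels,
    kinds: dict[str, str],
) -> pd.DataFrame:
    """Association table for every deficit column, with BH q-values and ranks.

    ``kinds`` maps each column of ``matrix`` to binary/ordinal/continuous.
    Ranking is by q ascending, ties broken by raw p, then |effect| descending,
    then name.
    """
    results = []
    for col in matrix.columns:
        res = deficit_cluster_association(matrix[col], labels, kinds[col])
        results.append(res)
    df = pd.DataFrame(
        {
            "name": [r.name for r in results],
            "family": [r.family for r in results],
            "effect": [r.effect for r in results],
            "p": [r.p for r in results],
            "note": [r.note for r in results],
        }
    )
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["_abs_effect"] = df["effect"].abs()
    df = df.sort_values(["q", "p", "_abs_effect", "name"], ascending=[True, True, False, True], kind="stable")
    df = df.drop(columns="_abs_effect").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def refine_selection(results: pd.DataFrame, alpha: float = 0.05) -> RefinedSelection:
    """Keep deficits with FDR-adjusted q strictly below alpha, in rank order."""
    kept = results.loc[results["q"] < alpha]
    if kept.empty:
        logger.warning("no deficit passes FDR threshold alpha=%s; empty refined selection", alpha)
    items = kept.sort_values("rank")["name"].tolist()
    return RefinedSelection(items=items, alpha=alpha, n_kept=len(items))
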