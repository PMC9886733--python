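"""End-to-end orchestration: screen -> impute -> FAMD -> HCPC -> rank -> FI -> evaluate.

Every stage writes its artifact into the output directory and records it in a
manifest JSON along with the parameters and master seed, so a rerun with the
same configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deficits import Codebook, ScreenCriteria, build_deficit_matrix, compute_fi, screen_deficits, summarize_fi
from .famd import fit_famd, knn_impute, select_components, variable_contributions
from .hcpc import choose_q, consolidate, cut_tree, order_fit_frail, ward_tree
from .io import read_cohort
from .ranking import rank_deficits, refine_selection

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    cohort_path: str
    codebook_path: str | None  # None -> packaged fixture codebook
    out_dir: str
    criteria: ScreenCriteria = field(default_factory=ScreenCriteria)
    knn_k: int = 10
    variance_target: float = 0.80
    q: int | None = 2
    q_max: int = 10
    alpha: float = 0.05
    fi_max_missing: float = 0.20
    famd_on_scores: bool = False
    seed: int = 0
    log_level: str = "INFO"


def _load_codebook(config: RunConfig) -> Codebook:
    if config.codebook_path is None:
        from .deficits import load_table1_codebook

        return load_table1_codebook()
    return Codebook.from_yaml(config.codebook_path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "criteria": vars(config.criteria) if not isinstance(config.criteria, ScreenCriteria) else {
                "min_prevalence": config.criteria.min_prevalence,
                "max_prevalence": config.criteria.max_prevalence,
                "max_missing": config.criteria.max_missing,
            },
            "knn_k": config.knn_k,
            "variance_target": config.variance_target,
            "q": config.q,
            "q_max": config.q_max,
            "alpha": config.alpha,
            "fi_max_missing": config.fi_max_missing,
            "famd_on_scores": config.famd_on_scores,
        },
        "stages": {},
    }

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    codebook = _load_codebook(config)
    cohort = _stage("read_cohort")(lambda: read_cohort(config.cohort_path, codebook))

    # 1. screening
    report = _stage("screen")(lambda: screen_deficits(cohort, codebook, config.criteria))
    report.to_csv(out / "screen_report.tsv", sep="\t")
    kept = report.index[report["kept"]].tolist()
    manifest["stages"]["screen"] = {"output": "screen_report.tsv", "n_kept": len(kept)}

    # 2. imputation + FAMD on kept variables
    kinds = {d.name: d.kind for d in codebook.deficits}
    if config.famd_on_scores:
        table = build_deficit_matrix(cohort, codebook, items=kept)
        cont_cols: list[str] = []
        cat_cols = kept
    else:
        table = cohort[kept].copy()
        cont_cols = [c for c in kept if kinds[c] == "continuous"]
        cat_cols = [c for c in kept if kinds[c] != "continuous"]
    complete = _stage("impute")(lambda: knn_impute(table, cont_cols, cat_cols, k=config.knn_k))
    model = _stage("famd")(lambda: fit_famd(complete, cont_cols, cat_cols))
    m = select_components(model, config.variance_target)
    eig = pd.DataFrame(
        {"eigenvalue": model.eigenvalues, "share": model.explained, "cumulative": np.cumsum(model.explained)}
    )
    eig.to_csv(out / "famd_eigenvalues.tsv", sep="\t", index_label="component")
    pd.DataFrame(model.scores[:, :m]).to_csv(out / "famd_scores.csv", index=False)
    variable_contributions(model).iloc[:, : min(5, model.scores.shape[1])].to_csv(
        out / "famd_contributions.tsv", sep="\t"
    )
    manifest["stages"]["famd"] = {
        "outputs": ["famd_eigenvalues.tsv", "famd_scores.csv", "famd_contributions.tsv"],
        "n_components": m,
        "total_inertia": model.total_inertia,
    }

    # 3. clustering on retained components
    scores = model.scores[:, :m]
    tree = _stage("cluster")(lambda: ward_tree(scores))
    q = config.q if config.q is not None else choose_q(tree, q_max=min(config.q_max, tree.n - 1))
    solution = consolidate(scores, cut_tree(tree, q))
    labels = solution.labels
    manifest["stages"]["cluster"] = {
        "q": int(q),
        "within_inertia": solution.within,
        "n_iter": solution.n_iter,
        "output": "cluster_labels.csv",
    }

    # 4. ranking + refined selection on the kept raw-scale variables
    rank_table = _stage("rank")(lambda: rank_deficits(cohort[kept], labels, {k: kinds[k] for k in kept}))
    rank_table.to_csv(out / "ranking.tsv", sep="\t", index=False)
    selection = refine_selection(rank_table, alpha=config.alpha)
    manifest["stages"]["rank"] = {"output": "ranking.tsv", "n_kept": selection.n_kept, "alpha": config.alpha}

    # 5. FI variants
    matrix = build_deficit_matrix(cohort, codebook, items=kept)
    fi_table = pd.DataFrame(index=cohort.index)
    fi_table["fi_s"] = compute_fi(matrix, kept, max_missing=config.fi_max_missing)
    if selection.items:
        fi_table["fi_r"] = compute_fi(matrix, selection.items, max_missing=config.fi_max_missing)
    fic_items = [c for c in codebook.item_list("fi_c") if c in matrix.columns]
    if fic_items:
        fi_table["fi_c"] = compute_fi(matrix, fic_items, max_missing=config.fi_max_missing)
    if len(np.unique(labels)) == 2:
        fi_table["cluster"] = order_fit_frail(labels, fi_table["fi_s"].to_numpy())
    else:
        fi_table["cluster"] = labels
    fi_table.to_csv(out / "fi_table.csv", index=False)
    pd.DataFrame(
        {"subject": cohort.index, "cluster": fi_table["cluster"]}
    ).to_csv(out / "cluster_labels.csv", index=False)
    manifest["stages"]["fi"] = {
        "output": "fi_table.csv",
        "variants": [c for c in fi_table.columns if c.startswith("fi_")],
        "summary": {c: summarize_fi(fi_table[c]) for c in fi_table.columns if c.startswith("fi_")},
    }

    manifest["refined_items"] = selection.items
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
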