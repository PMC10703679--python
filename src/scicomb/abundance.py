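"""Differential cell-type abundance across conditions.

Cells are tallied per (subcluster, RT well); each well is a replicate nested
in one animal, condition and sex. Per subcluster, an NB-GLM LRT compares
counts ~ condition (+ sex) against counts ~ (sex), with a log(replicate
total) offset — i.e. a test on cell fractions. Fold change between
conditions is computed on pooled fractions with a 1e-5 pseudocount, so empty
subclusters give a finite, symmetric ratio. A subcluster is called changed
when |log2 FC| crosses twofold and q < 0.05; subclusters with fewer than 20
cells in either sex are excluded from calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .stats import bh_adjust, nb_lrt


@dataclass
class AbundanceTable:
    counts: pd.DataFrame  # subcluster x replicate
    replicate_meta: pd.DataFrame  # index replicate; columns animal, condition, sex

    def __post_init__(self):
        if list(self.counts.columns) != list(self.replicate_meta.index):
            raise ValueError("replicate columns and metadata rows must align")
        for col in ("animal", "condition", "sex"):
            if col not in self.replicate_meta.columns:
                raise ValueError(f"replicate_meta missing {col!r}")

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def build_abundance_table(cell_meta: pd.DataFrame) -> AbundanceTable:
    """Tally cells into a subcluster x replicate matrix (explicit zeros).

    ``cell_meta`` needs columns subcluster, replicate, animal, condition,
    sex; a row with any missing value is an error naming the cell.
    """
    required = ["subcluster", "replicate", "animal", "condition", "sex"]
    missing_cols = [c for c in required if c not in cell_meta.columns]
    if missing_cols:
        raise ValueError(f"cell metadata missing columns {missing_cols}")
    bad = cell_meta[required].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"cells with missing metadata: {cell_meta.index[bad].tolist()[:5]}")
    counts = (
        cell_meta.groupby(["subcluster", "replicate"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    meta = (
        cell_meta[["replicate", "animal", "condition", "sex"]]
        .drop_duplicates()
        .set_index("replicate")
    )
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"replicates with inconsistent metadata: {dup}")
    meta = meta.loc[counts.columns]
    return AbundanceTable(counts, meta)


def abundance_fold_change(
    table: AbundanceTable, case: str, control: str, pseudocount: float = 1e-5
) -> pd.Series:
    """FC = (case fraction + pc) / (control fraction + pc), per subcluster."""
    cond = table.replicate_meta["condition"]
    out = {}
    fracs = {}
    for label, name in ((case, "case"), (control, "control")):
        cols = cond.index[cond == label]
        if len(cols) == 0:
            raise ValueError(f"condition {label!r} absent from the table")
        sub = table.counts[cols].sum(axis=1)
        total = sub.sum()
        if total == 0:
            raise ValueError(f"condition {label!r} has zero cells")
        fracs[name] = sub / total
    return (fracs["case"] + pseudocount) / (fracs["control"] + pseudocount)


def test_abundance(
    table: AbundanceTable,
    case: str,
    control: str,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-subcluster NB-GLM LRT of condition with log-total offset.

    Returns a table with lrt_stat, p, q; all-zero subclusters get q = 1 and
    a flag instead of a model fit.
    """
    cond = table.replicate_meta["condition"]
    cols = cond.index[cond.isin([case, control])]
    if (cond.loc[cols] == case).sum() < 2 or (cond.loc[cols] == control).sum() < 2:
        raise ValueError("need >=2 replicates per condition")
    sub = table.counts[cols]
    meta = table.replicate_meta.loc[cols]
    offset = np.log(sub.sum(axis=0).to_numpy().astype(float))
    is_case = (meta["condition"] == case).to_numpy(dtype=float)
    X_red = np.ones((len(cols), 1))
    if config.abundance_sex_covariate and meta["sex"].nunique() > 1:
        X_red = np.hstack([X_red, pd.get_dummies(meta["sex"], drop_first=True, dtype=float).to_numpy()])
    X_full = np.hstack([X_red, is_case[:, None]])
    rows = []
    for sc in sub.index:
        y = sub.loc[sc].to_numpy(dtype=float)
        if y.sum() == 0:
            rows.append({"subcluster": sc, "lrt_stat": 0.0, "p": np.nan, "flag": "all_zero"})
            continue
        res = nb_lrt(y, X_full, X_red, offset)
        rows.append({"subcluster": sc, "lrt_stat": res.lrt_stat, "p": res.p,
                     "flag": "" if res.converged else "degenerate"})
    out = pd.DataFrame(rows).set_index("subcluster")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.loc[out["flag"] == "all_zero", "q"] = 1.0
    return out


def cells_per_sex(table: AbundanceTable) -> pd.DataFrame:
    sex = table.replicate_meta["sex"]
    out = {}
    for s in sorted(sex.unique()):
        out[s] = table.counts[sex.index[sex == s]].sum(axis=1)
    return pd.DataFrame(out)


def call_significant(
    fc: pd.Series, q: pd.Series, table: AbundanceTable, config: PipelineConfig
) -> pd.DataFrame:
    """Classify each subcluster: up / down / ns / excluded.

    Exclusion (fewer than ``abundance_min_cells_per_sex`` cells in either
    sex) takes precedence over significance.
    """
    per_sex = cells_per_sex(table)
    min_sex = per_sex.min(axis=1)
    rows = []
    for sc in fc.index:
        if min_sex.loc[sc] < config.abundance_min_cells_per_sex:
            call = "excluded"
        elif q.loc[sc] < config.de_fdr and fc.loc[sc] > config.abundance_fc_min:
            call = "up"
        elif q.loc[sc] < config.de_fdr and fc.loc[sc] < 1.0 / config.abundance_fc_min:
            call = "down"
        else:
            call = "ns"
        rows.append({"subcluster": sc, "fc": fc.loc[sc], "q": q.loc[sc],
                     "min_cells_per_sex": int(min_sex.loc[sc]), "call": call})
    return pd.DataFrame(rows).set_index("subcluster")
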