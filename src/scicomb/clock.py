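"""Transcriptomic aging clock.

Cells of one cell type are merged into pseudobulk profiles of ~15 randomly
binned cells within each animal (bins never span animals, so no profile
mixes ages). A ridge regression predicts ln(age in months) from the
standardized pseudobulk expression, trained on 80% of the pseudobulk cells
with the remaining 20% held out; the split is stratified so that no animal
contributes to both sides. The ridge penalty is chosen by internal 5-fold
cross-validation over a log-spaced grid unless fixed by the caller.

Age acceleration of a query profile is predicted ln(age) minus chronological
ln(age); positive values mean an older-than-expected transcriptome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge, RidgeCV

from .config import PipelineConfig


def make_pseudobulk(
    expr: pd.DataFrame,  # cells x genes, normalized scale
    cell_meta: pd.DataFrame,  # index cell; columns animal, cell_type
    animal_meta: pd.DataFrame,  # index animal; column age_months
    k: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Average random bins of ~k cells within each (animal, cell type).

    Returns a frame with the pseudobulk profiles plus columns ``animal``,
    ``cell_type`` and ``ln_age``. Groups with fewer than k/2 cells are
    dropped.
    """
    rng = np.random.default_rng(seed)
    rows = []
    meta_rows = []
    for (animal, ctype), grp in sorted(
        cell_meta.groupby(["animal", "cell_type"], sort=True), key=lambda t: t[0]
    ):
        cells = sorted(grp.index)
        if len(cells) < k / 2:
            continue
        cells = list(rng.permutation(cells))
        n_bins = max(1, round(len(cells) / k))
        for b in range(n_bins):
            members = cells[b::n_bins]
            rows.append(expr.loc[members].mean(axis=0))
            meta_rows.append(
                {
                    "animal": animal,
                    "cell_type": ctype,
                    "n_cells": len(members),
                    "ln_age": float(np.log(animal_meta.loc[animal, "age_months"])),
                }
            )
    if not rows:
        raise ValueError("no (animal, cell type) group reached k/2 cells")
    profiles = pd.DataFrame(rows).reset_index(drop=True)
    meta = pd.DataFrame(meta_rows)
    return pd.concat([profiles, meta], axis=1)


@dataclass
class ClockModel:
    cell_type: str
    features: List[str]
    coefficients: np.ndarray
    intercept: float
    ridge_penalty: float
    feature_mean: np.ndarray
    feature_std: np.ndarray
    train_animals: List = field(default_factory=list)

    def predict(self, profiles: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in profiles.columns]
        if missing:
            raise ValueError(f"query profiles missing features: {missing[:5]}")
        X = profiles[self.features].to_numpy(dtype=float)
        Xs = (X - self.feature_mean) / self.feature_std
        return Xs @ self.coefficients + self.intercept

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cell_type": self.cell_type,
                    "features": self.features,
                    "coefficients": self.coefficients.tolist(),
                    "intercept": self.intercept,
                    "ridge_penalty": self.ridge_penalty,
                    "feature_mean": self.feature_mean.tolist(),
                    "feature_std": self.feature_std.tolist(),
                    "train_animals": [str(a) for a in self.train_animals],
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        d = json.loads(Path(path).read_text())
        return cls(
            d["cell_type"], d["features"], np.asarray(d["coefficients"]),
            d["intercept"], d["ridge_penalty"], np.asarray(d["feature_mean"]),
            np.asarray(d["feature_std"]), d["train_animals"],
        )


def _split_by_animal(meta: pd.DataFrame, train_frac: float, rng) -> Tuple[np.ndarray, np.ndarray]:
    """80/20 split stratified by age group, at animal granularity, so no
    animal spans both sides."""
    train_animals = []
    for _, grp in meta.drop_duplicates("animal").groupby("ln_age"):
        animals = sorted(grp["animal"])
        animals = list(rng.permutation(animals))
        n_train = max(1, int(round(train_frac * len(animals))))
        if n_train == len(animals) and len(animals) > 1:
            n_train -= 1
        train_animals.extend(animals[:n_train])
    is_train = meta["animal"].isin(train_animals).to_numpy()
    return np.where(is_train)[0], np.where(~is_train)[0]


def fit_clock(
    pseudobulk: pd.DataFrame,
    config: PipelineConfig,
    seed: int = 0,
    penalty: Optional[float] = None,
) -> Dict[str, Tuple[ClockModel, pd.DataFrame]]:
    """Fit one ridge clock per cell type.

    Returns ``{cell_type: (model, holdout)}`` where ``holdout`` carries the
    held-out profiles' predicted and true ln(age). Cell types observed at
    fewer than three distinct ages are skipped.
    """
    meta_cols = ["animal", "cell_type", "n_cells", "ln_age"]
    features = [c for c in pseudobulk.columns if c not in meta_cols]
    out = {}
    rng = np.random.default_rng(seed)
    for ctype, grp in pseudobulk.groupby("cell_type"):
        if grp["ln_age"].nunique() < 3:
            continue
        tr, te = _split_by_animal(grp, config.clock_train_frac, rng)
        X = grp[features].to_numpy(dtype=float)
        y = grp["ln_age"].to_numpy(dtype=float)
        mean = X[tr].mean(axis=0)
        std = X[tr].std(axis=0)
        std = np.where(std > 0, std, 1.0)
        Xs = (X - mean) / std
        if penalty is None:
            cv = RidgeCV(alphas=np.logspace(-4, 4, 17)).fit(Xs[tr], y[tr])
            alpha = float(cv.alpha_)
        else:
            alpha = float(penalty)
        model = Ridge(alpha=alpha, solver="svd").fit(Xs[tr], y[tr])
        cm = ClockModel(
            str(ctype), features, model.coef_.copy(), float(model.intercept_),
            alpha, mean, std, sorted(grp.iloc[tr]["animal"].unique().tolist()),
        )
        holdout = grp.iloc[te][["animal", "ln_age"]].copy()
        holdout["predicted_ln_age"] = Xs[te] @ cm.coefficients + cm.intercept
        out[str(ctype)] = (cm, holdout.reset_index(drop=True))
    if not out:
        raise ValueError("no cell type had >= 3 distinct ages")
    return out


def age_acceleration(model: ClockModel, profiles: pd.DataFrame, ln_age: Sequence[float]) -> pd.Series:
    """Predicted ln(age) minus chronological ln(age) per query profile."""
    pred = model.predict(profiles)
    return pd.Series(pred - np.asarray(ln_age, dtype=float), index=profiles.index, name="age_acceleration")
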