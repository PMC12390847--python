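"""Predicting soil native pH from presence/absence of resurgent-growth taxa.

Samples whose metabolite dynamics fall in the resurgent-growth regime
(Regime III) are encoded as binary presence/absence vectors over the enriched
taxa (at a chosen taxonomic level and relative-abundance threshold).  A LASSO
linear model with additive terms predicts the native pH of the source soil;
the penalty is chosen by ten-fold cross-validation.  Prediction quality (R^2)
is computed on per-soil means, both in-sample and under a leave-one-soil-out
(LOSO) procedure, and calibrated against a soil-level permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .abundance import CountTable

__all__ = [
    "PresenceMatrix",
    "PHRegressionResult",
    "NativePHLasso",
    "build_presence_matrix",
    "fit_lasso_cv",
    "loso_predict",
    "r2_by_soil",
    "permutation_pvalue",
]


@dataclass
class PresenceMatrix:
    """Binary samples x taxa matrix with per-sample soil id and native pH."""

    X: pd.DataFrame  # binary entries
    native_ph: pd.Series
    soil_id: pd.Series

    def __post_init__(self) -> None:
        vals = self.X.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence entries must be binary")
        if self.native_ph.isna().any():
            raise ValueError("every sample needs a native pH")


@dataclass
class PHRegressionResult:
    coefficients: pd.Series
    intercept: float
    alpha: float
    pred_in: pd.Series
    r2_in: float
    pred_loso: pd.Series | None = None
    r2_loso: float | None = None
    permutation_p: float | None = None
    perm_r2: np.ndarray | None = None


def build_presence_matrix(table: CountTable, enriched: set, level: str = "family",
                          rel_thresh: float = 0.001,
                          sample_ids=None) -> PresenceMatrix:
    """Binary presence of enriched taxa at a relative-abundance threshold.

    Relative abundance is reads/total reads of the sample (spike-ins
    excluded).  ASVs are aggregated to ``level`` by summing relative
    abundances before thresholding, so a taxon is present if its members
    jointly exceed the threshold (OR at threshold 0).
    """
    if not enriched:
        raise ValueError("empty enriched taxon set")
    counts = table.counts.drop(columns=list(table.spike_ids))
    if sample_ids is not None:
        counts = counts.loc[sample_ids]
    asvs = [a for a in enriched if a in counts.columns]
    if not asvs:
        raise ValueError("no enriched ASVs present in the count table")
    rel = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    rel = rel[asvs]
    if level == "asv":
        grouped = rel
    else:
        labels = table.taxonomy.reindex(asvs)[level].fillna("unassigned")
        grouped = rel.T.groupby(labels.values).sum().T
    X = (grouped > rel_thresh).astype(int)
    meta = table.meta.loc[X.index]
    return PresenceMatrix(X=X, native_ph=meta["native_pH"].astype(float),
                          soil_id=meta["soil_id"].astype(str))


class NativePHLasso:
    """Model object for the native-pH LASSO analysis."""

    def __init__(self, presence: PresenceMatrix, folds: int = 10, seed: int = 0,
                 n_alphas: int = 50):
        if presence.native_ph.nunique() < 2:
            raise ValueError("constant response: regression degenerate")
        self.presence = presence
        self.folds = folds
        self.seed = seed
        self.n_alphas = n_alphas

    def _fit_lasso(self, X: np.ndarray, y: np.ndarray, seed: int) -> LassoCV:
        cv = KFold(n_splits=min(self.folds, len(y)), shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = LassoCV(cv=cv, alphas=self.n_alphas, random_state=seed,
                            max_iter=5000)
            model.fit(X, y)
        return model

    def fit(self, loso: bool = True, n_perm: int = 0, perm_seed: int | None = None
            ) -> PHRegressionResult:
        """Fit the CV-penalized LASSO; optionally add LOSO predictions and a
        soil-level permutation p-value for the in-sample R^2."""
        P = self.presence
        X = P.X.to_numpy(float)
        y = P.native_ph.to_numpy(float)
        model = self._fit_lasso(X, y, self.seed)
        pred_in = pd.Series(model.predict(X), index=P.X.index)
        res = PHRegressionResult(
            coefficients=pd.Series(model.coef_, index=P.X.columns),
            intercept=float(model.intercept_),
            alpha=float(model.alpha_),
            pred_in=pred_in,
            r2_in=r2_by_soil(pred_in, P.native_ph, P.soil_id),
        )
        if loso:
            res.pred_loso = self._loso_predict()
            res.r2_loso = r2_by_soil(res.pred_loso, P.native_ph, P.soil_id)
        if n_perm:
            res.permutation_p, res.perm_r2 = self._permutation(n_perm, perm_seed)
        return res

    def _loso_predict(self) -> pd.Series:
        P = self.presence
        soils = P.soil_id.unique()
        if len(soils) < 3:
            raise ValueError("leave-one-soil-out needs at least 3 soils")
        preds = pd.Series(index=P.X.index, dtype=float)
        for soil in soils:
            test = P.soil_id == soil
            Xtr = P.X.loc[~test].to_numpy(float)
            ytr = P.native_ph.loc[~test].to_numpy(float)
            model = self._fit_lasso(Xtr, ytr, self.seed)
            preds.loc[test] = model.predict(P.X.loc[test].to_numpy(float))
        return preds

    def _permutation(self, n_perm: int, seed: int | None) -> tuple[float, np.ndarray]:
        """Permute native pH at the soil level (all samples of a soil move
        together), refit, and collect in-sample soil-level R^2 values."""
        if n_perm < 100:
            warnings.warn("fewer than 100 permutations: p-value will be coarse")
        P = self.presence
        rng = np.random.default_rng(self.seed if seed is None else seed)
        soils = P.soil_id.unique()
        soil_ph = P.native_ph.groupby(P.soil_id).first()
        X = P.X.to_numpy(float)
        obs = self.fit(loso=False).r2_in
        r2s = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(soil_ph.loc[soils].to_numpy())
            ph_map = dict(zip(soils, perm))
            y = P.soil_id.map(ph_map).to_numpy(float)
            if np.unique(y).size < 2:
                r2s[b] = 0.0
                continue
            model = self._fit_lasso(X, y, self.seed)
            pred = pd.Series(model.predict(X), index=P.X.index)
            r2s[b] = r2_by_soil(pred, pd.Series(y, index=P.X.index), P.soil_id)
        p = (1.0 + np.sum(r2s >= obs)) / (1.0 + n_perm)
        return float(p), r2s


def fit_lasso_cv(presence: PresenceMatrix, folds: int = 10, seed: int = 0,
                 **kwargs) -> PHRegressionResult:
    """Functional facade: CV-min LASSO of native pH on presences."""
    return NativePHLasso(presence, folds=folds, seed=seed).fit(**kwargs)


def loso_predict(presence: PresenceMatrix, folds: int = 10, seed: int = 0) -> pd.Series:
    """Out-of-sample predictions, refitting with each soil held out in turn."""
    return NativePHLasso(presence, folds=folds, seed=seed)._loso_predict()


def r2_by_soil(pred: pd.Series, obs: pd.Series, soil_id: pd.Series) -> float:
    """R^2 = 1 - SS_res/SS_tot on per-soil mean predicted vs observed pH.

    May be negative: predictions worse than the mean.
    """
    pm = pred.groupby(soil_id).mean()
    om = obs.groupby(soil_id).mean()
    if len(om) < 2 or np.allclose(om.var(ddof=0), 0):
        raise ValueError("observed per-soil means have no variance")
    ss_res = float(((pm - om) ** 2).sum())
    ss_tot = float(((om - om.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def permutation_pvalue(presence: PresenceMatrix, n_perm: int = 1000,
                       seed: int = 0, folds: int = 10) -> tuple[float, np.ndarray]:
    """Soil-level permutation p-value of the in-sample soil-level R^2,
    smoothed as (1 + #{perm >= obs})/(1 + n_perm)."""
    return NativePHLasso(presence, folds=folds, seed=seed)._permutation(n_perm, seed)
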