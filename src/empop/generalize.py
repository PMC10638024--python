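"""Model x morphology evaluation, selection and variability statistics.

Every (e-model, morphology) pair is evaluated — optionally after rho-factor
AIS/soma adaptation — and classified as VALID (cost below the 5 sd
threshold), FEATURE_FAIL (some feature z-score at or above it) or
NON_SPIKING (the rheobase search failed).  A generalizable sub-population
is then selected by greedily pruning the worst-failing rows/columns until
the remaining submatrix's VALID fraction reaches a target (default 0.95).

Variability statistics: the mean-centered Levene test (one-way ANOVA on
absolute deviations from group means) compares feature-variance between
groups; Pearson correlations link parameters to features; feature-feature
dependence beyond linearity is measured with equal-frequency binned mutual
information.

Gradient-boosted tree surrogates (pluggable, XGBoost by default) predict
rho-factor targets and resistance-model coefficients from the normalized
parameters passing a Pearson filter (|r| > 0.4 and 0.7 respectively), and
classify e-model generalizability from all parameters.  Predictions are
only emitted for inputs whose selected parameters lie within the training
10th-90th percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cost import VALIDITY_THRESHOLD, FeatureTarget, evaluate_emodel
from .morph import Morphology
from .protocols import ProtocolSuite
from .rho import AdaptationResult, ResistanceSurrogate, RhoError, RhoTargets, adapt_ais_soma

__all__ = [
    "EvalMatrix",
    "SelectionConfig",
    "evaluate_pairs",
    "select_generalizable",
    "levene_mean_centered",
    "correlation_analysis",
    "binned_mutual_information",
    "FilteredRegressor",
    "train_surrogates",
]

STATUSES = ("VALID", "FEATURE_FAIL", "NON_SPIKING", "FAILED")


@dataclass
class SelectionConfig:
    validity_threshold: float = VALIDITY_THRESHOLD  # sd
    strict_threshold: float = 3.0  # sd
    target_fraction: float = 0.95  # required VALID fraction after selection

    def __post_init__(self) -> None:
        if self.validity_threshold <= 0 or self.strict_threshold <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class EvalMatrix:
    """Complete e-model x morphology evaluation grid."""

    emodels: list[str]
    morphologies: list[str]
    status: np.ndarray  # (n_emodels, n_morphs) of STATUSES strings
    cost: np.ndarray  # (n_emodels, n_morphs)
    rho: np.ndarray  # achieved rho per pair (nan without adaptation)
    rho_ais: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.emodels):
            for j, m in enumerate(self.morphologies):
                rows.append(
                    {
                        "emodel": e, "morph": m, "status": self.status[i, j],
                        "cost": self.cost[i, j], "rho": self.rho[i, j],
                        "rho_ais": self.rho_ais[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def valid_fraction(self) -> float:
        return float(np.mean(self.status == "VALID"))


def evaluate_pairs(
    emodels: dict[str, dict[str, float]],
    morphs: dict[str, Morphology],
    targets: list[FeatureTarget],
    suite: ProtocolSuite | None = None,
    *,
    adapt: bool = False,
    rho_targets: dict[str, RhoTargets] | None = None,
    surrogates: dict[str, tuple[ResistanceSurrogate, ResistanceSurrogate]] | None = None,
    base_params: dict[str, float] | None = None,
    validity_threshold: float = VALIDITY_THRESHOLD,
) -> EvalMatrix:
    """Evaluate every (e-model, morphology) pair with the reduced feature set.

    With ``adapt=True``, ``rho_targets`` (keyed by e-model id) and
    ``surrogates`` (``(soma, AIS)`` per e-model) must be provided; pairs
    whose adaptation fails are marked FAILED with the sentinel cost.
    """
    suite = suite or ProtocolSuite()
    if adapt and (rho_targets is None or surrogates is None):
        raise ValueError("adapt=True requires rho_targets and surrogates")
    e_ids = list(emodels)
    m_ids = list(morphs)
    shape = (len(e_ids), len(m_ids))
    status = np.full(shape, "FAILED", dtype=object)
    cost = np.full(shape, np.nan)
    rho = np.full(shape, np.nan)
    rho_ais = np.full(shape, np.nan)
    for i, eid in enumerate(e_ids):
        params = emodels[eid]
        for j, mid in enumerate(m_ids):
            soma_scale = ais_scale = 1.0
            if adapt:
                try:
                    soma_sur, ais_sur = surrogates[eid]
                    adapted: AdaptationResult = adapt_ais_soma(
                        morphs[mid], {**(base_params or {}), **params},
                        rho_targets[eid], soma_sur, ais_sur,
                    )
                    soma_scale, ais_scale = adapted.soma_scale, adapted.ais_scale
                    rho[i, j] = adapted.achieved.rho
                    rho_ais[i, j] = adapted.achieved.rho_ais
                except (RhoError, KeyError) as exc:
                    status[i, j] = "FAILED"
                    continue
            res = evaluate_emodel(
                params, morphs[mid], suite, targets, feature_set="reduced",
                soma_scale=soma_scale, ais_scale=ais_scale, base_params=base_params,
                validity_threshold=validity_threshold,
            )
            status[i, j] = res.status
            cost[i, j] = res.cost
    return EvalMatrix(
        emodels=e_ids, morphologies=m_ids, status=status,
        cost=cost, rho=rho, rho_ais=rho_ais,
    )


def select_generalizable(
    matrix: EvalMatrix, cfg: SelectionConfig | None = None
) -> tuple[list[str], list[str]]:
    """Greedy selection of a generalizable sub-population.

    Repeatedly drop the e-model row or morphology column with the most
    non-VALID cells (whichever single removal eliminates more failures;
    ties prefer dropping a row) until the remaining submatrix's VALID
    fraction reaches the target.  Deterministic; may return empty lists.
    """
    cfg = cfg or SelectionConfig()
    ok = matrix.status == "VALID"
    rows = list(range(len(matrix.emodels)))
    cols = list(range(len(matrix.morphologies)))
    while rows and cols:
        sub = ok[np.ix_(rows, cols)]
        if sub.mean() >= cfg.target_fraction:
            break
        row_fail = (~sub).sum(axis=1)
        col_fail = (~sub).sum(axis=0)
        ri = int(np.argmax(row_fail))
        ci = int(np.argmax(col_fail))
        if row_fail[ri] >= col_fail[ci]:
            rows.pop(ri)
        else:
            cols.pop(ci)
    if not rows or not cols:
        import warnings

        warnings.warn("selection is empty: no submatrix reached the target fraction")
        return [], []
    return [matrix.emodels[i] for i in rows], [matrix.morphologies[j] for j in cols]


def levene_mean_centered(groups: list[np.ndarray]) -> tuple[float, float]:
    """Levene's test for equal variances, centered with the group means.

    One-way ANOVA on absolute deviations from group means; degenerate input
    with zero within-group variance everywhere returns (0, 1).
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    devs = [np.abs(a - a.mean()) for a in arrs]
    # degenerate: identical absolute deviations everywhere (0/0 in the ANOVA)
    if np.ptp(np.concatenate(devs)) == 0:
        return 0.0, 1.0
    w, p = stats.levene(*arrs, center="mean")
    return float(w), float(p)


def binned_mutual_information(
    x: np.ndarray, y: np.ndarray, bins: int = 16, remove_outliers: bool = False
) -> float:
    """Mutual information (nats) from equal-frequency binning.

    Ties are broken by rank order before quantile binning.  Optional outlier
    removal drops points outside median +- 5 MAD on either variable.
    """
    from sklearn.metrics import mutual_info_score

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if remove_outliers:
        keep = np.ones(len(x), dtype=bool)
        for v in (x, y):
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            if mad > 0:
                keep &= np.abs(v - med) <= 5 * mad
        x, y = x[keep], y[keep]

    def quantile_codes(v: np.ndarray) -> np.ndarray:
        ranks = stats.rankdata(v, method="ordinal")  # rank order breaks ties
        return np.minimum(((ranks - 1) * bins) // len(v), bins - 1).astype(int)

    return float(mutual_info_score(quantile_codes(x), quantile_codes(y)))


def correlation_analysis(
    frame: pd.DataFrame,
    param_cols: list[str] | None = None,
    feature_cols: list[str] | None = None,
    mi_bins: int = 16,
    remove_outliers: bool = False,
) -> dict:
    """Pearson r and p for parameter-feature and parameter-parameter pairs,
    plus binned mutual information between features.

    Column conventions follow :func:`empop.mcmc.records_to_frame`:
    parameters as ``param:<name>``, features/z-scores as any other numeric
    column passed in ``feature_cols``.  Constant columns yield missing (NaN)
    correlations.
    """
    if len(frame) < 30:
        raise ValueError("need >= 30 samples for correlation analysis")
    if param_cols is None:
        param_cols = [c for c in frame.columns if c.startswith("param:")]
    if feature_cols is None:
        feature_cols = [c for c in frame.columns if c.startswith("feat:")]

    def pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        if np.std(a) == 0 or np.std(b) == 0:
            return math.nan, math.nan
        r, p = stats.pearsonr(a, b)
        return float(r), float(p)

    pf_r = pd.DataFrame(index=param_cols, columns=feature_cols, dtype=float)
    pf_p = pf_r.copy()
    for pc in param_cols:
        for fc in feature_cols:
            r, p = pearson(frame[pc].to_numpy(), frame[fc].to_numpy())
            pf_r.loc[pc, fc] = r
            pf_p.loc[pc, fc] = p
    pp_r = pd.DataFrame(index=param_cols, columns=param_cols, dtype=float)
    for a in param_cols:
        for b in param_cols:
            pp_r.loc[a, b] = pearson(frame[a].to_numpy(), frame[b].to_numpy())[0]
    ff_mi = pd.DataFrame(index=feature_cols, columns=feature_cols, dtype=float)
    for a in feature_cols:
        for b in feature_cols:
            ff_mi.loc[a, b] = binned_mutual_information(
                frame[a].to_numpy(), frame[b].to_numpy(), mi_bins, remove_outliers
            )
    return {
        "param_feature_r": pf_r,
        "param_feature_p": pf_p,
        "param_param_r": pp_r,
        "feature_feature_mi": ff_mi,
    }


# ---------------------------------------------------------------------------
# ML surrogates
# ---------------------------------------------------------------------------

def _default_learner(kind: str):
    """Gradient-boosted trees; XGBoost when available, sklearn otherwise."""
    try:
        import xgboost as xgb

        if kind == "regressor":
            return xgb.XGBRegressor(learning_rate=0.1, n_estimators=100, verbosity=0)
        return xgb.XGBClassifier(learning_rate=0.1, n_estimators=100, verbosity=0)
    except ImportError:
        from sklearn.ensemble import (
            GradientBoostingClassifier,
            GradientBoostingRegressor,
        )

        if kind == "regressor":
            return GradientBoostingRegressor(learning_rate=0.1)
        return GradientBoostingClassifier(learning_rate=0.1)


@dataclass
class FilteredRegressor:
    """Pearson-filtered, percentile-guarded regressor for one target.

    Only parameters with |Pearson r| above ``r_threshold`` enter the model;
    with no such parameter the predictor degrades to the training mean.
    Predictions are refused (NaN + flag) for inputs whose selected
    parameters fall outside the training 10th-90th percentiles.
    """

    r_threshold: float
    selected: list[str] = field(default_factory=list)
    model: object | None = None
    fallback_mean: float = math.nan
    p10: np.ndarray | None = None
    p90: np.ndarray | None = None
    cv_scores: np.ndarray | None = None

    def fit(self, X: pd.DataFrame, y: np.ndarray, learner=None, cv: int = 10) -> "FilteredRegressor":
        y = np.asarray(y, dtype=float)
        if np.std(y) == 0:
            import warnings

            warnings.warn("degenerate constant target; using mean predictor")
            self.fallback_mean = float(y.mean())
            self.selected = []
            return self
        self.selected = [
            c
            for c in X.columns
            if np.std(X[c]) > 0 and abs(stats.pearsonr(X[c], y)[0]) > self.r_threshold
        ]
        self.fallback_mean = float(y.mean())
        if not self.selected:
            return self
        Xs = X[self.selected].to_numpy()
        self.p10 = np.percentile(Xs, 10, axis=0)
        self.p90 = np.percentile(Xs, 90, axis=0)
        self.model = learner if learner is not None else _default_learner("regressor")
        if cv and len(y) >= cv * 2:
            from sklearn.base import clone
            from sklearn.model_selection import cross_val_score

            self.cv_scores = cross_val_score(clone(self.model), Xs, y, cv=cv, scoring="r2")
        self.model.fit(Xs, y)
        return self

    def predict(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Returns (predictions, in_range mask); out-of-range rows are NaN."""
        n = len(X)
        if not self.selected:
            return np.full(n, self.fallback_mean), np.ones(n, dtype=bool)
        Xs = X[self.selected].to_numpy()
        in_range = np.all((Xs >= self.p10) & (Xs <= self.p90), axis=1)
        out = np.full(n, np.nan)
        if in_range.any():
            out[in_range] = self.model.predict(Xs[in_range])
        return out, in_range


def train_surrogates(
    records: pd.DataFrame,
    *,
    rho_targets: pd.DataFrame | None = None,
    resistance_coeffs: pd.DataFrame | None = None,
    generalizable: np.ndarray | None = None,
    learner_factory=None,
    cv: int = 10,
) -> dict:
    """Train the rho regressors (|r| > 0.4 filter), resistance-coefficient
    regressors (|r| > 0.7) and the generalizability classifier.

    ``records`` must carry ``param:`` columns aligned row-wise with the
    supplied targets.  Returns a dict with one FilteredRegressor per target
    column and, when labels are given, the fitted classifier with its
    10-fold accuracy scores.
    """
    if len(records) < 50:
        raise ValueError("need >= 50 training records")
    param_cols = [c for c in records.columns if c.startswith("param:")]
    X = records[param_cols]
    out: dict = {}
    if rho_targets is not None:
        out["rho"] = {
            col: FilteredRegressor(r_threshold=0.4).fit(
                X, rho_targets[col].to_numpy(),
                learner=learner_factory("regressor") if learner_factory else None,
                cv=cv,
            )
            for col in rho_targets.columns
        }
    if resistance_coeffs is not None:
        out["resistance"] = {
            col: FilteredRegressor(r_threshold=0.7).fit(
                X, resistance_coeffs[col].to_numpy(),
                learner=learner_factory("regressor") if learner_factory else None,
                cv=cv,
            )
            for col in resistance_coeffs.columns
        }
    if generalizable is not None:
        from sklearn.model_selection import cross_val_score

        clf = (
            learner_factory("classifier") if learner_factory else _default_learner("classifier")
        )
        y = np.asarray(generalizable).astype(int)
        scores = None
        if cv and len(y) >= cv * 2 and len(np.unique(y)) > 1:
            from sklearn.base import clone

            scores = cross_val_score(clone(clf), X.to_numpy(), y, cv=cv, scoring="accuracy")
        clf.fit(X.to_numpy(), y)
        out["generalizability"] = {"model": clf, "cv_accuracy": scores}
    return out
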