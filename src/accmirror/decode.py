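"""Cross-modal stimulus-intensity decoding.

Stimulus intensity is coded 0 = Ctrl, 1 = Low, 2 = High and regressed on
population response-window spike counts with an L1-penalized (lasso)
linear model — a sparse decoder that seeks a linear combination of as few
cells as possible. The penalty is chosen to minimize leave-one-out
cross-validated squared error in the *training* modality; the common-coding
test then applies the fitted model verbatim (no refitting) to the spike
counts of the other modality and asks whether predicted and actual
intensity still correlate.

Intensity is treated as ordinal-numeric (Gaussian loss): performance is
the Pearson correlation between decoded and actual intensity, with
t = r·√(df/(1−r²)) on df = n_trials − 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV, Lasso, LassoCV
from sklearn.model_selection import LeaveOneOut
from statsmodels.stats.multitest import multipletests

from .cells import CellStats

INTENSITY_LABELS = {0: "Ctrl", 1: "Low", 2: "High"}


@dataclass
class TrialFeatureMatrix:
    """Trials × cells response-window spike counts with intensity labels."""

    X: np.ndarray
    y: np.ndarray
    modality: str
    cell_ids: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, float)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows must match labels")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def subset(self, cell_ids: list[str]) -> "TrialFeatureMatrix":
        if not cell_ids:
            raise ValueError("empty cell subset")
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return TrialFeatureMatrix(self.X[:, idx], self.y, self.modality, list(cell_ids))


def build_features(
    all_stats: list[CellStats],
    modality: str,
    n_per_intensity: int = 10,
) -> tuple[TrialFeatureMatrix, list[str]]:
    """Assemble the trial × cell count matrix for one modality.

    Conditions map to intensities Ctrl=0, Low=1, High=2; trials are stacked
    in that fixed order, the first ``n_per_intensity`` trials per
    condition. Cells lacking the full complement in any condition are
    excluded; the returned log lists them.
    """
    conds = [("Ctrl", 0), ("Low", 1), ("High", 2)]
    cols, ids, dropped = [], [], []
    for cs in all_stats:
        vecs = []
        ok = True
        for cond, _ in conds:
            key = (modality, cond, "response")
            v = cs.counts.get(key)
            if v is None or len(v) < n_per_intensity:
                ok = False
                break
            vecs.append(np.asarray(v[:n_per_intensity], float))
        if ok:
            cols.append(np.concatenate(vecs))
            ids.append(cs.unit_id)
        else:
            dropped.append(cs.unit_id)
    if not cols:
        raise ValueError("no eligible cells")
    X = np.column_stack(cols)
    y = np.concatenate([np.full(n_per_intensity, code) for _, code in conds])
    return TrialFeatureMatrix(X, y, modality, ids), dropped


# --------------------------------------------------------------------------
# model

@dataclass
class DecoderModel:
    """Fitted sparse linear decoder (results object).

    Weights are on the standardized-count scale used by the solver;
    ``predict`` applies the stored standardization, so the model transfers
    verbatim to a matrix of raw counts from another modality.
    """

    weights: np.ndarray
    intercept: float
    alpha: float
    train_modality: str
    cell_ids: list[str]
    feature_means: np.ndarray
    feature_scales: np.ndarray
    degenerate: bool = False

    @property
    def selected_cells(self) -> list[str]:
        return [c for c, w in zip(self.cell_ids, self.weights) if w != 0]

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.weights != 0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.feature_means) / self.feature_scales
        return Xs @ self.weights + self.intercept

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell": self.cell_ids, "weight": self.weights}
        ).sort_values("weight", key=np.abs, ascending=False, ignore_index=True)


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _alpha_grid(Xs, y, n_alphas=100, decades=4.0):
    n = len(y)
    alpha_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max) - decades, n_alphas)


def fit_decoder(
    train: TrialFeatureMatrix,
    alpha: float | None = None,
    l1_ratio: float = 1.0,
    n_alphas: int = 100,
) -> DecoderModel:
    """Fit the lasso decoder, selecting the penalty by LOO CV.

    The penalty grid descends 4 decades from the smallest penalty that
    zeroes every weight; ``alpha`` overrides the search (fixed-penalty
    mode). ``l1_ratio < 1`` switches to elastic net. The final model is
    refit on all training trials at the chosen penalty.
    """
    if len(np.unique(train.y)) < 2:
        raise ValueError("need at least 2 distinct labels")
    Xs, mu, sd = _standardize(train.X)
    degenerate = bool(np.all(train.X.std(axis=0) == 0))
    if degenerate:
        return DecoderModel(
            weights=np.zeros(train.X.shape[1]),
            intercept=float(train.y.mean()),
            alpha=np.inf,
            train_modality=train.modality,
            cell_ids=train.cell_ids,
            feature_means=mu,
            feature_scales=sd,
            degenerate=True,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if alpha is None:
            grid = _alpha_grid(Xs, train.y, n_alphas)
            if l1_ratio >= 1.0:
                cv = LassoCV(alphas=grid, cv=LeaveOneOut(), max_iter=5000)
            else:
                cv = ElasticNetCV(
                    alphas=grid, l1_ratio=l1_ratio, cv=LeaveOneOut(), max_iter=5000
                )
            cv.fit(Xs, train.y)
            alpha = float(cv.alpha_)
            coef, intercept = cv.coef_, float(cv.intercept_)
        else:
            model = Lasso(alpha=alpha, max_iter=5000)
            model.fit(Xs, train.y)
            coef, intercept = model.coef_, float(model.intercept_)
    return DecoderModel(
        weights=np.asarray(coef),
        intercept=intercept,
        alpha=float(alpha),
        train_modality=train.modality,
        cell_ids=train.cell_ids,
        feature_means=mu,
        feature_scales=sd,
    )


# --------------------------------------------------------------------------
# evaluation

@dataclass
class DecodingEvaluation:
    """Predicted vs actual intensity with the associated statistics."""

    predictions: np.ndarray
    actual: np.ndarray
    modality: str
    train_modality: str
    r: float
    t: float
    df: int
    p: float
    pairwise: pd.DataFrame  # higher, lower, t, p, p_fdr
    anova_F: float
    anova_p: float
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            f"decode {self.train_modality} -> {self.modality}: "
            f"r = {self.r:.2f}, t({self.df}) = {self.t:.2f}, p = {self.p:.3g}",
            f"one-way ANOVA across intensities: F = {self.anova_F:.2f}, "
            f"p = {self.anova_p:.3g}",
        ]
        for _, row in self.pairwise.iterrows():
            lines.append(
                f"  {row['higher']} > {row['lower']}: t = {row['t']:.2f}, "
                f"p_fdr = {row['p_fdr']:.3g}"
            )
        return "\n".join(lines)


def evaluate_predictions(
    predictions: np.ndarray,
    actual: np.ndarray,
    modality: str,
    train_modality: str,
) -> DecodingEvaluation:
    """Correlation, pairwise intensity tests (BH-FDR corrected) and ANOVA."""
    pred = np.asarray(predictions, float)
    y = np.asarray(actual, float)
    n = len(y)
    df = n - 2
    degenerate = pred.std() == 0 or y.std() == 0
    if degenerate:
        r, t, p = 0.0, 0.0, 1.0
    else:
        r = float(np.corrcoef(pred, y)[0, 1])
        t = r * np.sqrt(df / max(1.0 - r**2, 1e-12))
        p = float(2 * stats.t.sf(abs(t), df))
    levels = sorted(np.unique(y))
    rows = []
    for i, hi in enumerate(levels):
        for lo in levels[:i]:
            res = stats.ttest_ind(pred[y == hi], pred[y == lo], alternative="greater")
            rows.append(
                (
                    INTENSITY_LABELS.get(int(hi), str(hi)),
                    INTENSITY_LABELS.get(int(lo), str(lo)),
                    float(res.statistic),
                    float(res.pvalue),
                )
            )
    pw = pd.DataFrame(rows, columns=["higher", "lower", "t", "p"])
    pw["p_fdr"] = (
        multipletests(pw["p"], method="fdr_bh")[1] if len(pw) else np.array([])
    )
    groups = [pred[y == lv] for lv in levels]
    if degenerate or len(groups) < 2:
        F, ap = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, ap = (float(v) for v in stats.f_oneway(*groups))
        if not np.isfinite(F):
            F, ap = 0.0, 1.0
    return DecodingEvaluation(
        predictions=pred,
        actual=y,
        modality=modality,
        train_modality=train_modality,
        r=r,
        t=float(t),
        df=df,
        p=p,
        pairwise=pw,
        anova_F=F,
        anova_p=ap,
        degenerate=degenerate,
    )


def decode_within_loo(
    matrix: TrialFeatureMatrix,
    nested: bool = True,
    alpha: float | None = None,
    l1_ratio: float = 1.0,
) -> DecodingEvaluation:
    """Leave-one-out decoding within a modality.

    Each trial is predicted by a model fitted with that trial held out;
    with ``nested`` (default) the penalty is re-selected by inner LOO CV in
    every fold, so the held-out trial never influences model selection.
    ``alpha`` fixes the penalty instead (fixed-penalty mode).
    """
    n = matrix.n_trials
    preds = np.empty(n)
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        sub = TrialFeatureMatrix(
            matrix.X[rest], matrix.y[rest], matrix.modality, matrix.cell_ids
        )
        model = fit_decoder(
            sub, alpha=None if nested and alpha is None else alpha, l1_ratio=l1_ratio
        )
        preds[i] = model.predict(matrix.X[i : i + 1])[0]
    return evaluate_predictions(preds, matrix.y, matrix.modality, matrix.modality)


def decode_cross(
    model: DecoderModel, test: TrialFeatureMatrix
) -> DecodingEvaluation:
    """Apply a trained decoder verbatim to the other modality's counts."""
    if test.modality == model.train_modality:
        raise ValueError("cross-modal test requires a different modality")
    if test.cell_ids != model.cell_ids:
        raise ValueError("cell columns do not match the trained model")
    preds = model.predict(test.X)
    return evaluate_predictions(preds, test.y, test.modality, model.train_modality)


@dataclass
class SubsetDecoding:
    within: dict[str, DecodingEvaluation]  # train modality -> within-LOO eval
    cross: dict[str, DecodingEvaluation]  # train modality -> cross-modal eval
    models: dict[str, DecoderModel]


def subset_decode(
    matrices: dict[str, TrialFeatureMatrix],
    cell_subset: list[str] | None = None,
    nested: bool = True,
) -> SubsetDecoding:
    """Full within/cross analysis in both directions, optionally on a
    cell subset (e.g. the dual-responsive mirror cells)."""
    mods = list(matrices)
    if len(mods) != 2:
        raise ValueError("need exactly two modalities")
    use = {
        m: (matrices[m].subset(cell_subset) if cell_subset is not None else matrices[m])
        for m in mods
    }
    within, cross, models = {}, {}, {}
    for train_mod in mods:
        test_mod = mods[1] if train_mod == mods[0] else mods[0]
        models[train_mod] = fit_decoder(use[train_mod])
        within[train_mod] = decode_within_loo(use[train_mod], nested=nested)
        cross[train_mod] = decode_cross(models[train_mod], use[test_mod])
    return SubsetDecoding(within=within, cross=cross, models=models)
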