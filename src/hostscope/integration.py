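"""Score fusion and calibration: combined-hosts random forest, empirical
score -> PPV calibration curves, the composite confidence score, and final
genus-level predictions.

Method scores live on [0, 1]; a calibration curve is an empirical, monotone
map from score to positive predictive value (PPV = 1 - FDR) computed on
sliding windows and evaluated on a fine grid.  The composite score for a
virus-host-genus pair fuses the calibrated PPVs of all methods that agree
on the pair: methods below the 0.5 PPV floor are discarded, the best method
supplies the main FDR, and each additional method multiplies it by its
doubled (rescaled) FDR, so agreement can only raise the composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split

from .classifiers import FOREST_RANGES, ClassifierSpec
from .taxonomy import HostFrame

METHODS = ("blast_clf", "crispr_clf", "combined_rf", "phage_based")


@dataclass(frozen=True)
class IntegrationConfig:
    """Constants of the composite-score integration.

    ``ppv_floor * rescale_factor`` must equal 1 so that a rescaled FDR stays
    below 1 exactly when the method's PPV clears the floor.
    """

    ppv_floor: float = 0.5
    rescale_factor: float = 2.0
    report_min: float = 75.0
    default_min: float = 90.0
    score_scale: float = 100.0

    def __post_init__(self) -> None:
        if abs(self.ppv_floor * self.rescale_factor - 1.0) > 1e-12:
            raise ValueError("ppv_floor * rescale_factor must equal 1")


# ---------------------------------------------------------------------------
# genus aggregation
# ---------------------------------------------------------------------------

def aggregate_to_genus(scores: pd.DataFrame, frame: HostFrame) -> pd.DataFrame:
    """Reduce per-genome scores to per-genus scores by the max over member
    genomes; the contributing genome is recorded."""
    if scores.empty:
        return pd.DataFrame(columns=["virus_id", "host_genus", "score", "genome_id"])
    df = scores.copy()
    df["host_genus"] = df["genome_id"].map(frame.genus_series)
    df = df.sort_values(["virus_id", "host_genus", "score", "genome_id"],
                        ascending=[True, True, False, True], kind="mergesort")
    out = df.groupby(["virus_id", "host_genus"], as_index=False).first()
    return out[["virus_id", "host_genus", "score", "genome_id"]]


# ---------------------------------------------------------------------------
# combined features
# ---------------------------------------------------------------------------

def build_combined_features(scores_by_classifier: Mapping[str, pd.DataFrame],
                            classifier_ids: Sequence[str]) -> pd.DataFrame:
    """Per virus-candidate pair, 3 features per selected classifier:
    (score, rank among the virus's candidates, delta to the virus's best
    score).

    Candidates are the union over classifiers; a pair unscored by a
    classifier is imputed as score 0 with rank ``n_candidates`` and delta
    ``best - 0``.  Ranks share the minimum rank on ties.
    """
    pieces = []
    for cid in classifier_ids:
        df = scores_by_classifier[cid]
        pieces.append(df.set_index(["virus_id", "genome_id"])["score"].rename(cid))
    wide = pd.concat(pieces, axis=1).reset_index()
    wide = wide.sort_values(["virus_id", "genome_id"], kind="mergesort").reset_index(drop=True)
    out = wide[["virus_id", "genome_id"]].copy()
    for cid in classifier_ids:
        s = wide[cid].fillna(0.0).to_numpy(float)
        missing = wide[cid].isna().to_numpy()
        grp = wide.groupby("virus_id")[cid]
        best = grp.transform("max").fillna(0.0).to_numpy(float)
        # shared-minimum rank on ties: 1 + number of strictly greater scores
        rank = (wide.assign(_s=np.where(missing, -np.inf, s))
                    .groupby("virus_id")["_s"]
                    .transform(lambda c: c.rank(method="min", ascending=False))
                    .to_numpy(float))
        n_cand = wide.groupby("virus_id")["genome_id"].transform("size").to_numpy(float)
        rank = np.where(missing, n_cand, rank)
        out[f"{cid}:score"] = s
        out[f"{cid}:rank"] = rank
        out[f"{cid}:delta"] = np.maximum(best, 0.0) - s
    return out


# ---------------------------------------------------------------------------
# combined-hosts random forest
# ---------------------------------------------------------------------------

@dataclass
class CombinedRF:
    """Fitted combined-hosts random forest over 3K fused features."""

    estimator: RandomForestClassifier
    classifier_ids: tuple[str, ...]
    spec: ClassifierSpec
    metrics: dict = field(default_factory=dict)

    @property
    def feature_cols(self) -> list[str]:
        return [f"{cid}:{part}" for cid in self.classifier_ids
                for part in ("score", "rank", "delta")]

    def score(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_cols].to_numpy(float)
        idx = int(np.nonzero(self.estimator.classes_ == 1)[0][0])
        return self.estimator.predict_proba(X)[:, idx]


def recall_at_fdr(y: np.ndarray, scores: np.ndarray, max_fdr: float = 0.05) -> float:
    """Largest recall achievable at an observed FDR <= ``max_fdr``."""
    order = np.argsort(-scores, kind="mergesort")
    ys = np.asarray(y)[order]
    tp = np.cumsum(ys)
    n = np.arange(1, len(ys) + 1)
    ok = (1 - tp / n) <= max_fdr
    total_pos = ys.sum()
    if total_pos == 0 or not ok.any():
        return 0.0
    return float(tp[ok].max() / total_pos)


def sample_balanced_pairs(features: pd.DataFrame, labels: np.ndarray,
                          virus_strata: pd.DataFrame,
                          n_per_stratum: int = 700, max_correct: int = 10,
                          max_incorrect: int = 5, seed: int = 0) -> np.ndarray:
    """Row indices of the balanced combined-RF training set.

    Viruses are stratified by evidence type (both blast and CRISPR hits /
    either / neither), up to ``n_per_stratum`` sampled per stratum; for each
    sampled virus up to ``max_correct`` correct and ``max_incorrect``
    incorrect pairs are kept.
    """
    rng = np.random.default_rng(seed)
    has_b = virus_strata["has_blast"].astype(bool)
    has_c = virus_strata["has_crispr"].astype(bool)
    strata = {"both": virus_strata.index[has_b & has_c],
              "either": virus_strata.index[has_b ^ has_c],
              "neither": virus_strata.index[~has_b & ~has_c]}
    viruses_in_features = set(features["virus_id"])
    chosen_viruses = []
    for name in ("both", "either", "neither"):
        pool = sorted(set(strata[name]) & viruses_in_features)
        k = min(n_per_stratum, len(pool))
        if k < n_per_stratum:
            import warnings
            warnings.warn(f"stratum {name!r} has only {len(pool)} viruses "
                          f"(requested {n_per_stratum}); taking all")
        if k:
            chosen_viruses.extend(rng.choice(pool, size=k, replace=False))
    chosen_viruses = set(chosen_viruses)
    idx_out = []
    lab = np.asarray(labels).astype(int)
    for virus_id, grp in features.groupby("virus_id", sort=True):
        if virus_id not in chosen_viruses:
            continue
        rows = grp.index.to_numpy()
        corr = rows[lab[rows] == 1]
        inc = rows[lab[rows] == 0]
        if len(corr) > max_correct:
            corr = rng.choice(corr, size=max_correct, replace=False)
        if len(inc) > max_incorrect:
            inc = rng.choice(inc, size=max_incorrect, replace=False)
        idx_out.extend(np.sort(np.concatenate([corr, inc])))
    return np.array(sorted(idx_out), dtype=int)


def train_combined_rf(features: pd.DataFrame, labels: np.ndarray,
                      classifier_ids: Sequence[str],
                      virus_strata: pd.DataFrame,
                      n_per_stratum: int = 700, max_correct: int = 10,
                      max_incorrect: int = 5, n_trials: int = 10,
                      top_n: int = 5, seed: int = 0) -> CombinedRF:
    """Train and select the combined-hosts random forest.

    Random search over the forest ranges (trees 100-1000, depth 4-32,
    min examples per node 2-10); among the ``top_n`` most accurate trials on
    the held-out 20% split, the candidate with the highest recall at 5% FDR
    is selected.
    """
    rows = sample_balanced_pairs(features, labels, virus_strata, n_per_stratum,
                                 max_correct, max_incorrect, seed=seed)
    X = features.iloc[rows]
    cols = [f"{cid}:{p}" for cid in classifier_ids for p in ("score", "rank", "delta")]
    Xm = X[cols].to_numpy(float)
    y = np.asarray(labels).astype(int)[rows]
    if len(np.unique(y)) < 2:
        raise ValueError("combined-RF training set contains a single class")
    X_tr, X_val, y_tr, y_val = train_test_split(Xm, y, test_size=0.2,
                                                random_state=seed, stratify=y)
    rng = np.random.default_rng(seed)
    trials = []
    for t in range(n_trials):
        trial_seed = int(rng.integers(0, 2**31 - 1))
        hp = (("n_trees", int(rng.integers(100, 1001))),
              ("max_depth", int(rng.integers(4, 33))),
              ("min_examples", int(rng.integers(2, 11))))
        spec = ClassifierSpec(kind="random_forest", hyperparams=hp, seed=trial_seed)
        est = RandomForestClassifier(n_estimators=spec.hp["n_trees"],
                                     max_depth=spec.hp["max_depth"],
                                     min_samples_leaf=spec.hp["min_examples"],
                                     random_state=trial_seed, n_jobs=1)
        est.fit(X_tr, y_tr)
        idx = int(np.nonzero(est.classes_ == 1)[0][0])
        p = est.predict_proba(X_val)[:, idx]
        trials.append((spec, est,
                       float(accuracy_score(y_val, (p >= 0.5).astype(int))),
                       recall_at_fdr(y_val, p, 0.05)))
    by_acc = sorted(trials, key=lambda t: (-t[2], t[0].seed))[:top_n]
    spec, est, acc, rec = max(by_acc, key=lambda t: (t[3], -t[0].seed))
    return CombinedRF(estimator=est, classifier_ids=tuple(classifier_ids),
                      spec=spec,
                      metrics={"val_accuracy": acc, "recall_at_5fdr": rec,
                               "n_train_pairs": int(len(rows))})


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Monotone empirical score -> PPV map on a 0.001 grid."""

    grid: np.ndarray
    ppv: np.ndarray
    support: np.ndarray
    window: float

    def ppv_at(self, scores) -> np.ndarray | float:
        out = np.interp(np.asarray(scores, float), self.grid, self.ppv)
        return float(out) if np.isscalar(scores) else out

    def to_tsv(self, path) -> None:
        pd.DataFrame({"score": self.grid, "ppv": self.ppv,
                      "n_support": self.support}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, window: float = float("nan")) -> "CalibrationCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(grid=df["score"].to_numpy(float), ppv=df["ppv"].to_numpy(float),
                   support=df["n_support"].to_numpy(float), window=window)


def _bspline_basis(x: np.ndarray, df: int = 10, degree: int = 3) -> np.ndarray:
    """Fixed-knot B-spline design matrix on [0, 1]."""
    from scipy.interpolate import BSpline
    inner = np.linspace(0.0, 1.0, df - degree + 2)[1:-1]
    knots = np.r_[np.zeros(degree + 1), inner, np.ones(degree + 1)]
    cols = [BSpline.basis_element(knots[i:i + degree + 2], extrapolate=False)(
        np.clip(x, 0.0, 1.0)) for i in range(len(knots) - degree - 1)]
    return np.nan_to_num(np.column_stack(cols))


def _penalized_logit_smooth(s: np.ndarray, y: np.ndarray, grid: np.ndarray,
                            df: int = 10, alpha: float = 50.0,
                            max_iter: int = 30) -> np.ndarray:
    """Binomial P-spline: penalized IRLS with a second-difference penalty on
    the logit (constant and linear trends are unpenalized)."""
    X = _bspline_basis(s, df)
    Xg = _bspline_basis(grid, df)
    k = X.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)
    P = alpha * (D.T @ D) + 1e-8 * np.eye(k)
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-6)
        z = eta + (y - mu) / w
        beta_new = np.linalg.solve(X.T @ (X * w[:, None]) + P, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    eta_g = np.clip(Xg @ beta, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta_g))


def fit_calibration(scores, labels, window: float = 0.05,
                    step: float = 0.001) -> CalibrationCurve:
    """Empirical PPV calibration: sliding windows, smoothed and monotone.

    The raw PPV (correct / total within the window centred on each grid
    score) provides the per-window support; the smooth score -> PPV trend is
    a penalized binomial spline on the logit scale (curvature penalty, so
    flat or log-linear PPV trends are recovered without bias), projected
    onto the monotone cone by isotonic regression weighted by window
    support and clamped to [0, 1].
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(float)
    if s.size == 0:
        raise ValueError("cannot calibrate on empty input")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 6)
    order = np.argsort(s, kind="mergesort")
    ss, ys = s[order], y[order]
    cum = np.concatenate([[0.0], np.cumsum(ys)])
    lo = np.searchsorted(ss, grid - window / 2, side="left")
    hi = np.searchsorted(ss, grid + window / 2, side="right")
    n_in = (hi - lo).astype(float)
    if y.min() == 1.0 or y.max() == 0.0:  # degenerate: constant empirical PPV
        ppv = np.full_like(grid, y.min())
        return CalibrationCurve(grid=grid, ppv=ppv, support=n_in, window=window)
    smooth = _penalized_logit_smooth(s, y, grid)
    # empty windows take the smooth trend with a nominal weight
    weights = np.where(n_in > 0, n_in, 0.1)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True,
                             out_of_bounds="clip")
    iso.fit(grid, smooth, sample_weight=weights)
    ppv = np.clip(iso.predict(grid), 0.0, 1.0)
    return CalibrationCurve(grid=grid, ppv=ppv, support=n_in, window=window)


# ---------------------------------------------------------------------------
# composite score
# ---------------------------------------------------------------------------

def composite_score(ppvs: Mapping[str, float],
                    cfg: IntegrationConfig | None = None
                    ) -> tuple[float | None, str | None, list[str]]:
    """Fuse calibrated per-method PPVs for one virus-genus pair.

    Methods with PPV below the floor are discarded; if none remain the pair
    gets no prediction (None).  Otherwise the best method's FDR is
    multiplied by the doubled FDRs of the other passing methods and the
    composite is one minus that product.  Returns (composite, main method,
    methods used).
    """
    cfg = cfg or IntegrationConfig()
    passing = {m: p for m, p in ppvs.items() if p >= cfg.ppv_floor}
    if not passing:
        return None, None, []
    main = max(sorted(passing), key=lambda m: passing[m])
    fdr = 1.0 - passing[main]
    for m, p in sorted(passing.items()):
        if m != main:
            fdr *= cfg.rescale_factor * (1.0 - p)
    comp = 1.0 - fdr
    return float(comp), main, sorted(passing)


def finalize_predictions(composites: pd.DataFrame, final_curve: CalibrationCurve,
                         cfg: IntegrationConfig | None = None,
                         min_score: float | None = None) -> pd.DataFrame:
    """Map composites through the final calibration curve to confidences.

    ``composites`` needs columns virus_id, host_genus, composite,
    main_method, methods_used (plus any per-method PPV columns, carried
    through).  Rows below ``report_min`` (default 75) are dropped; pass
    ``min_score`` (within [report_min, 100]) to filter at the summary
    cutoff.  Output sorted per virus by descending confidence.
    """
    cfg = cfg or IntegrationConfig()
    out = composites.copy()
    if out.empty:
        out["confidence"] = pd.Series(dtype=float)
        return out
    out["confidence"] = cfg.score_scale * final_curve.ppv_at(
        out["composite"].to_numpy(float))
    floor = cfg.report_min if min_score is None else float(min_score)
    if not (cfg.report_min <= floor <= cfg.score_scale):
        raise ValueError(f"min_score must lie in [{cfg.report_min}, {cfg.score_scale}]")
    out = out[out["confidence"] >= floor]
    # composite breaks confidence ties (the curve can saturate)
    out = out.sort_values(["virus_id", "confidence", "composite", "host_genus"],
                          ascending=[True, False, False, True], kind="mergesort")
    return out.reset_index(drop=True)
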