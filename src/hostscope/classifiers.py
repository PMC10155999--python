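"""Per-tool classifiers scoring "is this candidate host the correct genus?".

Covers the full single-tool workflow: balanced training-set construction
(controlling the incorrect-pair and known-virus fractions, with three
hit-subsampling variants per instance emulating uneven host-database
coverage), training of feed-forward / distance-pooled / random-forest
classifiers, seeded random hyperparameter search, and the iterative
error-rate-driven selection of the final classifier subset anchored on
non-ambiguous cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, log_loss, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .encoding import CandidateLimits, ScoreBinning, enumerate_candidates
from .providers import sort_hits
from .taxonomy import DistanceBinning, HostFrame

CLASSIFIER_KINDS = ("dense_net", "conv_net", "random_forest")

#: distance-bin index at or below which a hit counts as "close" for the
#: sparse_close training variant.
SPARSE_CLOSE_BIN = 4


@dataclass(frozen=True)
class TrainingConstraints:
    """Balance constraints on sampled training instances."""

    frac_incorrect_range: tuple[float, float] = (0.60, 0.85)
    frac_known_range: tuple[float, float] = (0.45, 0.70)
    known_aai_threshold: float = 70.0  # consumed upstream as a boolean flag
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.frac_incorrect_range, self.frac_known_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("constraint ranges must satisfy 0 <= lo <= hi <= 1")


class InfeasibleConstraintsError(ValueError):
    """Raised when the labelled pool cannot satisfy the balance constraints."""


@dataclass
class TrainingSet:
    """Encoded training instances for one tool.

    ``records`` has one row per instance (virus_id, genome_id, variant,
    label, known); ``counts[i]`` is the instance's hit matrix.  ``label`` is
    1 when the candidate's genus equals the virus's true host genus.
    """

    tool: str
    dbin: DistanceBinning
    sbin: ScoreBinning
    records: pd.DataFrame
    counts: np.ndarray

    def __len__(self) -> int:
        return len(self.records)

    @property
    def y(self) -> np.ndarray:
        return self.records["label"].to_numpy(int)

    def X(self, mode: str = "flat_counts") -> np.ndarray:
        n = self.counts.shape[0]
        flat = self.counts.reshape(n, -1).astype(float)
        if mode == "flat_counts":
            return flat
        if mode != "summary":
            raise ValueError(f"unknown feature mode: {mode!r}")
        row0 = self.counts[:, 0, :]
        n_sb = row0.shape[1]
        best0 = ((row0 > 0) * np.arange(1, n_sb + 1)).max(axis=1).astype(float)
        near = self.counts[:, :3, :].sum(axis=(1, 2)).astype(float)
        total = self.counts.sum(axis=(1, 2)).astype(float)
        return np.hstack([flat, np.column_stack([best0, near, total])])


def _feasible_counts(avail: dict[tuple[int, int], int], n_target: int,
                     constraints: TrainingConstraints
                     ) -> dict[tuple[int, int], int]:
    """Solve for per-stratum sample counts satisfying both marginal ranges.

    Strata are keyed by (label_incorrect, known).  Shrinks n until a feasible
    integer allocation exists; raises with the achievable pool fractions if
    none does.
    """
    a_ik = avail.get((1, 1), 0)   # incorrect & known
    a_iu = avail.get((1, 0), 0)
    a_ck = avail.get((0, 1), 0)
    a_cu = avail.get((0, 0), 0)
    pool = a_ik + a_iu + a_ck + a_cu
    (ilo, ihi) = constraints.frac_incorrect_range
    (klo, khi) = constraints.frac_known_range
    n = min(n_target, pool)
    while n >= 8:
        n_inc = int(np.clip(round(0.5 * (ilo + ihi) * n),
                            max(int(np.ceil(ilo * n)), n - (a_ck + a_cu)),
                            min(int(np.floor(ihi * n)), a_ik + a_iu)))
        n_kn = int(np.clip(round(0.5 * (klo + khi) * n),
                           max(int(np.ceil(klo * n)), n - (a_iu + a_cu)),
                           min(int(np.floor(khi * n)), a_ik + a_ck)))
        ok_inc = int(np.ceil(ilo * n)) <= n_inc <= int(np.floor(ihi * n))
        ok_kn = int(np.ceil(klo * n)) <= n_kn <= int(np.floor(khi * n))
        if ok_inc and ok_kn:
            lo = max(0, n_inc - a_iu, n_kn - a_ck, n_inc + n_kn - n)
            hi = min(a_ik, n_inc, n_kn, n_inc + n_kn - n + a_cu)
            if lo <= hi:
                x = int(np.clip(round(n_inc * n_kn / n), lo, hi))
                return {(1, 1): x, (1, 0): n_inc - x, (0, 1): n_kn - x,
                        (0, 0): n - n_inc - n_kn + x}
        n = n - max(1, n // 20)
    inc_frac = (a_ik + a_iu) / pool if pool else float("nan")
    kn_frac = (a_ik + a_ck) / pool if pool else float("nan")
    raise InfeasibleConstraintsError(
        f"cannot satisfy balance constraints: pool has incorrect fraction "
        f"{inc_frac:.3f} (need within {constraints.frac_incorrect_range}) and "
        f"known fraction {kn_frac:.3f} (need within {constraints.frac_known_range})")


def build_training_instances(hits: pd.DataFrame, tool: str, frame: HostFrame,
                             truth: pd.DataFrame,
                             constraints: TrainingConstraints | None = None,
                             n_target: int = 20000,
                             dbin: DistanceBinning | None = None,
                             sbin: ScoreBinning | None = None,
                             limits: CandidateLimits | None = None,
                             seed: int = 0) -> TrainingSet:
    """Build a balanced, encoded training set for one tool.

    ``truth`` is indexed by virus_id with columns ``true_genus`` and
    ``known`` (bool).  Virus-candidate pairs are sampled so that the
    incorrect-pair fraction and the known-virus fraction fall inside the
    configured ranges; each sampled pair contributes three instances with
    different hit subsets: ``all_hits``, ``random_subset`` (each hit kept
    with one uniform per-instance probability) and ``sparse_close`` (one
    random close hit, distance bin <= 4, plus all distant hits).
    """
    constraints = constraints or TrainingConstraints()
    dbin = dbin or DistanceBinning()
    sbin = sbin or ScoreBinning()
    limits = limits or CandidateLimits()
    rng = np.random.default_rng(seed)

    genus = frame.genus_series
    pairs = []   # (virus_id, genome_id, label, known)
    per_virus: dict[str, pd.DataFrame] = {}
    for virus_id, vhits in hits.groupby("virus_id", sort=True):
        if virus_id not in truth.index:
            continue
        candidates, retained = enumerate_candidates(vhits, tool, limits)
        per_virus[virus_id] = retained
        tg = truth.at[virus_id, "true_genus"]
        kn = int(bool(truth.at[virus_id, "known"]))
        for cand in candidates:
            pairs.append((virus_id, cand, int(genus[cand] == tg), kn))
    pool = pd.DataFrame(pairs, columns=["virus_id", "genome_id", "label", "known"])
    if pool.empty:
        raise InfeasibleConstraintsError("no labelled virus-candidate pairs available")

    avail = pool.groupby([1 - pool["label"], pool["known"]]).size()
    avail = {(int(i), int(k)): int(v) for (i, k), v in avail.items()}
    take = _feasible_counts(avail, n_target, constraints)
    chosen = []
    for (inc, kn), cnt in take.items():
        stratum = pool[((1 - pool["label"]) == inc) & (pool["known"] == kn)]
        if cnt > 0:
            idx = rng.choice(stratum.index.to_numpy(), size=cnt, replace=False)
            chosen.append(pool.loc[np.sort(idx)])
    sampled = pd.concat(chosen).sort_values(["virus_id", "genome_id"]).reset_index(drop=True)

    n_db, n_sb = dbin.n_bins, sbin.n_score_bins(tool)
    rec_rows, tensors = [], []
    for row in sampled.itertuples(index=False):
        retained = per_virus[row.virus_id]
        ci = frame.index_of(row.genome_id)
        hit_idx = np.array([frame.index_of(g) for g in retained["genome_id"]])
        db = dbin.bin_array(frame.distance_matrix[ci, hit_idx])
        sb = sbin.bin_scores(tool, retained)
        n_hits = len(retained)
        close = np.nonzero(db <= SPARSE_CLOSE_BIN)[0]
        far = np.nonzero(db > SPARSE_CLOSE_BIN)[0]
        subsets = {"all_hits": np.arange(n_hits)}
        u = rng.random()
        keep = np.nonzero(rng.random(n_hits) < u)[0]
        if keep.size == 0:
            keep = np.array([rng.integers(n_hits)])
        subsets["random_subset"] = keep
        if close.size:
            one = np.array([rng.choice(close)])
            subsets["sparse_close"] = np.sort(np.concatenate([one, far]))
        else:
            subsets["sparse_close"] = np.array([rng.integers(n_hits)])
        for variant, idx in subsets.items():
            counts = np.zeros((n_db, n_sb), dtype=np.int64)
            np.add.at(counts, (db[idx], sb[idx]), 1)
            rec_rows.append((row.virus_id, row.genome_id, variant,
                             int(row.label), bool(row.known)))
            tensors.append(counts)

    records = pd.DataFrame(rec_rows, columns=["virus_id", "genome_id", "variant",
                                              "label", "known"])
    return TrainingSet(tool=tool, dbin=dbin, sbin=sbin, records=records,
                       counts=np.stack(tensors))


# ---------------------------------------------------------------------------
# classifier specs / training
# ---------------------------------------------------------------------------

FOREST_RANGES = {"n_trees": (100, 1000), "max_depth": (4, 32), "min_examples": (2, 10)}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration inside the declared search space."""

    kind: str
    hyperparams: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind: {self.kind!r}")
        hp = dict(self.hyperparams)
        if self.kind == "random_forest":
            for name, (lo, hi) in FOREST_RANGES.items():
                v = hp.get(name)
                if v is not None and not (lo <= v <= hi):
                    raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @property
    def hp(self) -> dict:
        return dict(self.hyperparams)


def _pooled_along_distance(X: np.ndarray, n_db: int, n_sb: int, kernel: int) -> np.ndarray:
    """Fixed sliding-window sums along the distance axis (the conv-net
    variant's local feature map), appended to the flat counts."""
    M = X.reshape(X.shape[0], n_db, n_sb)
    pools = [M[:, i:i + kernel, :].sum(axis=1) for i in range(n_db - kernel + 1)]
    pooled = np.concatenate(pools, axis=1)
    return np.hstack([X, pooled])


@dataclass
class TrainedClassifier:
    """A fitted per-tool classifier with its encoding configuration."""

    classifier_id: str
    tool: str
    spec: ClassifierSpec
    estimator: object
    mode: str
    n_db: int
    n_sb: int
    metrics: dict = field(default_factory=dict)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.spec.kind == "conv_net":
            kernel = int(self.spec.hp.get("kernel", 3))
            return _pooled_along_distance(X, self.n_db, self.n_sb, kernel)
        return X

    def score(self, X: np.ndarray) -> np.ndarray:
        """Probability that the candidate host is the correct genus."""
        Xt = self._transform(np.asarray(X, float))
        proba = self.estimator.predict_proba(Xt)
        idx = int(np.nonzero(self.estimator.classes_ == 1)[0][0])
        return proba[:, idx]

    def score_training_set(self, ts: TrainingSet) -> np.ndarray:
        return self.score(ts.X(self.mode))


def feature_mode_for(kind: str) -> str:
    return "summary" if kind == "random_forest" else "flat_counts"


def _build_estimator(spec: ClassifierSpec):
    hp = spec.hp
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_trees", 300)),
            max_depth=int(hp.get("max_depth", 16)),
            min_samples_leaf=int(hp.get("min_examples", 2)),
            random_state=spec.seed, n_jobs=1)
    layers = hp.get("layers", (32,))
    if isinstance(layers, (int, float)):
        layers = (int(layers),)
    net = MLPClassifier(hidden_layer_sizes=tuple(int(w) for w in layers),
                        alpha=float(hp.get("alpha", 1e-4)),
                        max_iter=int(hp.get("max_iter", 200)),
                        random_state=spec.seed)
    return make_pipeline(StandardScaler(), net)


def train_single_tool(train_set: TrainingSet, spec: ClassifierSpec,
                      classifier_id: str | None = None) -> TrainedClassifier:
    """Train one classifier on 80% of the instances, validating on 20%."""
    mode = feature_mode_for(spec.kind)
    X = train_set.X(mode)
    y = train_set.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    n_db, n_sb = train_set.counts.shape[1], train_set.counts.shape[2]
    clf = TrainedClassifier(
        classifier_id=classifier_id or f"{train_set.tool}_{spec.kind}_{spec.seed}",
        tool=train_set.tool, spec=spec, estimator=_build_estimator(spec),
        mode=mode, n_db=n_db, n_sb=n_sb)
    Xt = clf._transform(X)
    X_tr, X_val, y_tr, y_val = train_test_split(
        Xt, y, test_size=0.2, random_state=spec.seed, stratify=y)
    clf.estimator.fit(X_tr, y_tr)
    idx = int(np.nonzero(clf.estimator.classes_ == 1)[0][0])
    p_val = clf.estimator.predict_proba(X_val)[:, idx]
    clf.metrics = {
        "val_accuracy": float(accuracy_score(y_val, (p_val >= 0.5).astype(int))),
        "val_log_loss": float(log_loss(y_val, p_val, labels=[0, 1])),
    }
    if len(np.unique(y_val)) == 2:
        clf.metrics["val_auc"] = float(roc_auc_score(y_val, p_val))
    return clf


def _sample_spec(kind: str, rng: np.random.Generator, seed: int) -> ClassifierSpec:
    if kind == "random_forest":
        hp = (("n_trees", int(rng.integers(100, 1001))),
              ("max_depth", int(rng.integers(4, 33))),
              ("min_examples", int(rng.integers(2, 11))))
    else:
        n_layers = int(rng.integers(1, 3))
        widths = tuple(int(rng.choice([16, 32, 64])) for _ in range(n_layers))
        hp = (("layers", widths),
              ("alpha", float(10 ** rng.uniform(-5, -2))),
              ("max_iter", 200))
        if kind == "conv_net":
            hp = hp + (("kernel", int(rng.integers(2, 5))),)
    return ClassifierSpec(kind=kind, hyperparams=hp, seed=seed)


def tune_hyperparameters(train_set: TrainingSet, kind: str, n_trials: int = 100,
                         seed: int = 0, top_n: int = 5) -> list[TrainedClassifier]:
    """Seeded random search over the declared ranges; returns the best
    ``top_n`` trained classifiers (max validation accuracy for forests,
    min validation log-loss for nets).

    Trials are drawn sequentially from one seeded stream, so the first k
    trials of a longer search coincide with a shorter search at the same
    seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    trained = []
    for trial in range(n_trials):
        trial_seed = int(rng.integers(0, 2**31 - 1))
        spec = _sample_spec(kind, rng, trial_seed)
        clf = train_single_tool(train_set, spec,
                                classifier_id=f"{train_set.tool}_{kind}_{trial}")
        trained.append(clf)
    if kind == "random_forest":
        key = lambda c: (-c.metrics["val_accuracy"], c.classifier_id)
    else:
        key = lambda c: (c.metrics["val_log_loss"], c.classifier_id)
    return sorted(trained, key=key)[:top_n]


# ---------------------------------------------------------------------------
# classifier-set selection on non-ambiguous cases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NonAmbiguousThresholds:
    """Raw-metric thresholds defining non-ambiguous virus cases per tool."""

    blast_total_len: float = 10000.0
    crispr_mismatches: int = 0
    kmer_model_p: float = 1e-5
    s2star_like_score: float = 0.8
    php_like_score: float = 1450.0

    def nonambiguous_viruses(self, tool: str, hits: pd.DataFrame) -> set[str]:
        """Viruses with at least one hit passing the tool's stringent cutoff."""
        if hits.empty:
            return set()
        if tool == "blast":
            m = hits["total_aln_len"] >= self.blast_total_len
        elif tool == "crispr":
            m = hits["mismatches"] <= self.crispr_mismatches
        elif tool == "kmer_model":
            m = hits["pvalue"] <= self.kmer_model_p
        elif tool == "s2star_like":
            m = hits["score"] >= self.s2star_like_score
        elif tool == "php_like":
            m = hits["score"] >= self.php_like_score
        else:
            raise ValueError(f"no non-ambiguous threshold for tool {tool!r}")
        return set(hits.loc[m, "virus_id"].unique())


@dataclass(frozen=True)
class SelectionConfig:
    percentile: float = 10.0
    add_if_extra_correct: float = 0.05
    add_if_corrects_fp: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.percentile <= 50):
            raise ValueError("percentile must be in (0, 50]")
        for f in (self.add_if_extra_correct, self.add_if_corrects_fp):
            if not (0 < f < 1):
                raise ValueError("selection fractions must be in (0, 1)")


def best_prediction_per_virus(scores: pd.DataFrame) -> pd.DataFrame:
    """Best-scoring candidate per virus (ties broken by genome_id)."""
    ordered = scores.sort_values(["virus_id", "score", "genome_id"],
                                 ascending=[True, False, True], kind="mergesort")
    return ordered.groupby("virus_id", as_index=False).first()


def _classifier_case_sets(best: pd.DataFrame, truth: pd.DataFrame,
                          genus: pd.Series, nonambig: set[str],
                          percentile: float) -> tuple[set[str], set[str], float]:
    """(above-cutoff correct, above-cutoff incorrect) virus sets + cutoff."""
    sub = best[best["virus_id"].isin(nonambig)].copy()
    if sub.empty:
        return set(), set(), float("nan")
    sub["correct"] = [genus[g] == truth.at[v, "true_genus"]
                      for v, g in zip(sub["virus_id"], sub["genome_id"])]
    corr_scores = sub.loc[sub["correct"], "score"]
    if corr_scores.empty:
        return set(), set(sub["virus_id"]), float("inf")
    cutoff = float(np.percentile(corr_scores, percentile))
    above_correct = set(sub.loc[sub["correct"] & (sub["score"] >= cutoff), "virus_id"])
    above_incorrect = set(sub.loc[~sub["correct"] & (sub["score"] > cutoff), "virus_id"])
    return above_correct, above_incorrect, cutoff


def select_classifier_set(candidates: list[TrainedClassifier],
                          eval_scores: dict[str, pd.DataFrame],
                          truth: pd.DataFrame, frame: HostFrame,
                          nonambiguous: set[str],
                          cfg: SelectionConfig | None = None
                          ) -> list[TrainedClassifier]:
    """Iterative error-rate-driven subset selection.

    For each candidate classifier, the cutoff is the 10th percentile of its
    scores on correctly-predicted non-ambiguous cases and the error rate is
    the number of incorrect predictions scoring above that cutoff.  Starting
    from the lowest-error classifier, further classifiers are added while
    they either add >= 5% more correct non-ambiguous predictions or give a
    correct above-cutoff prediction for >= 10% of the current false
    positives.
    """
    cfg = cfg or SelectionConfig()
    if not nonambiguous:
        raise ValueError("no non-ambiguous cases; revise NonAmbiguousThresholds")
    genus = frame.genus_series
    info = {}
    for clf in candidates:
        best = best_prediction_per_virus(eval_scores[clf.classifier_id])
        ac, ai, cutoff = _classifier_case_sets(best, truth, genus, nonambiguous,
                                               cfg.percentile)
        info[clf.classifier_id] = {"correct": ac, "incorrect": ai,
                                   "error": len(ai), "cutoff": cutoff}
    n_cases = len(nonambiguous)
    remaining = sorted(candidates, key=lambda c: (info[c.classifier_id]["error"],
                                                  c.classifier_id))
    selected = [remaining.pop(0)]
    covered = set(info[selected[0].classifier_id]["correct"])
    fp = set(info[selected[0].classifier_id]["incorrect"]) - covered
    while remaining:
        added = None
        for clf in remaining:
            ci = info[clf.classifier_id]
            new_correct = ci["correct"] - covered
            corrects = ci["correct"] & fp
            if (len(new_correct) >= cfg.add_if_extra_correct * n_cases or
                    (fp and len(corrects) >= cfg.add_if_corrects_fp * len(fp))):
                added = clf
                break
        if added is None:
            break
        remaining.remove(added)
        selected.append(added)
        ci = info[added.classifier_id]
        covered |= ci["correct"]
        fp = (fp | ci["incorrect"]) - covered
    return selected
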