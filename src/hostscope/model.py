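"""Top-level modelling surface: `HostPredictor` and `HostPredictorResults`.

`HostPredictor` is built from a host reference frame, per-tool hit tables
and genus-level training labels; `fit()` runs the whole training workflow
(balanced instance construction, per-tool classifier search and selection,
combined-forest training, PPV calibration on a disjoint calibration split)
and returns a `HostPredictorResults` holding the trained components, their
diagnostics, `predict()` and `summary()`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import (NonAmbiguousThresholds, SelectionConfig,
                          TrainedClassifier, TrainingConstraints,
                          best_prediction_per_virus, build_training_instances,
                          select_classifier_set, tune_hyperparameters)
from .encoding import CandidateLimits, ScoreBinning, encode_tool_features
from .integration import (CalibrationCurve, CombinedRF, IntegrationConfig,
                          aggregate_to_genus, build_combined_features,
                          composite_score, finalize_predictions, fit_calibration,
                          train_combined_rf)
from .providers import HOST_TOOLS
from .taxonomy import (DistanceBinning, HostFrame, LabelMappingConfig,
                       map_label_to_genera)

GENERIC_TOOLS = ("s2star_like", "php_like")


@dataclass
class FitConfig:
    """Tunable configuration of the full fitting workflow.

    Defaults are sized for desk-scale benchmarks: a couple of random-search
    trials per classifier kind and ~1,500 labelled pairs (x3 hit-subset
    variants) per tool.  ``tool_kinds`` follows the published layout:
    forests and nets for the alignment-based tools, nets for the
    alignment-free ones.
    """

    tool_kinds: dict = field(default_factory=lambda: {
        "blast": ("random_forest", "dense_net"),
        "crispr": ("random_forest", "dense_net"),
        "kmer_model": ("dense_net",),
        "s2star_like": ("dense_net",),
        "php_like": ("dense_net",),
    })
    n_trials: int = 2
    top_per_kind: int = 1
    n_target_pairs: int = 1500
    max_selected: int = 10
    constraints: TrainingConstraints = field(default_factory=TrainingConstraints)
    limits: CandidateLimits = field(default_factory=CandidateLimits)
    dbin: DistanceBinning = field(default_factory=DistanceBinning)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    nonambiguous: NonAmbiguousThresholds = field(default_factory=NonAmbiguousThresholds)
    combined_n_per_stratum: int = 700
    combined_max_correct: int = 10
    combined_max_incorrect: int = 5
    combined_n_trials: int = 8
    window_single: float = 0.05
    window_combined: float = 0.01
    window_phage: float = 0.01
    window_final: float = 0.01
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    label_mapping: LabelMappingConfig = field(default_factory=LabelMappingConfig)


def _subset(hit_tables: dict[str, pd.DataFrame], viruses) -> dict[str, pd.DataFrame]:
    vs = set(viruses)
    return {t: df[df["virus_id"].isin(vs)].reset_index(drop=True)
            for t, df in hit_tables.items()}


class HostPredictor:
    """Integrated genus-level host predictor.

    Parameters
    ----------
    frame : HostFrame
        Host tree + lineage table.
    hit_tables : dict of tool name -> DataFrame
        Per-tool virus -> genome hit tables (provider column conventions).
    truth : DataFrame indexed by virus_id
        Columns ``true_genus`` and ``known`` (bool novelty flag); required
        for fitting.
    phage_predictions : DataFrame, optional
        Phage-based tool output: virus_id, predicted_label, score in [0, 1].
    label_tallies : dict, optional
        predicted_label -> {genus: genome count} used to map phage-based
        labels onto host genera.
    """

    def __init__(self, frame: HostFrame, hit_tables: dict[str, pd.DataFrame],
                 truth: pd.DataFrame | None = None,
                 phage_predictions: pd.DataFrame | None = None,
                 label_tallies: dict | None = None,
                 config: FitConfig | None = None) -> None:
        self.frame = frame
        self.hit_tables = {t: hit_tables.get(t, pd.DataFrame(columns=["virus_id", "genome_id"]))
                           for t in HOST_TOOLS}
        self.truth = truth
        self.phage_predictions = phage_predictions
        self.label_tallies = label_tallies or {}
        self.config = config or FitConfig()

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, train_viruses=None,
            calibration_viruses=None) -> "HostPredictorResults":
        """Train classifiers on ``train_viruses`` and calibrate every
        score -> PPV curve on the disjoint ``calibration_viruses``.

        When the splits are not given, labelled viruses are shuffled
        (seeded) and split 2:1.
        """
        if self.truth is None:
            raise ValueError("fitting requires training labels (truth table)")
        cfg = self.config
        rng_root = np.random.SeedSequence(seed)
        stage_seeds = rng_root.generate_state(64).astype(np.int64) % (2**31 - 1)

        all_viruses = np.array(sorted(self.truth.index))
        if train_viruses is None or calibration_viruses is None:
            perm = np.random.default_rng(stage_seeds[0]).permutation(all_viruses)
            n_tr = int(round(len(perm) * 2 / 3))
            train_viruses = perm[:n_tr]
            calibration_viruses = perm[n_tr:]
        train_viruses = sorted(train_viruses)
        calibration_viruses = sorted(calibration_viruses)
        if set(train_viruses) & set(calibration_viruses):
            raise ValueError("train and calibration virus sets must be disjoint")

        train_hits = _subset(self.hit_tables, train_viruses)
        cal_hits = _subset(self.hit_tables, calibration_viruses)

        sbin = ScoreBinning()
        for tool in GENERIC_TOOLS:
            df = train_hits[tool]
            if len(df):
                sbin.fit_quantiles(tool, df["score"].to_numpy(float))

        # --- per-tool classifier search + selection -----------------------
        selected: dict[str, list[TrainedClassifier]] = {}
        diagnostics: dict = {"tools": {}, "n_train_viruses": len(train_viruses),
                             "n_calibration_viruses": len(calibration_viruses)}
        si = 1
        for tool in HOST_TOOLS:
            hits = train_hits[tool]
            kinds = cfg.tool_kinds.get(tool, ())
            if hits.empty or not kinds:
                selected[tool] = []
                continue
            ts = build_training_instances(
                hits, tool, self.frame, self.truth, cfg.constraints,
                n_target=cfg.n_target_pairs, dbin=cfg.dbin, sbin=sbin,
                limits=cfg.limits, seed=int(stage_seeds[si]))
            si += 1
            candidates = []
            for kind in kinds:
                top = tune_hyperparameters(ts, kind, n_trials=cfg.n_trials,
                                           seed=int(stage_seeds[si]),
                                           top_n=cfg.top_per_kind)
                si += 1
                candidates.extend(top)
            nonambig = cfg.nonambiguous.nonambiguous_viruses(tool, cal_hits[tool])
            eval_scores = {c.classifier_id:
                           _score_classifier(c, cal_hits[tool], self.frame,
                                             cfg.dbin, sbin, cfg.limits)
                           for c in candidates}
            if nonambig and len(candidates) > 1:
                sel = select_classifier_set(candidates, eval_scores, self.truth,
                                            self.frame, nonambig, cfg.selection)
            else:
                sel = candidates[:1]
            selected[tool] = sel
            diagnostics["tools"][tool] = {
                "n_instances": len(ts),
                "n_candidates": len(candidates),
                "selected": [c.classifier_id for c in sel],
                "val_metrics": {c.classifier_id: c.metrics for c in sel},
                "n_nonambiguous": len(nonambig),
            }

        order = []
        for tool in HOST_TOOLS:
            order.extend(c for c in selected[tool])
        order = order[:cfg.max_selected]
        order_ids = [c.classifier_id for c in order]

        results = HostPredictorResults(
            model=self, sbin=sbin, selected=selected, selected_order=order,
            diagnostics=diagnostics)

        # --- combined-hosts forest on the training split ------------------
        train_scores = {c.classifier_id:
                        _score_classifier(c, train_hits[c.tool], self.frame,
                                          cfg.dbin, sbin, cfg.limits)
                        for c in order}
        features = build_combined_features(train_scores, order_ids)
        genus = self.frame.genus_series
        labels = np.array([int(genus[g] == self.truth.at[v, "true_genus"])
                           for v, g in zip(features["virus_id"], features["genome_id"])])
        strata = pd.DataFrame({
            "has_blast": [v in set(train_hits["blast"]["virus_id"]) for v in train_viruses],
            "has_crispr": [v in set(train_hits["crispr"]["virus_id"]) for v in train_viruses],
        }, index=train_viruses)
        results.combined = train_combined_rf(
            features, labels, order_ids, strata,
            n_per_stratum=cfg.combined_n_per_stratum,
            max_correct=cfg.combined_max_correct,
            max_incorrect=cfg.combined_max_incorrect,
            n_trials=cfg.combined_n_trials, seed=int(stage_seeds[40]))
        diagnostics["combined_rf"] = results.combined.metrics

        # --- calibration on the held-out calibration split ----------------
        phage_cal = None
        if self.phage_predictions is not None:
            vs = set(calibration_viruses)
            phage_cal = self.phage_predictions[
                self.phage_predictions["virus_id"].isin(vs)].reset_index(drop=True)
        results._fit_calibration(cal_hits, phage_cal, self.truth)
        return results


def _score_classifier(clf: TrainedClassifier, hits: pd.DataFrame,
                      frame: HostFrame, dbin: DistanceBinning, sbin: ScoreBinning,
                      limits: CandidateLimits) -> pd.DataFrame:
    """(virus_id, genome_id, score) for every candidate of every virus."""
    feats = encode_tool_features(hits, clf.tool, frame, dbin, sbin, limits,
                                 mode=clf.mode)
    out = feats[["virus_id", "genome_id"]].copy()
    if len(feats):
        X = feats.drop(columns=["virus_id", "genome_id"]).to_numpy(float)
        out["score"] = clf.score(X)
    else:
        out["score"] = pd.Series(dtype=float)
    return out


@dataclass
class HostPredictorResults:
    """Fitted components of the integrated predictor, with prediction and
    reporting helpers."""

    model: HostPredictor
    sbin: ScoreBinning
    selected: dict
    selected_order: list
    diagnostics: dict
    combined: CombinedRF | None = None
    curves: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def frame(self) -> HostFrame:
        return self.model.frame

    @property
    def config(self) -> FitConfig:
        return self.model.config

    def _classifier_genus_scores(self, clf: TrainedClassifier,
                                 hits: pd.DataFrame) -> pd.DataFrame:
        scores = _score_classifier(clf, hits, self.frame, self.config.dbin,
                                   self.sbin, self.config.limits)
        return aggregate_to_genus(scores, self.frame)

    def _combined_genus_scores(self, hit_tables: dict) -> pd.DataFrame:
        order_ids = [c.classifier_id for c in self.selected_order]
        per_clf = {c.classifier_id:
                   _score_classifier(c, hit_tables[c.tool], self.frame,
                                     self.config.dbin, self.sbin, self.config.limits)
                   for c in self.selected_order}
        if all(df.empty for df in per_clf.values()):
            return pd.DataFrame(columns=["virus_id", "host_genus", "score", "genome_id"])
        features = build_combined_features(per_clf, order_ids)
        scores = features[["virus_id", "genome_id"]].copy()
        scores["score"] = self.combined.score(features)
        return aggregate_to_genus(scores, self.frame)

    def _phage_genus_scores(self, phage: pd.DataFrame | None) -> pd.DataFrame:
        cols = ["virus_id", "host_genus", "score"]
        if phage is None or phage.empty:
            return pd.DataFrame(columns=cols)
        rows = []
        for r in phage.itertuples(index=False):
            tally = self.model.label_tallies.get(r.predicted_label)
            if not tally:
                continue
            for genus in sorted(map_label_to_genera(tally, self.config.label_mapping)):
                rows.append((r.virus_id, genus, float(r.score)))
        df = pd.DataFrame(rows, columns=cols)
        if df.empty:
            return df
        df = df.sort_values(["virus_id", "host_genus", "score"],
                            ascending=[True, True, False], kind="mergesort")
        return df.drop_duplicates(["virus_id", "host_genus"]).reset_index(drop=True)

    # ------------------------------------------------------------------
    def _fit_calibration(self, cal_hits: dict, phage_cal: pd.DataFrame | None,
                         truth: pd.DataFrame) -> None:
        """Fit every score -> PPV curve on the calibration split."""
        cfg = self.config
        genus_truth = truth["true_genus"]

        def correct_labels(df: pd.DataFrame) -> np.ndarray:
            return np.array([genus_truth.get(v) == g
                             for v, g in zip(df["virus_id"], df["host_genus"])], int)

        # curves are fitted on every scored (virus, genus) pair of the
        # calibration split so the whole score range has empirical support
        for tool in ("blast", "crispr"):
            for clf in self.selected[tool]:
                gsc = self._classifier_genus_scores(clf, cal_hits[tool])
                if len(gsc):
                    self.curves[clf.classifier_id] = fit_calibration(
                        gsc["score"], correct_labels(gsc), window=cfg.window_single)
        comb = self._combined_genus_scores(cal_hits)
        if len(comb):
            self.curves["combined_rf"] = fit_calibration(
                comb["score"], correct_labels(comb), window=cfg.window_combined)
        ph = self._phage_genus_scores(phage_cal)
        if len(ph):
            self.curves["phage_based"] = fit_calibration(
                ph["score"], correct_labels(ph), window=cfg.window_phage)
        comps = self._composite_table(cal_hits, phage_cal)
        if len(comps):
            self.curves["final"] = fit_calibration(
                comps["composite"], correct_labels(comps),
                window=cfg.window_final)

    # ------------------------------------------------------------------
    def method_ppv_table(self, hit_tables: dict,
                         phage: pd.DataFrame | None) -> pd.DataFrame:
        """One row per (virus, genus, method) with raw score and calibrated
        PPV, for the four integrated methods."""
        rows = []
        for tool, method in (("blast", "blast_clf"), ("crispr", "crispr_clf")):
            for clf in self.selected[tool]:
                curve = self.curves.get(clf.classifier_id)
                if curve is None:
                    continue
                gsc = self._classifier_genus_scores(clf, hit_tables[tool])
                for r in gsc.itertuples(index=False):
                    rows.append((r.virus_id, r.host_genus, method,
                                 float(r.score), float(curve.ppv_at(r.score))))
        if self.combined is not None and "combined_rf" in self.curves:
            curve = self.curves["combined_rf"]
            gsc = self._combined_genus_scores(hit_tables)
            for r in gsc.itertuples(index=False):
                rows.append((r.virus_id, r.host_genus, "combined_rf",
                             float(r.score), float(curve.ppv_at(r.score))))
        if "phage_based" in self.curves:
            curve = self.curves["phage_based"]
            gsc = self._phage_genus_scores(phage)
            for r in gsc.itertuples(index=False):
                rows.append((r.virus_id, r.host_genus, "phage_based",
                             float(r.score), float(curve.ppv_at(r.score))))
        df = pd.DataFrame(rows, columns=["virus_id", "host_genus", "method",
                                         "raw_score", "ppv"])
        if df.empty:
            return df
        # several classifiers can back one method: keep the best-PPV row
        df = df.sort_values(["virus_id", "host_genus", "method", "ppv", "raw_score"],
                            ascending=[True, True, True, False, False],
                            kind="mergesort")
        return df.drop_duplicates(["virus_id", "host_genus", "method"]).reset_index(drop=True)

    def _composite_table(self, hit_tables: dict,
                         phage: pd.DataFrame | None) -> pd.DataFrame:
        ppvs = self.method_ppv_table(hit_tables, phage)
        rows = []
        for (virus, genus), grp in ppvs.groupby(["virus_id", "host_genus"], sort=True):
            per_method = dict(zip(grp["method"], grp["ppv"]))
            comp, main, used = composite_score(per_method, self.config.integration)
            if comp is None:
                continue
            rows.append((virus, genus, comp, main, ";".join(used),
                         json.dumps({m: round(p, 6) for m, p in sorted(per_method.items())})))
        return pd.DataFrame(rows, columns=["virus_id", "host_genus", "composite",
                                           "main_method", "methods_used",
                                           "method_ppvs"])

    # ------------------------------------------------------------------
    def predict(self, hit_tables: dict | None = None,
                phage_predictions: pd.DataFrame | None = None,
                min_score: float | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Genus-level predictions for a set of hit tables.

        Returns ``(summary, detailed)``: the summary has one row per
        retained (virus, genus) with confidence in [75, 100] filtered at
        ``min_score`` (default: the report floor 75), best genus first per
        virus; the detailed table has one row per (virus, genus, method)
        with raw score and calibrated PPV.
        """
        if hit_tables is None:
            hit_tables = self.model.hit_tables
        hit_tables = {t: hit_tables.get(t, pd.DataFrame(columns=["virus_id", "genome_id"]))
                      for t in HOST_TOOLS}
        detailed = self.method_ppv_table(hit_tables, phage_predictions)
        comps = self._composite_table(hit_tables, phage_predictions)
        if "final" not in self.curves or comps.empty:
            empty = comps.iloc[0:0].assign(confidence=pd.Series(dtype=float))
            return empty, detailed
        summary = finalize_predictions(comps, self.curves["final"],
                                       self.config.integration, min_score=min_score)
        summary = summary.copy()
        summary["host_lineage"] = [self.frame.genus_lineage_string(g)
                                   for g in summary["host_genus"]]
        cols = ["virus_id", "host_genus", "host_lineage", "confidence",
                "main_method", "methods_used", "composite", "method_ppvs"]
        return summary[cols], detailed

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text overview of the fitted predictor."""
        lines = ["Integrated host predictor", "=" * 60]
        d = self.diagnostics
        lines.append(f"Training viruses:    {d.get('n_train_viruses', '?')}")
        lines.append(f"Calibration viruses: {d.get('n_calibration_viruses', '?')}")
        lines.append("-" * 60)
        lines.append(f"{'tool':<12} {'instances':>9} {'selected classifiers'}")
        for tool, td in d.get("tools", {}).items():
            sel = ",".join(td["selected"]) or "-"
            lines.append(f"{tool:<12} {td['n_instances']:>9} {sel}")
        if self.combined is not None:
            m = self.combined.metrics
            lines.append("-" * 60)
            lines.append(f"combined-hosts-RF: val acc {m['val_accuracy']:.3f}, "
                         f"recall@5%FDR {m['recall_at_5fdr']:.3f}, "
                         f"{m['n_train_pairs']} training pairs")
        lines.append("-" * 60)
        lines.append("calibration curves: " + ", ".join(sorted(self.curves)) or "none")
        return "\n".join(lines)


def _best_genus_per_virus(gsc: pd.DataFrame) -> pd.DataFrame:
    if gsc.empty:
        return gsc
    ordered = gsc.sort_values(["virus_id", "score", "host_genus"],
                              ascending=[True, False, True], kind="mergesort")
    return ordered.groupby("virus_id", as_index=False).first()


def _best_composite_per_virus(comps: pd.DataFrame) -> pd.DataFrame:
    if comps.empty:
        return comps
    ordered = comps.sort_values(["virus_id", "composite", "host_genus"],
                                ascending=[True, False, True], kind="mergesort")
    return ordered.groupby("virus_id", as_index=False).first()
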