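"""Hit-matrix encoding: turn one virus's hits into per-candidate-host count
matrices over (phylogenetic-distance bin x score bin).

Every genome with at least one retained hit becomes a candidate host; for a
candidate, each retained hit of the same virus/tool contributes a count at
(distance-to-candidate bin, score bin).  Score bins are oriented so a larger
index always means a stronger hit (identity ascending, mismatches reversed,
-log10 p ascending, generic scores by training-set quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .providers import RANK_KEYS, sort_hits
from .taxonomy import DistanceBinning, HostFrame


@dataclass(frozen=True)
class CandidateLimits:
    """Per-virus hit truncation: 50 best hits for blast, 30 for other tools."""

    top_k_blast: int = 50
    top_k_other: int = 30

    def __post_init__(self) -> None:
        if self.top_k_blast < 1 or self.top_k_other < 1:
            raise ValueError("top-k limits must be >= 1")

    def top_k(self, tool: str) -> int:
        return self.top_k_blast if tool == "blast" else self.top_k_other


@dataclass
class ScoreBinning:
    """Per-tool score-to-bin transforms.

    blast uses a 4x3 grid (mean identity {[80,85),[85,90),[90,95),[95,100]}
    x match count {1, 2-4, >=5}); CRISPR uses the mismatch count reversed so
    bin 7 is a perfect match; the k-mer model bins -log10(p) at {2, 5}
    (aligned with the p <= 0.2 reporting cutoff); generic tools use quantile
    bins whose edges are fitted once on training scores and then frozen.
    """

    identity_edges: tuple[float, ...] = (85.0, 90.0, 95.0)
    n_match_edges: tuple[float, ...] = (2.0, 5.0)
    max_mismatches: int = 7
    neglogp_edges: tuple[float, ...] = (2.0, 5.0)
    n_quantile_bins: int = 4
    quantile_edges: dict = field(default_factory=dict)

    def n_score_bins(self, tool: str) -> int:
        if tool == "blast":
            return (len(self.identity_edges) + 1) * (len(self.n_match_edges) + 1)
        if tool == "crispr":
            return self.max_mismatches + 1
        if tool == "kmer_model":
            return len(self.neglogp_edges) + 1
        return self.n_quantile_bins

    def fit_quantiles(self, tool: str, scores: np.ndarray) -> None:
        """Freeze quantile edges for a generic tool from training scores."""
        qs = np.linspace(0, 1, self.n_quantile_bins + 1)[1:-1]
        self.quantile_edges[tool] = tuple(np.quantile(np.asarray(scores, float), qs))

    def bin_scores(self, tool: str, hits: pd.DataFrame) -> np.ndarray:
        """Map each hit row to its flat score-bin index (0 = worst)."""
        if tool == "blast":
            idb = np.searchsorted(self.identity_edges,
                                  hits["mean_identity"].to_numpy(float), side="right")
            nmb = np.searchsorted(self.n_match_edges,
                                  hits["n_matches"].to_numpy(float), side="right")
            return idb * (len(self.n_match_edges) + 1) + nmb
        if tool == "crispr":
            mm = np.minimum(hits["mismatches"].to_numpy(int), self.max_mismatches)
            return self.max_mismatches - mm
        if tool == "kmer_model":
            t = -np.log10(np.maximum(hits["pvalue"].to_numpy(float), 1e-300))
            return np.searchsorted(self.neglogp_edges, t, side="left")
        if tool not in self.quantile_edges:
            raise ValueError(f"quantile edges not fitted for tool {tool!r}")
        return np.searchsorted(self.quantile_edges[tool],
                               hits["score"].to_numpy(float), side="right")


@dataclass
class HitMatrix:
    """Count tally of one virus's hits for one tool, centred on a candidate."""

    virus_id: str
    candidate_genome_id: str
    tool: str
    counts: np.ndarray  # (n_distance_bins, n_score_bins) int array

    @property
    def n_hits_total(self) -> int:
        return int(self.counts.sum())


def enumerate_candidates(hits: pd.DataFrame, tool: str,
                         limits: CandidateLimits | None = None
                         ) -> tuple[list[str], pd.DataFrame]:
    """Truncate one virus's hits to the tool's top-k and list candidates.

    Hits are ordered best-first by the tool metric (ties broken by
    genome_id); every genome with a retained hit is a candidate host.
    """
    limits = limits or CandidateLimits()
    retained = sort_hits(hits, tool).head(limits.top_k(tool))
    candidates = sorted(retained["genome_id"].unique())
    return candidates, retained


def encode_matrix(virus_id: str, candidate_genome_id: str, retained: pd.DataFrame,
                  frame: HostFrame, dbin: DistanceBinning, sbin: ScoreBinning,
                  tool: str) -> HitMatrix:
    """Tally one virus's retained hits around one candidate host."""
    n_db, n_sb = dbin.n_bins, sbin.n_score_bins(tool)
    counts = np.zeros((n_db, n_sb), dtype=np.int64)
    ci = frame.index_of(candidate_genome_id)
    if len(retained):
        hit_idx = np.array([frame.index_of(g) for g in retained["genome_id"]])
        d = frame.distance_matrix[ci, hit_idx]
        db = dbin.bin_array(d)
        sb = sbin.bin_scores(tool, retained)
        np.add.at(counts, (db, sb), 1)
    return HitMatrix(virus_id, candidate_genome_id, tool, counts)


def flatten_features(matrix: HitMatrix, mode: str = "flat_counts") -> np.ndarray:
    """Row-major flattening; ``summary`` appends tree-model summary stats:
    best score bin at distance 0 (1-based, 0 if empty), hit count within the
    three closest distance bins, and the total hit count."""
    flat = matrix.counts.astype(float).ravel(order="C")
    if mode == "flat_counts":
        return flat
    if mode != "summary":
        raise ValueError(f"unknown feature mode: {mode!r}")
    row0 = matrix.counts[0]
    nz = np.nonzero(row0)[0]
    best0 = float(nz.max() + 1) if nz.size else 0.0
    near = float(matrix.counts[:3].sum())
    return np.concatenate([flat, [best0, near, float(matrix.n_hits_total)]])


def feature_length(tool: str, dbin: DistanceBinning, sbin: ScoreBinning,
                   mode: str) -> int:
    base = dbin.n_bins * sbin.n_score_bins(tool)
    return base + (3 if mode == "summary" else 0)


def encode_tool_features(hits: pd.DataFrame, tool: str, frame: HostFrame,
                         dbin: DistanceBinning, sbin: ScoreBinning,
                         limits: CandidateLimits | None = None,
                         mode: str = "flat_counts") -> pd.DataFrame:
    """Encode all viruses of one tool's hit table in one pass.

    Returns one row per (virus, candidate) with columns ``virus_id``,
    ``genome_id`` and ``f0..f{d-1}`` feature columns.  Output is invariant
    to the input row order.
    """
    limits = limits or CandidateLimits()
    n_db, n_sb = dbin.n_bins, sbin.n_score_bins(tool)
    dim = feature_length(tool, dbin, sbin, mode)
    vids, gids, feats = [], [], []
    if len(hits):
        for g in hits.loc[:, "genome_id"].unique():
            frame.index_of(g)  # fail fast with the genome named
    for virus_id, vhits in hits.groupby("virus_id", sort=True):
        candidates, retained = enumerate_candidates(vhits, tool, limits)
        hit_idx = np.array([frame.index_of(g) for g in retained["genome_id"]])
        cand_idx = np.array([frame.index_of(g) for g in candidates])
        sb = sbin.bin_scores(tool, retained)
        d = frame.distance_matrix[np.ix_(cand_idx, hit_idx)]
        db = dbin.bin_array(d)  # (n_cand, n_hits)
        n_cand, n_hits = db.shape
        tensor = np.zeros((n_cand, n_db, n_sb), dtype=np.int64)
        ci = np.repeat(np.arange(n_cand), n_hits)
        np.add.at(tensor, (ci, db.ravel(), np.tile(sb, n_cand)), 1)
        for j, cand in enumerate(candidates):
            m = HitMatrix(virus_id, cand, tool, tensor[j])
            vids.append(virus_id)
            gids.append(cand)
            feats.append(flatten_features(m, mode))
    if not feats:
        cols = [f"f{i}" for i in range(dim)]
        return pd.DataFrame(columns=["virus_id", "genome_id", *cols])
    fm = np.vstack(feats)
    out = pd.DataFrame(fm, columns=[f"f{i}" for i in range(fm.shape[1])])
    out.insert(0, "genome_id", gids)
    out.insert(0, "virus_id", vids)
    return out


def features_to_tsv(features: pd.DataFrame, path, tool: str) -> None:
    """Cache encoded matrices as a columnar TSV (virus, candidate, tool, counts)."""
    df = features.copy()
    df.insert(2, "tool", tool)
    df.to_csv(path, sep="\t", index=False)


def features_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=["tool"])
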