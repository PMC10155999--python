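"""Per-tool virus -> host-genome hit providers.

Hits come from three places: parsed outputs of external alignment tools
(blast tabular), generic per-pair score tables (alignment-free tools,
phage-based predictors), and two built-in desk-scale providers — an ungapped
CRISPR spacer matcher with a low-complexity filter, and an order-k Markov
model scorer — so the whole pipeline runs without external binaries.

All providers emit pandas DataFrames with a fixed column set per tool; the
``sort_hits`` helper orders any table best-hit-first using the tool's native
metric orientation (mismatches and p-values are lower-better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

HOST_TOOLS = ("blast", "crispr", "kmer_model", "s2star_like", "php_like")

#: per-tool ranking: list of (column, ascending) applied best-first,
#: genome_id as the deterministic tiebreak.
RANK_KEYS: dict[str, list[tuple[str, bool]]] = {
    "blast": [("n_matches", False), ("mean_identity", False)],
    "crispr": [("mismatches", True)],
    "kmer_model": [("pvalue", True)],
    "s2star_like": [("score", False)],
    "php_like": [("score", False)],
}

BLAST_COLUMNS = ["virus_id", "genome_id", "n_matches", "mean_identity", "total_aln_len"]
CRISPR_COLUMNS = ["virus_id", "genome_id", "spacer_id", "spacer_len",
                  "mismatches", "strand", "virus_pos"]


def sort_hits(df: pd.DataFrame, tool: str) -> pd.DataFrame:
    """Order a hit table best-first by the tool's metric, ties by genome_id."""
    if tool not in RANK_KEYS:
        raise ValueError(f"unknown tool: {tool!r}")
    keys = RANK_KEYS[tool] + [("genome_id", True)]
    cols = [c for c, _ in keys]
    asc = [a for _, a in keys]
    return df.sort_values(cols, ascending=asc, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# blast tabular
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlastFilters:
    """HSP-level filters applied while parsing blast tabular output."""

    max_evalue: float = 1e-3
    min_identity: float = 80.0
    min_len: int = 500


_OUTFMT6 = ("qseqid sseqid pident length mismatch gapopen qstart qend "
            "sstart send evalue bitscore").split()


def parse_blast_tab(path, filters: BlastFilters | None = None,
                    contig_map: Mapping[str, str] | None = None,
                    on_unknown: str = "error") -> pd.DataFrame:
    """Parse 12-column blast tabular (outfmt 6) output into filtered HSPs.

    Only HSPs with e-value <= ``max_evalue``, identity >= ``min_identity``
    and alignment length >= ``min_len`` are kept.  Subject ids are resolved
    to genome ids through ``contig_map`` when given; an unresolvable subject
    raises (``on_unknown='error'``) or is dropped with a warning
    (``on_unknown='skip'``).

    Returns a DataFrame with columns virus_id, genome_id, identity, length,
    evalue, bitscore.
    """
    filters = filters or BlastFilters()
    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"malformed blast row at line {lineno}: "
                                 f"expected 12 columns, got {len(parts)}")
            try:
                pident = float(parts[2])
                length = int(parts[3])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"malformed blast row at line {lineno}: {exc}") from None
            subject = parts[1]
            if contig_map is not None:
                if subject not in contig_map:
                    if on_unknown == "error":
                        raise KeyError(f"unresolvable subject id {subject!r} "
                                       f"at line {lineno}")
                    warnings.warn(f"skipping unresolvable subject id {subject!r}")
                    continue
                genome = contig_map[subject]
            else:
                genome = subject
            if evalue > filters.max_evalue:
                continue
            if pident < filters.min_identity:
                continue
            if length < filters.min_len:
                continue
            rows.append((parts[0], genome, pident, length, evalue, bitscore))
    return pd.DataFrame(rows, columns=["virus_id", "genome_id", "identity",
                                       "length", "evalue", "bitscore"])


def aggregate_blast(hsps: pd.DataFrame) -> pd.DataFrame:
    """Summarise filtered HSPs per (virus, genome) pair.

    n_matches = HSP count, mean_identity = unweighted mean of HSP identities,
    total_aln_len = summed HSP alignment length.
    """
    if hsps.empty:
        return pd.DataFrame(columns=BLAST_COLUMNS)
    g = hsps.groupby(["virus_id", "genome_id"], sort=True)
    out = g.agg(n_matches=("identity", "size"),
                mean_identity=("identity", "mean"),
                total_aln_len=("length", "sum")).reset_index()
    return out[BLAST_COLUMNS]


# ---------------------------------------------------------------------------
# spacer complexity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexityConfig:
    """Configuration of the custom spacer complexity score.

    The score is ``(CWF - 2) * 2`` unless the AT-skew statistic exceeds
    ``skew_threshold``, in which case it is ``skew + 0.1``.  CWF is the
    Wootton-Federhen-style complexity, computed here as the Shannon entropy
    (base 2) of mononucleotide frequencies; ``cwf_variant='inverted'``
    selects ``(2 - CWF) * 2`` so that low-complexity sequences score high on
    that branch too.  ``skew_variant`` picks |nA-nT|/(nA+nT) (``abs_skew``)
    or the AT fraction (``at_content``).  Hits with score >=
    ``filter_threshold`` are discarded by the spacer filter.
    """

    skew_threshold: float = 0.65
    cwf_variant: str = "as_written"
    skew_variant: str = "abs_skew"
    filter_threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.cwf_variant not in ("as_written", "inverted"):
            raise ValueError("cwf_variant must be 'as_written' or 'inverted'")
        if self.skew_variant not in ("abs_skew", "at_content"):
            raise ValueError("skew_variant must be 'abs_skew' or 'at_content'")
        for t in (self.skew_threshold, self.filter_threshold):
            if not (0 <= t <= 1.2):
                raise ValueError("thresholds must lie in [0, 1.2]")


def spacer_complexity(seq: str, cfg: ComplexityConfig | None = None) -> float:
    """Low-complexity score of a spacer sequence (higher = less complex)."""
    cfg = cfg or ComplexityConfig()
    s = seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    n = sum(counts.values())
    if n == 0:
        raise ValueError("sequence empty or all-N")
    na, nt = counts["A"], counts["T"]
    if cfg.skew_variant == "abs_skew":
        skew = abs(na - nt) / (na + nt) if (na + nt) > 0 else 0.0
    else:
        skew = (na + nt) / n
    if skew > cfg.skew_threshold:
        return skew + 0.1
    freqs = np.array([c for c in counts.values() if c > 0], dtype=float) / n
    cwf = float(-(freqs * np.log2(freqs)).sum())
    if cfg.cwf_variant == "as_written":
        return (cwf - 2.0) * 2.0
    return (2.0 - cwf) * 2.0


# ---------------------------------------------------------------------------
# spacer matching
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _encode(seq: str, n_code: int) -> np.ndarray:
    """Encode DNA as uint8; non-ACGT characters get ``n_code`` so that an N
    never matches anything (including another N)."""
    return np.array([_CODE.get(c, n_code) for c in seq.upper()], dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def match_spacers(virus_seq: str, spacers: Sequence[tuple[str, str]],
                  max_mm: int = 7) -> pd.DataFrame:
    """Ungapped scan of each spacer against both strands of a virus sequence.

    Every placement (0-based start on the + strand of the virus) whose
    Hamming mismatch count over the entire spacer is <= ``max_mm`` is
    reported; N counts as a mismatch.  A placement matching on both strands
    (palindromic spacer) is reported once, with its minimum-mismatch strand
    (+ preferred on ties).  A spacer longer than the virus yields no hits.
    Columns: spacer_id, spacer_len, mismatches, strand, virus_pos.
    """
    v = _encode(virus_seq, n_code=4)
    rows = []
    for spacer_id, sp_seq in spacers:
        m = len(sp_seq)
        if m == 0 or m > len(v):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(v, m)
        mm_fwd = (windows != _encode(sp_seq, n_code=5)).sum(axis=1)
        mm_rev = (windows != _encode(reverse_complement(sp_seq), n_code=5)).sum(axis=1)
        mm = np.minimum(mm_fwd, mm_rev)
        strands = np.where(mm_fwd <= mm_rev, "+", "-")
        for pos in np.nonzero(mm <= max_mm)[0]:
            rows.append((spacer_id, m, int(mm[pos]), str(strands[pos]), int(pos)))
    df = pd.DataFrame(rows, columns=["spacer_id", "spacer_len", "mismatches",
                                     "strand", "virus_pos"])
    return df.sort_values(["spacer_id", "mismatches", "strand", "virus_pos"],
                          kind="mergesort").reset_index(drop=True)


def read_fasta(path) -> dict[str, str]:
    """id -> uppercase sequence map from a FASTA file."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def crispr_hits_from_sequences(virus_seqs: Mapping[str, str],
                               spacers_by_genome: Mapping[str, Sequence[tuple[str, str]]],
                               max_mm: int = 7, min_spacer_len: int = 25,
                               complexity_cfg: ComplexityConfig | None = None
                               ) -> pd.DataFrame:
    """Full sequence-level CRISPR provider.

    Scans every genome's spacer set against every virus, keeps the best
    placement per (virus, genome, spacer) and applies the spacer filters
    (length >= 25 nt, < 8 mismatches, complexity < 0.6).  Returns the
    standard crispr hit-table columns.
    """
    seqs_flat = {sid: seq for sps in spacers_by_genome.values()
                 for sid, seq in sps}
    pieces = []
    for vid in sorted(virus_seqs):
        for gid in sorted(spacers_by_genome):
            sps = spacers_by_genome[gid]
            if not sps:
                continue
            placements = match_spacers(virus_seqs[vid], sps, max_mm=max_mm)
            if placements.empty:
                continue
            best = best_spacer_hits(placements)
            kept = filter_spacer_hits(best, seqs_flat,
                                      min_spacer_len=min_spacer_len,
                                      complexity_cfg=complexity_cfg)
            if kept.empty:
                continue
            kept = kept.copy()
            kept.insert(0, "genome_id", gid)
            kept.insert(0, "virus_id", vid)
            pieces.append(kept)
    if not pieces:
        return pd.DataFrame(columns=CRISPR_COLUMNS)
    return pd.concat(pieces, ignore_index=True)[CRISPR_COLUMNS]


def best_spacer_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Reduce placements to one row per spacer: the minimum-mismatch placement
    (ties: + strand first, then smallest position)."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(["spacer_id", "mismatches", "strand", "virus_pos"],
                               kind="mergesort")
    return ordered.groupby("spacer_id", as_index=False).first()


def filter_spacer_hits(hits: pd.DataFrame, spacer_seqs: Mapping[str, str],
                       min_spacer_len: int = 25, max_mm_exclusive: int = 8,
                       complexity_cfg: ComplexityConfig | None = None) -> pd.DataFrame:
    """Retain spacer hits with length >= 25 nt, mismatches < 8 and a spacer
    complexity score below the filter threshold (default 0.6)."""
    cfg = complexity_cfg or ComplexityConfig()
    if hits.empty:
        return hits.copy()
    keep = (hits["spacer_len"] >= min_spacer_len) & (hits["mismatches"] < max_mm_exclusive)
    cx = {sid: spacer_complexity(spacer_seqs[sid], cfg)
          for sid in hits.loc[keep, "spacer_id"].unique()}
    keep &= hits["spacer_id"].map(lambda s: cx.get(s, np.inf) < cfg.filter_threshold)
    return hits.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Markov-model alignment-free scorer
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    """Order-k Markov model of a host genome with a Gaussian null.

    ``logp[context, base]`` holds conditional log-probabilities estimated
    from k-mer counts with an additive pseudocount; the null (mean/sd of the
    per-base mean log-likelihood over shuffled copies of the training
    sequence) turns scores into one-sided p-values.
    """

    order: int
    logp: np.ndarray
    genome_id: str
    null_mean: float
    null_sd: float

    def prob_table(self) -> np.ndarray:
        return np.exp(self.logp)


def _context_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(context index, next-base) pairs over positions with a clean window."""
    n = codes.size
    if n <= k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = codes < 4
    if k == 0:
        mask = valid
        return np.zeros(int(mask.sum()), dtype=np.int64), codes[mask].astype(np.int64)
    win_ok = np.ones(n - k, dtype=bool)
    ctx = np.zeros(n - k, dtype=np.int64)
    for off in range(k):
        seg = codes[off:off + n - k]
        win_ok &= seg < 4
        ctx = ctx * 4 + seg
    nxt = codes[k:]
    win_ok &= nxt < 4
    return ctx[win_ok], nxt[win_ok].astype(np.int64)


def _mean_loglik(codes: np.ndarray, k: int, logp: np.ndarray) -> float:
    ctx, nxt = _context_codes(codes, k)
    if ctx.size == 0:
        raise ValueError("sequence too short (or all ambiguous) for this model order")
    return float(logp[ctx, nxt].mean())


def train_markov(host_seq: str, order: int = 2, pseudocount: float = 1.0,
                 genome_id: str = "", n_null: int = 30,
                 seed: int = 0) -> MarkovModel:
    """Fit an order-k Markov model to a host sequence.

    The null distribution is estimated by scoring ``n_null`` random
    permutations of the training sequence (same base composition, k-mer
    structure destroyed) under the fitted model.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    codes = _encode(host_seq, n_code=4)
    ctx, nxt = _context_codes(codes, order)
    if ctx.size == 0:
        raise ValueError("host sequence too short for requested order")
    counts = np.zeros((4 ** order, 4))
    np.add.at(counts, (ctx, nxt), 1.0)
    counts += pseudocount
    logp = np.log(counts / counts.sum(axis=1, keepdims=True))
    rng = np.random.default_rng(seed)
    null_scores = []
    for _ in range(n_null):
        shuf = rng.permutation(codes)
        try:
            null_scores.append(_mean_loglik(shuf, order, logp))
        except ValueError:
            continue
    null_mean = float(np.mean(null_scores))
    null_sd = float(max(np.std(null_scores, ddof=1), 1e-9))
    return MarkovModel(order=order, logp=logp, genome_id=genome_id,
                       null_mean=null_mean, null_sd=null_sd)


def markov_score(virus_seq: str, model: MarkovModel) -> float:
    """Mean log-likelihood per base of the virus under the host model."""
    codes = _encode(virus_seq, n_code=4)
    return _mean_loglik(codes, model.order, model.logp)


def markov_pvalue(score: float, model: MarkovModel) -> float:
    """One-sided p-value: high scores give small p under the Gaussian null."""
    return float(norm.sf((score - model.null_mean) / model.null_sd))


def kmer_model_hits(virus_seqs: Mapping[str, str], models: Iterable[MarkovModel],
                    max_p: float = 0.2) -> pd.DataFrame:
    """Score every virus against every host model, keeping p <= ``max_p``."""
    rows = []
    for model in models:
        for vid, seq in virus_seqs.items():
            s = markov_score(seq, model)
            p = markov_pvalue(s, model)
            if p <= max_p:
                rows.append((vid, model.genome_id, s, p))
    return pd.DataFrame(rows, columns=["virus_id", "genome_id", "score", "pvalue"])


# ---------------------------------------------------------------------------
# generic score tables / phage-based predictions
# ---------------------------------------------------------------------------

def _read_score_tsv(path, value_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expect = {"virus_id", "score"}
    if not expect <= set(df.columns):
        raise ValueError(f"score table must have columns {sorted(expect | set(value_cols))}")
    for i, v in enumerate(df["score"]):
        try:
            float(v)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric score {v!r} at line {i + 2}") from None
    df["score"] = df["score"].astype(float)
    return df


def parse_score_table(path, tool: str) -> pd.DataFrame:
    """Read a generic TSV (virus_id, genome_id, score) for an alignment-free
    tool, deduplicating (virus, genome) pairs by the tool's best orientation."""
    if tool not in ("kmer_model", "s2star_like", "php_like"):
        raise ValueError(f"unknown score-table tool: {tool!r}")
    df = _read_score_tsv(path, ["genome_id"])
    if "genome_id" not in df.columns:
        raise ValueError("score table must have a genome_id column")
    if tool == "kmer_model":
        # score column holds a p-value for the alignment-free k-mer tool
        df = df.rename(columns={"score": "pvalue"})
        df["score"] = -df["pvalue"]
    dup = df.duplicated(["virus_id", "genome_id"], keep=False)
    if dup.any():
        warnings.warn("duplicated (virus, genome) rows; keeping best score")
        df = sort_hits(df, tool).drop_duplicates(["virus_id", "genome_id"], keep="first")
    cols = ["virus_id", "genome_id", "score"] + (["pvalue"] if tool == "kmer_model" else [])
    return df[cols].reset_index(drop=True)


def parse_phage_based(path) -> pd.DataFrame:
    """Read phage-based predictions: TSV (virus_id, predicted_label, score)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    label_col = "predicted_label" if "predicted_label" in df.columns else "label"
    if not {"virus_id", label_col, "score"} <= set(df.columns):
        raise ValueError("phage-based table needs virus_id, predicted_label, score")
    for i, v in enumerate(df["score"]):
        try:
            float(v)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric score {v!r} at line {i + 2}") from None
    df["score"] = df["score"].astype(float)
    df = df.rename(columns={label_col: "predicted_label"})
    dup = df.duplicated(["virus_id", "predicted_label"], keep=False)
    if dup.any():
        warnings.warn("duplicated (virus, label) rows; keeping best score")
        df = (df.sort_values(["virus_id", "predicted_label", "score"],
                             ascending=[True, True, False], kind="mergesort")
                .drop_duplicates(["virus_id", "predicted_label"], keep="first"))
    return df[["virus_id", "predicted_label", "score"]].reset_index(drop=True)
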