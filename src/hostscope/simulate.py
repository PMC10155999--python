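"""Self-contained synthetic worlds for training, calibrating and evaluating
the integrated predictor.

A world is a host frame (random tree with genus-clustered leaves + lineage
table), a set of viruses with known true hosts, per-tool hit tables whose
scores are drawn from separable correct-host vs background distributions,
and phage-based predictions with genus-resolvable labels.  Signal hits land
on the true host genome (and, with decayed strength, on its genus
siblings); background hits are scattered uniformly over all genomes.
`simulate_sequences` additionally emits toy FASTA-level data (genus-biased
host genomes, viruses sharing their host's composition, spacers copied from
virus substrings) so the sequence-level providers can be exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import FitConfig, HostPredictor
from .taxonomy import HostFrame


@dataclass(frozen=True)
class ToolProfile:
    """Signal geometry of one synthetic tool.

    ``p_fire`` is the probability the tool produces a hit on the true host
    genome; each same-genus sibling independently receives a weaker hit
    with probability ``p_sibling``; background hits are Poisson per virus,
    landing on uniformly random genomes.
    """

    p_fire: float
    p_sibling: float
    background_rate: float


DEFAULT_PROFILES: dict[str, ToolProfile] = {
    "blast": ToolProfile(p_fire=0.70, p_sibling=0.40, background_rate=2.0),
    "crispr": ToolProfile(p_fire=0.50, p_sibling=0.25, background_rate=0.8),
    "kmer_model": ToolProfile(p_fire=0.85, p_sibling=0.60, background_rate=3.0),
    "s2star_like": ToolProfile(p_fire=0.85, p_sibling=0.60, background_rate=3.0),
    "php_like": ToolProfile(p_fire=0.85, p_sibling=0.60, background_rate=3.0),
}

#: signal profiles for the noiseless limit: every tool fires on the true
#: host, siblings never outscore it, and background scores are disjoint
#: from signal scores.
NOISELESS_PROFILES: dict[str, ToolProfile] = {
    t: ToolProfile(p_fire=1.0, p_sibling=0.0, background_rate=p.background_rate)
    for t, p in DEFAULT_PROFILES.items()
}


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions of the default synthetic benchmark."""

    n_genera: int = 60
    genomes_per_genus: tuple[int, int] = (2, 4)
    n_viruses: int = 800
    frac_known: float = 0.55
    within_genus_bl: tuple[float, float] = (0.02, 0.10)
    backbone_bl: tuple[float, float] = (0.20, 0.60)
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    phage_p_predict: float = 0.60
    phage_p_correct: float = 0.80
    signal_mode: str = "default"  # 'default' | 'noiseless' | 'noise_only'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 2:
            raise ValueError("need at least 2 genera")
        if self.n_viruses < 1:
            raise ValueError("need at least 1 virus")
        if self.signal_mode not in ("default", "noiseless", "noise_only"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")


@dataclass
class World:
    """A fully specified synthetic benchmark instance."""

    config: WorldConfig
    frame: HostFrame
    truth: pd.DataFrame           # index virus_id: true_genome, true_genus, known
    hit_tables: dict              # tool -> DataFrame
    phage_predictions: pd.DataFrame
    label_tallies: dict


# ---------------------------------------------------------------------------
# tree / frame generation
# ---------------------------------------------------------------------------

def _random_join(parts: list[str], rng: np.random.Generator,
                 bl: tuple[float, float]) -> str:
    """Random binary topology over subtrees with U(bl) edge lengths."""
    parts = list(parts)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        l1, l2 = rng.uniform(*bl, size=2)
        parts.append(f"({a}:{l1:.6f},{b}:{l2:.6f})")
    return parts[0]


def simulate_frame(cfg: WorldConfig, rng: np.random.Generator) -> HostFrame:
    """Random genus-clustered host tree + lineage table.

    Within-genus branch lengths are an order of magnitude shorter than
    backbone branches, so within-genus patristic distances are
    stochastically smaller than between-genus ones.
    """
    lo, hi = cfg.genomes_per_genus
    genus_trees, lineage_rows = [], []
    for gi in range(cfg.n_genera):
        genus = f"g{gi:03d}"
        n = int(rng.integers(lo, hi + 1))
        leaves = []
        for j in range(n):
            gid = f"G{gi:03d}_{j}"
            leaves.append(gid)
            lineage_rows.append(
                f"{gid}\td__Bacteria;p__P{gi % 7};c__C{gi % 7};o__O{gi % 11};"
                f"f__F{gi % 23};g__{genus};s__{genus} sp{j}")
        genus_trees.append(_random_join(leaves, rng, cfg.within_genus_bl))
    newick = _random_join(genus_trees, rng, cfg.backbone_bl) + ";"
    return HostFrame.from_strings(newick, "\n".join(lineage_rows))


# ---------------------------------------------------------------------------
# per-tool score samplers
# ---------------------------------------------------------------------------

def _blast_row(kind: str, rng) -> dict:
    if kind == "signal":
        n = 1 + int(rng.poisson(2.5))
        ident = float(rng.uniform(88, 99.5))
        lens = rng.uniform(800, 6000, size=n)
    elif kind == "sibling":
        n = 1 + int(rng.poisson(1.0))
        ident = float(rng.uniform(82, 93))
        lens = rng.uniform(600, 3000, size=n)
    else:
        n = 1 + int(rng.random() < 0.1)
        ident = float(rng.uniform(80, 88))
        lens = rng.uniform(500, 1500, size=n)
    return {"n_matches": n, "mean_identity": round(ident, 2),
            "total_aln_len": int(lens.sum())}


def _crispr_rows(kind: str, rng) -> dict:
    if kind == "signal":
        mm = int(rng.choice([0, 1, 2, 3], p=[0.45, 0.30, 0.15, 0.10]))
        ln = int(rng.integers(28, 46))
    elif kind == "sibling":
        mm = int(rng.integers(1, 5))
        ln = int(rng.integers(27, 42))
    else:
        mm = int(rng.integers(4, 8))
        ln = int(rng.integers(25, 41))
    return {"spacer_len": ln, "mismatches": mm,
            "strand": "+" if rng.random() < 0.5 else "-",
            "virus_pos": int(rng.integers(0, 1000))}


def _kmer_row(kind: str, rng) -> dict:
    if kind == "signal":
        nlp = float(rng.uniform(4, 10))
    elif kind == "sibling":
        nlp = float(rng.uniform(0.8, 5))
    else:
        nlp = float(rng.uniform(0.7, 1.5))
    return {"score": round(nlp, 4), "pvalue": float(10 ** -nlp)}


def _s2star_row(kind: str, rng) -> dict:
    if kind == "signal":
        s = rng.uniform(0.72, 0.95)
    elif kind == "sibling":
        s = rng.uniform(0.60, 0.85)
    else:
        s = rng.uniform(0.30, 0.68)
    return {"score": round(float(s), 4)}


def _php_row(kind: str, rng) -> dict:
    if kind == "signal":
        s = rng.normal(1500, 60)
    elif kind == "sibling":
        s = rng.normal(1380, 70)
    else:
        s = rng.normal(1150, 100)
    return {"score": round(float(max(s, 800.0)), 1)}


_SAMPLERS = {"blast": _blast_row, "crispr": _crispr_rows, "kmer_model": _kmer_row,
             "s2star_like": _s2star_row, "php_like": _php_row}

#: in noiseless mode, disjoint score ranges guarantee the signal hit always
#: outranks every background hit.
def _noiseless_override(tool: str, kind: str, rng) -> dict:
    if kind != "signal":
        return _SAMPLERS[tool](kind, rng)
    if tool == "blast":
        return {"n_matches": 5 + int(rng.poisson(2)),
                "mean_identity": round(float(rng.uniform(97, 100)), 2),
                "total_aln_len": int(rng.uniform(12000, 30000))}
    if tool == "crispr":
        return {"spacer_len": int(rng.integers(30, 46)), "mismatches": 0,
                "strand": "+", "virus_pos": int(rng.integers(0, 1000))}
    if tool == "kmer_model":
        nlp = float(rng.uniform(8, 12))
        return {"score": round(nlp, 4), "pvalue": float(10 ** -nlp)}
    if tool == "s2star_like":
        return {"score": round(float(rng.uniform(0.9, 0.99)), 4)}
    return {"score": round(float(rng.normal(1700, 20)), 1)}


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

def simulate_world(cfg: WorldConfig | None = None) -> World:
    """Generate a complete, seeded synthetic benchmark world."""
    cfg = cfg or WorldConfig()
    rng = np.random.default_rng(cfg.seed)
    frame = simulate_frame(cfg, rng)
    genomes = frame.genome_ids
    genus = frame.genus_series
    genera = sorted(genus.unique())

    noise_only = cfg.signal_mode == "noise_only"
    noiseless = cfg.signal_mode == "noiseless"
    profiles = NOISELESS_PROFILES if noiseless else cfg.profiles

    viruses = [f"v{i:04d}" for i in range(cfg.n_viruses)]
    truth_rows = []
    tool_rows: dict[str, list] = {t: [] for t in _SAMPLERS}
    phage_rows = []
    spacer_counter = 0

    for vid in viruses:
        true_genome = genomes[int(rng.integers(len(genomes)))]
        true_genus = genus[true_genome]
        known = bool(rng.random() < cfg.frac_known)
        truth_rows.append((vid, true_genome, true_genus, known))
        siblings = [g for g in frame.genomes_of_genus(true_genus) if g != true_genome]

        for tool, prof in profiles.items():
            sampler = (lambda k, t=tool: _noiseless_override(t, k, rng)) if noiseless \
                else (lambda k, t=tool: _SAMPLERS[t](k, rng))
            placed: dict[str, str] = {}
            if not noise_only:
                if rng.random() < prof.p_fire:
                    placed[true_genome] = "signal"
                for sib in siblings:
                    if rng.random() < prof.p_sibling:
                        placed[sib] = "sibling"
            n_bg = int(rng.poisson(prof.background_rate))
            for g in rng.choice(genomes, size=n_bg, replace=True):
                placed.setdefault(str(g), "background")
            for g in sorted(placed):
                kind = placed[g]
                row = sampler(kind)
                if tool == "crispr":
                    row["spacer_id"] = f"sp{spacer_counter:06d}"
                    spacer_counter += 1
                tool_rows[tool].append({"virus_id": vid, "genome_id": g, **row})

        # phage-based prediction
        if not noise_only and rng.random() < cfg.phage_p_predict:
            if noiseless or rng.random() < cfg.phage_p_correct:
                label_genus = true_genus
                score = float(rng.beta(6, 2)) if not noiseless else float(rng.uniform(0.95, 1.0))
            else:
                label_genus = genera[int(rng.integers(len(genera)))]
                score = float(rng.beta(2, 4))
            phage_rows.append((vid, f"L_{label_genus}", round(score, 4)))
        elif noise_only and rng.random() < cfg.phage_p_predict:
            label_genus = genera[int(rng.integers(len(genera)))]
            phage_rows.append((vid, f"L_{label_genus}", round(float(rng.beta(2, 4)), 4)))

    col_order = {
        "blast": ["virus_id", "genome_id", "n_matches", "mean_identity", "total_aln_len"],
        "crispr": ["virus_id", "genome_id", "spacer_id", "spacer_len",
                   "mismatches", "strand", "virus_pos"],
        "kmer_model": ["virus_id", "genome_id", "score", "pvalue"],
        "s2star_like": ["virus_id", "genome_id", "score"],
        "php_like": ["virus_id", "genome_id", "score"],
    }
    hit_tables = {t: pd.DataFrame(rows)[col_order[t]] if rows
                  else pd.DataFrame(columns=col_order[t])
                  for t, rows in tool_rows.items()}
    truth = pd.DataFrame(truth_rows, columns=["virus_id", "true_genome",
                                              "true_genus", "known"]).set_index("virus_id")
    phage = pd.DataFrame(phage_rows, columns=["virus_id", "predicted_label", "score"])
    # labels map back onto genera through a dominated genome tally
    label_tallies = {f"L_{g}": {g: 8, genera[(gi + 1) % len(genera)]: 1}
                     for gi, g in enumerate(genera)}
    return World(config=cfg, frame=frame, truth=truth, hit_tables=hit_tables,
                 phage_predictions=phage, label_tallies=label_tallies)


# ---------------------------------------------------------------------------
# sequence-level emulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceConfig:
    host_len: int = 4000
    virus_len: int = 1500
    spacers_per_host: int = 3
    spacer_len_range: tuple[int, int] = (8, 110)  # pre-filter draw range
    seed: int = 0


@dataclass
class SequenceWorld:
    host_seqs: dict
    virus_seqs: dict
    spacers: dict  # genome_id -> list of (spacer_id, seq)


_BASES = np.array(list("ACGT"))


def _biased_seq(rng, length: int, at_frac: float) -> str:
    p = np.array([at_frac / 2, (1 - at_frac) / 2, (1 - at_frac) / 2, at_frac / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def simulate_sequences(world: World, cfg: SequenceConfig | None = None) -> SequenceWorld:
    """Toy FASTA-level data consistent with the world's truth table.

    Host genomes carry a genus-specific AT bias which their viruses share;
    each virus donates exact substrings to its true host's spacer set.
    Spacers are drawn with lengths in a wide range and then filtered to
    [10, 100] nt, mirroring database-construction practice.
    """
    cfg = cfg or SequenceConfig()
    rng = np.random.default_rng(cfg.seed)
    frame = world.frame
    genera = sorted(frame.genus_series.unique())
    at = {g: float(rng.uniform(0.30, 0.70)) for g in genera}
    host_seqs = {gid: _biased_seq(rng, cfg.host_len, at[frame.genus_series[gid]])
                 for gid in frame.genome_ids}
    virus_seqs = {}
    spacers: dict[str, list] = {gid: [] for gid in frame.genome_ids}
    counter = 0
    for vid, row in world.truth.iterrows():
        virus_seqs[vid] = _biased_seq(rng, cfg.virus_len, at[row["true_genus"]])
        for _ in range(cfg.spacers_per_host):
            ln = int(rng.integers(*cfg.spacer_len_range))
            if not (10 <= ln <= 100):
                continue  # database-construction length filter
            if ln >= cfg.virus_len:
                continue
            start = int(rng.integers(0, cfg.virus_len - ln))
            spacers[row["true_genome"]].append(
                (f"seq_sp{counter:06d}", virus_seqs[vid][start:start + ln]))
            counter += 1
    return SequenceWorld(host_seqs=host_seqs, virus_seqs=virus_seqs, spacers=spacers)


# ---------------------------------------------------------------------------
# benchmark loop
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Recall/FDR of final predictions at the standard confidence cutoffs."""

    per_cutoff: pd.DataFrame      # cutoff, n_predictions, n_correct, recall, fdr
    method_counts: pd.DataFrame   # main_method counts at the default cutoff
    n_test_viruses: int

    def to_json(self) -> str:
        return json.dumps({
            "n_test_viruses": self.n_test_viruses,
            "per_cutoff": self.per_cutoff.to_dict(orient="records"),
            "method_counts": self.method_counts.to_dict(orient="records"),
        }, indent=2)

    def to_tsv(self, path) -> None:
        self.per_cutoff.to_csv(path, sep="\t", index=False)


def split_viruses(world: World, seed: int,
                  fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
                  ) -> tuple[list, list, list]:
    """Disjoint train/calibration/test virus sets (seeded shuffle)."""
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(world.truth.index))
    perm = rng.permutation(ids)
    n = len(perm)
    n_tr = int(round(fractions[0] * n))
    n_cal = int(round(fractions[1] * n))
    train = sorted(perm[:n_tr])
    cal = sorted(perm[n_tr:n_tr + n_cal])
    test = sorted(perm[n_tr + n_cal:])
    assert not (set(train) & set(cal)) and not (set(train) & set(test)) \
        and not (set(cal) & set(test))
    return train, cal, test


def _subset_tables(world: World, viruses) -> tuple[dict, pd.DataFrame]:
    vs = set(viruses)
    tables = {t: df[df["virus_id"].isin(vs)].reset_index(drop=True)
              for t, df in world.hit_tables.items()}
    phage = world.phage_predictions[
        world.phage_predictions["virus_id"].isin(vs)].reset_index(drop=True)
    return tables, phage


def run_benchmark(world: World, fit_config: FitConfig | None = None,
                  seed: int = 0, cutoffs: tuple[float, ...] = (75.0, 90.0, 95.0)
                  ) -> BenchmarkReport:
    """Full train -> calibrate -> predict loop with disjoint virus splits.

    Single-tool classifiers and the combined forest are trained on the
    training split, every calibration curve is fitted on the calibration
    split, and the report measures genus-level recall and FDR of the
    best-per-virus predictions on the test split at each cutoff.
    """
    fit_config = fit_config or FitConfig()
    train, cal, test = split_viruses(world, seed)
    min_cal = max(5, 1)
    if len(cal) < min_cal or len(train) < 10:
        raise ValueError("splits too small to fit calibration windows")
    model = HostPredictor(world.frame, world.hit_tables, truth=world.truth,
                          phage_predictions=world.phage_predictions,
                          label_tallies=world.label_tallies, config=fit_config)
    results = model.fit(seed=seed, train_viruses=train, calibration_viruses=cal)
    test_tables, test_phage = _subset_tables(world, test)
    summary, _ = results.predict(test_tables, test_phage, min_score=None)
    best = summary.groupby("virus_id", as_index=False).first() if len(summary) \
        else summary
    genus_truth = world.truth["true_genus"]
    rows = []
    default_cut = 90.0
    method_counts = pd.DataFrame(columns=["main_method", "n"])
    for cut in cutoffs:
        kept = best[best["confidence"] >= cut] if len(best) else best
        n_pred = len(kept)
        n_corr = int(sum(genus_truth[v] == g
                         for v, g in zip(kept["virus_id"], kept["host_genus"]))) \
            if n_pred else 0
        rows.append({"cutoff": cut, "n_predictions": n_pred, "n_correct": n_corr,
                     "recall": n_corr / len(test),
                     "fdr": (1 - n_corr / n_pred) if n_pred else float("nan")})
        if cut == default_cut and n_pred:
            method_counts = (kept.groupby("main_method").size()
                             .rename("n").reset_index())
    return BenchmarkReport(per_cutoff=pd.DataFrame(rows),
                           method_counts=method_counts,
                           n_test_viruses=len(test))


def pooled_benchmark(seeds, fit_config: FitConfig | None = None,
                     world_config: WorldConfig | None = None,
                     cutoff: float = 90.0) -> dict:
    """Run the default benchmark once per seed and pool test predictions.

    Returns pooled counts and the observed FDR (fraction of retained
    predictions whose genus is wrong) at ``cutoff``, plus per-seed reports.
    """
    base = world_config or WorldConfig()
    reports = []
    n_pred = n_corr = 0
    for seed in seeds:
        world = simulate_world(replace(base, seed=int(seed)))
        rep = run_benchmark(world, fit_config, seed=int(seed))
        reports.append(rep)
        row = rep.per_cutoff[rep.per_cutoff["cutoff"] == cutoff].iloc[0]
        n_pred += int(row["n_predictions"])
        n_corr += int(row["n_correct"])
    fdr = (1 - n_corr / n_pred) if n_pred else float("nan")
    return {"cutoff": cutoff, "n_predictions": n_pred, "n_correct": n_corr,
            "fdr": fdr, "reports": reports}
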