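"""Host reference frame: phylogeny, taxonomy, distance binning, label mapping.

The frame couples a rooted tree over host genome representatives with a
rank-complete lineage table (domain..species).  Genus is the prediction unit
throughout the package; phylogenetic (patristic) distances between genome
representatives are the geometry on which hit matrices are built.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_GTDB_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


class UnknownGenomeError(KeyError):
    """A genome id was not found among the tree leaves / lineage table."""


@dataclass(frozen=True)
class DistanceBinning:
    """Half-open distance bins [e_i, e_{i+1}); the last bin is open-ended.

    ``edges`` must start at 0 and be strictly ascending.  A distance at or
    beyond the last edge falls into the final (overflow) bin, so
    ``n_bins == len(edges)``.
    """

    edges: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 1 or e[0] != 0.0:
            raise ValueError("first edge must be 0")
        if np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly ascending")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    def bin(self, d: float) -> int:
        if d < 0:
            raise ValueError(f"distance must be non-negative, got {d}")
        return int(np.searchsorted(self.edges, d, side="right")) - 1

    def bin_array(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        return np.searchsorted(self.edges, d, side="right") - 1


def bin_distance(d: float, binning: DistanceBinning) -> int:
    """Index of the half-open bin containing patristic distance ``d``."""
    return binning.bin(d)


@dataclass(frozen=True)
class LabelMappingConfig:
    """Thresholds for mapping a phage-based tool's host label onto genera.

    A label is backed by a tally of reference genomes; a genus is accepted if
    it covers at least ``frac_small`` of the tally when the tally holds fewer
    than ``small_max`` genomes, ``frac_mid`` for ``small_max``..``mid_max``
    genomes (inclusive), and ``frac_large`` above that.
    """

    small_max: int = 10
    mid_max: int = 100
    frac_small: float = 0.50
    frac_mid: float = 0.20
    frac_large: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.frac_large <= self.frac_mid <= self.frac_small <= 1):
            raise ValueError("fractions must satisfy 0 < frac_large <= frac_mid <= frac_small <= 1")

    def threshold_for(self, total: int) -> float:
        if total < self.small_max:
            return self.frac_small
        if total <= self.mid_max:
            return self.frac_mid
        return self.frac_large


def map_label_to_genera(tally: Mapping[str, int], cfg: LabelMappingConfig | None = None) -> set[str]:
    """Genera covering enough of a label's genome tally to inherit the label.

    May return an empty set (no genus dominant enough) or several genera.
    """
    cfg = cfg or LabelMappingConfig()
    if not tally:
        raise ValueError("tally must be non-empty")
    if any(c < 1 for c in tally.values()):
        raise ValueError("tally counts must be >= 1")
    total = sum(tally.values())
    thr = cfg.threshold_for(total)
    return {g for g, c in tally.items() if c / total >= thr}


def _parse_lineage_string(s: str) -> list[str]:
    parts = [p.strip() for p in s.split(";")]
    if len(parts) != 7:
        raise ValueError(f"expected 7 ';'-separated ranks, got {len(parts)}: {s!r}")
    out = []
    for part, pref in zip(parts, _GTDB_PREFIXES):
        out.append(part[len(pref):] if part.startswith(pref) else part)
    return out


def read_lineage_table(path_or_buf) -> pd.DataFrame:
    """Read a lineage TSV in either accepted dialect.

    Dialect A: two columns, ``genome_id<TAB>d__...;p__...;...;s__...``
    (GTDB-style lineage string).  Dialect B: eight columns, genome_id plus the
    seven ranks.  A header row naming the ranks is tolerated in dialect B.
    """
    raw = pd.read_csv(path_or_buf, sep="\t", header=None, dtype=str)
    if raw.shape[1] == 2:
        rows = [_parse_lineage_string(s) for s in raw.iloc[:, 1]]
        df = pd.DataFrame(rows, columns=list(RANKS))
        df.insert(0, "genome_id", raw.iloc[:, 0].values)
    elif raw.shape[1] == 8:
        df = raw.copy()
        df.columns = ["genome_id", *RANKS]
        if str(df.iloc[0]["genus"]).lower() == "genus":  # header row
            df = df.iloc[1:].reset_index(drop=True)
    else:
        raise ValueError(f"lineage table must have 2 or 8 columns, got {raw.shape[1]}")
    return df.set_index("genome_id")


class HostFrame:
    """Rooted, branch-length tree over host genome representatives + lineages.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree whose leaf taxon labels are genome ids.
    lineage : pandas.DataFrame
        Indexed by genome_id with the seven rank columns; every tree leaf must
        appear exactly once and carry a non-empty genus.
    """

    def __init__(self, tree: dendropy.Tree, lineage: pd.DataFrame) -> None:
        self.tree = tree
        self.lineage = lineage
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf labels in tree")
        missing = set(leaves) - set(lineage.index)
        if missing:
            raise ValueError(f"leaves missing from lineage table: {sorted(missing)[:5]}")
        if lineage.index.has_duplicates:
            raise ValueError("duplicate genome ids in lineage table")
        for e in tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValueError("negative branch length in tree")
        bad = lineage.loc[leaves, "genus"].astype(str).str.len() == 0
        if bad.any():
            raise ValueError("empty genus for some genomes")
        self.genome_ids: list[str] = sorted(leaves)
        self._index = {g: i for i, g in enumerate(self.genome_ids)}
        self._dist: np.ndarray | None = None

    # -- construction -------------------------------------------------------
    @classmethod
    def from_files(cls, newick_path, lineage_path) -> "HostFrame":
        tree = dendropy.Tree.get(path=str(newick_path), schema="newick",
                                 preserve_underscores=True)
        return cls(tree, read_lineage_table(lineage_path))

    @classmethod
    def from_strings(cls, newick: str, lineage_tsv: str) -> "HostFrame":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree, read_lineage_table(io.StringIO(lineage_tsv)))

    # -- distances ----------------------------------------------------------
    @property
    def distance_matrix(self) -> np.ndarray:
        """Dense patristic distance matrix ordered like ``genome_ids``."""
        if self._dist is None:
            n = len(self.genome_ids)
            dist = np.zeros((n, n))
            pdm = self.tree.phylogenetic_distance_matrix()
            for t1, t2 in pdm.distinct_taxon_pair_iter():
                d = pdm.patristic_distance(t1, t2)
                i, j = self._index[t1.label], self._index[t2.label]
                dist[i, j] = dist[j, i] = d
            self._dist = dist
        return self._dist

    def index_of(self, genome_id: str) -> int:
        try:
            return self._index[genome_id]
        except KeyError:
            raise UnknownGenomeError(f"unknown genome id: {genome_id!r}") from None

    def patristic_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the unique path between leaves a and b."""
        i, j = self.index_of(a), self.index_of(b)
        return float(self.distance_matrix[i, j])

    # -- taxonomy -----------------------------------------------------------
    def genus_of(self, genome_id: str) -> str:
        if genome_id not in self.lineage.index:
            raise UnknownGenomeError(f"unknown genome id: {genome_id!r}")
        return str(self.lineage.at[genome_id, "genus"])

    @property
    def genus_series(self) -> pd.Series:
        return self.lineage.loc[self.genome_ids, "genus"].astype(str)

    def lineage_string(self, genome_id: str) -> str:
        if genome_id not in self.lineage.index:
            raise UnknownGenomeError(f"unknown genome id: {genome_id!r}")
        row = self.lineage.loc[genome_id]
        return ";".join(f"{p}{row[r]}" for p, r in zip(_GTDB_PREFIXES, RANKS))

    def genomes_of_genus(self, genus: str) -> list[str]:
        s = self.genus_series
        return [g for g in self.genome_ids if s[g] == genus]

    def genus_lineage_string(self, genus: str) -> str:
        """GTDB-style lineage string down to the genus rank."""
        members = self.genomes_of_genus(genus)
        if not members:
            raise UnknownGenomeError(f"unknown genus: {genus!r}")
        row = self.lineage.loc[members[0]]
        return ";".join(f"{p}{row[r]}" for p, r in zip(_GTDB_PREFIXES[:6], RANKS[:6]))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"HostFrame(n_genomes={len(self.genome_ids)}, "
                f"n_genera={self.genus_series.nunique()})")


def patristic_distance(frame: HostFrame, a: str, b: str) -> float:
    """Module-level convenience wrapper around :meth:`HostFrame.patristic_distance`."""
    return frame.patristic_distance(a, b)
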