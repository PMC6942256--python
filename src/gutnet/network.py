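"""Thresholded Pearson family-family co-abundance network and its null model.

Edges connect pairs of bacterial families whose relative-abundance profiles
across samples correlate with r strictly above ``r_min`` (default 0.3) and a
two-sided P-value strictly below ``p_max`` (default 1e-10).  The P-value is
the exact t-transform under bivariate normality:

    t = r * sqrt((n - 2) / (1 - r^2)),   p = 2 * P(T_{n-2} >= |t|).

The headline statistic is the intra-phylum edge fraction — the share of
edges whose endpoints belong to the same phylum — compared with its value in
a random graph on the same nodes with the same number of edges, for which
the analytic expectation under uniform edge placement is

    E[fraction] = sum_p C(n_p, 2) / C(N, 2)

over phylum sizes n_p.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .differential import AbundantFamilySet, DifferentialRecord, UNCHANGED
from .lineage import UNCLASSIFIED
from .table import AbundanceTable, RelativeAbundanceTable

DEFAULT_R_MIN = 0.3
DEFAULT_P_MAX = 1e-10
DEFAULT_MIN_PREVALENCE = 10


class ZeroVarianceError(ValueError):
    """A constant abundance vector cannot be correlation-tested."""


@dataclass(frozen=True)
class EdgeStat:
    """One tested family pair: Pearson r, two-sided P, sample count."""

    family_u: str
    family_v: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.family_u == self.family_v:
            raise ValueError(f"self-loop on {self.family_u!r}")
        if self.family_u > self.family_v:  # canonical unordered storage
            u, v = self.family_v, self.family_u
            object.__setattr__(self, "family_u", u)
            object.__setattr__(self, "family_v", v)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.family_u, self.family_v)


@dataclass
class NodeAttrs:
    """Family node annotations carried through network and subnetwork."""

    phylum: str
    mean_abundance: float
    direction: str | None = None
    healthy_mean: float | None = None


@dataclass
class CoAbundanceNetwork:
    """Family co-abundance graph with threshold provenance."""

    nodes: dict[str, NodeAttrs]
    edges: list[EdgeStat]
    r_min: float = DEFAULT_R_MIN
    p_max: float = DEFAULT_P_MAX

    def __post_init__(self) -> None:
        for e in self.edges:
            for endpoint in e.pair:
                if endpoint not in self.nodes:
                    raise ValueError(f"edge endpoint {endpoint!r} is not a node")
        self.edges = sorted(self.edges, key=lambda e: e.pair)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}

    def phylum_of(self, family: str) -> str:
        return self.nodes[family].phylum

    def nodes_per_phylum(self) -> pd.Series:
        counts = pd.Series([a.phylum for a in self.nodes.values()]).value_counts()
        return counts.sort_index()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for family, attrs in sorted(self.nodes.items()):
            data = {"phylum": attrs.phylum, "mean_abundance": attrs.mean_abundance}
            if attrs.direction is not None:
                data["direction_class"] = attrs.direction
            if attrs.healthy_mean is not None:
                data["healthy_mean_abundance"] = attrs.healthy_mean
            g.add_node(family, **data)
        for e in self.edges:
            g.add_edge(e.family_u, e.family_v, r=e.r, p=e.p, n=e.n)
        return g


@dataclass
class NullSummary:
    """Observed intra-phylum fraction against the uniform-random-edge null."""

    observed_fraction: float
    expected_fraction_analytic: float
    null_fractions: np.ndarray
    n_reps: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_fractions))


# ---------------------------------------------------------------------------
# Pearson statistic
# ---------------------------------------------------------------------------

def pearson_t_pvalue(r: float, n: int) -> float:
    """Two-sided P-value of Pearson r via the t-transform with n-2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


def pearson_edge(x, y) -> EdgeStat:
    """Pearson correlation test for one family pair.

    Raises :class:`ZeroVarianceError` for a constant input (such a pair is
    untestable and can never become an edge) and ``ValueError`` for length
    mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    xm = x - x.mean()
    ym = y - y.mean()
    sx = float(xm @ xm)
    sy = float(ym @ ym)
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("constant vector: correlation is undefined")
    r = float(np.clip((xm @ ym) / np.sqrt(sx * sy), -1.0, 1.0))
    return EdgeStat("x", "y", r, pearson_t_pvalue(r, n), n)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_network(table: RelativeAbundanceTable | AbundanceTable,
                  r_min: float = DEFAULT_R_MIN,
                  p_max: float = DEFAULT_P_MAX,
                  min_prevalence: int = DEFAULT_MIN_PREVALENCE,
                  include_unclassified: bool = False,
                  stratify_by_study: bool = False) -> CoAbundanceNetwork:
    """Build the family co-abundance network from a relative-abundance table.

    Families are node-eligible when present (> 0) in at least
    ``min_prevalence`` samples and, unless ``include_unclassified``, carry a
    named phylum and family label.  Edges require r strictly > ``r_min`` and
    P strictly < ``p_max``.  Constant (zero-variance) families are untestable
    and silently excluded from edges.

    ``stratify_by_study`` replaces the pooled r with the unweighted mean of
    per-study correlations (each study needs >= 3 samples); the P-value is
    then computed from the pooled sample count.
    """
    if isinstance(table, AbundanceTable):
        table = table.to_relative()
    fam = table.aggregate_to_rank("family")
    n_samples = fam.n_samples
    if n_samples < 3:
        raise ValueError(f"need at least 3 samples, got {n_samples}")

    eligible = []
    for taxon, lin in zip(fam.taxon_ids, fam.lineages):
        if not include_unclassified and (taxon == UNCLASSIFIED
                                         or lin.phylum == UNCLASSIFIED):
            continue
        prevalence = int((fam.values.loc[taxon] > 0).sum())
        if prevalence >= min_prevalence:
            eligible.append(taxon)
    if len(eligible) < 2:
        raise ValueError(f"fewer than 2 eligible families ({len(eligible)})")
    eligible = sorted(eligible)

    values = fam.values.loc[eligible].to_numpy()
    testable = values.std(axis=1) > 0
    nodes = {taxon: NodeAttrs(fam.lineage_of(taxon).phylum,
                              float(fam.values.loc[taxon].mean()))
             for taxon in eligible}

    if stratify_by_study:
        r_mat = _stratified_corr(fam, eligible)
    else:
        r_mat = np.corrcoef(values)
    edges: list[EdgeStat] = []
    for i, j in itertools.combinations(range(len(eligible)), 2):
        if not (testable[i] and testable[j]):
            continue
        r = float(np.clip(r_mat[i, j], -1.0, 1.0))
        if r <= r_min:
            continue
        p = pearson_t_pvalue(r, n_samples)
        if p < p_max:
            edges.append(EdgeStat(eligible[i], eligible[j], r, p, n_samples))
    return CoAbundanceNetwork(nodes, edges, r_min, p_max)


def _stratified_corr(fam: RelativeAbundanceTable, eligible: list[str]) -> np.ndarray:
    study_of = fam.metadata["study_id"]
    mats = []
    for study in sorted(study_of.unique()):
        cols = list(study_of.index[study_of == study])
        if len(cols) < 3:
            continue
        sub = fam.values.loc[eligible, cols].to_numpy()
        with np.errstate(invalid="ignore"):
            mats.append(np.corrcoef(sub))
    if not mats:
        raise ValueError("no study with >= 3 samples for stratified correlation")
    return np.nanmean(np.stack(mats), axis=0)


def intra_phylum_fraction(net: CoAbundanceNetwork) -> float:
    """Share of edges whose endpoint families belong to the same phylum."""
    if net.n_edges == 0:
        raise ValueError("intra-phylum fraction is undefined on an empty edge set")
    same = sum(net.phylum_of(e.family_u) == net.phylum_of(e.family_v)
               for e in net.edges)
    return same / net.n_edges


# ---------------------------------------------------------------------------
# Random-network null
# ---------------------------------------------------------------------------

def expected_intra_fraction(phyla: Sequence[str]) -> float:
    """Analytic intra-phylum fraction under uniform random edge placement."""
    n = len(phyla)
    total_pairs = comb(n, 2, exact=True)
    if total_pairs == 0:
        raise ValueError("need at least 2 nodes")
    sizes = pd.Series(list(phyla)).value_counts()
    intra = sum(comb(int(s), 2, exact=True) for s in sizes)
    return intra / total_pairs


def random_null(phyla: Sequence[str] | Mapping[str, str], n_edges: int,
                n_reps: int = 1000, seed: int = 0,
                observed_fraction: float = float("nan")) -> NullSummary:
    """Monte-Carlo + analytic null for the intra-phylum edge fraction.

    Each replicate places ``n_edges`` distinct edges uniformly at random on
    the given nodes (Erdos-Renyi G(n, m)) and records the intra-phylum
    fraction.
    """
    if isinstance(phyla, Mapping):
        phyla = [phyla[k] for k in sorted(phyla)]
    labels = np.asarray(list(phyla))
    n = labels.size
    total_pairs = comb(n, 2, exact=True)
    if n_edges < 1 or n_edges > total_pairs:
        raise ValueError(f"n_edges must be in [1, {total_pairs}], got {n_edges}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    iu, ju = np.triu_indices(n, 1)
    intra_pair = labels[iu] == labels[ju]
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_reps)
    for rep in range(n_reps):
        chosen = rng.choice(total_pairs, size=n_edges, replace=False)
        fractions[rep] = intra_pair[chosen].mean()
    return NullSummary(observed_fraction, expected_intra_fraction(labels),
                       fractions, n_reps, seed)


def network_null(net: CoAbundanceNetwork, n_reps: int = 1000,
                 seed: int = 0) -> NullSummary:
    """Null summary for an observed network (same nodes, same edge count)."""
    phyla = {f: a.phylum for f, a in net.nodes.items()}
    return random_null(phyla, net.n_edges, n_reps, seed,
                       observed_fraction=intra_phylum_fraction(net))


# ---------------------------------------------------------------------------
# Condition subnetwork (disease vs healthy)
# ---------------------------------------------------------------------------

def extract_condition_subnetwork(net: CoAbundanceNetwork,
                                 diff: Sequence[DifferentialRecord],
                                 abundant: Iterable[AbundantFamilySet],
                                 fold_threshold: float = 1.5,
                                 ) -> CoAbundanceNetwork:
    """Disease-vs-healthy subnetwork of the global co-abundance network.

    An edge is kept iff at least one endpoint belongs to the union of the
    most-abundant family sets AND at least one endpoint changed more than
    ``fold_threshold``-fold in either direction between the disease and the
    healthy condition.  Kept nodes are annotated with their direction class
    (for colouring) and their healthy-condition mean abundance (for sizing).

    The differential records are expected with the disease as condition_a
    and ``healthy`` as condition_b.
    """
    by_taxon = {r.taxon: r for r in diff}
    missing = sorted(set(net.nodes) - set(by_taxon))
    if missing:
        raise ValueError("families in network missing from differential table: "
                         f"{missing}")
    abundant_union: set[str] = set()
    for s in abundant:
        abundant_union |= set(s.families)

    def changed(family: str) -> bool:
        return by_taxon[family].fold > fold_threshold

    kept = [e for e in net.edges
            if (e.family_u in abundant_union or e.family_v in abundant_union)
            and (changed(e.family_u) or changed(e.family_v))]
    node_ids = sorted({f for e in kept for f in e.pair})
    nodes = {}
    for family in node_ids:
        rec = by_taxon[family]
        attrs = net.nodes[family]
        nodes[family] = NodeAttrs(attrs.phylum, attrs.mean_abundance,
                                  direction=rec.direction,
                                  healthy_mean=rec.mean_b)
    return CoAbundanceNetwork(nodes, kept, net.r_min, net.p_max)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def edge_dataframe(net: CoAbundanceNetwork) -> pd.DataFrame:
    rows = []
    for e in net.edges:
        pu, pv = net.phylum_of(e.family_u), net.phylum_of(e.family_v)
        rows.append({"family_u": e.family_u, "family_v": e.family_v,
                     "phylum_u": pu, "phylum_v": pv, "r": e.r, "p": e.p,
                     "n": e.n, "intra_phylum": pu == pv})
    columns = ["family_u", "family_v", "phylum_u", "phylum_v", "r", "p", "n",
               "intra_phylum"]
    return pd.DataFrame(rows, columns=columns)


def write_edge_tsv(net: CoAbundanceNetwork, path: str | Path,
                   header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        edge_dataframe(net).to_csv(fh, sep="\t", index=False)


def write_graphml(net: CoAbundanceNetwork, path: str | Path,
                  header_comment: str | None = None) -> None:
    """GraphML export readable by standard graph viewers."""
    path = Path(path)
    nx.write_graphml(net.to_networkx(), path)
    if header_comment:
        text = path.read_text(encoding="utf-8").splitlines(keepends=True)
        text.insert(1, f"<!-- {header_comment} -->\n")
        path.write_text("".join(text), encoding="utf-8")
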