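"""Model/Results front-ends over the network and differential stages.

These follow the familiar two-object pattern: a model is constructed from a
table plus tuning parameters, ``fit()`` does the computation, and the
returned results object carries the estimates, the null comparison and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import differential as da
from . import network as net
from .table import AbundanceTable, RelativeAbundanceTable


class CoAbundanceModel:
    """Thresholded Pearson co-abundance network model at family rank.

    Parameters
    ----------
    table : AbundanceTable or RelativeAbundanceTable
        Counts are normalised to relative abundance internally.
    r_min, p_max : float
        Strict edge thresholds on Pearson r and the two-sided P-value.
    min_prevalence : int
        Minimum number of samples a family must be present in.
    stratify_by_study : bool
        Use the mean of per-study correlations instead of pooled r.
    """

    def __init__(self, table: AbundanceTable | RelativeAbundanceTable, *,
                 r_min: float = net.DEFAULT_R_MIN,
                 p_max: float = net.DEFAULT_P_MAX,
                 min_prevalence: int = net.DEFAULT_MIN_PREVALENCE,
                 include_unclassified: bool = False,
                 stratify_by_study: bool = False) -> None:
        if not 0 <= r_min < 1:
            raise ValueError(f"r_min must be in [0, 1), got {r_min}")
        if not 0 < p_max <= 1:
            raise ValueError(f"p_max must be in (0, 1], got {p_max}")
        if min_prevalence < 0:
            raise ValueError("min_prevalence must be >= 0")
        self.table = table
        self.r_min = r_min
        self.p_max = p_max
        self.min_prevalence = min_prevalence
        self.include_unclassified = include_unclassified
        self.stratify_by_study = stratify_by_study

    @classmethod
    def from_counts(cls, table: AbundanceTable, **kwargs) -> "CoAbundanceModel":
        return cls(table, **kwargs)

    def fit(self, null_reps: int = 1000, seed: int = 0) -> "CoAbundanceResults":
        network = net.build_network(self.table, r_min=self.r_min,
                                    p_max=self.p_max,
                                    min_prevalence=self.min_prevalence,
                                    include_unclassified=self.include_unclassified,
                                    stratify_by_study=self.stratify_by_study)
        null = (net.network_null(network, n_reps=null_reps, seed=seed)
                if network.n_edges else None)
        return CoAbundanceResults(self, network, null)


@dataclass
class CoAbundanceResults:
    """Fitted co-abundance network plus its random-graph null comparison."""

    model: CoAbundanceModel
    network: net.CoAbundanceNetwork
    null: net.NullSummary | None

    @property
    def intra_phylum_fraction(self) -> float:
        return net.intra_phylum_fraction(self.network)

    @property
    def edges(self) -> pd.DataFrame:
        return net.edge_dataframe(self.network)

    def subnetwork(self, diff_results: "DifferentialResults",
                   abundant, fold_threshold: float = 1.5,
                   ) -> net.CoAbundanceNetwork:
        return net.extract_condition_subnetwork(self.network,
                                                diff_results.records, abundant,
                                                fold_threshold=fold_threshold)

    def summary(self) -> str:
        g = self.network
        lines = ["Co-abundance network", "=" * 21,
                 f"thresholds      r > {g.r_min}, P < {g.p_max}",
                 f"nodes           {g.n_nodes}",
                 f"edges           {g.n_edges}",
                 "", "Nodes per phylum:"]
        for phylum, count in g.nodes_per_phylum().items():
            lines.append(f"  {phylum:<20s} {count}")
        if self.null is not None:
            lines += ["",
                      f"intra-phylum edges (observed)        "
                      f"{100 * self.null.observed_fraction:.1f}%",
                      f"intra-phylum edges (random, analytic) "
                      f"{100 * self.null.expected_fraction_analytic:.1f}%",
                      f"intra-phylum edges (random, MC mean)  "
                      f"{100 * self.null.null_mean:.1f}%  "
                      f"({self.null.n_reps} reps, seed {self.null.seed})"]
        return "\n".join(lines)


class DifferentialAbundanceModel:
    """Fold-change classification of taxa between two conditions at a rank."""

    def __init__(self, table: AbundanceTable | RelativeAbundanceTable,
                 condition_a: str, condition_b: str, *, rank: str = "family",
                 fold_threshold: float = da.DEFAULT_FOLD_THRESHOLD,
                 pseudocount: float = da.DEFAULT_PSEUDOCOUNT,
                 central: str = "mean") -> None:
        if fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if isinstance(table, AbundanceTable):
            table = table.to_relative()
        self.table = table
        self.condition_a = condition_a
        self.condition_b = condition_b
        self.rank = rank
        self.fold_threshold = fold_threshold
        self.pseudocount = pseudocount
        self.central = central

    def fit(self) -> "DifferentialResults":
        records = da.differential_table(self.table, self.condition_a,
                                        self.condition_b, rank=self.rank,
                                        threshold=self.fold_threshold,
                                        pseudocount=self.pseudocount,
                                        central=self.central)
        return DifferentialResults(self, records)


@dataclass
class DifferentialResults:
    """Per-taxon fold changes with their three-way direction classes."""

    model: DifferentialAbundanceModel
    records: list[da.DifferentialRecord]

    @property
    def frame(self) -> pd.DataFrame:
        return da.records_frame(self.records)

    def changed(self) -> list[da.DifferentialRecord]:
        return [r for r in self.records if r.direction != da.UNCHANGED]

    def summary(self) -> str:
        m = self.model
        frame = self.frame
        n_up = (frame["direction"] == da.INCREASED_IN_A).sum()
        n_down = (frame["direction"] == da.INCREASED_IN_B).sum()
        lines = [f"Differential abundance ({m.condition_a} vs {m.condition_b}, "
                 f"rank {m.rank})",
                 f"fold threshold  > {m.fold_threshold} (strict), "
                 f"pseudocount {m.pseudocount}",
                 f"taxa            {len(frame)}",
                 f"increased in {m.condition_a:<8s} {n_up}",
                 f"increased in {m.condition_b:<8s} {n_down}",
                 f"unchanged       {len(frame) - n_up - n_down}", ""]
        changed = frame[frame["direction"] != da.UNCHANGED]
        if len(changed):
            lines.append(changed.to_string(index=False,
                                           float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
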