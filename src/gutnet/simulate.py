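"""Synthetic multi-study, multi-condition microbiome cohorts with ground truth.

The generative model mirrors the statistical structure the downstream
analysis assumes, without pretending to be an ecological simulator:

* one latent Gaussian factor per phylum per sample induces a correlation
  block among that phylum's families (``block_rho`` on the log scale);
* each family's log abundance is ``base_logmean + log(condition fold) +
  dispersion * (sqrt(rho) * phylum_factor + sqrt(1-rho) * noise)``;
* abundances are exponentiated, closed to proportions, and counts drawn
  multinomially at a per-sample depth uniform in ``depth_range`` — so every
  consumer is forced through normalisation, exactly as with real tables of
  heterogeneous sequencing depth.

Every dataset is accompanied by its :class:`GroundTruth` (which family pairs
share a latent factor, which families were fold-shifted in which condition),
so tests never re-derive the planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lineage import TaxonLineage, lineage_from_labels
from .table import AbundanceTable

DEFAULT_DEPTH_RANGE = (6936, 100972)  # per-sample read depth range emulated
DEFAULT_PHYLA = (("Firmicutes", 8), ("Bacteroidetes", 4),
                 ("Proteobacteria", 4), ("Actinobacteria", 4))

INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"


@dataclass
class SyntheticSpec:
    """Full parameterisation of one simulated cohort.

    ``phyla`` lists (phylum name, number of families); family names default
    to ``<phylum>_f<i>``.  ``base_logmeans`` (one per family, concatenated in
    phylum order) default to an even grid from +1 to -1 — roughly a 7-fold
    spread of expected relative abundance.  ``condition_effects`` maps
    condition -> family -> fold multiplier applied on the natural scale;
    samples are assigned round-robin to ``conditions``.
    """

    seed: int = 0
    n_studies: int = 3
    samples_per_study: int = 50
    phyla: tuple[tuple[str, int], ...] = DEFAULT_PHYLA
    block_rho: float = 0.8
    between_rho: float = 0.0
    base_logmeans: tuple[float, ...] | None = None
    dispersion: float = 0.35
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE
    condition_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    conditions: tuple[str, ...] | None = None
    family_names: tuple[str, ...] | None = None
    asv_split: bool = False
    max_asvs_per_family: int = 30

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies: must be >= 1")
        if self.samples_per_study < 1:
            raise ValueError("samples_per_study: must be >= 1")
        if not self.phyla or any(n < 1 for _, n in self.phyla):
            raise ValueError("phyla: need >= 1 family per phylum")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho: must be in [0, 1)")
        if not 0.0 <= self.between_rho < 1.0:
            raise ValueError("between_rho: must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion: must be >= 0")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range: need 1 <= min <= max")
        names = set(self.all_family_names())
        if self.base_logmeans is not None and len(self.base_logmeans) != len(names):
            raise ValueError("base_logmeans: one value per family required")
        for cond, effects in self.condition_effects.items():
            for fam, fold in effects.items():
                if fam not in names:
                    raise ValueError(f"condition_effects: unknown family {fam!r}")
                if fold <= 0:
                    raise ValueError(f"condition_effects: fold for {fam!r} "
                                     "must be > 0")

    # -- derived layout --------------------------------------------------
    def all_family_names(self) -> list[str]:
        if self.family_names is not None:
            return list(self.family_names)
        return [f"{phylum}_f{i + 1:02d}"
                for phylum, n in self.phyla for i in range(n)]

    def phylum_of_families(self) -> list[str]:
        return [phylum for phylum, n in self.phyla for _ in range(n)]

    def resolved_logmeans(self) -> np.ndarray:
        n = len(self.all_family_names())
        if self.base_logmeans is not None:
            return np.asarray(self.base_logmeans, dtype=float)
        return np.linspace(1.0, -1.0, n)

    def resolved_conditions(self) -> tuple[str, ...]:
        if self.conditions is not None:
            return self.conditions
        if self.condition_effects:
            return tuple(sorted(set(self.condition_effects) | {"healthy"}))
        return ("healthy",)

    def expected_proportions(self) -> pd.Series:
        """Softmax of the base log-means (the no-effect abundance target)."""
        w = np.exp(self.resolved_logmeans())
        return pd.Series(w / w.sum(), index=self.all_family_names())


@dataclass
class GroundTruth:
    """Planted structure emitted alongside every synthetic dataset."""

    planted_edges: frozenset[tuple[str, str]]
    planted_directions: dict[str, dict[str, str]]

    def direction(self, condition: str, family: str) -> str:
        return self.planted_directions.get(condition, {}).get(family, UNCHANGED)


def _ground_truth(spec: SyntheticSpec) -> GroundTruth:
    families = spec.all_family_names()
    phyla = spec.phylum_of_families()
    edges: set[tuple[str, str]] = set()
    if spec.block_rho > 0:
        for i in range(len(families)):
            for j in range(i + 1, len(families)):
                if phyla[i] == phyla[j]:
                    edges.add(tuple(sorted((families[i], families[j]))))
    directions: dict[str, dict[str, str]] = {}
    for cond in spec.resolved_conditions():
        effects = spec.condition_effects.get(cond, {})
        directions[cond] = {}
        for fam in families:
            fold = effects.get(fam, 1.0)
            if fold > 1:
                directions[cond][fam] = INCREASED
            elif fold < 1:
                directions[cond][fam] = DECREASED
            else:
                directions[cond][fam] = UNCHANGED
    return GroundTruth(frozenset(edges), directions)


def generate_dataset(spec: SyntheticSpec) -> tuple[AbundanceTable, GroundTruth]:
    """Draw one cohort from ``spec`` (deterministic given ``spec.seed``)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    families = spec.all_family_names()
    phyla = spec.phylum_of_families()
    phylum_names = [p for p, _ in spec.phyla]
    phylum_index = np.asarray([phylum_names.index(p) for p in phyla])
    n_fam = len(families)
    n_samples = spec.n_studies * spec.samples_per_study
    conditions = spec.resolved_conditions()

    study_ids = [f"S{k + 1:02d}" for k in range(spec.n_studies)
                 for _ in range(spec.samples_per_study)]
    sample_ids = [f"{study_ids[i]}.s{i + 1:04d}" for i in range(n_samples)]
    sample_conditions = [conditions[i % len(conditions)] for i in range(n_samples)]

    log_fold = np.zeros((n_samples, n_fam))
    for idx, cond in enumerate(sample_conditions):
        for fam, fold in spec.condition_effects.get(cond, {}).items():
            log_fold[idx, families.index(fam)] = np.log(fold)

    # fixed draw order => bit-reproducible output for a given seed
    global_factor = rng.standard_normal(n_samples)
    phylum_factors = rng.standard_normal((n_samples, len(phylum_names)))
    noise = rng.standard_normal((n_samples, n_fam))
    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1,
                          size=n_samples)

    if spec.between_rho > 0:
        phylum_factors = (np.sqrt(spec.between_rho) * global_factor[:, None]
                          + np.sqrt(1 - spec.between_rho) * phylum_factors)
    latent = (np.sqrt(spec.block_rho) * phylum_factors[:, phylum_index]
              + np.sqrt(1 - spec.block_rho) * noise)
    log_ab = spec.resolved_logmeans()[None, :] + log_fold + spec.dispersion * latent
    weights = np.exp(log_ab)
    props = weights / weights.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, n_fam), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(depths[i], props[i])

    lineages = [lineage_from_labels(kingdom="Bacteria", phylum=p, family=f)
                for p, f in zip(phyla, families)]
    matrix = pd.DataFrame(counts.T, index=pd.Index(families, name="taxon"),
                          columns=sample_ids)
    metadata = pd.DataFrame({"study_id": study_ids,
                             "condition": sample_conditions},
                            index=pd.Index(sample_ids, name="sample_id"))
    table = AbundanceTable(matrix, lineages, metadata)
    if spec.asv_split:
        table = _split_into_asvs(table, rng, spec.max_asvs_per_family)
    return table, _ground_truth(spec)


def _split_into_asvs(table: AbundanceTable, rng: np.random.Generator,
                     max_asvs: int) -> AbundanceTable:
    """Split each family row into 1-``max_asvs`` ASVs with Dirichlet weights."""
    rows = []
    ids = []
    lineages = []
    for family, lin in zip(table.taxon_ids, table.lineages):
        k = int(rng.integers(1, max_asvs + 1))
        weights = rng.dirichlet(np.ones(k))
        fam_counts = table.counts.loc[family].to_numpy()
        split = np.vstack([rng.multinomial(c, weights) for c in fam_counts]).T
        for a in range(k):
            ids.append(f"{family}_ASV{a + 1:02d}")
            lineages.append(TaxonLineage(*lin.labels,
                                         source_string=lin.source_string))
            rows.append(split[a])
    matrix = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="taxon"),
                          columns=table.sample_ids)
    keep = matrix.sum(axis=1) > 0  # drop all-zero ASVs from tiny splits
    matrix = matrix.loc[keep]
    lineages = [lin for lin, k in zip(lineages, keep) if k]
    return AbundanceTable(matrix, lineages, table.metadata.copy())


# ---------------------------------------------------------------------------
# IBD cohort preset
# ---------------------------------------------------------------------------

#: (family, phylum, base log-mean) for the 20-family IBD cohort preset.
IBD_FAMILIES = (
    ("Lachnospiraceae", "Firmicutes", 1.0),
    ("Ruminococcaceae", "Firmicutes", 0.9),
    ("Bacteroidaceae", "Bacteroidetes", 0.8),
    ("Prevotellaceae", "Bacteroidetes", 0.5),
    ("Bifidobacteriaceae", "Actinobacteria", 0.3),
    ("Veillonellaceae", "Firmicutes", 0.2),
    ("Rikenellaceae", "Bacteroidetes", 0.1),
    ("Streptococcaceae", "Firmicutes", 0.0),
    ("Coriobacteriaceae", "Actinobacteria", -0.1),
    ("Tannerellaceae", "Bacteroidetes", -0.2),
    ("Lactobacillaceae", "Firmicutes", -0.3),
    ("Christensenellaceae", "Firmicutes", -0.35),
    ("Erysipelotrichaceae", "Firmicutes", -0.4),
    ("Acidaminococcaceae", "Firmicutes", -0.45),
    ("Enterobacteriaceae", "Proteobacteria", -0.5),
    ("Burkholderiaceae", "Proteobacteria", -0.6),
    ("Pseudomonadaceae", "Proteobacteria", -0.7),
    ("Desulfovibrionaceae", "Proteobacteria", -0.8),
    ("Actinomycetaceae", "Actinobacteria", -0.9),
    ("Eggerthellaceae", "Actinobacteria", -1.0),
)

#: planted disease effects: Bacteroidaceae down 2.4-fold and
#: Enterobacteriaceae up 3.8-fold in CD; Enterobacteriaceae down 3.4-fold in UC.
IBD_EFFECTS = {
    "CD": {"Bacteroidaceae": 1 / 2.4, "Enterobacteriaceae": 3.8},
    "UC": {"Enterobacteriaceae": 1 / 3.4},
}


def ibd_cohort_spec(seed: int, n_per_condition: int) -> SyntheticSpec:
    """Three-condition (CD/UC/healthy) cohort spec over a 20-family base."""
    if n_per_condition < 2:
        raise ValueError("n_per_condition must be >= 2")
    order: dict[str, list[tuple[str, float]]] = {}
    for fam, phylum, base in IBD_FAMILIES:
        order.setdefault(phylum, []).append((fam, base))
    phyla = tuple((p, len(v)) for p, v in order.items())
    names = tuple(f for p, v in order.items() for f, _ in v)
    bases = tuple(b for p, v in order.items() for _, b in v)
    total = 3 * n_per_condition
    n_studies = 3 if total % 3 == 0 else 1
    return SyntheticSpec(seed=seed, n_studies=n_studies,
                         samples_per_study=total // n_studies,
                         phyla=phyla, family_names=names, base_logmeans=bases,
                         condition_effects={c: dict(v) for c, v in IBD_EFFECTS.items()},
                         conditions=("CD", "UC", "healthy"))


def generate_ibd_cohort(seed: int, n_per_condition: int,
                        ) -> tuple[AbundanceTable, GroundTruth]:
    """Simulated CD/UC/healthy cohort with the preset planted fold shifts."""
    return generate_dataset(ibd_cohort_spec(seed, n_per_condition))


# ---------------------------------------------------------------------------
# Ground-truth persistence
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, directory: str | Path,
                       header_comment: str | None = None) -> None:
    """Write planted edges and directions as TSVs next to the dataset."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = f"# {header_comment}\n" if header_comment else ""
    with open(directory / "planted_edges.tsv", "w", encoding="utf-8") as fh:
        fh.write(prefix + "family_u\tfamily_v\n")
        for u, v in sorted(truth.planted_edges):
            fh.write(f"{u}\t{v}\n")
    with open(directory / "planted_directions.tsv", "w", encoding="utf-8") as fh:
        fh.write(prefix + "condition\tfamily\tdirection\n")
        for cond in sorted(truth.planted_directions):
            for fam in sorted(truth.planted_directions[cond]):
                fh.write(f"{cond}\t{fam}\t{truth.planted_directions[cond][fam]}\n")


def read_ground_truth(directory: str | Path) -> GroundTruth:
    directory = Path(directory)
    edges = pd.read_csv(directory / "planted_edges.tsv", sep="\t", comment="#")
    dirs = pd.read_csv(directory / "planted_directions.tsv", sep="\t", comment="#")
    planted = frozenset(tuple(sorted((u, v)))
                        for u, v in zip(edges["family_u"], edges["family_v"]))
    directions: dict[str, dict[str, str]] = {}
    for _, row in dirs.iterrows():
        directions.setdefault(row["condition"], {})[row["family"]] = row["direction"]
    return GroundTruth(planted, directions)
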