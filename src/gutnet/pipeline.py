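"""End-to-end pipeline: table -> diversity, differential tables, network,
null summary, condition subnetworks, text report.

Every output file carries a header comment with the tool version, a hash of
the configuration and the seed, so any artefact can be traced back to the
exact run that produced it.  No timestamps are written: identical
configuration and seed reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from . import differential as da
from . import diversity as dv
from . import network as net
from .model import CoAbundanceModel, DifferentialAbundanceModel
from .table import AbundanceTable, parse_abundance_table, parse_metadata

log = logging.getLogger("gutnet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run."""

    abundance_path: str
    metadata_path: str | None = None
    dialect: str = "prefix"
    rank: str = "family"
    conditions: tuple[str, ...] = ("CD", "UC")
    reference_condition: str = "healthy"
    r_min: float = net.DEFAULT_R_MIN
    p_max: float = net.DEFAULT_P_MAX
    min_prevalence: int = net.DEFAULT_MIN_PREVALENCE
    fold_threshold: float = da.DEFAULT_FOLD_THRESHOLD
    top_k: int = da.DEFAULT_TOP_K
    null_reps: int = 1000
    seed: int = 0
    output_dir: str = "gutnet_out"

    def validate(self) -> None:
        if not 0 <= self.r_min < 1:
            raise ValueError(f"r_min must be in [0, 1), got {self.r_min}")
        if not 0 < self.p_max <= 1:
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.min_prevalence < 0:
            raise ValueError("min_prevalence must be >= 0")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.null_reps < 1:
            raise ValueError("null_reps must be >= 1")
        if self.dialect not in ("prefix", "silva", "plain"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    def config_hash(self) -> str:
        fields = asdict(self)
        fields.pop("output_dir")  # where outputs land does not alter them
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return (f"gutnet {__version__} | config {self.config_hash()} | "
                f"seed {self.seed}")


def run_pipeline(config: PipelineConfig,
                 table: AbundanceTable | None = None) -> dict[str, Path]:
    """Run every stage; return a name -> path map of the written artefacts.

    ``table`` may be passed directly (e.g. a simulated cohort) to skip the
    parse stage.  Any stage failure removes the partial outputs and raises
    :class:`PipelineError` naming the stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header()
    written: dict[str, Path] = {}
    stage = "setup"

    def emit(name: str, filename: str, writer) -> None:
        path = outdir / filename
        writer(path)
        written[name] = path

    t0 = time.perf_counter()
    try:
        if table is None:
            stage = "parse"
            metadata = (parse_metadata(config.metadata_path)
                        if config.metadata_path else None)
            table = parse_abundance_table(config.abundance_path,
                                          dialect=config.dialect,
                                          metadata=metadata)
        log.info("stage parse: %d taxa x %d samples", table.n_taxa,
                 table.n_samples)

        stage = "diversity"
        diversity = dv.sample_diversity(table)
        emit("diversity", "diversity.tsv",
             lambda p: _write_frame(diversity, p, header))
        log.info("stage diversity done (%.2fs)", time.perf_counter() - t0)

        stage = "differential"
        rel = table.to_relative()
        diff_results = {}
        for cond in config.conditions:
            model = DifferentialAbundanceModel(
                rel, cond, config.reference_condition, rank=config.rank,
                fold_threshold=config.fold_threshold)
            res = model.fit()
            diff_results[cond] = res
            emit(f"differential_{cond}",
                 f"differential_{cond}_vs_{config.reference_condition}.tsv",
                 lambda p, r=res: da.write_differential_tsv(r.records, p, header))
        log.info("stage differential done (%.2fs)", time.perf_counter() - t0)

        stage = "network"
        cam = CoAbundanceModel(rel, r_min=config.r_min, p_max=config.p_max,
                               min_prevalence=config.min_prevalence)
        cores = cam.fit(null_reps=config.null_reps, seed=config.seed)
        emit("network_graphml", "network.graphml",
             lambda p: net.write_graphml(cores.network, p, header))
        emit("network_edges", "network_edges.tsv",
             lambda p: net.write_edge_tsv(cores.network, p, header))
        if cores.null is not None:
            emit("null_summary", "null_summary.tsv",
                 lambda p: _write_null(cores.null, p, header))
        log.info("stage network done: %d nodes, %d edges (%.2fs)",
                 cores.network.n_nodes, cores.network.n_edges,
                 time.perf_counter() - t0)

        stage = "subnetwork"
        for cond in config.conditions:
            abundant = [da.top_abundant_families(rel, c, k=config.top_k)
                        for c in (cond, config.reference_condition)]
            sub = cores.subnetwork(diff_results[cond], abundant,
                                   fold_threshold=config.fold_threshold)
            emit(f"subnetwork_{cond}", f"subnetwork_{cond}.graphml",
                 lambda p, s=sub: net.write_graphml(s, p, header))
        log.info("stage subnetwork done (%.2fs)", time.perf_counter() - t0)

        stage = "report"
        emit("summary", "summary.txt",
             lambda p: p.write_text(_report(config, cores, diff_results) + "\n",
                                    encoding="utf-8"))
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return written


def _write_frame(frame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        frame.to_csv(fh, sep="\t", index=False)


def _write_null(null: net.NullSummary, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        fh.write("observed_fraction\texpected_fraction_analytic\t"
                 "null_mean\tnull_sd\tn_reps\tseed\n")
        fh.write(f"{null.observed_fraction:.6f}\t"
                 f"{null.expected_fraction_analytic:.6f}\t"
                 f"{null.null_mean:.6f}\t{null.null_fractions.std():.6f}\t"
                 f"{null.n_reps}\t{null.seed}\n")


def _report(config: PipelineConfig, cores, diff_results) -> str:
    lines = [f"# {config.header()}", "", cores.summary(), ""]
    for cond, res in diff_results.items():
        lines += [res.summary(), ""]
    return "\n".join(lines)
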