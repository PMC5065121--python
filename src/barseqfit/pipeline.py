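"""End-to-end reproducible pipeline: simulate → count → fit → classify.

Every stage writes its outputs as header-stamped TSVs under one output
directory; re-running the same configuration produces byte-identical files.
The simulated reads path (FASTQ emission + demultiplex + exact-match
counting) and the direct counts path are interchangeable by construction:
all sampling noise enters at the multinomial sequencing draw, and read
generation/counting are exact inverses.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from . import __version__, io
from .counting import count_sample, parse_fastq
from .dfe import dfe_summary
from .evocatalog import (
    per_sample_driver_stats,
    predict_drivers,
    validate_catalog as validate_eset,
)
from .fitness import counts_to_fitness
from .pool import (
    CompetitionDesign,
    DfeMixture,
    build_pool,
    generate_reads,
    make_tag_map,
    simulate_counts,
    write_fastq,
)

logger = logging.getLogger("barseqfit")

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of one full run."""

    outdir: str = "barseqfit_run"
    seed: int = 0
    n_strains: int = 2000
    n_control: int = 500
    collection: str = "haploid_deletion"
    condition: str = "glucose"
    timepoints: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18, 20)
    replicates: int = 2
    depth_per_strain: float = 462.0
    neutral: float = 0.90
    beneficial: float = 0.05
    deleterious: float = 0.05
    pseudocount: float = 10
    window: tuple[int, int] = (6, 20)
    min_total: int = 20
    cutoffs: tuple[float, ...] = (0.10, 0.05)
    include_t0: bool = False
    center_on_control: bool = False
    strict_drivers: bool = False
    use_reads: bool = False
    noise: bool = True
    eset_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("timepoints", "window", "cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def meta(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns a dict of output paths and key frames."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.meta()
    artifacts: dict = {"outdir": out}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        mixture = DfeMixture(
            neutral=config.neutral,
            beneficial=config.beneficial,
            deleterious=config.deleterious,
        )
        catalog, _ = build_pool(
            config.n_strains,
            mixture,
            n_control=config.n_control,
            seed=config.seed,
            collection=config.collection,
        )
        design = CompetitionDesign(
            condition=config.condition,
            timepoints=config.timepoints,
            replicates=config.replicates,
            depth_per_strain=config.depth_per_strain,
            seed=config.seed + 1,
        )
        counts, truth = simulate_counts(catalog, design, noise=config.noise)
        io.write_catalog(catalog, out / "catalog.tsv", meta)
        io.write_table(truth.to_frame(), out / "truth.tsv", meta)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("count")
        report = [f"reads_per_sample_expected\t{design.total_depth(len(catalog))}"]
        if config.use_reads:
            tag_map = make_tag_map(design)
            fastq = out / "reads.fastq"
            total = 0
            for i, (sample, tag) in enumerate(tag_map.items()):
                per_strain = dict(zip(counts.index, counts[sample].astype(int)))
                total += write_fastq(
                    generate_reads(per_strain, catalog, tag), fastq, append=i > 0
                )
            recounted, accounting, unmatched = count_sample(
                parse_fastq(fastq), catalog, tag_map
            )
            counts = recounted[counts.columns]
            report.append(f"reads_total\t{total}")
            report.append(f"unmatched_tags\t{unmatched}")
            for sample, acc in accounting.items():
                report.append(
                    f"sample\t{sample}\tdemux={acc.demultiplexed}"
                    f"\tassigned={acc.assigned}\tunassigned={acc.unassigned}"
                    f"\tambiguous={acc.ambiguous}"
                )
        io.write_counts(counts, out / "counts.tsv", meta)
        (out / "run_report.txt").write_text(
            "\n".join([f"# barseqfit {__version__}"] + report) + "\n"
        )
        artifacts["counts"] = counts
    except Exception as exc:
        raise RuntimeError(f"stage 'count' failed: {exc}") from exc

    try:
        stage("fit")
        fitness = counts_to_fitness(
            counts,
            pseudocount=config.pseudocount,
            window=config.window,
            min_total=config.min_total,
            include_t0=config.include_t0,
        )
        ann = {st.strain_id: (st.gene, st.collection) for st in catalog}
        fitness.insert(0, "gene", [ann[s][0] for s in fitness.index])
        fitness.insert(1, "collection", [ann[s][1] for s in fitness.index])
        if config.center_on_control:
            # remove the common population-mean term using the neutral
            # control collection's median, per condition
            is_ctrl = fitness["collection"] == "control"
            num = [c for c in fitness.columns if c.startswith("rep") or c == "mean_fitness"]
            for cond in fitness["condition"].unique():
                sel = fitness["condition"] == cond
                med = fitness.loc[sel & is_ctrl, "mean_fitness"].median()
                if med == med:  # controls present
                    fitness.loc[sel, num] = fitness.loc[sel, num] - med
        io.write_table(fitness, out / "fitness.tsv", meta)
        artifacts["fitness"] = fitness
        artifacts["truth"] = truth
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc

    try:
        stage("classify")
        control_ids = [st.strain_id for st in catalog if st.collection == "control"]
        summary = dfe_summary(fitness, control_ids, cutoffs=config.cutoffs)
        artifacts["dfe"] = summary
        payload = {
            "cutoffs": summary.cutoffs,
            "class_counts": {str(k): v for k, v in summary.class_counts.items()},
            "class_counts_dedup": {
                str(k): v for k, v in summary.class_counts_dedup.items()
            },
            "overlap": {str(k): v for k, v in summary.overlap.items()},
            "control_fraction": summary.control_fraction,
            "enrichment": {
                str(k): {d: list(t) for d, t in v.items()}
                for k, v in summary.enrichment.items()
            },
        }
        (out / "dfe_summary.json").write_text(json.dumps(payload, indent=2) + "\n")
        primary = config.cutoffs[0]
        beneficial = fitness[
            (~fitness.index.isin(control_ids))
            & (fitness["mean_fitness"] > primary)
        ][["gene", "collection", "condition", "mean_fitness"]]
        io.write_table(beneficial, out / "beneficial_strains.tsv", meta)
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    if config.eset_path:
        try:
            stage("drivers")
            eset = validate_eset(io.read_table(config.eset_path, index_col=None))
            annotated = predict_drivers(
                eset, fitness, cutoff=config.cutoffs[0], strict=config.strict_drivers
            )
            per_sample, stats = per_sample_driver_stats(annotated)
            io.write_table(annotated, out / "eset_annotated.tsv", meta, index=False)
            io.write_table(per_sample, out / "driver_stats.tsv", meta)
            (out / "driver_summary.json").write_text(
                json.dumps(stats, indent=2, default=float) + "\n"
            )
            artifacts["drivers"] = stats
        except Exception as exc:
            raise RuntimeError(f"stage 'drivers' failed: {exc}") from exc
    else:
        logger.info("no E-set catalog given; driver stage skipped")

    return artifacts
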