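"""End-to-end orchestration: one config in, the full table set out.

``run_pipeline`` reads an aligned FASTA (plus optional metadata TSV),
clusters OTUs, and writes the complete report bundle:

* ``diversity_summary.tsv`` — per-OTU composition, site/event counts,
  mean pairwise differences, theta estimators and haplotype structure;
* ``theta.tsv`` — population, n, S, theta_S, theta_pi;
* ``fst.tsv`` / ``fst_long.tsv`` — pairwise Fst (lower triangle) and a
  long table with both estimators, p-values and significance flags;
* ``country_haplotypes.tsv`` — per-country haplotype counts on a seeded
  subsample (when metadata are provided);
* ``nei_within_between_net.tsv`` — within on the diagonal, between above,
  net (dA) below;
* ``tree.nwk`` — NJ tree on K2P distances with bootstrap support;
* ``otus.tsv`` / ``haplotypes.tsv`` — id-to-group assignments;
* ``run_log.txt`` — seed, versions and every clamped/flagged event.

Given the same inputs and config, reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream_int
from .differentiation import fst_permutation_test, pairwise_fst
from .distances import population_distances
from .errors import ItsDivError, ComputationError, ParameterError
from .partitions import cluster_otus, collapse_haplotypes, country_haplotype_table
from .phylo import bootstrap_support
from .seq_io import (
    read_alignment,
    read_samples,
    write_newick,
    write_table,
)
from .site_stats import summarize_populations

logger = logging.getLogger(__name__)

DEFAULT_SWEEP = (100.0, 99.5, 99.0, 98.5, 98.0)
SIGNIFICANCE_LEVEL = 0.05


@dataclass
class RunConfig:
    """Plain-text-serialisable run configuration."""

    alignment: str
    out_dir: str
    samples: str | None = None
    otu_threshold: float | None = None
    sweep: tuple[float, ...] = ()
    linkage: str = "single"
    estimator: str = "nei_ratio"
    n_bootstrap: int = 1000
    n_permutations: int = 110
    seed: int = 20120427
    min_country_isolates: int = 4
    country_subsample: int = 4
    strip_all_gap_columns: bool = True

    def __post_init__(self) -> None:
        self.sweep = tuple(float(t) for t in self.sweep)
        if self.otu_threshold is not None:
            self.otu_threshold = float(self.otu_threshold)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["sweep"] = list(self.sweep)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class _StageError(ComputationError):
    pass


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ItsDivError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
        except Exception as exc:  # pragma: no cover - defensive
            raise _StageError(f"[stage {name}] {exc}") from exc
    return wrap


def _partition_frame(partition) -> pd.DataFrame:
    labels = partition.labels
    return pd.DataFrame(
        {"isolate_id": list(labels), "group": [labels[s] for s in labels]}
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a mapping from logical output name to file path.
    """
    if config.otu_threshold is None:
        raise ParameterError(
            "otu_threshold is required (no silent default); pass a percent "
            "similarity cut-off, optionally together with a sweep list"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    records: list[str] = []

    class _Collector(logging.Handler):
        def emit(self, record):
            records.append(f"{record.name}: {record.getMessage()}")

    collector = _Collector(level=logging.INFO)
    root = logging.getLogger("itsdiv")
    old_level = root.level
    root.addHandler(collector)
    root.setLevel(logging.INFO)
    try:
        aln = _stage("read_alignment")(
            read_alignment, config.alignment,
            strip_all_gap_columns=config.strip_all_gap_columns,
        )
        samples = None
        if config.samples:
            samples = _stage("read_samples")(read_samples, config.samples, aln)

        otus = _stage("cluster_otus")(
            cluster_otus, aln, config.otu_threshold, method=config.linkage
        )
        df = _partition_frame(otus)
        df.columns = ["isolate_id", "otu"]
        outputs["otus"] = out / "otus.tsv"
        write_table(df, outputs["otus"])
        for t in config.sweep:
            part_t = _stage("cluster_otus_sweep")(
                cluster_otus, aln, t, method=config.linkage
            )
            dft = _partition_frame(part_t)
            dft.columns = ["isolate_id", "otu"]
            path_t = out / f"otus_{t:g}.tsv"
            outputs[f"otus_{t:g}"] = path_t
            write_table(dft, path_t)
            records.append(
                f"itsdiv.pipeline: sweep threshold {t:g} -> "
                f"{len(part_t.groups)} OTUs"
            )

        haps = _stage("collapse_haplotypes")(collapse_haplotypes, aln)
        dfh = _partition_frame(haps)
        dfh.columns = ["isolate_id", "haplotype"]
        outputs["haplotypes"] = out / "haplotypes.tsv"
        write_table(dfh, outputs["haplotypes"])

        summary = _stage("diversity_summary")(summarize_populations, aln, otus)
        outputs["diversity_summary"] = out / "diversity_summary.tsv"
        write_table(summary, outputs["diversity_summary"])

        theta = summary[
            ["population", "n", "n_polymorphic_sites", "theta_S", "theta_pi"]
        ].rename(columns={"n_polymorphic_sites": "S"})
        outputs["theta"] = out / "theta.tsv"
        write_table(theta, outputs["theta"])

        nei = _stage("population_distances")(population_distances, aln, otus)
        outputs["nei"] = out / "nei_within_between_net.tsv"
        write_table(nei.to_dataframe(), outputs["nei"], index=True)

        fst_main = _stage("fst_permutation_test")(
            fst_permutation_test, aln, otus,
            n_permutations=config.n_permutations,
            seed=substream_int(config.seed, "permutation"),
            estimator=config.estimator,
        )
        other = "amova" if config.estimator == "nei_ratio" else "nei_ratio"
        fst_other = _stage("pairwise_fst")(pairwise_fst, aln, otus, other)

        pops = list(fst_main.populations)
        tri = pd.DataFrame("", index=pops, columns=pops, dtype=object)
        for i, a in enumerate(pops):
            tri.loc[a, pops[i]] = "0.00"
            for j in range(i):
                tri.loc[a, pops[j]] = f"{fst_main.fst[i, j]:.2f}"
        outputs["fst"] = out / "fst.tsv"
        write_table(tri, outputs["fst"], index=True)

        long_rows = []
        for i, a in enumerate(pops):
            for j in range(i + 1, len(pops)):
                b = pops[j]
                nei_v = fst_main.fst[i, j] if config.estimator == "nei_ratio" else fst_other.fst[i, j]
                amova_v = fst_main.fst[i, j] if config.estimator == "amova" else fst_other.fst[i, j]
                p = fst_main.p_values[i, j]
                if abs(nei_v - amova_v) > 0.01:
                    records.append(
                        f"itsdiv.pipeline: estimators differ by "
                        f"{abs(nei_v - amova_v):.3f} for {a} vs {b}"
                    )
                long_rows.append({
                    "pop_a": a, "pop_b": b,
                    "fst_nei": nei_v, "fst_amova": amova_v,
                    "fst_raw": fst_main.fst_raw[i, j],
                    "p_value": p,
                    "significant": bool(p <= SIGNIFICANCE_LEVEL),
                })
        outputs["fst_long"] = out / "fst_long.tsv"
        write_table(pd.DataFrame(long_rows), outputs["fst_long"])

        if len(aln) >= 3:
            tree = _stage("bootstrap_support")(
                bootstrap_support, aln,
                replicates=config.n_bootstrap,
                seed=substream_int(config.seed, "bootstrap"),
            )
            outputs["tree"] = out / "tree.nwk"
            _stage("write_newick")(write_newick, tree, outputs["tree"])
        else:
            records.append("itsdiv.pipeline: fewer than 3 sequences, no tree built")

        if samples is not None:
            table, _ = _stage("country_haplotype_table")(
                country_haplotype_table, aln, samples,
                min_isolates=config.min_country_isolates,
                subsample_to=config.country_subsample,
                seed=substream_int(config.seed, "subsample"),
            )
            if len(table):
                wide = table.pivot(index=["haplotype", "representative"],
                                   columns="country", values="count")
                rel = table.pivot(index=["haplotype", "representative"],
                                  columns="country", values="rel_freq")
                formatted = wide.astype(int).astype(str) + " (" + rel.map(lambda v: f"{v:.2f}") + ")"
                formatted = formatted.reset_index()
                formatted = formatted.sort_values(
                    "haplotype", key=lambda s: s.str.lstrip("H").astype(int)
                ).reset_index(drop=True)
                formatted.columns.name = None
                outputs["country_haplotypes"] = out / "country_haplotypes.tsv"
                write_table(formatted, outputs["country_haplotypes"])
            else:
                records.append(
                    "itsdiv.pipeline: no country met the minimum isolate count"
                )
    finally:
        root.removeHandler(collector)
        root.setLevel(old_level)

    log_lines = [
        f"itsdiv {__version__}",
        f"numpy {np.__version__}",
        f"pandas {pd.__version__}",
        f"seed {config.seed}",
        "config:",
    ]
    for key, value in asdict(config).items():
        log_lines.append(f"  {key}: {value}")
    log_lines.append("events:")
    log_lines.extend(f"  {r}" for r in records)
    outputs["run_log"] = out / "run_log.txt"
    outputs["run_log"].write_text("\n".join(log_lines) + "\n")
    return outputs
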