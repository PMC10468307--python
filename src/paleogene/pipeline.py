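"""Configuration-driven orchestration of the full analysis.

Stages: presence calling from the hit table → clade status and emergence
dating on the timetree → warming-period detection on the temperature series →
association summaries.  A run writes five artifacts into its output
directory: ``estimates.tsv`` (per gene), ``lwps.tsv``, ``summary.tsv`` (the
per-node histogram plus window and overlap tallies), ``overlay.png`` and a
machine-readable ``manifest.json`` recording every tunable parameter, input
path and version, so two runs with equal manifests produce equal outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    GeneSet,
    emergence_histogram,
    export_overlay,
    lwp_overlap,
    window_count,
)
from .clade_inference import (
    CladeRuleConfig,
    date_all_genes,
    estimates_to_frame,
)
from .paleotemp import (
    LwpConfig,
    detect_lwps,
    intervals_to_frame,
    read_temperature,
)
from .presence import (
    ThresholdConfig,
    call_presence,
    parse_hit_table,
    read_species_map,
    read_subject_lengths,
)
from .synthetic import (
    DEFAULT_N_GENES,
    DEFAULT_N_LEAVES,
    DEFAULT_OLDEST,
    DEFAULT_ROOT_AGE,
    ExcursionSpec,
    simulate_gene_histories,
    simulate_hit_table,
    simulate_temperature,
    simulate_tree,
)
from .timetree import read_age_ranges, read_timetree

__all__ = ["RunConfig", "PipelineError", "run", "simulate_bundle"]

log = logging.getLogger("paleogene")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class RunConfig:
    """Everything a run needs: input paths, thresholds, windows, seed."""

    tree: Path
    hits: Path
    species_map: Path
    temperature: Path
    gene_sets: Path
    out_dir: Path
    subject_lengths: Path | None = None
    age_ranges: Path | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    clade_rule: CladeRuleConfig = field(default_factory=CladeRuleConfig)
    lwp: LwpConfig = field(default_factory=LwpConfig)
    #: analysis windows in MYA, youngest bound first
    windows: tuple[tuple[float, float], ...] = ((0.0, 10.0), (0.0, 13.0))
    use_ranges: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})

        def p(key, required=True):
            if key not in raw or raw[key] is None:
                if required:
                    raise PipelineError(f"config: missing required path {key!r}")
                return None
            q = Path(raw[key])
            return q if q.is_absolute() else base / q

        return cls(
            tree=p("tree"),
            hits=p("hits"),
            species_map=p("species_map"),
            temperature=p("temperature"),
            gene_sets=p("gene_sets"),
            out_dir=p("out_dir"),
            subject_lengths=p("subject_lengths", required=False),
            age_ranges=p("age_ranges", required=False),
            thresholds=ThresholdConfig(**raw.get("thresholds", {})),
            clade_rule=CladeRuleConfig(**raw.get("clade_rule", {})),
            lwp=LwpConfig(**raw.get("lwp", {})),
            windows=tuple(
                tuple(w) for w in raw.get("windows", [(0, 10), (0, 13)])
            ),
            use_ranges=bool(raw.get("use_ranges", False)),
            seed=int(raw.get("seed", 0)),
        )

    def validate_paths(self) -> None:
        for name in ("tree", "hits", "species_map", "temperature", "gene_sets",
                     "subject_lengths", "age_ranges"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"config: {name} file not found: {value}")

    def manifest(self) -> dict:
        return {
            "paleogene_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "inputs": {
                k: str(getattr(self, k)) if getattr(self, k) else None
                for k in ("tree", "hits", "species_map", "temperature",
                          "gene_sets", "subject_lengths", "age_ranges")
            },
            "thresholds": dataclasses.asdict(self.thresholds),
            "clade_rule": dataclasses.asdict(self.clade_rule),
            "lwp": dataclasses.asdict(self.lwp),
            "windows": [list(w) for w in self.windows],
            "use_ranges": self.use_ranges,
            "seed": self.seed,
        }


def read_gene_sets(path) -> list[GeneSet]:
    """Two-column TSV (set_label, gene), ``#`` comments tolerated."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["set_label", "gene"], dtype=str,
        )
    except pd.errors.EmptyDataError:
        return []
    sets = []
    for label, sub in df.groupby("set_label", sort=True):
        sets.append(GeneSet(label=str(label), genes=tuple(sub["gene"])))
    return sets


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run(config: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns the paths of the written artifacts."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        stage = "timetree"
        ranges = (
            read_age_ranges(config.age_ranges) if config.age_ranges else None
        )
        tree = read_timetree(
            Path(config.tree).read_text(), age_ranges=ranges
        )
        log.info("[timetree] %d leaves, root %.3g MYA",
                 tree.n_leaves, tree.root.age)

        stage = "presence"
        species_map = read_species_map(config.species_map)
        lengths = (
            read_subject_lengths(config.subject_lengths)
            if config.subject_lengths
            else None
        )
        hits = parse_hit_table(config.hits, species_map, lengths)
        sets = read_gene_sets(config.gene_sets)
        genes = [g for gs in sets for g in gs.genes]
        presence = call_presence(
            hits, genes, tree.leaf_names(), config.thresholds
        )
        log.info(
            "[presence] %d hits read, %d cells detected at %.3g/%.3g",
            len(hits), int(presence.values.sum()),
            config.thresholds.min_identity,
            config.thresholds.min_subject_coverage,
        )

        stage = "clade_inference"
        estimates = date_all_genes(tree, presence, config.clade_rule)
        n_dated = sum(1 for e in estimates if e.category == "dated")
        log.info("[clade_inference] %d of %d genes dated",
                 n_dated, len(estimates))

        stage = "paleotemp"
        series = read_temperature(config.temperature)
        lwps = detect_lwps(series, config.lwp)
        log.info("[paleotemp] %d points, %d warming periods",
                 len(series), len(lwps))

        stage = "association"
        summary = emergence_histogram(estimates, sets)
        overlap = lwp_overlap(estimates, lwps, use_ranges=config.use_ranges)
        summary_rows = [
            {
                "record": "histogram",
                "set_label": r.set_label,
                "age_mya": r.age_mya,
                "value": int(r.count),
            }
            for r in summary.histogram.itertuples(index=False)
        ]
        for label, tally in sorted(summary.tallies.items()):
            for cat, n in tally.items():
                summary_rows.append(
                    {"record": f"tally_{cat}", "set_label": label,
                     "age_mya": "", "value": n}
                )
        for lo, hi in config.windows:
            for gs in sets:
                summary_rows.append(
                    {
                        "record": f"window_{lo:g}_{hi:g}",
                        "set_label": gs.label,
                        "age_mya": "",
                        "value": window_count(estimates, (lo, hi), gs),
                    }
                )
        summary_rows.append(
            {"record": "lwp_in", "set_label": "all", "age_mya": "",
             "value": overlap.n_in}
        )
        summary_rows.append(
            {"record": "lwp_out", "set_label": "all", "age_mya": "",
             "value": overlap.n_out}
        )
        summary_df = pd.DataFrame(
            summary_rows, columns=["record", "set_label", "age_mya", "value"]
        )
        log.info("[association] %d in / %d outside warming periods",
                 overlap.n_in, overlap.n_out)

        stage = "outputs"
        paths = {
            "estimates": out / "estimates.tsv",
            "lwps": out / "lwps.tsv",
            "summary": out / "summary.tsv",
        }
        _write_tsv(estimates_to_frame(estimates), paths["estimates"])
        _write_tsv(intervals_to_frame(lwps), paths["lwps"])
        _write_tsv(summary_df, paths["summary"])
        node_ranges = {
            e.age: e.age_range for e in estimates
            if e.category == "dated" and e.age_range is not None
        }
        _, fig_path = export_overlay(
            summary, series, out / "overlay", lwps=lwps,
            node_ranges=node_ranges,
        )
        paths["overlay"] = fig_path
        manifest_path = out / "manifest.json"
        manifest_path.write_text(
            json.dumps(config.manifest(), indent=2, sort_keys=True) + "\n"
        )
        paths["manifest"] = manifest_path
        return paths
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------


#: warming excursions injected by the default synthetic bundle: within a
#: cooling trend, warm rebounds near recent divergence-rich times plus two
#: deeper-time events (amplitudes °C, rising-limb durations MY)
DEFAULT_EXCURSIONS = (
    ExcursionSpec(center_age=2.5, amplitude=1.0, duration=0.4),
    ExcursionSpec(center_age=7.55, amplitude=1.2, duration=0.5),
    ExcursionSpec(center_age=12.0, amplitude=1.0, duration=0.5),
    ExcursionSpec(center_age=33.8, amplitude=1.5, duration=0.8),
    ExcursionSpec(center_age=55.8, amplitude=2.0, duration=1.0),
)


def simulate_bundle(
    out_dir,
    n_leaves: int = DEFAULT_N_LEAVES,
    root_age: float = DEFAULT_ROOT_AGE,
    n_genes: int = DEFAULT_N_GENES,
    gain_rate: float = 0.02,
    loss_rate: float = 0.0,
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    oldest: float = DEFAULT_OLDEST,
    excursions: Sequence[ExcursionSpec] = DEFAULT_EXCURSIONS,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a self-contained fixture bundle consumable by :func:`run`.

    The defaults mirror the study conditions: 32 species, root at 74 MYA,
    145 query genes (labelled 45 de novo + 100 cancer), a 66-MY temperature
    series.  A ``truth.tsv`` with the simulated emergence nodes and a ready
    ``config.yaml`` are included.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(seed).generate_state(4)
    ]

    tree = simulate_tree(n_leaves, root_age, seed=seeds[0])
    presence, truths = simulate_gene_histories(
        tree, n_genes, gain_rate=gain_rate, loss_rate=loss_rate, seed=seeds[1]
    )
    hits = simulate_hit_table(
        presence, fp_rate=fp_rate, fn_rate=fn_rate, seed=seeds[2]
    )
    series, truth_lwps = simulate_temperature(
        oldest=oldest, excursions=excursions, noise_sd=noise_sd, seed=seeds[3]
    )

    paths = {k: out / v for k, v in {
        "tree": "tree.nwk",
        "hits": "hits.tsv",
        "species_map": "species_map.tsv",
        "temperature": "temperature.tsv",
        "gene_sets": "gene_sets.tsv",
        "truth": "truth.tsv",
        "truth_lwps": "truth_lwps.tsv",
        "config": "config.yaml",
    }.items()}

    paths["tree"].write_text(tree.write_newick() + "\n")
    with open(paths["hits"], "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_gene}\t{h.subject_seq}\t{h.percent_identity}"
                f"\t{h.subject_start}\t{h.subject_end}\t{h.subject_length}\n"
            )
    with open(paths["species_map"], "w") as fh:
        for sp in tree.leaf_names():
            fh.write(f"{sp}|\t{sp}\n")
    with open(paths["temperature"], "w") as fh:
        fh.write("# synthetic global surface temperature (age_mya, ts_c)\n")
        for age, ts in zip(series.ages, series.ts):
            fh.write(f"{age:.6f}\t{ts:.6f}\n")
    n_denovo = min(45, n_genes)
    with open(paths["gene_sets"], "w") as fh:
        for i, t in enumerate(truths):
            label = "de_novo" if i < n_denovo else "cancer"
            fh.write(f"{label}\t{t.gene}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("gene\ttrue_node_id\ttrue_node_age\ttrue_gain_age\tn_events\n")
        for t in truths:
            fh.write(
                f"{t.gene}\t{'' if t.true_node_id is None else t.true_node_id}"
                f"\t{'' if t.true_node_age is None else f'{t.true_node_age:.6f}'}"
                f"\t{'' if t.true_gain_age is None else f'{t.true_gain_age:.6f}'}"
                f"\t{len(t.events)}\n"
            )
    _write_tsv(intervals_to_frame(truth_lwps), paths["truth_lwps"])
    config = {
        "tree": "tree.nwk",
        "hits": "hits.tsv",
        "species_map": "species_map.tsv",
        "temperature": "temperature.tsv",
        "gene_sets": "gene_sets.tsv",
        "out_dir": "results",
        "seed": seed,
    }
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths
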