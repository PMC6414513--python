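"""End-to-end orchestration of the analysis stages.

Runs the stages in acquisition order — simulate, bead-normalize, debarcode,
transform, gate, cluster, quantify, test, order — from one config and seed,
and produces the headline tables for each study scenario. The master event
table is kept on the raw-count scale throughout; each stage applies the
arcsinh transform to its own working view (clustering and trajectories on
transformed phenotype markers, FR tests on transformed biosynthesis
channels, IdU positivity on raw counts).

A single config seed feeds a per-stage seed stream hashed by stage name, so
inserting or skipping a stage does not perturb downstream seeds.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, synthetic_data
from .clustering import AnnotationRule, ClusterGraph, SpadeParams, spade
from .fr_test import FRParams, fr_matrix
from .io_core import EventTable, PipelineConfig, derive_seed, write_events
from .population_stats import (
    StatParams,
    bootstrap_median,
    idu_fraction_report,
    shift_table,
    transformed_median,
)

__all__ = [
    "RunManifest",
    "run",
    "scenario_report",
    "scenario_annotation_rules",
    "gate_phases",
]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, events_in: int, events_out: int, **extra) -> None:
        self.stages.append(
            {"stage": stage, "events_in": int(events_in), "events_out": int(events_out), **extra}
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


# ---------------------------------------------------------------------------
# scenario-specific population definitions


def scenario_annotation_rules(name: str) -> list[AnnotationRule]:
    """First-match phenotype annotation rules for each scenario's panel."""
    if name == "cellcycle":
        return []  # a single cell line; phases are gated, not annotated
    if name == "pbmc_timecourse":
        return [
            AnnotationRule("Monocyte", high=("CD14", "HLADR")),
            AnnotationRule("Bcell", high=("CD19", "HLADR")),
            AnnotationRule("Tcell_CD4", high=("CD3", "CD4")),
            AnnotationRule("Tcell_CD8", high=("CD3", "CD8a")),
            AnnotationRule("NK", high=("CD56",)),
            AnnotationRule("DC", high=("HLADR",), low=("CD14", "CD19", "CD3")),
            AnnotationRule(
                "Basophil", high=("CD45",), low=("CD3", "CD19", "CD56", "CD14", "HLADR")
            ),
        ]
    if name == "marrow_hierarchy":
        return [
            AnnotationRule("Ery", high=("CD235",), low=("CD3", "CD34")),
            AnnotationRule("Plasma", high=("CD38",), low=("CD34", "CD20"), threshold=4.0),
            AnnotationRule("HSC", high=("CD34",), low=("CD38", "CD19", "CD10", "CD235")),
            AnnotationRule("B_early", high=("CD10",), low=("CD14", "CD3")),
            AnnotationRule("Progenitor", high=("CD34",), low=("CD10",)),
            AnnotationRule("Bcell", high=("CD19",), low=("CD14", "CD3")),
            AnnotationRule("Tcell", high=("CD3",)),
            AnnotationRule("NK", high=("CD56",)),
            AnnotationRule("Monocyte", high=("CD14",)),
            AnnotationRule("pDC", high=("CD123",)),
        ]
    raise ValueError(f"no annotation rules for scenario {name!r}")


def gate_phases(table: EventTable, cofactor: float = 5.0) -> np.ndarray:
    """Call cell-cycle phases from CyclinB1 / pHH3 marker gates.

    CyclinB1-negative interphase cells are G0/G1, mid-level S, high G2;
    pHH3-high cells are mitotic, split early/late on CyclinB1 (high early,
    reduced in late mitosis). Thresholds sit between the design modes on
    the transformed scale.
    """
    cyc = preprocess.transform_values(table.column("CyclinB1"), cofactor)
    phh3 = preprocess.transform_values(table.column("pHH3"), cofactor)
    phase = np.full(table.n_events, "G0G1", dtype=object)
    phase[(cyc >= 2.0) & (cyc < 4.0)] = "S"
    phase[cyc >= 4.0] = "G2"
    mitotic = phh3 > 2.5
    phase[mitotic & (cyc >= 4.0)] = "M_early"
    phase[mitotic & (cyc < 4.0)] = "M_late"
    return phase


# ---------------------------------------------------------------------------
# orchestrated run


def run(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[RunManifest, dict]:
    """Execute the configured stages in order; returns (manifest, outputs).

    Outputs is a dict holding the artifacts each stage produced (event
    tables, cluster graph, statistics tables); when ``outdir`` is given
    they are also written to disk.
    """
    seed = config.seed if seed is None else seed
    cfg_hash = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in sorted(asdict(config).items())}, sort_keys=True
        ).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, seed=seed)
    outputs: dict = {}
    stages = config.stages or ["simulate", "normalize", "debarcode", "gate", "cluster", "stats"]

    table: EventTable | None = None
    if "simulate" in stages:
        if not config.scenario:
            raise ValueError("simulate stage requires config.scenario")
        design = synthetic_data.make_scenario(config.scenario, seed=derive_seed(seed, "simulate"))
        table = synthetic_data.simulate_experiment(design)
        outputs["design"] = design
        manifest.record("simulate", 0, table.n_events, scenario=config.scenario)

    if table is None:
        raise ValueError("no input: configure a simulate stage or load events first")

    if "normalize" in stages and table.channels_of_kind("bead"):
        try:
            table, bead_report = preprocess.bead_normalize(table)
            bead_mask = table.labels["bead_event"].to_numpy()
            table = table.subset(~bead_mask)
            outputs["bead_report"] = bead_report
            manifest.record("normalize", len(bead_mask), table.n_events)
        except ValueError as exc:
            warnings.warn(f"skipping bead normalization: {exc}", stacklevel=2)

    if "debarcode" in stages and config.barcode_keys:
        assign = preprocess.debarcode(
            table,
            keys=config.barcode_keys,
            min_separation=config.barcode_min_separation,
            cofactor=config.cofactor,
        )
        keep = assign["sample_id"].to_numpy() >= 0
        outputs["debarcode"] = assign
        n_in = table.n_events
        table = table.subset(keep)
        manifest.record("debarcode", n_in, table.n_events)

    if "gate" in stages:
        rules = config.gates or preprocess.viability_gates(table)
        mask, gate_report = preprocess.apply_gates(table, rules, cofactor=config.cofactor)
        outputs["gate_report"] = gate_report
        n_in = table.n_events
        table = table.subset(mask)
        manifest.record("gate", n_in, table.n_events)

    outputs["events"] = table

    graph: ClusterGraph | None = None
    if "cluster" in stages:
        params = SpadeParams(
            clustering_channels=list(config.clustering.get("channels", [])),
            downsample_target=config.clustering["downsample_target"],
            n_nodes=config.clustering["n_nodes"],
            density_k=config.clustering["density_k"],
            seed=derive_seed(seed, "cluster"),
        )
        transformed = preprocess.arcsinh(table, config.cofactor)
        rules = (
            scenario_annotation_rules(config.scenario)
            if config.scenario
            else [AnnotationRule(**r) for r in config.annotations]
        )
        graph = spade(transformed, params, rules=rules)
        outputs["graph"] = graph
        manifest.record("cluster", table.n_events, table.n_events, n_nodes=graph.n_nodes)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_events(table, outdir / "events.fcs")
        if graph is not None:
            (outdir / "graph.json").write_text(json.dumps(graph.to_dict()))
        manifest.to_json(outdir / "manifest.json")
    return manifest, outputs


# ---------------------------------------------------------------------------
# scenario reports


def scenario_report(
    name: str, seed: int = 0, n_events: int | None = None
) -> dict[str, pd.DataFrame]:
    """Produce the headline tables for one study scenario.

    cellcycle: per-phase biosynthesis medians (transformed scale) from
    marker-gated phases. pbmc_timecourse: the median-shift table versus the
    unstimulated control. marrow_hierarchy: per-population IdU-positive
    fractions with bootstrap CIs and the FR comparison matrix against HSC.
    """
    if name not in synthetic_data.SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid: {sorted(synthetic_data.SCENARIOS)}")
    kwargs = {} if n_events is None else {"n_events": n_events}
    design = synthetic_data.make_scenario(name, seed=derive_seed(seed, "simulate"), **kwargs)
    table = synthetic_data.simulate_experiment(design)
    table, gated = _standard_preprocess(table, design)

    if name == "cellcycle":
        return {"phase_medians": _phase_median_table(gated)}
    if name == "pbmc_timecourse":
        return {"shift_table": _pbmc_shift_table(gated, seed)}
    return _marrow_tables(gated, seed)


def _standard_preprocess(table, design):
    """Bead removal, debarcoding (when barcoded) and viability gating."""
    if table.channels_of_kind("bead"):
        table, _ = preprocess.bead_normalize(table)
        table = table.subset(~table.labels["bead_event"].to_numpy())
    if design.barcode_scheme is not None:
        scheme = design.barcode_scheme
        keys = [tuple(scheme.channels[j] for j in key) for key in scheme.keys]
        assign = preprocess.debarcode(table, keys=keys)
        sample_names = [s.name for s in design.samples]
        keep = (assign["sample_id"] >= 0) & (assign["sample_id"] < len(sample_names))
        table = table.subset(keep.to_numpy())
    mask, _ = preprocess.apply_gates(table, preprocess.viability_gates(table))
    return table, table.subset(mask)


def _phase_median_table(table: EventTable) -> pd.DataFrame:
    phases = gate_phases(table)
    chans = ["IdU", "BRU", "Puromycin", "p4EBP1"]
    rows = []
    for ph in synthetic_data.PHASES:
        sel = phases == ph
        if sel.sum() < 5:
            continue
        row = {"phase": ph, "n": int(sel.sum())}
        for ch in chans:
            row[ch] = transformed_median(table.column(ch)[sel])
        rows.append(row)
    return pd.DataFrame(rows).set_index("phase")


def _pbmc_shift_table(table: EventTable, seed: int) -> pd.DataFrame:
    transformed = preprocess.arcsinh(table, channels=None)
    params = SpadeParams(
        clustering_channels=transformed.channels_of_kind("phenotype"),
        n_nodes=150,
        seed=derive_seed(seed, "cluster"),
    )
    graph = spade(transformed, params, rules=scenario_annotation_rules("pbmc_timecourse"))
    channels = ["BRU", "Puromycin", "CD69", "pS6", "p4EBP1", "TNFa", "IFNg"]
    samples = table.labels["sample"].to_numpy()
    groups = {}
    for pop in sorted(set(graph.annotations) - {"unassigned"}):
        pop_mask = graph.events_of(pop)
        for cond in [s for s, _ in synthetic_data.PBMC_TIMEPOINTS]:
            sel = pop_mask & (samples == cond)
            if sel.sum() >= 20:
                groups[(pop, cond)] = table.columns(channels)[sel]
    return shift_table(groups, channels, control_condition="0h")


def _marrow_tables(table: EventTable, seed: int) -> dict[str, pd.DataFrame]:
    transformed = preprocess.arcsinh(table, channels=None)
    params = SpadeParams(
        clustering_channels=transformed.channels_of_kind("phenotype"),
        n_nodes=175,
        seed=derive_seed(seed, "cluster"),
    )
    graph = spade(transformed, params, rules=scenario_annotation_rules("marrow_hierarchy"))
    stat_params = StatParams(seed=derive_seed(seed, "stats"))

    rows = []
    pop_events: dict[str, EventTable] = {}
    for pop in sorted(set(graph.annotations) - {"unassigned"}):
        sub = table.subset(graph.events_of(pop))
        if sub.n_events < 40:
            continue
        pop_events[pop] = sub
        fraction, split = idu_fraction_report(sub, stat_params)
        row = {"population": pop, "n": sub.n_events, "idu_fraction": fraction,
               "idu_split_reported": split is not None}
        for ch in ("BRU", "Puromycin"):
            summ = bootstrap_median(
                np.arcsinh(sub.column(ch) / stat_params.cofactor),
                stat_params,
                seed=derive_seed(seed, f"boot-{pop}-{ch}"),
            )
            row[f"{ch}_median"] = summ.point_estimate
            row[f"{ch}_ci_low"] = summ.ci_low
            row[f"{ch}_ci_high"] = summ.ci_high
        rows.append(row)
    stats = pd.DataFrame(rows).set_index("population")

    fr_chan = ["BRU", "Puromycin"]
    hsc = np.arcsinh(pop_events["HSC"].columns(fr_chan) / stat_params.cofactor)
    half = len(hsc) // 2
    others = {"HSC": hsc[half:]}
    for pop, sub in pop_events.items():
        if pop != "HSC":
            others[pop] = np.arcsinh(sub.columns(fr_chan) / stat_params.cofactor)
    fr = fr_matrix(
        hsc[:half],
        others,
        FRParams(seed=derive_seed(seed, "frtest")),
        reference_name="HSC",
    )
    return {"population_stats": stats, "fr_vs_hsc": fr}
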