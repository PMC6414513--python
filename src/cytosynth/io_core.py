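"""Shared data model and I/O for mass-cytometry event tables.

The central container is :class:`EventTable`: an ``(n_events, n_channels)``
matrix of nonnegative ion counts with ordered channel metadata
(:class:`ChannelDef`), optional per-event truth/annotation labels, and a flag
tracking whether (a subset of) channels have been arcsinh-transformed.
Event order is meaningful throughout the pipeline: filters return index
masks, and subsetting preserves order.

Files are read and written as FCS (see :mod:`cytosynth._fcs`) or delimited
text with a header row; truth labels travel in a ``<stem>.labels.tsv``
sidecar keyed by event index, never inside the FCS TEXT segment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ChannelDef",
    "EventTable",
    "GateRule",
    "PipelineConfig",
    "ConfigError",
    "read_events",
    "write_events",
    "load_config",
    "save_config",
    "derive_seed",
]

ChannelKind = Literal[
    "phenotype", "biosynthesis", "barcode", "bead", "viability", "dna_content", "signaling"
]

_KINDS = {"phenotype", "biosynthesis", "barcode", "bead", "viability", "dna_content", "signaling"}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass(frozen=True)
class ChannelDef:
    """One measured channel: a short marker name and its metal mass tag."""

    name: str
    mass_tag: str = ""
    kind: str = "phenotype"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")


@dataclass
class EventTable:
    """Cells x channels matrix of ion counts plus channel metadata."""

    values: np.ndarray
    channels: list[ChannelDef]
    labels: pd.DataFrame | None = None
    transformed: bool = False
    transformed_channels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (events x channels)")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.channels)} channel defs"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique within a panel")
        tags = [c.mass_tag for c in self.channels if c.mass_tag]
        if len(set(tags)) != len(tags):
            raise ValueError("mass tags must be unique within a panel")
        if not self.transformed and self.values.size and self.values.min() < 0:
            raise ValueError("raw ion counts must be nonnegative")
        if self.labels is not None and len(self.labels) != self.n_events:
            raise ValueError("labels must have one row per event")

    # -- basic accessors -------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def index_of(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.index_of(name)]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.index_of(n) for n in names]
        return self.values[:, idx]

    def channels_of_kind(self, kind: str) -> list[str]:
        return [c.name for c in self.channels if c.kind == kind]

    def subset(self, mask_or_index: np.ndarray) -> "EventTable":
        """Row-subset preserving event order; labels follow."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        labels = None
        if self.labels is not None:
            labels = self.labels.iloc[idx].reset_index(drop=True)
        return EventTable(
            values=self.values[idx],
            channels=list(self.channels),
            labels=labels,
            transformed=self.transformed,
            transformed_channels=self.transformed_channels,
        )

    def copy(self) -> "EventTable":
        return EventTable(
            values=self.values.copy(),
            channels=list(self.channels),
            labels=None if self.labels is None else self.labels.copy(),
            transformed=self.transformed,
            transformed_channels=self.transformed_channels,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)


@dataclass(frozen=True)
class GateRule:
    """Threshold filter on one channel (e.g. drop cisplatin-positive events)."""

    channel: str
    op: Literal["gt", "ge", "lt", "le"]
    threshold: float
    action: Literal["keep", "drop", "flag"] = "keep"
    scale: Literal["raw", "transformed"] = "transformed"
    name: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("gate threshold must be finite")
        if self.op not in ("gt", "ge", "lt", "le"):
            raise ValueError(f"unknown gate op {self.op!r}")
        if self.action not in ("keep", "drop", "flag"):
            raise ValueError(f"unknown gate action {self.action!r}")


@dataclass
class PipelineConfig:
    """Validated description of one analysis run.

    Defaults follow the study conventions of this kind of experiment:
    arcsinh cofactor 5, IdU positivity above 10 raw counts with a 4%
    reporting rule, bootstrap R=1000 at 95%, FR sampling S=200 / N=100,
    SPADE 15% downsampling.
    """

    panel: list[ChannelDef] = field(default_factory=list)
    cofactor: float = 5.0
    gates: list[GateRule] = field(default_factory=list)
    barcode_keys: list[list[str]] = field(default_factory=list)
    barcode_min_separation: float = 1.5
    clustering: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    fr: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    comparisons: list[dict] = field(default_factory=list)
    scenario: str | None = None
    stages: list[str] = field(default_factory=list)
    annotations: list[dict] = field(default_factory=list)
    seed: int = 0

    _CLUSTER_DEFAULTS = {"downsample_target": 0.15, "n_nodes": 150, "density_k": 15}
    _STATS_DEFAULTS = {
        "bootstrap_R": 1000,
        "ci_level": 0.95,
        "idu_threshold": 10.0,
        "idu_report_min": 0.04,
    }
    _FR_DEFAULTS = {"S": 200, "N": 100, "channels": ["BRU", "Puromycin"]}
    _TRAJ_DEFAULTS = {"k": 30, "l": 25, "n_graphs": 20, "n_waypoints": 150}

    def __post_init__(self) -> None:
        if self.cofactor <= 0:
            raise ConfigError("cofactor must be positive")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ConfigError("seed must be a nonnegative integer")
        self.clustering = {**self._CLUSTER_DEFAULTS, **self.clustering}
        self.stats = {**self._STATS_DEFAULTS, **self.stats}
        self.fr = {**self._FR_DEFAULTS, **self.fr}
        self.trajectory = {**self._TRAJ_DEFAULTS, **self.trajectory}
        self.validate()

    def validate(self) -> None:
        names = {c.name for c in self.panel}
        if self.panel:
            referenced = [g.channel for g in self.gates]
            referenced += [ch for key in self.barcode_keys for ch in key]
            referenced += list(self.clustering.get("channels", []))
            for ch in referenced:
                if ch not in names:
                    raise ConfigError(f"config references unknown channel {ch!r}")


# ---------------------------------------------------------------------------
# event I/O


def _labels_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.tsv")


def _infer_format(path: Path, format: str | None) -> str:
    if format:
        return format
    return "fcs" if path.suffix.lower() == ".fcs" else "delimited"


def read_events(
    path: str | Path,
    format: Literal["fcs", "delimited"] | None = None,
    panel: Sequence[ChannelDef] | None = None,
) -> EventTable:
    """Read an event table from FCS or header-bearing delimited text.

    A ``<name>.labels.tsv`` sidecar, when present, is attached as per-event
    labels. If ``panel`` is given, its kind/mass-tag metadata is matched to
    the file's channel names; otherwise channels default to phenotype kind
    (FCS carries the mass tag in $PnS where the file was written by
    :func:`write_events`).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "fcs":
        from . import _fcs

        short, long, data = _fcs.read_fcs(path)
        channels = [ChannelDef(name=s, mass_tag=l) for s, l in zip(short, long)]
    else:
        df = pd.read_csv(path, sep=None, engine="python")
        data = df.to_numpy(dtype=np.float64)
        channels = [ChannelDef(name=str(c)) for c in df.columns]
    if panel is not None:
        by_name = {c.name: c for c in panel}
        channels = [by_name.get(c.name, c) for c in channels]
    labels = None
    lp = _labels_path(path)
    if lp.exists():
        labels = pd.read_csv(lp, sep="\t")
    data = np.maximum(data, 0.0)  # FCS float round-trip may graze zero
    return EventTable(values=data, channels=channels, labels=labels)


def write_events(
    table: EventTable,
    path: str | Path,
    format: Literal["fcs", "delimited"] | None = None,
) -> Path:
    """Write an event table (FCS 3.1 or delimited); labels go to a sidecar."""
    if table.n_events == 0:
        raise ValueError("refusing to write an empty event table")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "fcs":
        from . import _fcs

        _fcs.write_fcs(
            path,
            names=table.channel_names,
            data=table.values,
            long_names=[c.mass_tag for c in table.channels],
        )
    else:
        table.to_frame().to_csv(path, sep="\t", index=False)
    if table.labels is not None:
        table.labels.to_csv(_labels_path(path), sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# config I/O


def _config_to_dict(cfg: PipelineConfig) -> dict:
    out = dataclasses.asdict(cfg)
    out["panel"] = [dataclasses.asdict(c) for c in cfg.panel]
    out["gates"] = [dataclasses.asdict(g) for g in cfg.gates]
    return out


def _config_from_dict(doc: dict) -> PipelineConfig:
    doc = dict(doc or {})
    panel = [ChannelDef(**c) for c in doc.pop("panel", [])]
    gates = [GateRule(**g) for g in doc.pop("gates", [])]
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(panel=panel, gates=gates, **doc)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config, filling defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _config_from_dict(doc or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# seeding


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31.

    Hashing the stage name into the stream means inserting or skipping a
    stage does not perturb the seeds of the stages downstream of it.
    """
    import zlib

    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)
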