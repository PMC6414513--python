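"""Synthetic mass-cytometry event generator with ground-truth labels.

Generates raw ion-count event tables with the signal structure the analysis
pipeline assumes: multi-population mixtures over phenotype markers;
biosynthesis channels (IdU for nascent DNA on iodine, BRU for nascent RNA
and puromycin for nascent protein on lanthanide antibody channels) with
population- and cell-cycle-phase-specific intensities; small-molecule
inhibitor dose-response on those channels; palladium sample barcodes with
doublets; calibration-bead events; cisplatin-positive dead and
cleaved-caspase-positive apoptotic cells; and +1-mass isotope spillover.

Counts are drawn from a zero-inflated log-normal-Poisson model: each event's
latent intensity is lambda = exp(Normal(log median, spread)) and the
observed count is Poisson(lambda), with an extra point mass at zero whose
weight depends on the channel kind. This reproduces the zero mode plus
right-skewed positive mode characteristic of ion-count cytometry channels.

Every operation is deterministic given its seed, and every generated event
carries truth labels (population, cell-cycle phase, viability, bead flag,
barcode id, singlet/doublet, latent differentiation coordinate) so each
downstream stage can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import ChannelDef, EventTable

__all__ = [
    "PopulationSpec",
    "InhibitorModel",
    "BarcodeScheme",
    "SampleSpec",
    "ExperimentDesign",
    "hill_response",
    "apply_inhibitor",
    "simulate_events",
    "simulate_cell_cycle",
    "pool_with_barcodes",
    "inject_spillover",
    "make_scenario",
    "simulate_experiment",
    "SCENARIOS",
]

PHASES = ("G0G1", "S", "G2", "M_early", "M_late")

DEFAULT_SPREAD = 0.35  # log-scale dispersion of the latent intensity

#: Extra point mass at zero, by channel kind.
DEFAULT_ZERO_INFLATION = {
    "phenotype": 0.03,
    "biosynthesis": 0.0,
    "barcode": 0.0,
    "bead": 0.0,
    "viability": 0.0,
    "dna_content": 0.0,
    "signaling": 0.02,
}

LABEL_COLUMNS = [
    "sample",
    "population",
    "phase",
    "u",
    "dead",
    "apoptotic",
    "bead",
    "doublet",
    "barcode_id",
]


# ---------------------------------------------------------------------------
# design types


@dataclass
class PopulationSpec:
    """One cell population: frequency, per-channel medians and dispersions.

    ``phase_profile`` optionally structures the population over cell-cycle
    phases: ``{"fractions": {phase: f}, "overrides": {phase: {channel:
    median}}}``. ``continuum`` optionally makes selected channel medians
    functions of a latent differentiation coordinate u ~ Uniform(0, 1)
    (e.g. a developing B-cell lineage); supported shapes are ``linear``,
    ``sigmoid`` and ``bump`` (see :func:`_continuum_median`).
    """

    name: str
    frequency: float
    channel_medians: dict[str, float] = field(default_factory=dict)
    channel_spreads: dict[str, float] = field(default_factory=dict)
    idu_positive_fraction: float = 0.0
    idu_positive_median: float = 200.0
    phase_profile: dict | None = None
    continuum: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.frequency <= 1:
            raise ValueError(f"{self.name}: frequency must be in [0, 1]")
        if any(m < 0 for m in self.channel_medians.values()):
            raise ValueError(f"{self.name}: channel medians must be nonnegative")
        if not 0 <= self.idu_positive_fraction <= 1:
            raise ValueError(f"{self.name}: idu_positive_fraction must be in [0, 1]")
        if self.phase_profile is not None:
            fr = self.phase_profile.get("fractions", {})
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: phase fractions must sum to 1")
            for ph in fr:
                if ph not in PHASES:
                    raise ValueError(f"{self.name}: unknown phase {ph!r}")


@dataclass
class InhibitorModel:
    """Four-parameter Hill dose-response acting on channel medians.

    The primary ``target_channel`` and any ``secondary_targets`` (each with
    its own ic50/hill/floor) have their medians multiplied by
    ``floor + (1 - floor) / (1 + (dose/ic50)**hill)`` — e.g. actinomycin D
    suppressing BRU, or cycloheximide suppressing puromycin with secondary
    suppression of BRU and IdU.
    """

    target_channel: str
    ic50: float
    hill: float = 1.0
    floor: float = 0.0
    secondary_targets: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if not 0 <= self.floor <= 1:
            raise ValueError("floor must be in [0, 1]")


@dataclass
class BarcodeScheme:
    """k-of-m combinatorial metal barcode (default 3-of-6 palladium, 20 keys)."""

    channels: list[str]
    keys: list[tuple[int, ...]]
    doublet_rate: float = 0.0
    high_median: float = 200.0
    high_spread: float = 0.3

    def __post_init__(self) -> None:
        if len(set(map(tuple, self.keys))) != len(self.keys):
            raise ValueError("barcode keys must be distinct")
        k_sizes = {len(k) for k in self.keys}
        if len(k_sizes) != 1:
            raise ValueError("all keys must set the same number of channels high")
        if not 0 <= self.doublet_rate <= 1:
            raise ValueError("doublet_rate must be in [0, 1]")

    @property
    def m(self) -> int:
        return len(self.channels)

    @property
    def k(self) -> int:
        return len(self.keys[0])

    @classmethod
    def default_3_of_6(cls, channels: Sequence[str] | None = None, **kw) -> "BarcodeScheme":
        """The 20-key 3-high-of-6 palladium scheme."""
        from itertools import combinations

        chans = list(channels) if channels else [f"Pd{m}" for m in (102, 104, 105, 106, 108, 110)]
        if len(chans) != 6:
            raise ValueError("default scheme needs 6 barcode channels")
        return cls(channels=chans, keys=list(combinations(range(6), 3)), **kw)


@dataclass
class SampleSpec:
    """A barcoded sample: a name plus per-channel median multipliers.

    Multipliers model condition effects (stimulation time, inhibitor dose)
    applied uniformly to every population's medians for that sample.
    """

    name: str
    channel_multipliers: dict[str, float] = field(default_factory=dict)
    n_events: int | None = None


@dataclass
class ExperimentDesign:
    """Full description of one synthetic acquisition."""

    panel: list[ChannelDef]
    populations: list[PopulationSpec]
    n_events: int = 10_000
    dead_fraction: float = 0.0
    apoptotic_fraction: float = 0.0
    bead_fraction: float = 0.0
    samples: list[SampleSpec] = field(default_factory=list)
    barcode_scheme: BarcodeScheme | None = None
    spillover: list[tuple[str, str, float]] = field(default_factory=list)
    inhibitor: tuple[InhibitorModel, float] | None = None
    zero_inflation: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ZERO_INFLATION))
    sensitivity: tuple[float, float] | None = None
    dead_channel: str = "Cisplatin"
    apoptosis_channel: str = "cCaspase3"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p.frequency for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population frequencies sum to {total}, not 1")
        for f in (self.dead_fraction, self.apoptotic_fraction, self.bead_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        for src, dst, frac in self.spillover:
            if not 0 <= frac < 1:
                raise ValueError(f"spillover fraction {frac} out of [0, 1)")

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.panel]


# ---------------------------------------------------------------------------
# dose-response


def hill_response(dose: float, ic50: float, hill: float, floor: float) -> float:
    """Fractional remaining signal at ``dose``: floor + (1-floor)/(1+(d/ic50)^h)."""
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    if dose == 0:
        return 1.0
    return floor + (1.0 - floor) / (1.0 + (dose / ic50) ** hill)


def apply_inhibitor(
    medians: dict[str, float], model: InhibitorModel, dose: float
) -> dict[str, float]:
    """Scale channel medians by the inhibitor's Hill curves (monotone in dose)."""
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    out = dict(medians)
    targets: dict[str, tuple[float, float, float]] = {
        model.target_channel: (model.ic50, model.hill, model.floor)
    }
    targets.update(model.secondary_targets)
    for channel, (ic50, hill, floor) in targets.items():
        if channel in out:
            out[channel] = out[channel] * hill_response(dose, ic50, hill, floor)
    return out


# ---------------------------------------------------------------------------
# count model


def _sample_counts(
    medians: np.ndarray, spread: float | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Zero-inflation-free log-normal-Poisson draw; medians may be per-event."""
    medians = np.asarray(medians, dtype=float)
    lam = np.zeros_like(medians)
    pos = medians > 0
    if np.any(pos):
        sp = spread if np.isscalar(spread) else np.asarray(spread)[pos]
        lam[pos] = np.exp(rng.normal(np.log(medians[pos]), sp))
    return rng.poisson(lam).astype(float)


def _continuum_median(shape: dict, u: np.ndarray) -> np.ndarray:
    """Evaluate a continuum channel-median curve at latent coordinate u."""
    kind = shape.get("kind", "linear")
    if kind == "linear":
        return shape["lo"] + (shape["hi"] - shape["lo"]) * u
    if kind == "sigmoid":
        z = (u - shape["center"]) / shape.get("width", 0.05)
        return shape["lo"] + (shape["hi"] - shape["lo"]) / (1.0 + np.exp(-z))
    if kind == "bump":
        z = (u - shape["center"]) / shape.get("width", 0.08)
        return shape["base"] + shape["amp"] * np.exp(-0.5 * z**2)
    raise ValueError(f"unknown continuum shape {kind!r}")


def _population_block(
    spec: PopulationSpec,
    panel: Sequence[ChannelDef],
    n: int,
    rng: np.random.Generator,
    zero_inflation: dict[str, float],
    multipliers: dict[str, float] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw n events for one population; returns (values, labels)."""
    names = [c.name for c in panel]
    values = np.zeros((n, len(panel)))
    mult = multipliers or {}

    # Phase structure: draw phases, then per-channel per-event medians.
    if spec.phase_profile is not None:
        fr = spec.phase_profile.get("fractions", {})
        probs = np.array([fr.get(ph, 0.0) for ph in PHASES])
        phase_idx = rng.choice(len(PHASES), size=n, p=probs / probs.sum())
        phases = np.array(PHASES, dtype=object)[phase_idx]
        overrides = spec.phase_profile.get("overrides", {})
    else:
        phases = np.full(n, "", dtype=object)
        overrides = {}
        if spec.idu_positive_fraction > 0:
            # Shorthand for an S-phase subfraction on the IdU channel only.
            in_s = rng.random(n) < spec.idu_positive_fraction
            phases[in_s] = "S"
            phases[~in_s] = "G0G1"

    u = np.full(n, np.nan)
    if spec.continuum is not None:
        u = rng.random(n)

    for j, ch in enumerate(panel):
        base = spec.channel_medians.get(ch.name, 0.0) * mult.get(ch.name, 1.0)
        med = np.full(n, float(base))
        if spec.continuum is not None and ch.name in spec.continuum:
            med = np.asarray(_continuum_median(spec.continuum[ch.name], u), dtype=float)
            med = med * mult.get(ch.name, 1.0)
        for ph, over in overrides.items():
            if ch.name in over:
                med[phases == ph] = over[ch.name] * mult.get(ch.name, 1.0)
        if spec.phase_profile is None and ch.name == "IdU" and spec.idu_positive_fraction > 0:
            med[phases == "S"] = spec.idu_positive_median * mult.get(ch.name, 1.0)
        spread = spec.channel_spreads.get(ch.name, DEFAULT_SPREAD)
        col = _sample_counts(med, spread, rng)
        zi = zero_inflation.get(ch.kind, 0.0)
        if zi > 0:
            col[rng.random(n) < zi] = 0.0
        values[:, j] = col

    labels = pd.DataFrame(
        {
            "sample": "",
            "population": spec.name,
            "phase": phases,
            "u": u,
            "dead": False,
            "apoptotic": False,
            "bead": False,
            "doublet": False,
            "barcode_id": -1,
        }
    )
    return values, labels


# ---------------------------------------------------------------------------
# main simulators


def simulate_events(
    design: ExperimentDesign,
    seed: int | None = None,
    n_events: int | None = None,
    multipliers: dict[str, float] | None = None,
    sample_name: str = "",
) -> EventTable:
    """Simulate one sample's raw-count event table with truth labels.

    Populations are drawn at their design frequencies; dead/apoptotic flags
    elevate the cisplatin / cleaved-caspase channels; a ``bead_fraction`` of
    events are calibration beads (high in every bead channel, background
    elsewhere); spillover, inhibitor effects and a linear sensitivity drift
    are applied when configured. Deterministic given the seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = int(design.n_events if n_events is None else n_events)
    panel = design.panel
    names = design.channel_names

    pops = design.populations
    if design.inhibitor is not None:
        model, dose = design.inhibitor
        pops = [
            replace(p, channel_medians=apply_inhibitor(p.channel_medians, model, dose))
            for p in pops
        ]

    n_beads = rng.binomial(n, design.bead_fraction) if design.bead_fraction else 0
    n_cells = n - n_beads
    freqs = np.array([p.frequency for p in pops])
    counts = rng.multinomial(n_cells, freqs / freqs.sum())

    blocks, labels = [], []
    for spec, n_pop in zip(pops, counts):
        v, lab = _population_block(
            spec, panel, int(n_pop), rng, design.zero_inflation, multipliers
        )
        blocks.append(v)
        labels.append(lab)

    values = np.vstack(blocks) if blocks else np.zeros((0, len(panel)))
    lab = pd.concat(labels, ignore_index=True) if labels else pd.DataFrame(columns=LABEL_COLUMNS)

    # Viability structure: cisplatin-positive dead, cleaved-caspase apoptotic.
    dead = rng.random(n_cells) < design.dead_fraction
    apop = rng.random(n_cells) < design.apoptotic_fraction
    for channel, mask, high in (
        (design.dead_channel, dead, 300.0),
        (design.apoptosis_channel, apop, 200.0),
    ):
        if channel in names and mask.any():
            j = names.index(channel)
            values[mask, j] = _sample_counts(np.full(mask.sum(), high), 0.3, rng)
    lab["dead"] = dead
    lab["apoptotic"] = apop

    if n_beads:
        bead_vals = np.zeros((n_beads, len(panel)))
        for j, ch in enumerate(panel):
            if ch.kind == "bead":
                bead_vals[:, j] = _sample_counts(np.full(n_beads, 500.0), 0.2, rng)
        bead_lab = pd.DataFrame(
            {
                "sample": "",
                "population": "bead",
                "phase": "",
                "u": np.nan,
                "dead": False,
                "apoptotic": False,
                "bead": True,
                "doublet": False,
                "barcode_id": -1,
            },
            index=range(n_beads),
        )
        values = np.vstack([values, bead_vals])
        lab = pd.concat([lab, bead_lab], ignore_index=True)

    # Shuffle so population blocks are interleaved like a real acquisition.
    order = rng.permutation(len(values))
    values = values[order]
    lab = lab.iloc[order].reset_index(drop=True)
    lab["sample"] = sample_name

    table = EventTable(values=values, channels=list(panel), labels=lab)
    if design.spillover:
        table = inject_spillover(table, design.spillover, seed=int(rng.integers(2**31)))
    if design.sensitivity is not None:
        s0, s1 = design.sensitivity
        scale = np.linspace(s0, s1, table.n_events)
        lam = table.values * scale[:, None]
        table.values = rng.poisson(lam).astype(float)
    return table


def simulate_cell_cycle(
    spec: PopulationSpec, panel: Sequence[ChannelDef], n: int, seed: int = 0
) -> EventTable:
    """Simulate one phase-structured population (requires a phase_profile)."""
    if spec.phase_profile is None:
        raise ValueError("simulate_cell_cycle needs a PopulationSpec with phase_profile")
    rng = np.random.default_rng(seed)
    values, labels = _population_block(spec, panel, n, rng, dict(DEFAULT_ZERO_INFLATION))
    return EventTable(values=values, channels=list(panel), labels=labels)


def pool_with_barcodes(
    tables: Sequence[EventTable], scheme: BarcodeScheme, seed: int = 0
) -> EventTable:
    """Pool barcoded samples and create doublets.

    Each sample receives the k-of-m key at its index: its events' "high"
    barcode channels draw around ``high_median`` counts and "low" channels
    stay at zero. Doublets are created at ``doublet_rate`` by adding the
    channel values of a random second event (from any sample) onto an
    event, mimicking two cells fused in one ion cloud.
    """
    if len(tables) > len(scheme.keys):
        raise ValueError(f"{len(tables)} samples but only {len(scheme.keys)} barcode keys")
    if not tables:
        raise ValueError("no tables to pool")
    rng = np.random.default_rng(seed)
    panel = list(tables[0].channels)
    names = [c.name for c in panel]
    missing = [ch for ch in scheme.channels if ch not in names]
    if missing:
        panel = panel + [ChannelDef(name=ch, mass_tag=ch, kind="barcode") for ch in missing]
        names = [c.name for c in panel]
    bc_idx = [names.index(ch) for ch in scheme.channels]

    blocks, labels = [], []
    for i, t in enumerate(tables):
        v = np.zeros((t.n_events, len(panel)))
        v[:, : t.n_channels] = t.values
        for j in (bc_idx[j] for j in scheme.keys[i]):
            v[:, j] = _sample_counts(
                np.full(t.n_events, scheme.high_median), scheme.high_spread, rng
            )
        lab = (
            t.labels.copy()
            if t.labels is not None
            else pd.DataFrame(index=range(t.n_events))
        )
        for col, default in (
            ("population", ""),
            ("phase", ""),
            ("u", np.nan),
            ("dead", False),
            ("apoptotic", False),
            ("bead", False),
            ("doublet", False),
        ):
            if col not in lab.columns:
                lab[col] = default
        lab["barcode_id"] = i
        if "sample" not in lab.columns or (lab["sample"] == "").all():
            lab["sample"] = f"sample{i}"
        blocks.append(v)
        labels.append(lab)

    values = np.vstack(blocks)
    lab = pd.concat(labels, ignore_index=True)
    n = len(values)

    if scheme.doublet_rate > 0:
        is_doublet = rng.random(n) < scheme.doublet_rate
        partners = rng.integers(0, n, size=n)
        idx = np.flatnonzero(is_doublet)
        values[idx] = values[idx] + values[partners[idx]]
        lab.loc[idx, "doublet"] = True

    order = rng.permutation(n)
    return EventTable(values=values[order], channels=panel, labels=lab.iloc[order].reset_index(drop=True))


def _bead_block(panel: Sequence[ChannelDef], n: int, rng: np.random.Generator) -> np.ndarray:
    vals = np.zeros((n, len(panel)))
    for j, ch in enumerate(panel):
        if ch.kind == "bead":
            vals[:, j] = _sample_counts(np.full(n, 500.0), 0.2, rng)
    return vals


def simulate_experiment(design: ExperimentDesign, seed: int | None = None) -> EventTable:
    """Simulate a full acquisition: one table, or barcoded samples pooled.

    With ``design.samples`` set, each sample is simulated with its own
    condition multipliers, pooled through the barcode scheme (doublets
    included), and calibration beads are appended to the pooled run.
    """
    master = np.random.default_rng(design.seed if seed is None else seed)
    if not design.samples:
        return simulate_events(design, seed=int(master.integers(2**31)))

    tables = []
    for samp in design.samples:
        n = samp.n_events if samp.n_events is not None else design.n_events // len(design.samples)
        t = simulate_events(
            replace(design, bead_fraction=0.0, sensitivity=None),
            seed=int(master.integers(2**31)),
            n_events=n,
            multipliers=samp.channel_multipliers,
            sample_name=samp.name,
        )
        tables.append(t)
    if design.barcode_scheme is None:
        raise ValueError("multi-sample designs need a barcode_scheme")
    pooled = pool_with_barcodes(tables, design.barcode_scheme, seed=int(master.integers(2**31)))

    if design.bead_fraction > 0:
        rng = np.random.default_rng(int(master.integers(2**31)))
        n_beads = rng.binomial(pooled.n_events, design.bead_fraction)
        bead_vals = _bead_block(pooled.channels, n_beads, rng)
        bead_lab = pd.DataFrame(
            {
                "sample": "",
                "population": "bead",
                "phase": "",
                "u": np.nan,
                "dead": False,
                "apoptotic": False,
                "bead": True,
                "doublet": False,
                "barcode_id": -1,
            },
            index=range(n_beads),
        )
        values = np.vstack([pooled.values, bead_vals])
        lab = pd.concat([pooled.labels, bead_lab], ignore_index=True)
        order = rng.permutation(len(values))
        pooled = EventTable(
            values=values[order],
            channels=pooled.channels,
            labels=lab.iloc[order].reset_index(drop=True),
        )
    return pooled


def inject_spillover(
    table: EventTable, rules: Sequence[tuple[str, str, float]], seed: int = 0
) -> EventTable:
    """Add +1-mass isotope contamination: dst += Poisson(fraction * src)."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for src, dst, frac in rules:
        if not 0 <= frac < 1:
            raise ValueError(f"spillover fraction {frac} out of [0, 1)")
        if frac == 0:
            continue
        s = out.column(src)
        if s.max() == 0:
            continue
        out.values[:, out.index_of(dst)] += rng.poisson(frac * s)
    return out


# ---------------------------------------------------------------------------
# scenarios


def _biosynthesis_channels() -> list[ChannelDef]:
    return [
        ChannelDef("IdU", "I127", "biosynthesis"),
        ChannelDef("BRU", "Sm150", "biosynthesis"),
        ChannelDef("Puromycin", "Gd158", "biosynthesis"),
    ]


def _viability_channels() -> list[ChannelDef]:
    return [
        ChannelDef("Cisplatin", "Pt195", "viability"),
        ChannelDef("cCaspase3", "Nd142", "viability"),
    ]


def _bead_channels() -> list[ChannelDef]:
    return [ChannelDef("Ce140", "Ce140", "bead"), ChannelDef("Eu151", "Eu151", "bead")]


def _barcode_channels() -> list[ChannelDef]:
    return [
        ChannelDef(f"Pd{m}", f"Pd{m}", "barcode") for m in (102, 104, 105, 106, 108, 110)
    ]


def _cellcycle_design(
    seed: int,
    n_events: int = 100_000,
    s_fraction: float = 0.30,
    m_fraction: float = 0.02,
    m_bru_ratio: float = 0.3,
    mlate_puromycin_ratio: float = 0.3,
) -> ExperimentDesign:
    """Asynchronously dividing cell line with cell-cycle phase structure.

    Mitosis is the rarest phase (default 2%, split early/late 60/40); nascent
    RNA (BRU) is suppressed in mitosis to ``m_bru_ratio`` of the G2 median,
    nascent protein (puromycin) only in late mitosis, and 4EBP1
    phosphorylation peaks in early mitosis.
    """
    panel = [
        ChannelDef("CyclinB1", "Tb159", "phenotype"),
        ChannelDef("pHH3", "Eu153", "phenotype"),
        ChannelDef("p4EBP1", "Er170", "signaling"),
        ChannelDef("pS6", "Yb172", "signaling"),
        *_biosynthesis_channels(),
        *_viability_channels(),
        *_bead_channels(),
    ]
    bru, puro = 300.0, 300.0
    m_early = round(m_fraction * 0.6, 9)
    m_late = round(m_fraction - m_early, 9)
    g2 = 1.0 - s_fraction - m_fraction - 0.50
    pop = PopulationSpec(
        name="cellline",
        frequency=1.0,
        channel_medians={
            "CyclinB1": 5,
            "pHH3": 1,
            "p4EBP1": 30,
            "pS6": 30,
            "IdU": 1,
            "BRU": bru,
            "Puromycin": puro,
            "Cisplatin": 2,
            "cCaspase3": 2,
        },
        phase_profile={
            "fractions": {
                "G0G1": 0.50,
                "S": s_fraction,
                "G2": g2,
                "M_early": m_early,
                "M_late": m_late,
            },
            "overrides": {
                "S": {"IdU": 200, "CyclinB1": 60},
                "G2": {"CyclinB1": 250},
                "M_early": {
                    "CyclinB1": 250,
                    "pHH3": 150,
                    "BRU": bru * m_bru_ratio,
                    "p4EBP1": 120,
                },
                "M_late": {
                    "CyclinB1": 60,
                    "pHH3": 150,
                    "BRU": bru * m_bru_ratio,
                    "Puromycin": puro * mlate_puromycin_ratio,
                    "p4EBP1": 60,
                },
            },
        },
    )
    return ExperimentDesign(
        panel=panel,
        populations=[pop],
        n_events=n_events,
        dead_fraction=0.03,
        apoptotic_fraction=0.02,
        bead_fraction=0.02,
        seed=seed,
    )


#: (time label, channel multipliers) for the stimulation time course:
#: immediate S6/4EBP1 phosphorylation, an RNA-synthesis (BRU) burst during
#: the first hour that returns to baseline by 5 h, protein synthesis
#: (puromycin) and CD69/cytokines rising only at 2-5 h.
PBMC_TIMEPOINTS: list[tuple[str, dict[str, float]]] = [
    ("0h", {}),
    ("0.25h", {"pS6": 8, "p4EBP1": 3}),
    ("0.5h", {"pS6": 8, "p4EBP1": 3, "BRU": 2.2}),
    ("1h", {"pS6": 8, "p4EBP1": 3, "BRU": 2.2}),
    ("2h", {"pS6": 8, "p4EBP1": 3, "BRU": 1.3, "Puromycin": 2.0, "CD69": 10, "TNFa": 6, "IFNg": 4}),
    ("5h", {"pS6": 6, "p4EBP1": 2, "BRU": 1.0, "Puromycin": 2.5, "CD69": 25, "TNFa": 10, "IFNg": 6}),
]


def _pbmc_population(name, freq, markers, bru=100, puro=200, p4ebp1=20, idu=0.005):
    medians = {
        "CD45": 300, "CD3": 2, "CD4": 2, "CD8a": 2, "CD19": 2, "CD56": 2,
        "CD14": 2, "HLADR": 2, "pS6": 20, "p4EBP1": p4ebp1, "CD69": 3,
        "TNFa": 2, "IFNg": 2, "IdU": 1, "BRU": bru, "Puromycin": puro,
        "Cisplatin": 2, "cCaspase3": 2,
    }
    medians.update(markers)
    return PopulationSpec(
        name=name, frequency=freq, channel_medians=medians, idu_positive_fraction=idu
    )


def _pbmc_design(seed: int, n_events: int = 120_000) -> ExperimentDesign:
    """Whole-blood mononuclear stimulation time course, 6 barcoded samples.

    Seven immune populations; B cells carry the highest baseline RNA
    synthesis and myeloid cells (monocytes, DCs) the highest baseline
    protein synthesis, with condition effects given by PBMC_TIMEPOINTS.
    ``n_events`` is the total across the six samples.
    """
    panel = [
        ChannelDef("CD45", "Y89", "phenotype"),
        ChannelDef("CD3", "Nd143", "phenotype"),
        ChannelDef("CD4", "Gd157", "phenotype"),
        ChannelDef("CD8a", "Nd146", "phenotype"),
        ChannelDef("CD19", "Nd144", "phenotype"),
        ChannelDef("CD56", "Yb176", "phenotype"),
        ChannelDef("CD14", "Sm147", "phenotype"),
        ChannelDef("HLADR", "Yb174", "phenotype"),
        ChannelDef("pS6", "Yb172", "signaling"),
        ChannelDef("p4EBP1", "Er170", "signaling"),
        ChannelDef("CD69", "Dy164", "signaling"),
        ChannelDef("TNFa", "Lu175", "signaling"),
        ChannelDef("IFNg", "Ho165", "signaling"),
        *_biosynthesis_channels(),
        *_viability_channels(),
        *_barcode_channels(),
        *_bead_channels(),
    ]
    populations = [
        _pbmc_population("Tcell_CD4", 0.28, {"CD3": 300, "CD4": 300}),
        _pbmc_population("Tcell_CD8", 0.15, {"CD3": 300, "CD8a": 300}),
        _pbmc_population("Bcell", 0.12, {"CD19": 300, "HLADR": 300}, bru=250),
        _pbmc_population("NK", 0.10, {"CD56": 300}, puro=250),
        _pbmc_population("Monocyte", 0.22, {"CD14": 300, "HLADR": 300}, puro=400, p4ebp1=60),
        _pbmc_population("DC", 0.05, {"HLADR": 300}, puro=380, p4ebp1=60),
        _pbmc_population("Basophil", 0.08, {"CD45": 100}),
    ]
    return ExperimentDesign(
        panel=panel,
        populations=populations,
        n_events=n_events,
        dead_fraction=0.05,
        apoptotic_fraction=0.03,
        bead_fraction=0.02,
        samples=[SampleSpec(name, mult) for name, mult in PBMC_TIMEPOINTS],
        barcode_scheme=BarcodeScheme.default_3_of_6(doublet_rate=0.05),
        spillover=[("CD4", "Puromycin", 0.02)],
        seed=seed,
    )


def _marrow_population(name, freq, markers, bru, puro, idu=0.0, rrna=50):
    medians = {
        "CD45": 300, "CD34": 2, "CD38": 2, "CD19": 2, "CD20": 2, "CD10": 2,
        "IgM": 2, "CD3": 2, "CD56": 2, "CD14": 2, "CD235": 2, "CD123": 2,
        "rRNA": rrna, "pS6": 15, "IdU": 1, "BRU": bru, "Puromycin": puro,
        "Cisplatin": 2, "cCaspase3": 2,
    }
    medians.update(markers)
    return PopulationSpec(
        name=name, frequency=freq, channel_medians=medians, idu_positive_fraction=idu
    )


#: Latent-coordinate curves for the developing B-cell lineage: CD34 falls as
#: CD19 rises; CD10 is lost late as CD20 comes up; surface IgM switches on
#: (half-rise at u = 0.6, the heavy-chain rearrangement checkpoint) and a
#: burst of nascent RNA synthesis (BRU) follows it, peaking at u = 0.75,
#: together with S6 phosphorylation marking the rewired signaling state.
B_CONTINUUM = {
    "CD34": {"kind": "sigmoid", "lo": 300, "hi": 2, "center": 0.30, "width": 0.08},
    "CD19": {"kind": "sigmoid", "lo": 20, "hi": 300, "center": 0.25, "width": 0.08},
    "CD10": {"kind": "sigmoid", "lo": 200, "hi": 5, "center": 0.80, "width": 0.06},
    "CD20": {"kind": "sigmoid", "lo": 2, "hi": 300, "center": 0.75, "width": 0.08},
    "IgM": {"kind": "sigmoid", "lo": 2, "hi": 250, "center": 0.60, "width": 0.05},
    "BRU": {"kind": "bump", "base": 40, "amp": 300, "center": 0.75, "width": 0.08},
    "pS6": {"kind": "sigmoid", "lo": 10, "hi": 80, "center": 0.62, "width": 0.05},
}

#: Markers used to order the B lineage in pseudotime (construction channels).
B_TRAJECTORY_CHANNELS = ["CD34", "CD19", "CD10", "CD20", "IgM"]


def _marrow_design(seed: int, n_events: int = 100_000) -> ExperimentDesign:
    """Healthy bone-marrow hierarchy: 13 populations incl. a B-cell continuum.

    Erythroid precursors are high in all three biosynthesis channels; plasma
    cells combine high protein synthesis and rRNA with background de novo
    RNA synthesis; progenitors run hotter than HSCs.
    """
    panel = [
        ChannelDef("CD45", "Y89", "phenotype"),
        ChannelDef("CD34", "Nd148", "phenotype"),
        ChannelDef("CD38", "Er167", "phenotype"),
        ChannelDef("CD19", "Nd144", "phenotype"),
        ChannelDef("CD20", "Dy163", "phenotype"),
        ChannelDef("CD10", "Gd156", "phenotype"),
        ChannelDef("IgM", "Yb171", "phenotype"),
        ChannelDef("CD3", "Nd143", "phenotype"),
        ChannelDef("CD56", "Yb176", "phenotype"),
        ChannelDef("CD14", "Sm147", "phenotype"),
        ChannelDef("CD235", "Pr141", "phenotype"),
        ChannelDef("CD123", "Eu151b", "phenotype"),
        ChannelDef("rRNA", "Ir193", "phenotype"),
        ChannelDef("pS6", "Yb172", "signaling"),
        *_biosynthesis_channels(),
        *_viability_channels(),
        *_bead_channels(),
    ]
    b_lineage = PopulationSpec(
        name="B_lineage",
        frequency=0.15,
        channel_medians={
            "CD45": 300, "CD38": 100, "CD3": 2, "CD56": 2, "CD14": 2,
            "CD235": 2, "CD123": 2, "rRNA": 100, "IdU": 1, "Puromycin": 180,
            "Cisplatin": 2, "cCaspase3": 2,
        },
        idu_positive_fraction=0.10,
        continuum=dict(B_CONTINUUM),
    )
    populations = [
        _marrow_population("HSC", 0.02, {"CD34": 300}, bru=60, puro=60, idu=0.01),
        _marrow_population("MPP", 0.03, {"CD34": 300, "CD38": 60}, bru=80, puro=120, idu=0.03),
        _marrow_population("CMP", 0.04, {"CD34": 300, "CD38": 300}, bru=100, puro=150, idu=0.08),
        _marrow_population(
            "GMP", 0.05, {"CD34": 300, "CD38": 300, "CD123": 150}, bru=100, puro=180, idu=0.10
        ),
        _marrow_population(
            "MEP", 0.03, {"CD34": 300, "CD38": 300, "CD235": 60}, bru=150, puro=180, idu=0.12
        ),
        _marrow_population(
            "Ery_early", 0.07, {"CD235": 300, "CD45": 30}, bru=400, puro=400, idu=0.35, rrna=300
        ),
        _marrow_population(
            "Ery_late", 0.08, {"CD235": 300, "CD45": 10}, bru=150, puro=200, idu=0.15
        ),
        b_lineage,
        _marrow_population(
            "Plasma", 0.03, {"CD19": 60, "CD38": 400}, bru=2, puro=500, rrna=400
        ),
        _marrow_population("NK", 0.08, {"CD56": 300}, bru=30, puro=150),
        _marrow_population("Tcell", 0.25, {"CD3": 300}, bru=20, puro=100, idu=0.002),
        _marrow_population("Monocyte", 0.14, {"CD14": 300}, bru=80, puro=300, idu=0.01),
        _marrow_population("pDC", 0.03, {"CD123": 300}, bru=100, puro=200),
    ]
    return ExperimentDesign(
        panel=panel,
        populations=populations,
        n_events=n_events,
        dead_fraction=0.04,
        apoptotic_fraction=0.02,
        bead_fraction=0.02,
        seed=seed,
    )


SCENARIOS = {
    "cellcycle": _cellcycle_design,
    "pbmc_timecourse": _pbmc_design,
    "marrow_hierarchy": _marrow_design,
}


def make_scenario(name: str, seed: int = 0, **overrides) -> ExperimentDesign:
    """Build a fully parameterized design for a named study scenario."""
    try:
        builder = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid scenarios: {sorted(SCENARIOS)}"
        ) from None
    return builder(seed=seed, **overrides)
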