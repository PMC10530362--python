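"""Seeded synthetic electrophysiology data with the structure of the
published AAQ/QAQ experiments.

Generates per-cell inhibition-ratio tables over voltage or concentration
grids (additive Gaussian noise on the ratio, clipped to (0.01, 1.2]),
per-condition mean/SD/n summaries, and noisy current traces driven by the
kinetic simulator.  Ships a transcription of the published parameter values
as named presets ("compound/receptor/illumination") so every stage of the
package is exercisable without any recording on disk.

The generator emulates the *statistical shape* of the measurements —
5–7 cells per condition, ratio SDs of 0.02–0.08, voltage grids from +20 to
−140 mV, half-log concentration series in 1–500 µM — not the biophysics of
a patch-clamp rig (no series-resistance or junction-potential artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics
from .models import (
    BlockParams,
    HillParams,
    ThermoContext,
    hill_ratio,
    ratio_eq1,
    ratio_eq2,
    ratio_eq3,
)

__all__ = [
    "Preset",
    "GeneratorConfig",
    "TraceOptions",
    "GeneratedRatios",
    "presets",
    "preset",
    "preset_names",
    "gen_voltage_dataset",
    "gen_concentration_dataset",
    "gen_trace",
    "summarize_cells",
    "DEFAULT_VOLTAGE_GRID",
    "DEFAULT_CONCENTRATION_GRID",
]

#: +20 … −140 mV in 20 mV steps, the scanned holding-potential range.
DEFAULT_VOLTAGE_GRID = tuple(range(20, -141, -20))
#: Half-log series spanning the 1–500 µM working range.
DEFAULT_CONCENTRATION_GRID = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 500.0)
#: Standard holding potential for concentration-response experiments.
DEFAULT_HOLDING_MV = -70.0


@dataclass(frozen=True)
class Preset:
    """One named reference parameter set or reference observation.

    ``kind`` is "hill" (IC50/slope), "block" (voltage-model parameters) or
    "point" (a single published ratio observation).  ``source`` is a
    human-readable provenance note; "reported" marks directly published
    values, "derived" marks values computed here from published anchors,
    "calibrated" marks values chosen to satisfy published constraints.
    """

    name: str
    compound: str
    receptor: str
    illumination: str
    kind: str
    source: str
    hill: HillParams | None = None
    ic50_sd: float | None = None
    block: BlockParams | None = None
    observation: dict | None = None


def _hill(name, ic50, sd, source="reported concentration-response fit"):
    compound, receptor, illum = name.split("/")
    return Preset(name=name, compound=compound, receptor=receptor,
                  illumination=illum, kind="hill", source=source,
                  hill=HillParams(ic50=ic50, hill_n=1.0), ic50_sd=sd)


def _block(name, params, source):
    compound, receptor, illum = name.split("/")
    return Preset(name=name, compound=compound, receptor=receptor,
                  illumination=illum, kind="block", source=source, block=params)


def _point(name, voltage, conc, ratio, sd, n, source="reported single-condition ratio"):
    compound, receptor, illum = name.split("/")
    return Preset(
        name=name, compound=compound, receptor=receptor, illumination=illum,
        kind="point", source=source,
        observation={"voltage_mV": voltage, "concentration_uM": conc,
                     "ratio": ratio, "sd": sd, "n_cells": n},
    )


# Single-site K_b values for the NMDA voltage presets are derived exactly
# from the published single-concentration anchors (30 µM): ratio 0.26 at
# −120 mV for QAQ (z = 2) and 0.31 for AAQ (z = 1), with the consensus
# delta_b = 0.18 at 296 K.  Illuminated K_b scales by the IC50 shift
# (parallel-shift interpretation: light changes affinity, not depth).
_KB_QAQ_NMDA = 57.33213007825109
_KB_AAQ_NMDA = 31.43413073789602

_PRESETS: tuple[Preset, ...] = (
    # --- concentration-response (Hill) parameters, NMDA ---
    _hill("AAQ/NMDA/dark", 19.0, 1.4),
    _hill("QAQ/NMDA/dark", 18.6, 1.0),
    _hill("AAQ/NMDA/380nm", 68.4, 7.2),
    _hill("QAQ/NMDA/380nm", 48.2, 7.7),
    # --- concentration-response, calcium-permeable AMPA ---
    _hill("AAQ/CP-AMPA/dark", 28.5, 1.1),
    _hill("QAQ/CP-AMPA/dark", 17.0, 2.0),
    _hill("AAQ/CP-AMPA/380nm", 107.2, 20.6),
    _hill("QAQ/CP-AMPA/380nm", 55.4, 1.17),
    # --- voltage-block parameters, NMDA (impermeant single site) ---
    _block("QAQ/NMDA/dark",
           BlockParams(K_b=_KB_QAQ_NMDA, delta_b=0.18, z=2),
           "reported delta_b; K_b derived from the 30 uM, -120 mV anchor"),
    _block("AAQ/NMDA/dark",
           BlockParams(K_b=_KB_AAQ_NMDA, delta_b=0.18, z=1),
           "reported delta_b; K_b derived from the 30 uM, -120 mV anchor"),
    _block("QAQ/NMDA/380nm",
           BlockParams(K_b=_KB_QAQ_NMDA * 48.2 / 18.6, delta_b=0.18, z=2),
           "derived: dark K_b scaled by the illuminated/dark IC50 ratio"),
    _block("AAQ/NMDA/380nm",
           BlockParams(K_b=_KB_AAQ_NMDA * 68.4 / 19.0, delta_b=0.18, z=1),
           "derived: dark K_b scaled by the illuminated/dark IC50 ratio"),
    # --- voltage-block parameters, calcium-permeable AMPA (permeant,
    #     two sites).  delta values reported; K_b/K_p/K_vin calibrated so
    #     the curves show the published phenomenology: ~15-20% residual
    #     inhibition at +20 mV (K_vin = 150 uM at 30 uM drug), relief of
    #     block negative to -70 mV for QAQ (V* ~ -80 mV) and only beyond
    #     the scanned range for AAQ (V* ~ -120 mV), potency at -70 mV
    #     consistent with the dark IC50s. ---
    _block("QAQ/CP-AMPA/dark",
           BlockParams(K_b=310.0, delta_b=0.70, K_p=7.0, delta_p=0.15,
                       K_vin=150.0, z=2),
           "reported delta_b=0.70, delta_p=0.15; K's calibrated to the "
           "published residual, relief and potency constraints"),
    _block("AAQ/CP-AMPA/dark",
           BlockParams(K_b=280.0, delta_b=0.90, K_p=12.0, delta_p=0.15,
                       K_vin=150.0, z=1),
           "reported delta_b=0.90, delta_p=0.15; K's calibrated to the "
           "published residual, relief and potency constraints"),
    _block("QAQ/CP-AMPA/380nm",
           BlockParams(K_b=310.0 * 55.4 / 17.0, delta_b=0.70,
                       K_p=7.0 * 55.4 / 17.0, delta_p=0.15, K_vin=150.0, z=2),
           "derived: dark K_b, K_p scaled by the illuminated/dark IC50 ratio"),
    _block("AAQ/CP-AMPA/380nm",
           BlockParams(K_b=280.0 * 107.2 / 28.5, delta_b=0.90,
                       K_p=12.0 * 107.2 / 28.5, delta_p=0.15, K_vin=150.0, z=1),
           "derived: dark K_b, K_p scaled by the illuminated/dark IC50 ratio"),
    # --- published single-condition reference ratios ---
    _point("QAQ/NMDA-m120/dark", -120.0, 30.0, 0.26, 0.06, 6),
    _point("QAQ/NMDA-m20/dark", -20.0, 30.0, 0.62, 0.08, 6),
    _point("AAQ/NMDA-m120/dark", -120.0, 30.0, 0.31, 0.04, 6),
    _point("AAQ/NMDA-m20/dark", -20.0, 30.0, 0.46, 0.07, 6),
    _point("AAQ/CI-AMPA-30uM/dark", -70.0, 30.0, 0.77, 0.05, 5),
    _point("QAQ/CI-AMPA-30uM/dark", -70.0, 30.0, 0.89, 0.05, 7),
    _point("AAQ/CI-AMPA-100uM/dark", -70.0, 100.0, 0.43, 0.06, 5),
    _point("QAQ/CI-AMPA-300uM/dark", -70.0, 300.0, 0.61, 0.02, 5),
)


def presets() -> list[Preset]:
    """All named reference presets (parameter sets and point observations)."""
    return list(_PRESETS)


def preset_names(kind: str | None = None) -> list[str]:
    return [p.name for p in _PRESETS if kind is None or p.kind == kind]


def _normalize(name: str) -> str:
    return name.strip().lower().replace("_", "/").replace("-", "/")


def preset(name: str, kind: str | None = None) -> Preset:
    """Look up a preset by name (separator- and case-insensitive)."""
    wanted = _normalize(name)
    matches = [
        p for p in _PRESETS
        if _normalize(p.name) == wanted and (kind is None or p.kind == kind)
    ]
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        kinds = sorted(p.kind for p in matches)
        raise KeyError(
            f"preset name {name!r} is ambiguous across kinds {kinds}; pass kind="
        )
    available = ", ".join(preset_names(kind))
    raise KeyError(f"unknown preset {name!r}; available: {available}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions for a synthetic ratio dataset.

    Either a preset name (resolved per mode: "block" presets for voltage
    datasets, "hill" presets for concentration datasets) or explicit
    parameters.  Defaults are the published study conditions: n = 6 cells,
    ratio noise SD 0.05 (mid-range of the reported 0.02–0.08), 30 µM drug
    on the +20…−140 mV grid, −70 mV for concentration series.
    """

    preset: str | None = None
    block_params: BlockParams | None = None
    hill_params: HillParams | None = None
    compound: str = "drug"
    receptor: str = "receptor"
    illumination: str = "dark"
    voltage_grid: tuple = DEFAULT_VOLTAGE_GRID
    concentration_uM: float = 30.0
    concentration_grid: tuple = DEFAULT_CONCENTRATION_GRID
    holding_mV: float = DEFAULT_HOLDING_MV
    n_cells: int = 6
    noise_sd: float = 0.05
    seed: int = 0
    temperature: float = 296.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if len(self.voltage_grid) == 0 or len(self.concentration_grid) == 0:
            raise ValueError("voltage and concentration grids must be non-empty")

    def resolve_block(self) -> tuple[BlockParams, str, str, str]:
        if self.block_params is not None:
            return self.block_params, self.compound, self.receptor, self.illumination
        if self.preset is None:
            raise ValueError("need a preset name or explicit block_params")
        p = preset(self.preset, kind="block")
        return p.block, p.compound, p.receptor, p.illumination

    def resolve_hill(self) -> tuple[HillParams, str, str, str]:
        if self.hill_params is not None:
            return self.hill_params, self.compound, self.receptor, self.illumination
        if self.preset is None:
            raise ValueError("need a preset name or explicit hill_params")
        p = preset(self.preset, kind="hill")
        return p.hill, p.compound, p.receptor, p.illumination


@dataclass(frozen=True)
class GeneratedRatios:
    """Per-cell observations plus the per-condition mean/SD/n summary."""

    cells: pd.DataFrame
    summary: pd.DataFrame


_CLIP_LO, _CLIP_HI = 0.01, 1.2


def summarize_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-cell rows to per-condition mean ratio, SD and n."""
    keys = ["compound", "receptor", "illumination", "voltage_mV", "concentration_uM"]
    g = cells.groupby(keys, sort=False)["ratio"]
    out = g.agg(ratio="mean", sd="std", n_cells="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


def _assemble(clean: np.ndarray, grid_cols: dict, cfg: GeneratorConfig,
              compound: str, receptor: str, illumination: str) -> GeneratedRatios:
    rng = np.random.default_rng(cfg.seed)
    n_cond = len(clean)
    rows = []
    for cell in range(1, cfg.n_cells + 1):
        noisy = clean + rng.normal(0.0, cfg.noise_sd, size=n_cond) if cfg.noise_sd > 0 else clean.copy()
        noisy = np.clip(noisy, _CLIP_LO, _CLIP_HI)
        df = pd.DataFrame(grid_cols)
        df.insert(0, "illumination", illumination)
        df.insert(0, "receptor", receptor)
        df.insert(0, "compound", compound)
        df["cell"] = cell
        df["ratio"] = noisy
        rows.append(df)
    cells = pd.concat(rows, ignore_index=True)
    return GeneratedRatios(cells=cells, summary=summarize_cells(cells))


def _block_model_values(params: BlockParams, C, V, thermo: ThermoContext) -> np.ndarray:
    if params.K_vin is not None:
        return np.asarray(ratio_eq3(C, V, params, thermo))
    if params.K_p > 0:
        return np.asarray(ratio_eq2(C, V, params, thermo))
    return np.asarray(ratio_eq1(C, V, params, thermo))


def gen_voltage_dataset(cfg: GeneratorConfig) -> GeneratedRatios:
    """Per-cell ratio observations over the voltage grid at one concentration.

    The clean curve is the closed-form block model implied by the
    parameters (two-site when K_vin is set, permeant when K_p > 0, else
    single-site); per-cell noise is additive Gaussian, i.i.d. across
    voltages, clipped to (0.01, 1.2].  Identical seed, identical table.
    """
    params, compound, receptor, illumination = cfg.resolve_block()
    thermo = ThermoContext(cfg.temperature)
    V = np.asarray(cfg.voltage_grid, dtype=float)
    C = np.full_like(V, cfg.concentration_uM)
    clean = _block_model_values(params, C, V, thermo)
    grid_cols = {"voltage_mV": V, "concentration_uM": C}
    return _assemble(clean, grid_cols, cfg, compound, receptor, illumination)


def gen_concentration_dataset(cfg: GeneratorConfig) -> GeneratedRatios:
    """Per-cell ratio observations over the concentration grid at fixed V.

    Uses the Hill model at the standard −70 mV holding potential.
    """
    params, compound, receptor, illumination = cfg.resolve_hill()
    C = np.asarray(cfg.concentration_grid, dtype=float)
    clean = np.asarray(hill_ratio(C, params))
    grid_cols = {
        "voltage_mV": np.full_like(C, cfg.holding_mV),
        "concentration_uM": C,
    }
    return _assemble(clean, grid_cols, cfg, compound, receptor, illumination)


@dataclass(frozen=True)
class TraceOptions:
    """Sampling and noise model for synthetic current traces."""

    sample_rate_hz: float = 1000.0
    noise_sd: float = 0.0        # additive Gaussian, current units
    drift_per_s: float = 0.0     # linear baseline drift, current units / s

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_trace(
    protocol: kinetics.Protocol,
    scheme: kinetics.KineticScheme,
    options: TraceOptions = TraceOptions(),
    seed: int = 0,
    thermo: ThermoContext = ThermoContext(),
) -> pd.DataFrame:
    """Noisy current trace for a protocol: simulate, add noise and drift.

    Returns a DataFrame with time_s, segment, current_clean and current
    columns; with zero noise and drift, ``current`` equals the simulator
    output exactly.  Deterministic given the seed.
    """
    dt = 1.0 / options.sample_rate_hz
    tc = kinetics.simulate(scheme, protocol, dt=dt, thermo=thermo)
    rng = np.random.default_rng(seed)
    current = tc.current.copy()
    if options.drift_per_s != 0.0:
        current = current + options.drift_per_s * tc.time
    if options.noise_sd > 0:
        current = current + rng.normal(0.0, options.noise_sd, size=len(current))
    return pd.DataFrame({
        "time_s": tc.time,
        "segment": tc.segment_index,
        "current_clean": tc.current,
        "current": current,
    })
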