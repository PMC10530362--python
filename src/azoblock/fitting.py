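"""Parameter estimation for the voltage- and concentration-block models.

Weighted nonlinear least squares (weights 1/sd^2 when per-condition SDs are
available) with seeded multi-start over log-uniform K draws, exact two-point
inversion of the single-site model, joint dark/illuminated fits sharing the
electrical depths, case-resampling bootstrap intervals, and AICc model
selection.

Input tables are pandas DataFrames with columns ``voltage_mV``,
``concentration_uM``, ``ratio`` and optionally ``sd``, ``n_cells``,
``cell`` (schema of :mod:`azoblock.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

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
    "FitResult",
    "JointFitResult",
    "UnderdeterminedError",
    "DEFAULT_BOUNDS",
    "fit_voltage_curve",
    "two_point_delta",
    "fit_concentration_curve",
    "joint_fit_dark_light",
    "bootstrap_ci",
    "select_model",
    "aicc",
]


class UnderdeterminedError(ValueError):
    """Fewer informative observations than free parameters."""


#: Default box bounds for the optimizer: K's in uM, depths dimensionless.
DEFAULT_BOUNDS = {
    "K_b": (1e-2, 1e5),
    "K_p": (0.0, 1e5),
    "K_vin": (1e-2, 1e5),
    "delta_b": (0.0, 1.0),
    "delta_p": (0.0, 1.0),
    "ic50": (1e-2, 1e5),
    "hill_n": (0.05, 10.0),
}

_MODEL_FREE = {
    "eq1": ("K_b", "delta_b"),
    "eq2": ("K_b", "delta_b", "K_p", "delta_p"),
    "eq3": ("K_b", "delta_b", "K_p", "delta_p", "K_vin"),
    "hill": ("ic50", "hill_n"),
}


def aicc(weighted_ssr: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for a least-squares fit.

    Gaussian log-likelihood up to a constant: n ln(SSR/n) + 2k + correction.
    Returns +inf when the correction denominator n - k - 1 is not positive.
    """
    if n - k - 1 <= 0:
        return math.inf
    ssr = max(weighted_ssr, 1e-300)
    return n * math.log(ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    """Estimates, uncertainties and model-selection metadata for one fit."""

    model: str
    estimates: dict
    stderr: dict
    objective: float          # weighted SSR at the optimum
    ndata: int
    nvary: int
    aicc: float
    fixed: dict
    success: bool
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)
    bootstrap: dict | None = None   # name -> (2.5, 97.5) percentiles

    def block_params(self, z: int) -> BlockParams:
        e = self.estimates
        return BlockParams(
            K_b=e["K_b"], delta_b=e["delta_b"],
            K_p=e.get("K_p", 0.0), delta_p=e.get("delta_p", 0.0),
            K_vin=e.get("K_vin"), z=z,
        )

    def hill_params(self) -> HillParams:
        return HillParams(ic50=self.estimates["ic50"], hill_n=self.estimates["hill_n"])

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": self.estimates,
            "stderr": self.stderr,
            "objective": self.objective,
            "ndata": self.ndata,
            "nvary": self.nvary,
            "aicc": self.aicc,
            "fixed": self.fixed,
            "success": self.success,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
            "bootstrap": self.bootstrap,
        }


@dataclass
class JointFitResult:
    """Shared-depth dark/illuminated fit plus the unshared comparison."""

    shared: FitResult
    per_state: dict            # illumination label -> FitResult (unshared)
    aicc_shared: float
    aicc_unshared: float
    residual_trend: dict       # illumination label -> runs-test p-value
    residual_trend_flag: bool


def _weights(df: pd.DataFrame) -> np.ndarray:
    """1/sd^2 weights; unit weights when any sd is missing or zero."""
    if "sd" not in df.columns:
        return np.ones(len(df))
    sd = pd.to_numeric(df["sd"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        return np.ones(len(df))
    return 1.0 / sd**2


def _eval_model(model: str, values: dict, C, V, z: int, thermo: ThermoContext):
    if model == "hill":
        return hill_ratio(C, HillParams(values["ic50"], values["hill_n"]))
    params = BlockParams(
        K_b=values["K_b"], delta_b=values["delta_b"],
        K_p=values.get("K_p", 0.0), delta_p=values.get("delta_p", 0.0),
        K_vin=values.get("K_vin"), z=z,
    )
    fn = {"eq1": ratio_eq1, "eq2": ratio_eq2, "eq3": ratio_eq3}[model]
    return fn(C, V, params, thermo)


def _make_parameters(model: str, fixed: dict | None, bounds: dict | None) -> lmfit.Parameters:
    fixed = fixed or {}
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    pars = lmfit.Parameters()
    for name in _MODEL_FREE[model]:
        lo, hi = bounds[name]
        if name in fixed:
            pars.add(name, value=fixed[name], vary=False)
        else:
            start = math.sqrt(max(lo, 1e-3) * hi) if name.startswith(("K", "ic")) else 0.5 * (lo + hi)
            pars.add(name, value=start, min=lo, max=hi)
    return pars


def _draw_start(pars: lmfit.Parameters, rng: np.random.Generator) -> None:
    for name, p in pars.items():
        if not p.vary:
            continue
        if name.startswith(("K", "ic")):
            lo = max(p.min, 1e-3)
            p.value = math.exp(rng.uniform(math.log(lo), math.log(p.max)))
        else:
            p.value = rng.uniform(p.min, p.max)


def _minimize_multistart(
    residual, pars: lmfit.Parameters, starts: int, seed: int | None
) -> lmfit.minimizer.MinimizerResult:
    rng = np.random.default_rng(seed)
    best = None
    for i in range(max(starts, 1)):
        trial = pars.copy()
        if i > 0:
            _draw_start(trial, rng)
        try:
            res = lmfit.minimize(residual, trial, method="least_squares")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best


def _result_from(
    model: str, res, ndata: int, fixed: dict, seed: int | None,
    diagnostics: dict | None = None,
) -> FitResult:
    estimates = {k: float(v.value) for k, v in res.params.items()}
    stderr = {
        k: (float(v.stderr) if v.vary and v.stderr is not None else None)
        for k, v in res.params.items()
    }
    nvary = sum(1 for v in res.params.values() if v.vary)
    return FitResult(
        model=model,
        estimates=estimates,
        stderr=stderr,
        objective=float(res.chisqr),
        ndata=ndata,
        nvary=nvary,
        aicc=aicc(float(res.chisqr), ndata, nvary),
        fixed=dict(fixed),
        success=bool(res.success),
        seed=seed,
        diagnostics=diagnostics or {},
    )


def fit_voltage_curve(
    data: pd.DataFrame,
    model: str = "eq1",
    z: int = 1,
    fixed: dict | None = None,
    bounds: dict | None = None,
    starts: int = 20,
    seed: int | None = 0,
    thermo: ThermoContext = ThermoContext(),
) -> FitResult:
    """Weighted least-squares fit of a block model to ratio-vs-voltage data.

    ``model`` is one of eq1 (impermeant single site), eq2 (permeant) or
    eq3 (permeant plus independent voltage-insensitive site); the blocker
    charge ``z`` is fixed from chemistry, never fitted.  ``fixed`` pins
    named parameters; the best of ``starts`` seeded multi-starts is
    returned.
    """
    if model not in ("eq1", "eq2", "eq3"):
        raise ValueError(f"unknown voltage model {model!r}")
    fixed = fixed or {}
    C = data["concentration_uM"].to_numpy(dtype=float)
    V = data["voltage_mV"].to_numpy(dtype=float)
    y = data["ratio"].to_numpy(dtype=float)
    w = np.sqrt(_weights(data))
    free = [n for n in _MODEL_FREE[model] if n not in fixed]
    informative = np.unique(np.c_[C, V], axis=0).shape[0]
    if informative < len(free):
        raise UnderdeterminedError(
            f"{informative} informative (C, V) conditions cannot determine "
            f"free parameters {free} of model {model}"
        )
    pars = _make_parameters(model, fixed, bounds)

    def residual(p):
        return (np.asarray(_eval_model(model, p.valuesdict(), C, V, z, thermo)) - y) * w

    res = _minimize_multistart(residual, pars, starts, seed)
    out = _result_from(model, res, len(y), fixed, seed)
    out.diagnostics["z"] = z
    return out


def two_point_delta(
    ratio1: float,
    V1: float,
    ratio2: float,
    V2: float,
    z: int,
    thermo: ThermoContext = ThermoContext(),
) -> tuple[float, float]:
    """Exact inversion of the single-site model from two observations.

    With B(V) = 1/ratio - 1 = (C/K_b) e^{-z delta_b V / Vt}:

        delta_b = -(RT/F) ln(B1/B2) / (z (V1 - V2)),
        K_b / C  by back-substitution at (ratio1, V1).

    Returns (delta_b, K_b_over_C).  Ratios of exactly 1 (no block) carry
    no information and raise ``ValueError``.
    """
    if V1 == V2:
        raise ValueError("V1 and V2 must differ")
    for r in (ratio1, ratio2):
        if not 0.0 < r < 1.0:
            raise ValueError(f"ratios must lie in (0, 1); got {r} (B = 1/r - 1 undefined or 0)")
    B1 = 1.0 / ratio1 - 1.0
    B2 = 1.0 / ratio2 - 1.0
    delta_b = -thermo.vt_mV * math.log(B1 / B2) / (z * (V1 - V2))
    kb_over_c = math.exp(-z * delta_b * V1 / thermo.vt_mV) / B1
    return delta_b, kb_over_c


def fit_concentration_curve(
    data: pd.DataFrame,
    fixed: dict | None = None,
    bounds: dict | None = None,
    starts: int = 10,
    seed: int | None = 0,
) -> FitResult:
    """Hill fit (IC50, Hill slope) of ratio-vs-concentration data at fixed V.

    Requires at least three distinct concentrations.  When the observed
    ratios do not bracket 0.5 the IC50 is an extrapolation; a
    ``bracket_warning`` is recorded in the diagnostics rather than
    refusing the fit.
    """
    fixed = fixed or {}
    C = data["concentration_uM"].to_numpy(dtype=float)
    y = data["ratio"].to_numpy(dtype=float)
    if np.unique(C).size < 3:
        raise UnderdeterminedError(
            f"need >= 3 distinct concentrations for a Hill fit, got {np.unique(C).size}"
        )
    w = np.sqrt(_weights(data))
    pars = _make_parameters("hill", fixed, bounds)

    def residual(p):
        return (np.asarray(_eval_model("hill", p.valuesdict(), C, None, 1, None)) - y) * w

    res = _minimize_multistart(residual, pars, starts, seed)
    diagnostics = {}
    if y.min() > 0.5 or y.max() < 0.5:
        diagnostics["bracket_warning"] = (
            "observed ratios do not bracket 0.5; IC50 is extrapolated"
        )
    out = _result_from("hill", res, len(y), fixed, seed, diagnostics)
    return out


def _runs_test_p(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs test p-value on residual signs (two-sided)."""
    signs = np.sign(residuals[residuals != 0])
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    n = n1 + n2
    if n1 == 0 or n2 == 0 or n < 4:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    from scipy.stats import norm

    zstat = (runs - mu) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(zstat)))


def joint_fit_dark_light(
    dark: pd.DataFrame,
    light: pd.DataFrame,
    model: str = "eq1",
    z: int = 1,
    share: tuple[str, ...] = ("delta_b", "delta_p"),
    fixed: dict | None = None,
    bounds: dict | None = None,
    starts: int = 20,
    seed: int | None = 0,
    thermo: ThermoContext = ThermoContext(),
) -> JointFitResult:
    """Fit dark and illuminated slices with shared electrical depths.

    Photoisomerization is interpreted as changing site affinity (per-state
    K_b, K_p, K_vin) but not site location (shared delta set).  Returns
    the shared fit, the per-state unshared fits, both total AICc values,
    and a runs-test flag on the shared-fit residuals that signals a
    systematic trend (i.e. genuinely different depths between states).
    """
    if model not in ("eq1", "eq2", "eq3"):
        raise ValueError(f"unknown voltage model {model!r}")
    fixed = fixed or {}
    share = tuple(s for s in share if s in _MODEL_FREE[model])
    slices = {"dark": dark, "light": light}
    arrays = {}
    for lab, df in slices.items():
        arrays[lab] = (
            df["concentration_uM"].to_numpy(dtype=float),
            df["voltage_mV"].to_numpy(dtype=float),
            df["ratio"].to_numpy(dtype=float),
            np.sqrt(_weights(df)),
        )

    bset = {**DEFAULT_BOUNDS, **(bounds or {})}
    pars = lmfit.Parameters()
    for name in _MODEL_FREE[model]:
        lo, hi = bset[name]
        start = math.sqrt(max(lo, 1e-3) * hi) if name.startswith("K") else 0.5 * (lo + hi)
        if name in fixed:
            if name in share:
                pars.add(name, value=fixed[name], vary=False)
            else:
                for lab in slices:
                    pars.add(f"{name}_{lab}", value=fixed[name], vary=False)
        elif name in share:
            pars.add(name, value=start, min=lo, max=hi)
        else:
            for lab in slices:
                pars.add(f"{name}_{lab}", value=start, min=lo, max=hi)

    def values_for(p: lmfit.Parameters, lab: str) -> dict:
        v = p.valuesdict()
        out = {}
        for name in _MODEL_FREE[model]:
            out[name] = v[name] if name in v else v[f"{name}_{lab}"]
        return out

    def residual(p):
        parts = []
        for lab, (C, V, y, w) in arrays.items():
            parts.append((np.asarray(_eval_model(model, values_for(p, lab), C, V, z, thermo)) - y) * w)
        return np.concatenate(parts)

    res = _minimize_multistart(residual, pars, starts, seed)
    ndata = sum(len(a[2]) for a in arrays.values())
    shared_fit = _result_from(model, res, ndata, fixed, seed)
    shared_fit.diagnostics["z"] = z
    shared_fit.diagnostics["shared"] = list(share)

    per_state = {}
    for lab, df in slices.items():
        per_state[lab] = fit_voltage_curve(
            df, model=model, z=z, fixed=fixed, bounds=bounds,
            starts=starts, seed=seed, thermo=thermo,
        )
    aicc_unshared = aicc(
        sum(f.objective for f in per_state.values()),
        ndata,
        sum(f.nvary for f in per_state.values()),
    )

    trend = {}
    for lab, (C, V, y, w) in arrays.items():
        r = (y - np.asarray(_eval_model(model, values_for(res.params, lab), C, V, z, thermo)))
        order = np.argsort(V)
        trend[lab] = _runs_test_p(r[order])
    flag = any(p < 0.05 for p in trend.values())

    return JointFitResult(
        shared=shared_fit,
        per_state=per_state,
        aicc_shared=shared_fit.aicc,
        aicc_unshared=aicc_unshared,
        residual_trend=trend,
        residual_trend_flag=flag,
    )


def _resample(data: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Case-resampling: over cells when cell ids are present, else rows."""
    if "cell" in data.columns:
        cells = data["cell"].unique()
        picked = rng.choice(cells, size=len(cells), replace=True)
        parts = [data[data["cell"] == c] for c in picked]
        return pd.concat(parts, ignore_index=True)
    idx = rng.integers(0, len(data), size=len(data))
    return data.iloc[idx].reset_index(drop=True)


def bootstrap_ci(
    data: pd.DataFrame,
    model: str = "eq1",
    n_boot: int = 200,
    seed: int = 0,
    z: int = 1,
    fixed: dict | None = None,
    bounds: dict | None = None,
    starts: int = 10,
    thermo: ThermoContext = ThermoContext(),
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> FitResult:
    """Case-resampling bootstrap percentile intervals for a model fit.

    Fits the full data first (multi-start), then refits ``n_boot``
    resampled datasets starting from the point estimate.  Replicates
    with too few informative conditions or failed optimizations are
    skipped and counted in the diagnostics.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    if model == "hill":
        base = fit_concentration_curve(data, fixed=fixed, bounds=bounds,
                                       starts=starts, seed=seed)
    else:
        base = fit_voltage_curve(data, model=model, z=z, fixed=fixed, bounds=bounds,
                                 starts=starts, seed=seed, thermo=thermo)
    free = [n for n in _MODEL_FREE[model] if n not in (fixed or {})]
    draws: dict[str, list[float]] = {n: [] for n in free}
    skipped = 0
    warm = {n: base.estimates[n] for n in free}
    for _ in range(n_boot):
        sample = _resample(data, rng)
        try:
            if model == "hill":
                rep = fit_concentration_curve(
                    sample, fixed={**(fixed or {})}, bounds=bounds, starts=1, seed=None)
            else:
                rep = _refit_warm(sample, model, z, fixed, bounds, warm, thermo)
        except (UnderdeterminedError, RuntimeError):
            skipped += 1
            continue
        for n in free:
            draws[n].append(rep.estimates[n])
    out = FitResult(**{**base.__dict__})
    out.bootstrap = {
        n: (
            float(np.percentile(draws[n], percentiles[0])),
            float(np.percentile(draws[n], percentiles[1])),
        )
        for n in free
        if draws[n]
    }
    out.diagnostics = {
        **base.diagnostics,
        "n_boot": n_boot,
        "n_skipped": skipped,
        "bootstrap_seed": seed,
    }
    return out


def _refit_warm(
    sample: pd.DataFrame, model: str, z: int, fixed: dict | None,
    bounds: dict | None, warm: dict, thermo: ThermoContext,
) -> FitResult:
    """Single-start refit from a warm start (bootstrap replicate path)."""
    fixed = fixed or {}
    C = sample["concentration_uM"].to_numpy(dtype=float)
    V = sample["voltage_mV"].to_numpy(dtype=float)
    y = sample["ratio"].to_numpy(dtype=float)
    w = np.sqrt(_weights(sample))
    free = [n for n in _MODEL_FREE[model] if n not in fixed]
    if np.unique(np.c_[C, V], axis=0).shape[0] < len(free):
        raise UnderdeterminedError("resample has too few informative conditions")
    pars = _make_parameters(model, fixed, bounds)
    for n, v in warm.items():
        pars[n].value = float(np.clip(v, pars[n].min + 1e-12, pars[n].max - 1e-12))

    def residual(p):
        return (np.asarray(_eval_model(model, p.valuesdict(), C, V, z, thermo)) - y) * w

    res = lmfit.minimize(residual, pars, method="least_squares")
    return _result_from(model, res, len(y), fixed, None)


def select_model(
    data: pd.DataFrame,
    candidates: tuple[str, ...] = ("eq1", "eq3"),
    z: int = 1,
    fixed: dict | None = None,
    bounds: dict | None = None,
    starts: int = 20,
    seed: int | None = 0,
    thermo: ThermoContext = ThermoContext(),
) -> list[FitResult]:
    """Fit each candidate model and rank by AICc (ties -> fewer parameters).

    Candidates that are underdetermined on the slice receive AICc = +inf
    (recorded in the diagnostics), so on uninformative data the ranking
    degenerates to preferring the smaller model.
    """
    results = []
    for model in candidates:
        try:
            fr = fit_voltage_curve(data, model=model, z=z, fixed=fixed, bounds=bounds,
                                   starts=starts, seed=seed, thermo=thermo)
        except UnderdeterminedError as exc:
            fr = FitResult(
                model=model, estimates={}, stderr={}, objective=math.inf,
                ndata=len(data), nvary=len(_MODEL_FREE[model]), aicc=math.inf,
                fixed=dict(fixed or {}), success=False, seed=seed,
                diagnostics={"underdetermined": str(exc)},
            )
        results.append(fr)
    results.sort(key=lambda r: (r.aicc, r.nvary))
    return results
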