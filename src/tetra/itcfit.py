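"""Weighted least-squares fitting of binding models to titration isotherms.

Dissociation constants are optimized on a log10 scale (they span nM to mM),
enthalpies linearly. The objective is the weighted residual sum of squares
between observed and forward-simulated per-injection heats; the first
injection is excluded by default (the usual small-purge anomaly). A
deterministic multistart (perturbed log-Kd / dH starting points drawn from a
seeded generator) replaces the interactive refit loops of commercial ITC
software.

Identifiability: a step with c = M0 / Kd above ~1000 produces a near-vertical
transition whose Kd is bounded but not point-identified under noise; such
steps are flagged ``bounded_only`` in the fit diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .itc import (
    BindingModel,
    ITCError,
    Isotherm,
    ThermoStep,
    TitrationScheme,
    simulate_isotherm,
    thermo_decompose,
)

C_STEEP = 1000.0  # c-value above which Kd is flagged bounded-only


class FitError(RuntimeError):
    pass


@dataclass
class ParamSpec:
    name: str  # "kd1", "dh1", ..., "n_sites"
    init: float
    lower: float = -np.inf
    upper: float = np.inf
    fixed: bool = False

    def __post_init__(self) -> None:
        if not (self.lower <= self.init <= self.upper):
            raise FitError(f"{self.name}: init {self.init} outside [{self.lower}, {self.upper}]")


@dataclass
class FitSpec:
    kind: str  # "one_set" | "sequential"
    params: list[ParamSpec]
    exclude_first_injection: bool = True
    weights: np.ndarray | None = None  # per-usable-injection; unit if None
    multistart: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not any(not p.fixed for p in self.params):
            # all-fixed specs are allowed for forward-RSS evaluation only
            pass

    @classmethod
    def for_model(
        cls,
        model: BindingModel,
        fixed: Sequence[str] = (),
        kd_bounds: tuple[float, float] = (1e-15, 1.0),
        dh_bounds: tuple[float, float] = (-1e5, 1e5),
        **kwargs,
    ) -> "FitSpec":
        """Spec initialized at a model's parameter values."""
        params = []
        for i, (kd, dh) in enumerate(zip(model.kd, model.dh), start=1):
            params.append(ParamSpec(f"kd{i}", kd, *kd_bounds, fixed=f"kd{i}" in fixed))
            params.append(ParamSpec(f"dh{i}", dh, *dh_bounds, fixed=f"dh{i}" in fixed))
        if model.kind == "one_set":
            params.append(ParamSpec("n_sites", model.n_sites, 1e-3, 100.0,
                                    fixed="n_sites" in fixed))
        return cls(model.kind, params, **kwargs)

    def n_steps(self) -> int:
        return sum(1 for p in self.params if p.name.startswith("kd"))

    def to_model(self, values: dict[str, float]) -> BindingModel:
        n = self.n_steps()
        kd = tuple(values[f"kd{i}"] for i in range(1, n + 1))
        dh = tuple(values[f"dh{i}"] for i in range(1, n + 1))
        if self.kind == "one_set":
            return BindingModel.one_set(values.get("n_sites", 1.0), kd[0], dh[0])
        return BindingModel.sequential(tuple(zip(kd, dh)))


@dataclass
class FitResult:
    params: dict[str, float]
    rss: float
    residuals: np.ndarray
    model: BindingModel
    spec: FitSpec
    n_obs: int
    n_free: int
    diagnostics: dict = field(default_factory=dict)
    thermo: list[ThermoStep] = field(default_factory=list)
    uncertainty: dict[str, tuple[float, float]] | None = None

    def aicc(self) -> float:
        """Small-sample Akaike information criterion for RSS-based fits."""
        n, k = self.n_obs, self.n_free
        rss = max(self.rss, 1e-300)
        aic = n * np.log(rss / n) + 2 * k
        corr = 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
        return float(aic + corr)

    def table(self) -> str:
        """Human-readable per-event table of Kd, dG, dH, -TdS."""
        lines = [f"{'event':>6} {'Kd (M)':>12} {'dG':>10} {'dH':>10} {'-TdS':>10}  kJ/mol"]
        for i, step in enumerate(self.thermo, start=1):
            lines.append(
                f"{i:>6} {step.kd:>12.4g} {step.dG:>10.2f} {step.dH:>10.2f} {step.mTdS:>10.2f}"
            )
        return "\n".join(lines)


def _usable(iso: Isotherm, spec: FitSpec) -> tuple[np.ndarray, np.ndarray]:
    q = iso.q_norm
    mask = np.ones(len(q), dtype=bool)
    if spec.exclude_first_injection:
        mask[0] = False
    w = spec.weights if spec.weights is not None else np.ones(mask.sum())
    if len(w) != mask.sum():
        raise FitError("weights must match the number of usable injections")
    return mask, np.sqrt(np.asarray(w, dtype=float))


def _pack(spec: FitSpec) -> tuple[list[ParamSpec], np.ndarray, np.ndarray, np.ndarray]:
    free = [p for p in spec.params if not p.fixed]
    x0, lo, hi = [], [], []
    for p in free:
        if p.name.startswith("kd"):
            x0.append(np.log10(p.init))
            lo.append(np.log10(p.lower) if p.lower > 0 else -18.0)
            hi.append(np.log10(p.upper) if np.isfinite(p.upper) else 3.0)
        else:
            x0.append(p.init)
            lo.append(p.lower)
            hi.append(p.upper)
    return free, np.array(x0), np.array(lo), np.array(hi)


def _unpack(spec: FitSpec, free: list[ParamSpec], x: np.ndarray) -> dict[str, float]:
    values = {p.name: p.init for p in spec.params}
    for p, v in zip(free, x):
        values[p.name] = 10.0 ** v if p.name.startswith("kd") else float(v)
    return values


def fit(iso: Isotherm, scheme: TitrationScheme, spec: FitSpec) -> FitResult:
    """Fit a binding model to an isotherm by bounded least squares.

    Runs ``spec.multistart`` perturbed starting points (deterministic given
    ``spec.seed``) and keeps the best-RSS solution. With every parameter
    fixed, returns the forward-model RSS without optimizing.
    """
    mask, sqrt_w = _usable(iso, spec)
    q_obs = iso.q_norm[mask]
    free, x0, lo, hi = _pack(spec)
    if len(q_obs) < len(free) + 1:
        raise FitError(
            f"need at least {len(free) + 1} usable injections, have {len(q_obs)}"
        )

    def residual(x: np.ndarray) -> np.ndarray:
        values = _unpack(spec, free, x)
        try:
            model = spec.to_model(values)
            sim = simulate_isotherm(scheme, model)
        except ITCError:
            return np.full(len(q_obs), 1e6)
        return sqrt_w * (sim.q_norm[mask] - q_obs)

    if not free:
        res = residual(np.empty(0))
        values = _unpack(spec, free, np.empty(0))
        return _finish(values, res, iso, scheme, spec, free, {"n_starts": 0})

    rng = np.random.default_rng(spec.seed)
    starts = [x0]
    for _ in range(max(0, spec.multistart - 1)):
        jitter = np.array(
            [
                rng.uniform(-1.0, 1.0) if p.name.startswith("kd")
                else p.init * rng.uniform(-0.5, 0.5)
                for p in free
            ]
        )
        starts.append(np.clip(x0 + jitter, lo, hi))

    best = None
    n_converged = 0
    for s in starts:
        try:
            sol = least_squares(
                residual, s, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000,
            )
        except Exception:
            continue
        n_converged += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("no multistart converged")
    values = _unpack(spec, free, best.x)
    return _finish(values, residual(best.x), iso, scheme, spec, free,
                   {"n_starts": len(starts), "n_converged": n_converged,
                    "optimizer_status": int(best.status)})


def _finish(values, res, iso, scheme, spec, free, extra) -> FitResult:
    model = spec.to_model(values)
    m0 = scheme.cell_conc_M
    c_values = [m0 / kd for kd in model.kd]
    diagnostics = {
        "c_values": c_values,
        "bounded_only": [f"kd{i}" for i, c in enumerate(c_values, start=1) if c > C_STEEP],
        **extra,
    }
    thermo = [
        thermo_decompose(kd, dh, scheme.temperature_K)
        for kd, dh in zip(model.kd, model.dh)
    ]
    return FitResult(
        params=values,
        rss=float(np.sum(res**2)),
        residuals=res,
        model=model,
        spec=spec,
        n_obs=len(res),
        n_free=len(free),
        diagnostics=diagnostics,
        thermo=thermo,
    )


def bootstrap_uncertainty(
    iso: Isotherm,
    scheme: TitrationScheme,
    spec: FitSpec,
    n_resamples: int = 200,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap; 2.5/97.5 percentile intervals per free parameter."""
    if n_resamples < 20:
        raise FitError("n_resamples must be >= 20")
    base = fit(iso, scheme, spec)
    mask, _ = _usable(iso, spec)
    sim = simulate_isotherm(scheme, base.model)
    fitted_q = sim.q_norm[mask]
    resid = iso.q_norm[mask] - fitted_q
    rng = np.random.default_rng(seed)
    free_names = [p.name for p in spec.params if not p.fixed]
    draws: dict[str, list[float]] = {n: [] for n in free_names}
    # restart each refit from the base estimate, single start
    refit_spec = replace(
        spec,
        params=[replace(p, init=base.params[p.name]) for p in spec.params],
        multistart=1,
    )
    for _ in range(n_resamples):
        q_new = iso.q_norm.copy()
        q_new[mask] = fitted_q + rng.choice(resid, size=len(resid), replace=True)
        iso_new = Isotherm(iso.molar_ratio, q_new, iso.injection_volumes_ul)
        try:
            r = fit(iso_new, scheme, refit_spec)
        except FitError:
            continue
        for n in free_names:
            draws[n].append(r.params[n])
    intervals = {}
    for n in free_names:
        vals = np.array(draws[n])
        if vals.size == 0:
            raise FitError("all bootstrap refits failed")
        intervals[n] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    return intervals


def model_compare(
    iso: Isotherm, scheme: TitrationScheme, specs: Sequence[FitSpec]
) -> list[tuple[FitSpec, FitResult, float]]:
    """Fit every candidate spec and rank ascending by small-sample AIC.

    Ties keep input order (stable sort).
    """
    if len(specs) < 2:
        raise FitError("need at least 2 candidate specs")
    results = [(spec, fit(iso, scheme, spec)) for spec in specs]
    ranked = sorted(
        ((spec, res, res.aicc()) for spec, res in results), key=lambda t: t[2]
    )
    return ranked
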