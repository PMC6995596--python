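"""Stepwise binding equilibria and titration-isotherm forward model.

The assembly of the FXIII-A2B2 heterotetramer and its calcium-driven
disassembly after thrombin cleavage are both described by stepwise
(sequential) binding schemes:

    M + A <-> MA          (Kd_1, dH_1)
    MA + A <-> MA2        (Kd_2, dH_2)
    [MA2 + A <-> MA3]     (Kd_3, dH_3)

where M is the macromolecule in the calorimeter cell (the FXIII-A2 dimer for
assembly, the cleaved heterotetramer for calcium binding) and A the titrant
from the syringe (FXIII-B monomer, or Ca2+). The ligation-state populations
follow from the binding polynomial

    Phi([A]) = 1 + sum_j beta_j [A]^j,   beta_j = prod_{i<=j} 1/Kd_i,

with [MA_j] = [M]_free * beta_j [A]^j. The classic single-set-of-sites model
(n identical independent sites) is also supported.

Heats are in kJ/mol, concentrations molar, volumes microliter, temperatures
Kelvin. Free energies use the 1 M standard state: dG = R T ln(Kd / 1 M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

R_GAS = 8.314  # J / (mol K)


class ITCError(ValueError):
    pass


def default_injection_volumes(first: float = 0.4, n_rest: int = 19, rest: float = 2.0) -> tuple[float, ...]:
    """MicroCal-class schedule: one small purge injection then equal shots (uL)."""
    return (first,) + (rest,) * n_rest


@dataclass(frozen=True)
class TitrationScheme:
    cell_conc_M: float
    syringe_conc_M: float
    cell_volume_ul: float = 200.0
    injection_volumes_ul: tuple[float, ...] = field(default_factory=default_injection_volumes)
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.cell_conc_M <= 0 or self.syringe_conc_M <= 0:
            raise ITCError("concentrations must be > 0")
        if self.cell_volume_ul <= 0 or any(v <= 0 for v in self.injection_volumes_ul):
            raise ITCError("volumes must be > 0")
        if len(self.injection_volumes_ul) < 2:
            raise ITCError("need at least 2 injections")
        object.__setattr__(self, "injection_volumes_ul", tuple(self.injection_volumes_ul))


@dataclass(frozen=True)
class BindingModel:
    kind: str  # "one_set" | "sequential"
    kd: tuple[float, ...]  # M, one entry per step (one entry for one_set)
    dh: tuple[float, ...]  # kJ/mol, aligned with kd
    n_sites: float = 1.0  # one_set only

    def __post_init__(self) -> None:
        object.__setattr__(self, "kd", tuple(float(k) for k in self.kd))
        object.__setattr__(self, "dh", tuple(float(h) for h in self.dh))
        if self.kind not in ("one_set", "sequential"):
            raise ITCError(f"unknown model kind {self.kind!r}")
        if any(k <= 0 for k in self.kd):
            raise ITCError("Kd must be > 0")
        if len(self.kd) != len(self.dh):
            raise ITCError("kd and dh must align")
        if self.kind == "sequential" and not 1 <= len(self.kd) <= 3:
            raise ITCError("sequential models support 1-3 steps")
        if self.kind == "one_set" and (len(self.kd) != 1 or self.n_sites <= 0):
            raise ITCError("one_set takes a single (Kd, dH) and n_sites > 0")

    @classmethod
    def one_set(cls, n_sites: float, kd: float, dh: float) -> "BindingModel":
        return cls("one_set", (kd,), (dh,), n_sites=n_sites)

    @classmethod
    def sequential(cls, steps: Sequence[tuple[float, float]]) -> "BindingModel":
        kd, dh = zip(*steps)
        return cls("sequential", tuple(kd), tuple(dh))

    @property
    def n_steps(self) -> int:
        return len(self.kd)

    def betas(self) -> np.ndarray:
        """Overall association constants beta_j = prod_{i<=j} 1/Kd_i (sequential)."""
        return np.cumprod(1.0 / np.asarray(self.kd))


def _bound_per_m(a_free: float, model: BindingModel) -> float:
    """Average ligand bound per macromolecule at free ligand a_free."""
    if model.kind == "one_set":
        x = a_free / model.kd[0]
        return model.n_sites * x / (1.0 + x)
    betas = model.betas()
    j = np.arange(1, model.n_steps + 1)
    terms = betas * a_free ** j
    phi = 1.0 + terms.sum()
    return float((j * terms).sum() / phi)


def free_ligand(A_total: float, M_total: float, model: BindingModel) -> float:
    """Free titrant concentration solving the mass balance.

    A_total = [A] + M_total * nu([A]) with nu the bound-per-macromolecule
    function; the left side is strictly increasing in [A], so the root is
    unique and bracketed by [0, A_total]. Solved to machine precision.
    """
    if A_total < 0 or M_total < 0:
        raise ITCError("totals must be >= 0")
    if A_total == 0:
        return 0.0
    if M_total == 0:
        return A_total

    def balance(a: float) -> float:
        return a + M_total * _bound_per_m(a, model) - A_total

    try:
        root = brentq(balance, 0.0, A_total, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    except Exception as exc:
        raise ITCError(
            f"mass balance failed to converge: A_tot={A_total}, M_tot={M_total}, "
            f"f(0)={balance(0.0)}, f(A_tot)={balance(A_total)}"
        ) from exc
    return float(root)


def species(A_free: float, M_total: float, model: BindingModel) -> np.ndarray:
    """Ligation-state concentrations [M, MA, MA2, ...] in M.

    For the single-set model with integer n the states follow the binomial
    site-filling distribution; the sum over states always equals M_total.
    """
    if A_free < 0:
        raise ITCError("A_free must be >= 0")
    if model.kind == "sequential":
        betas = model.betas()
        j = np.arange(1, model.n_steps + 1)
        terms = betas * A_free ** j
    else:
        n = model.n_sites
        if abs(n - round(n)) > 1e-9:
            raise ITCError("species decomposition needs integer n_sites")
        n = int(round(n))
        j = np.arange(1, n + 1)
        terms = np.array([math.comb(n, int(jj)) * (A_free / model.kd[0]) ** jj for jj in j])
    phi = 1.0 + terms.sum()
    m_free = M_total / phi
    return np.concatenate(([m_free], m_free * terms))


@dataclass
class Isotherm:
    """Per-injection normalized heats against cumulative molar ratio."""

    molar_ratio: np.ndarray  # cumulative A/M in cell after each injection
    q_norm: np.ndarray  # kJ per mol of injectant
    injection_volumes_ul: tuple[float, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.q_norm = np.asarray(self.q_norm, dtype=float)
        if not (len(self.molar_ratio) == len(self.q_norm) == len(self.injection_volumes_ul)):
            raise ITCError("isotherm arrays must align with the injection schedule")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ITCError("molar ratio must be strictly increasing")

    @property
    def n_injections(self) -> int:
        return len(self.q_norm)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {
                "injection": np.arange(1, self.n_injections + 1),
                "volume_ul": self.injection_volumes_ul,
                "molar_ratio": self.molar_ratio,
                "q_norm_kJ_per_mol": self.q_norm,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "Isotherm":
        df = pd.read_csv(path).sort_values("injection")
        return cls(
            df["molar_ratio"].to_numpy(),
            df["q_norm_kJ_per_mol"].to_numpy(),
            tuple(df["volume_ul"].to_numpy()),
        )


def _heat_content(A_total: float, M_total: float, model: BindingModel, volume_l: float) -> float:
    """Cell heat content H = V0 * sum_j dH_j * [states with >= j ligands], kJ."""
    a_free = free_ligand(A_total, M_total, model)
    if model.kind == "one_set":
        bound = M_total * _bound_per_m(a_free, model)
        return volume_l * model.dh[0] * bound
    sp = species(a_free, M_total, model)  # [M, MA, MA2, ...]
    total = 0.0
    for jstep in range(1, model.n_steps + 1):
        total += model.dh[jstep - 1] * sp[jstep:].sum()
    return volume_l * total


def simulate_isotherm(
    scheme: TitrationScheme,
    model: BindingModel,
    dilution: str = "displacement",
    dilution_heat: float = 0.0,
) -> Isotherm:
    """Deterministic forward simulation of a titration.

    With the displacement (perfusion) model each injection of volume v
    expels a fraction v/V0 of the cell contents, so prior totals scale by
    (1 - v/V0) while the injectant adds c_syr * v / V0. The reported heat of
    injection i is q_i = H_i - H_{i-1} * (1 - v_i/V0), normalized per mole of
    injected titrant; ``dilution_heat`` (kJ/mol injectant) models a constant
    blank offset. ``dilution="none"`` disables the displacement factor for
    cross-checks against closed forms.
    """
    if dilution not in ("displacement", "none"):
        raise ITCError(f"unknown dilution mode {dilution!r}")
    v0 = scheme.cell_volume_ul
    volume_l = v0 * 1e-6
    m_tot = scheme.cell_conc_M
    a_tot = 0.0
    h_prev = 0.0
    ratios = []
    q_norm = []
    for v in scheme.injection_volumes_ul:
        f = 1.0 - v / v0 if dilution == "displacement" else 1.0
        m_tot *= f
        a_tot = a_tot * f + scheme.syringe_conc_M * (v / v0)
        h_now = _heat_content(a_tot, m_tot, model, volume_l)
        q = h_now - h_prev * f
        moles_injected = scheme.syringe_conc_M * v * 1e-6
        q_norm.append(q / moles_injected + dilution_heat)
        ratios.append(a_tot / m_tot)
        h_prev = h_now
    return Isotherm(
        np.array(ratios),
        np.array(q_norm),
        scheme.injection_volumes_ul,
        metadata={"model": model, "scheme": scheme, "dilution": dilution,
                  "dilution_heat": dilution_heat},
    )


@dataclass(frozen=True)
class ThermoStep:
    """Thermodynamic decomposition of one binding step (kJ/mol)."""

    kd: float  # M
    dG: float
    dH: float
    mTdS: float  # -T dS = dG - dH; positive means entropically unfavorable
    temperature_K: float

    def __post_init__(self) -> None:
        assert abs(self.dG - (self.dH + self.mTdS)) < 1e-9


def thermo_decompose(Kd: float, dH: float, T: float) -> ThermoStep:
    """dG = R T ln(Kd / 1 M); the entropic term follows as dG - dH."""
    if Kd <= 0 or T <= 0:
        raise ITCError("Kd and T must be > 0")
    dG = R_GAS * T * math.log(Kd) / 1000.0  # kJ/mol
    return ThermoStep(kd=Kd, dG=dG, dH=dH, mTdS=dG - dH, temperature_K=T)
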