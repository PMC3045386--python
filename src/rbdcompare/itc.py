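"""Single-site isothermal titration calorimetry: simulation and fitting.

A perfusion-cell titration (VP-ITC geometry) injects ligand X at syringe
concentration X0 into a fixed-volume cell containing macromolecule M.  Each
injection of volume dV displaces an equal volume of cell content, so total
concentrations evolve stepwise:

    M_t  <-  M_t (1 - dV/V0)
    X_t  <-  X_t (1 - dV/V0) + X0 dV/V0

After each injection the 1:1 mass-action equilibrium with n independent sites
per macromolecule gives the complex concentration as the physical root of

    [MX]^2 - (n M_t + X_t + Kd) [MX] + n M_t X_t = 0

and the integrated heat of injection i is

    q_i = dH * V0 * ([MX]_i - [MX]_{i-1} (1 - dV_i/V0)) + q_dil

with a constant per-injection dilution offset q_dil.  The fit estimates
(Kd, n, dH, q_dil) by nonlinear least squares; Kd parameterizes the model
directly (the association constant is available as a derived quantity).

Units: volumes µL, concentrations µM, dH cal/mol, heats µcal.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "TitrationDesign",
    "TitrationExperiment",
    "BindingFit",
    "bound_fraction",
    "expected_heats",
    "simulate_titration",
    "fit_single_site",
]


@dataclass(frozen=True)
class TitrationDesign:
    """Cell/syringe concentrations (µM), cell volume and injection schedule (µL)."""

    cell_volume: float = 1400.0
    cell_conc: float = 70.0
    syringe_conc: float = 800.0
    injection_volumes: tuple[float, ...] = tuple([10.0] * 28)
    temperature: float = 25.0

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if len(self.injection_volumes) < 5:
            raise ValueError("at least 5 injections required")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Total (M_t, X_t) in the cell after each injection, µM."""
        m = self.cell_conc
        x = 0.0
        ms, xs = [], []
        for dv in self.injection_volumes:
            f = 1.0 - dv / self.cell_volume
            m *= f
            x = x * f + self.syringe_conc * dv / self.cell_volume
            ms.append(m)
            xs.append(x)
        return np.array(ms), np.array(xs)


@dataclass
class TitrationExperiment:
    """Per-injection integrated heats (µcal) for a design."""

    design: TitrationDesign
    heats: np.ndarray

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.shape != (len(self.design.injection_volumes),):
            raise ValueError("one heat per injection required")

    @property
    def molar_ratio(self) -> np.ndarray:
        m, x = self.design.totals()
        return x / m

    def to_tsv(self) -> str:
        d = self.design
        buf = io.StringIO()
        buf.write(f"# cell_volume_uL\t{d.cell_volume}\n")
        buf.write(f"# cell_conc_uM\t{d.cell_conc}\n")
        buf.write(f"# syringe_conc_uM\t{d.syringe_conc}\n")
        buf.write(f"# temperature_C\t{d.temperature}\n")
        buf.write("injection_volume_uL\theat_ucal\n")
        for dv, q in zip(d.injection_volumes, self.heats):
            buf.write(f"{dv:g}\t{q:.6f}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "TitrationExperiment":
        header: dict[str, float] = {}
        vols, heats = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("\t")
                header[key.strip()] = float(val)
            elif line[0].isdigit() or line[0] in "+-.":
                dv, q = line.split("\t")
                vols.append(float(dv))
                heats.append(float(q))
        design = TitrationDesign(
            cell_volume=header["cell_volume_uL"],
            cell_conc=header["cell_conc_uM"],
            syringe_conc=header["syringe_conc_uM"],
            injection_volumes=tuple(vols),
            temperature=header.get("temperature_C", 25.0),
        )
        return cls(design, np.array(heats))


@dataclass
class BindingFit:
    """Fitted single-site parameters with standard errors."""

    kd: float                 # µM
    n_stoich: float
    dh: float                 # cal/mol
    dilution_offset: float    # µcal / injection
    kd_err: float = math.nan
    n_err: float = math.nan
    dh_err: float = math.nan
    offset_err: float = math.nan
    converged: bool = True
    message: str = ""
    residual_rms: float = math.nan

    @property
    def ka(self) -> float:
        """Association constant, M^-1 (derived from Kd in µM)."""
        return 1.0 / (self.kd * 1e-6)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kd_uM": self.kd,
                "n": self.n_stoich,
                "dH_cal_per_mol": self.dh,
                "dilution_offset_ucal": self.dilution_offset,
                "kd_err": self.kd_err,
                "n_err": self.n_err,
                "dH_err": self.dh_err,
                "offset_err": self.offset_err,
                "converged": self.converged,
                "message": self.message,
            },
            indent=2,
        )


def bound_fraction(total_m, total_x, kd: float, n: float = 1.0):
    """Complex concentration [MX] (µM) at equilibrium.

    Physical root of the quadratic mass-action equation for n independent,
    identical sites; satisfies 0 <= [MX] <= min(n*M_t, X_t).  Accepts scalars
    or arrays for the totals.  The Kd -> 0 limit gives stoichiometric binding.
    """
    total_m = np.asarray(total_m, dtype=float)
    total_x = np.asarray(total_x, dtype=float)
    if np.any(total_m < 0) or np.any(total_x < 0) or kd < 0 or n <= 0:
        raise ValueError("concentrations and Kd must be non-negative, n positive")
    sites = n * total_m
    b = sites + total_x + kd
    # stable form of the smaller quadratic root
    disc = np.sqrt(np.maximum(b * b - 4.0 * sites * total_x, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = np.where(b + disc > 0, 2.0 * sites * total_x / (b + disc), 0.0)
    mx = np.minimum(mx, np.minimum(sites, total_x))
    return mx if mx.ndim else float(mx)


def expected_heats(
    design: TitrationDesign,
    kd: float,
    n: float,
    dh: float,
    dilution_offset: float = 0.0,
) -> np.ndarray:
    """Noiseless per-injection heats (µcal) under the perfusion-cell model."""
    m_tot, x_tot = design.totals()
    mx = bound_fraction(m_tot, x_tot, kd, n)
    heats = np.empty(len(mx))
    mx_prev = 0.0
    for i, dv in enumerate(design.injection_volumes):
        f = 1.0 - dv / design.cell_volume
        # µM * µL * cal/mol = 1e-12 cal = 1e-6 µcal
        heats[i] = dh * (mx[i] - mx_prev * f) * design.cell_volume * 1e-6 + dilution_offset
        mx_prev = mx[i]
    return heats


def simulate_titration(
    design: TitrationDesign,
    kd: float,
    n: float,
    dh: float,
    dilution_offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TitrationExperiment:
    """Simulate one titration: model heats plus i.i.d. Gaussian noise (µcal)."""
    heats = expected_heats(design, kd, n, dh, dilution_offset)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return TitrationExperiment(design, heats)


def _initial_guess(experiment: TitrationExperiment) -> dict[str, float]:
    """Data-driven start values.

    Stoichiometry from the molar ratio at the steepest heat change, dH from
    the first-injection heat against the injected ligand (tight-binding
    approximation), offset from the tail of the titration, Kd from the cell
    concentration (c ~ 5 start).
    """
    d = experiment.design
    q = experiment.heats
    ratio = experiment.molar_ratio
    offset0 = float(np.median(q[-3:]))
    diffs = np.abs(np.diff(q))
    n0 = float(np.clip(ratio[int(np.argmax(diffs))], 0.1, 5.0))
    injected_uM = d.syringe_conc * d.injection_volumes[0] / d.cell_volume
    dh0 = (q[0] - offset0) / (injected_uM * d.cell_volume * 1e-6)
    if not np.isfinite(dh0) or dh0 == 0:
        dh0 = -1000.0
    kd0 = max(d.cell_conc / 5.0, 1e-3)
    return {"kd": kd0, "n": n0, "dh": float(dh0), "offset": offset0}


def fit_single_site(
    experiment: TitrationExperiment,
    exclude_first: bool = False,
) -> BindingFit:
    """Nonlinear least-squares fit of (Kd, n, dH, dilution offset).

    Deterministic given the data and the documented initialization.  On
    failure (or an unidentifiable fit: missing/huge error bars) the result is
    flagged ``converged=False`` with diagnostics rather than raising.
    ``exclude_first`` drops the first injection, a common correction for
    syringe leakage during equilibration.
    """
    d = experiment.design
    mask = np.ones(len(experiment.heats), dtype=bool)
    if exclude_first:
        mask[0] = False
    guess = _initial_guess(experiment)
    params = lmfit.Parameters()
    params.add("kd", value=guess["kd"], min=1e-6, max=1e6)
    params.add("n", value=guess["n"], min=1e-3, max=10.0)
    params.add("dh", value=guess["dh"])
    params.add("offset", value=guess["offset"])

    def residual(p):
        model = expected_heats(d, p["kd"].value, p["n"].value, p["dh"].value,
                               p["offset"].value)
        return (experiment.heats - model)[mask]

    try:
        result = lmfit.minimize(residual, params, method="leastsq")
    except Exception as exc:  # pragma: no cover - lmfit rarely raises here
        g = guess
        return BindingFit(g["kd"], g["n"], g["dh"], g["offset"],
                          converged=False, message=f"fit error: {exc}")
    p = result.params
    errs = [p["kd"].stderr, p["n"].stderr, p["dh"].stderr, p["offset"].stderr]
    identifiable = all(e is not None and np.isfinite(e) for e in errs)
    if identifiable:
        # Kd (or dH) errors larger than the estimate itself mean the curve
        # carries no binding information (e.g. pure offset data)
        identifiable = (p["kd"].stderr < abs(p["kd"].value)
                        and p["dh"].stderr < max(abs(p["dh"].value), 1e-12))
    rms = float(np.sqrt(np.mean(np.asarray(result.residual) ** 2)))
    return BindingFit(
        kd=float(p["kd"].value),
        n_stoich=float(p["n"].value),
        dh=float(p["dh"].value),
        dilution_offset=float(p["offset"].value),
        kd_err=float(p["kd"].stderr) if p["kd"].stderr is not None else math.nan,
        n_err=float(p["n"].stderr) if p["n"].stderr is not None else math.nan,
        dh_err=float(p["dh"].stderr) if p["dh"].stderr is not None else math.nan,
        offset_err=float(p["offset"].stderr) if p["offset"].stderr is not None else math.nan,
        converged=bool(result.success) and identifiable,
        message=str(result.message),
        residual_rms=rms,
    )
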