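"""Quantitative binding layer: Langmuir isotherm fits and electrolyte screening.

The sensor response to a duplex at bulk concentration C follows the Langmuir
adsorption isotherm for independent, identical sites,

    dG(C) = dG_max * C / (K_d + C),

where dG is the normalised conductance change (percent of baseline) and K_d
the equilibrium dissociation constant of the protein-duplex complex (nM).
Affinities of duplex variants are reported relative to a reference as
K_rel = K_d / K_d(ref).

The electrolyte side computes the ionic strength I = 1/2 * sum(c_i * z_i^2)
of the measurement buffer and the Debye-Hueckel screening length

    lambda_D = sqrt(eps_r * eps0 * kB * T / (2 * N_A * e^2 * I)),

which sets how far from the nanowire surface bound charge remains visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants, optimize


@dataclass(frozen=True)
class IonSpecies:
    name: str
    concentration: float  # mol/L
    charge: int


@dataclass(frozen=True)
class BufferSpec:
    """An electrolyte as explicit ionic species (no pH speciation model)."""

    species: tuple[IonSpecies, ...]
    temperature: float = 298.15  # K
    relative_permittivity: float = 78.5

    @property
    def electroneutral(self) -> bool:
        net = sum(s.concentration * s.charge for s in self.species)
        scale = sum(abs(s.concentration * s.charge) for s in self.species) or 1.0
        return abs(net) / scale < 1e-6


def make_buffer(species: list[tuple[str, float, int]], **kw) -> BufferSpec:
    return BufferSpec(tuple(IonSpecies(*s) for s in species), **kw)


#: 0.1x phosphate measurement solution: counter-ions of 240 uM NaH2PO4 +
#: 760 uM Na2HPO4 (pH 7.4); concentrations in mol/L.
PS_01X = make_buffer([
    ("Na+", 1.76e-3, +1),
    ("H2PO4-", 0.24e-3, -1),
    ("HPO4-2", 0.76e-3, -2),
])

#: 1x PBS (138 mM NaCl, 2.7 mM KCl, 8 mM Na2HPO4, 1.5 mM KH2PO4) as ions.
PBS_1X = make_buffer([
    ("Na+", 154e-3, +1),
    ("K+", 4.2e-3, +1),
    ("Cl-", 140.7e-3, -1),
    ("HPO4-2", 8e-3, -2),
    ("H2PO4-", 1.5e-3, -1),
])

BUILTIN_BUFFERS = {"ps_0.1x": PS_01X, "pbs_1x": PBS_1X}


def ionic_strength(buffer: BufferSpec) -> float:
    """Ionic strength I = 1/2 * sum(c_i * z_i^2), in mol/L."""
    for s in buffer.species:
        if s.concentration < 0:
            raise ValueError(f"negative concentration for {s.name}")
    return 0.5 * sum(s.concentration * s.charge**2 for s in buffer.species)


def debye_length(
    ionic_strength_molar: float,
    temperature: float = 298.15,
    relative_permittivity: float = 78.5,
) -> float:
    """Debye-Hueckel screening length in nm for an aqueous electrolyte.

    At 298 K in water this reduces to ~0.304 nm / sqrt(I in mol/L).
    """
    if ionic_strength_molar <= 0:
        raise ValueError("ionic strength must be positive")
    I_per_m3 = ionic_strength_molar * 1000 * constants.N_A  # ions -> number/m^3
    lam = math.sqrt(
        relative_permittivity
        * constants.epsilon_0
        * constants.k
        * temperature
        / (2 * constants.e**2 * I_per_m3)
    )
    return lam * 1e9


def buffer_debye_length(buffer: BufferSpec) -> float:
    """Convenience: screening length of a buffer in nm."""
    return debye_length(
        ionic_strength(buffer), buffer.temperature, buffer.relative_permittivity
    )


@dataclass(frozen=True)
class BindingCurve:
    """Observed (concentration in nM, normalised dG in %) pairs."""

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self):
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses differ in length")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if len(set(self.concentrations)) < 3:
            raise ValueError("need >= 3 distinct concentrations to fit")


@dataclass(frozen=True)
class LangmuirFit:
    """Result of a Langmuir isotherm fit (or a failure report)."""

    K_d: float = float("nan")  # nM
    K_d_stderr: float = float("nan")
    dG_max: float = float("nan")  # %
    dG_max_stderr: float = float("nan")
    dG_max_fixed: bool = False
    residual_ss: float = float("nan")
    ok: bool = True
    message: str = ""


def langmuir_response(C, dG_max: float, K_d: float):
    """Langmuir isotherm dG_max * C / (K_d + C); vectorised over C."""
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    C = np.asarray(C, dtype=float)
    out = dG_max * C / (K_d + C)
    return float(out) if out.ndim == 0 else out


def fit_langmuir(
    curve: BindingCurve,
    fix_dG_max: bool = True,
    saturation_threshold: float = 200.0,
) -> LangmuirFit:
    """Nonlinear least-squares fit of the Langmuir isotherm.

    With ``fix_dG_max`` the saturated response dG_max is pinned to the mean
    response at C >= ``saturation_threshold`` (nM) and only K_d is free; when
    no point reaches the threshold the fit silently falls back to a free
    dG_max.  K_d is fitted as log10(K_d) to enforce positivity; standard
    errors come from the local curvature of the fit.  Initialisation:
    dG_max0 = max response, K_d0 = concentration whose response is nearest
    dG_max0 / 2.  Deterministic for fixed input.
    """
    C = np.asarray(curve.concentrations, dtype=float)
    y = np.asarray(curve.responses, dtype=float)
    if np.allclose(y, 0):
        return LangmuirFit(ok=False, message="all responses are zero; K_d unidentifiable")

    dG_max0 = float(np.max(np.abs(y))) * np.sign(y[np.argmax(np.abs(y))])
    half_idx = int(np.argmin(np.abs(y - dG_max0 / 2)))
    K_d0 = float(C[half_idx]) if C[half_idx] > 0 else float(np.median(C[C > 0]))
    log_kd0 = math.log10(K_d0)

    sat = C >= saturation_threshold
    fixed = fix_dG_max and bool(sat.any())
    try:
        if fixed:
            dG_fixed = float(np.mean(y[sat]))

            def model(c, log_kd):
                return dG_fixed * c / (10.0**log_kd + c)

            popt, pcov = optimize.curve_fit(model, C, y, p0=[log_kd0], maxfev=10000)
            log_kd = popt[0]
            log_kd_se = math.sqrt(abs(pcov[0, 0]))
            dG_max, dG_max_se = dG_fixed, 0.0
        else:

            def model(c, dg, log_kd):
                return dg * c / (10.0**log_kd + c)

            popt, pcov = optimize.curve_fit(
                model, C, y, p0=[dG_max0, log_kd0], maxfev=10000
            )
            dG_max, log_kd = popt
            dG_max_se = math.sqrt(abs(pcov[0, 0]))
            log_kd_se = math.sqrt(abs(pcov[1, 1]))
    except RuntimeError as exc:
        return LangmuirFit(ok=False, message=f"fit did not converge: {exc}")

    K_d = 10.0**log_kd
    # delta method: se(K_d) = K_d * ln(10) * se(log10 K_d)
    K_d_se = K_d * math.log(10) * log_kd_se
    resid = y - dG_max * C / (K_d + C)
    return LangmuirFit(
        K_d=float(K_d),
        K_d_stderr=float(K_d_se),
        dG_max=float(dG_max),
        dG_max_stderr=float(dG_max_se),
        dG_max_fixed=fixed,
        residual_ss=float(np.sum(resid**2)),
    )


@dataclass(frozen=True)
class RelativeAffinity:
    name: str
    K_rel: float


def relative_kd(fits: dict[str, "LangmuirFit | float"], reference: str) -> dict[str, RelativeAffinity]:
    """K_rel = K_d / K_d(reference); the reference maps to exactly 1.

    Accepts a map of names to LangmuirFit objects or bare K_d values.
    """
    if reference not in fits:
        raise KeyError(f"reference {reference!r} not among fits")

    def kd(v):
        return v.K_d if isinstance(v, LangmuirFit) else float(v)

    ref = kd(fits[reference])
    if not ref > 0:
        raise ValueError("reference K_d must be positive")
    out = {}
    for name, v in fits.items():
        out[name] = RelativeAffinity(name, 1.0 if name == reference else kd(v) / ref)
    return out
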