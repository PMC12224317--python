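"""Mass-action kinetics of flavin reoxidation by O2 or cytochrome c.

The oxidative half-reaction of a flavoprotein amine oxidoreductase (FAO)
regenerates oxidized FAD from the hydroquinone (FADH2) produced by substrate
oxidation.  Two alternative oxidant branches are modelled:

* the oxidase branch, a single irreversible bimolecular step

      E.FlH2 + O2  ->  E.Fl_ox + H2O2          (rate constant k_o2)

* the dehydrogenase branch, two sequential, reversible one-electron
  transfers to oxidized cytochrome c, passing through the flavin
  semiquinone

      E.FlH2 + C_ox  <=>  E.FlSQ + C_red       (k1f forward, k1f/K1 reverse)
      E.FlSQ + C_ox  <=>  E.Fl_ox + C_red      (k2f forward, k2f/K2 reverse)

All concentrations are molar and refer to POST-MIX values, i.e. after the
1:1 dilution of a stopped-flow mixer (36 uM enzyme in the tonometer is 18 uM
observed).  Observables are Beer-Lambert sums at 450 nm (flavin oxidation)
or 550 nm (heme reduction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticScheme",
    "MixState",
    "SpectralModel",
    "ConcentrationTrajectory",
    "Trace",
    "SolverError",
    "simulate_mechanism",
    "equilibrium_endpoint",
    "absorbance_trace",
    "estimate_concentration",
]

SPECIES = ("E_FlH2", "E_FlSQ", "E_Flox", "C_ox", "C_red", "O2", "H2O2")

#: concentrations more negative than this (the solver's absolute tolerance)
#: are treated as solver failure; anything in (-_CLIP, 0) is clipped to zero
_CLIP = 1e-12


class SolverError(RuntimeError):
    """Raised when the stiff integrator fails or produces unphysical output."""


@dataclass(frozen=True)
class KineticScheme:
    """Rate constants of the flavin reoxidation mechanism.

    Parameters
    ----------
    k_o2 : float
        Bimolecular rate constant (M^-1 s^-1) of the oxidase branch.
    k1f, k2f : float
        Forward bimolecular rate constants (M^-1 s^-1) of the first and
        second one-electron transfer to cytochrome c.  These are the
        quantities reported as k_ox1^CytC and k_ox2^CytC.
    K1, K2 : float
        Dimensionless equilibrium constants of the two electron-transfer
        steps; the reverse rate constants are ``kif / Ki``.  ``math.inf``
        makes a step irreversible.  The experiments only establish that the
        reaction is reversible (amplitudes titrate with CytC), not the
        magnitude, so these default to 10 and are configuration, not data.
    """

    k_o2: float = 0.0
    k1f: float = 0.0
    k2f: float = 0.0
    K1: float = 10.0
    K2: float = 10.0

    def __post_init__(self) -> None:
        for name in ("k_o2", "k1f", "k2f"):
            v = getattr(self, name)
            if not (v >= 0.0) or math.isinf(v) or math.isnan(v):
                raise ValueError(f"rate constant {name}={v!r} must be finite and >= 0")
        for name in ("K1", "K2"):
            v = getattr(self, name)
            if not (v > 0.0) or math.isnan(v):
                raise ValueError(f"equilibrium constant {name}={v!r} must be > 0")

    @property
    def k1r(self) -> float:
        return 0.0 if math.isinf(self.K1) else self.k1f / self.K1

    @property
    def k2r(self) -> float:
        return 0.0 if math.isinf(self.K2) else self.k2f / self.K2

    @property
    def irreversible(self) -> bool:
        return self.k1r == 0.0 and self.k2r == 0.0


@dataclass(frozen=True)
class MixState:
    """Post-mix concentrations (M) at time zero.

    At most one oxidant branch may be populated per experiment (``o2`` or
    ``c_ox``/``c_red``), matching the anaerobic stopped-flow protocol in
    which CytC reactions are run with O2 purged out.
    """

    e_flh2: float = 0.0
    e_flsq: float = 0.0
    e_flox: float = 0.0
    c_ox: float = 0.0
    c_red: float = 0.0
    o2: float = 0.0
    h2o2: float = 0.0
    temperature: str = "4 °C"

    def __post_init__(self) -> None:
        for name in ("e_flh2", "e_flsq", "e_flox", "c_ox", "c_red", "o2", "h2o2"):
            v = getattr(self, name)
            if not (v >= 0.0) or math.isnan(v):
                raise ValueError(f"concentration {name}={v!r} must be >= 0")
        if self.o2 > 0.0 and (self.c_ox > 0.0 or self.c_red > 0.0):
            raise ValueError(
                "at most one oxidant branch may be populated: found both O2 and CytC"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.e_flh2, self.e_flsq, self.e_flox, self.c_ox, self.c_red,
             self.o2, self.h2o2],
            dtype=float,
        )

    @classmethod
    def from_array(cls, y: np.ndarray, temperature: str = "4 °C") -> "MixState":
        y = np.where((y < 0) & (y > -_CLIP), 0.0, y)
        return cls(*[float(v) for v in y], temperature=temperature)

    @property
    def enzyme_total(self) -> float:
        return self.e_flh2 + self.e_flsq + self.e_flox

    @property
    def cytc_total(self) -> float:
        return self.c_ox + self.c_red

    @property
    def electron_total(self) -> float:
        """Reducing equivalents: 2*[FlH2] + [FlSQ] + [C_red] + 2*[H2O2]."""
        return 2 * self.e_flh2 + self.e_flsq + self.c_red + 2 * self.h2o2


@dataclass(frozen=True)
class SpectralModel:
    """Extinction coefficients (M^-1 cm^-1) for the optical observables.

    Only eps450 of oxidized FAD (11300) and eps410 of CytC (106000) are
    measured quantities; the remaining coefficients are documented defaults
    that can be overridden.  At 550 nm the ferric heme contribution is folded
    into a single difference coefficient, i.e. ``eps550_c_red`` is the
    reduced-minus-oxidized difference and ``eps550_c_ox`` defaults to 0, so
    traces start at zero absorbance.  ``eps550_flsq`` defaults to 0; setting
    it positive reproduces the >50% first-phase amplitude at 550 nm, since
    semiquinone forms in the first electron transfer and decays in the
    second.  ``None`` marks a coefficient as unavailable, in which case a
    trace containing that species is rejected.
    """

    eps450_e_flox: float | None = 11300.0
    eps450_e_flh2: float | None = 900.0     # assumption, not a measured value
    eps450_e_flsq: float | None = 4000.0    # assumption, not a measured value
    eps550_c_red: float | None = 21000.0    # reduced-minus-oxidized difference
    eps550_c_ox: float | None = 0.0
    eps550_e_flsq: float | None = 0.0       # positive option models the 60/40 split
    eps410_cytc: float = 106000.0
    pathlength_cm: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "eps450_e_flox", "eps450_e_flh2", "eps450_e_flsq",
            "eps550_c_red", "eps550_c_ox", "eps550_e_flsq",
        ):
            v = getattr(self, name)
            if v is not None and (v < 0 or math.isnan(v)):
                raise ValueError(f"{name}={v!r} must be >= 0 or None")
        if self.eps410_cytc < 0 or self.pathlength_cm <= 0:
            raise ValueError("eps410_cytc must be >= 0 and pathlength_cm > 0")

    def coefficients(self, wavelength: int) -> dict[str, float | None]:
        if wavelength == 450:
            return {
                "E_FlH2": self.eps450_e_flh2,
                "E_FlSQ": self.eps450_e_flsq,
                "E_Flox": self.eps450_e_flox,
            }
        if wavelength == 550:
            return {
                "C_red": self.eps550_c_red,
                "C_ox": self.eps550_c_ox,
                "E_FlSQ": self.eps550_e_flsq,
            }
        raise ValueError(f"unsupported wavelength {wavelength}; use 450 or 550")


@dataclass
class ConcentrationTrajectory:
    """Time grid (s) and per-species concentration series (M)."""

    time: np.ndarray
    concentrations: dict[str, np.ndarray]
    scheme: KineticScheme | None = None
    init: MixState | None = None

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[species]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.time, **self.concentrations})

    def final_state(self) -> MixState:
        y = np.array([self.concentrations[s][-1] for s in SPECIES])
        temp = self.init.temperature if self.init is not None else "4 °C"
        return MixState.from_array(y, temperature=temp)


@dataclass
class Trace:
    """Time-resolved absorbance at one wavelength.

    ``oxidant_conc_M`` is the post-mix oxidant concentration, carried along
    so that k_obs values can be regressed against it downstream.
    """

    time: np.ndarray
    absorbance: np.ndarray
    wavelength: int = 450
    oxidant_conc_M: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must have equal length")
        if self.time.size < 8:
            raise ValueError("a trace needs at least 8 points")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.absorbance))):
            raise ValueError("trace contains non-finite values")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time.size)


def _rates(t: float, y: np.ndarray, s: KineticScheme) -> np.ndarray:
    a, b, x, cox, cred, o2, h2o2 = y
    v_o2 = s.k_o2 * a * o2
    v1 = s.k1f * a * cox - s.k1r * b * cred
    v2 = s.k2f * b * cox - s.k2r * x * cred
    return np.array([
        -v_o2 - v1,        # E_FlH2
        v1 - v2,           # E_FlSQ
        v_o2 + v2,         # E_Flox
        -v1 - v2,          # C_ox
        v1 + v2,           # C_red
        -v_o2,             # O2
        v_o2,              # H2O2
    ])


def _jacobian(t: float, y: np.ndarray, s: KineticScheme) -> np.ndarray:
    a, b, x, cox, cred, o2, _ = y
    J = np.zeros((7, 7))
    # d(v_o2)/dy
    dvo = np.zeros(7)
    dvo[0] = s.k_o2 * o2
    dvo[5] = s.k_o2 * a
    # d(v1)/dy
    dv1 = np.zeros(7)
    dv1[0] = s.k1f * cox
    dv1[3] = s.k1f * a
    dv1[1] = -s.k1r * cred
    dv1[4] = -s.k1r * b
    # d(v2)/dy
    dv2 = np.zeros(7)
    dv2[1] = s.k2f * cox
    dv2[3] = s.k2f * b
    dv2[2] = -s.k2r * cred
    dv2[4] = -s.k2r * x
    J[0] = -dvo - dv1
    J[1] = dv1 - dv2
    J[2] = dvo + dv2
    J[3] = -dv1 - dv2
    J[4] = dv1 + dv2
    J[5] = -dvo
    J[6] = dvo
    return J


def simulate_mechanism(
    scheme: KineticScheme,
    init: MixState,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> ConcentrationTrajectory:
    """Integrate the mass-action rate laws over ``t_grid``.

    ``t_grid`` must be strictly increasing and start at 0.  Uses a stiff
    integrator (BDF with analytic Jacobian); concentrations more negative
    than the absolute tolerance (1e-12 M) are treated as failure, smaller
    excursions are clipped to zero.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must be a 1-D array with at least two points")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    y0 = init.as_array()
    sol = solve_ivp(
        _rates,
        (0.0, float(t_grid[-1])),
        y0,
        t_eval=t_grid,
        method="BDF",
        jac=_jacobian,
        args=(scheme,),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(
            f"stiff solver failed ({sol.message}) for scheme={scheme!r}, init={init!r}"
        )
    y = sol.y
    if np.any(y < -_CLIP):
        raise SolverError(
            f"negative concentrations beyond tolerance for scheme={scheme!r}"
        )
    y = np.where(y < 0, 0.0, y)
    conc = {name: y[i] for i, name in enumerate(SPECIES)}
    return ConcentrationTrajectory(time=t_grid, concentrations=conc,
                                   scheme=scheme, init=init)


def _equilibrium_residual(ab: np.ndarray, scheme: KineticScheme,
                          totals: tuple[float, float, float],
                          h2o2: float) -> np.ndarray:
    """Mass-action net rates of the two CytC steps as a function of (a, b)."""
    E, C, elec = totals
    a, b = ab
    x = E - a - b
    cred = elec - 2 * a - b - 2 * h2o2
    cox = C - cred
    v1 = scheme.k1f * a * cox - scheme.k1r * b * cred
    v2 = scheme.k2f * b * cox - scheme.k2r * x * cred
    return np.array([v1, v2])


def equilibrium_endpoint(scheme: KineticScheme, init: MixState,
                         polish: bool = True) -> MixState:
    """Long-time limit of the CytC branch.

    For a reversible scheme the endpoint satisfies both step equilibria and
    all conservation laws ("an equilibrium is reached at the end of the
    reaction"); for an irreversible scheme the reaction runs to whichever
    pool (electrons or oxidized CytC) exhausts first.  Computed by stiff
    integration over successively longer windows, optionally polished by a
    Newton solve of the equilibrium conditions.
    """
    if init.cytc_total == 0.0 or (scheme.k1f == 0.0 and scheme.k2f == 0.0):
        raise ValueError("equilibrium_endpoint requires an active CytC branch")
    if init.o2 > 0.0:
        raise ValueError("equilibrium_endpoint is defined for the CytC branch only")

    scale = max(init.enzyme_total, init.cytc_total, 1e-12)
    kmax = max(scheme.k1f, scheme.k2f, scheme.k1r, scheme.k2r)
    t_char = 1.0 / (kmax * scale)
    state = init
    for horizon in (50.0, 500.0, 5000.0, 5e4, 5e5):
        t_grid = np.linspace(0.0, horizon * t_char, 50)
        traj = simulate_mechanism(scheme, state, t_grid)
        state = traj.final_state()
        resid = _equilibrium_residual(
            np.array([state.e_flh2, state.e_flsq]), scheme,
            (state.enzyme_total, state.cytc_total, state.electron_total),
            state.h2o2,
        )
        if np.max(np.abs(resid)) < 1e-10 * kmax * scale * scale:
            break

    if polish and not scheme.irreversible:
        from scipy.optimize import root

        totals = (state.enzyme_total, state.cytc_total, state.electron_total)
        sol = root(
            _equilibrium_residual,
            np.array([state.e_flh2, state.e_flsq]),
            args=(scheme, totals, state.h2o2),
            method="hybr",
            tol=1e-14,
        )
        a, b = sol.x
        x = totals[0] - a - b
        cred = totals[2] - 2 * a - b - 2 * state.h2o2
        cox = totals[1] - cred
        cand = np.array([a, b, x, cox, cred, 0.0, state.h2o2])
        if sol.success and np.all(cand > -_CLIP):
            state = MixState.from_array(cand, temperature=init.temperature)
    return state


def absorbance_trace(traj: ConcentrationTrajectory, spec: SpectralModel,
                     wavelength: int) -> Trace:
    """Beer-Lambert sum over species at each time point.

    Rejects the trace if a species that is actually present (nonzero at any
    time) lacks an extinction coefficient at the requested wavelength.
    """
    eps = spec.coefficients(wavelength)
    A = np.zeros_like(traj.time, dtype=float)
    for species, coeff in eps.items():
        conc = traj.concentrations[species]
        if coeff is None:
            if np.any(conc > 0):
                raise ValueError(
                    f"no extinction coefficient at {wavelength} nm for present "
                    f"species {species}"
                )
            continue
        A += coeff * conc
    A *= spec.pathlength_cm
    oxidant = None
    if traj.init is not None:
        oxidant = traj.init.o2 if traj.init.o2 > 0 else traj.init.cytc_total
    return Trace(time=traj.time.copy(), absorbance=A, wavelength=wavelength,
                 oxidant_conc_M=oxidant)


def estimate_concentration(absorbance: float, role: str,
                           spec: SpectralModel | None = None) -> float:
    """Protein concentration from a single absorbance reading.

    FAO concentrations use the flavin eps450 (11300 M^-1 cm^-1); CytC
    concentrations use the Soret eps410 (106000 M^-1 cm^-1).
    """
    if spec is None:
        spec = SpectralModel()
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    role_l = role.lower()
    if role_l == "fao":
        eps = spec.eps450_e_flox
        if eps is None:
            raise ValueError("eps450 for oxidized flavin is not set")
    elif role_l == "cytc":
        eps = spec.eps410_cytc
    else:
        raise ValueError(f"unknown role {role!r}; expected 'FAO' or 'CytC'")
    return absorbance / (eps * spec.pathlength_cm)
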