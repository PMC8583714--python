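"""Tissue material library, daily relaxation-curve model and Prony-series fitting.

Each callus element is a mixture of four tissue phases (connective tissue,
cartilage, woven bone, cortical bone).  The soft callus relaxes strongly after
every distraction step; that behaviour is carried by a normalized two-term
Prony shear-relaxation series fitted to an empirical family of daily
relaxation curves.  Mixture rules convert per-element tissue concentrations
into element-level elastic constants and Prony weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TissueState",
    "PronyModel",
    "RelaxationCurve",
    "MaterialLibrary",
    "PUBLISHED_CALLUS_PRONY",
    "RESIDUAL_FORCE_FRACTION",
    "relaxation_force",
    "residual_force",
    "sample_relaxation_curve",
    "fit_prony",
    "fit_published_callus_prony",
    "mixture_properties",
    "mixture_properties_arrays",
    "calibrate_instantaneous_modulus",
]

#: Long-time residual traction force as a fraction of the peak force on any
#: distraction day (empirical rule; dimensionless).
RESIDUAL_FORCE_FRACTION = 0.0623

# Coefficients of the empirical daily relaxation-force law.  Three Maxwell
# branches (amplitude N/mm, day-growth exponent 1/day, time constant s, plus
# an optional day-growth exponent on the time constant) and one equilibrium
# term.  Day dependence enters through exp(b*j) factors.
_RELAX_BRANCHES = (
    # (amplitude, day exponent, tau0, tau day exponent)
    (3.57, 0.17, 3690.0, 0.0),
    (6.79, 0.11, 469.3, 0.0),
    (6.89, 0.08, 9.95, 0.09),
)
_RELAX_EQUILIBRIUM = (1.22, 0.13)


@dataclass
class TissueState:
    """Per-element tissue composition (%) and blood perfusion (%).

    Concentrations must be non-negative and sum to 100.
    """

    c_conn: float = 100.0
    c_cart: float = 0.0
    c_bone: float = 0.0
    c_cort: float = 0.0
    perfusion: float = 0.0

    def validate(self, tol: float = 1e-6) -> None:
        comps = (self.c_conn, self.c_cart, self.c_bone, self.c_cort)
        if any(c < -tol for c in comps):
            raise ValueError(f"negative tissue concentration in {self}")
        total = sum(comps)
        if abs(total - 100.0) > max(tol, 1e-6 * 100):
            raise ValueError(f"tissue concentrations sum to {total}, not 100")
        if not -tol <= self.perfusion <= 100 + tol:
            raise ValueError(f"perfusion {self.perfusion} outside [0, 100]")


@dataclass(frozen=True)
class PronyModel:
    """Normalized shear-relaxation series g(t) = g_inf + sum_i g_i exp(-t/tau_i).

    ``g`` are the dimensionless branch weights, ``tau`` the time constants in
    seconds; ``E_inst`` is the instantaneous Young's modulus in MPa and ``nu``
    the (elastic) Poisson ratio.  The long-time fraction is
    ``g_inf = 1 - sum(g)`` and must lie in (0, 1).
    """

    g: tuple[float, ...]
    tau: tuple[float, ...]
    E_inst: float = 3.0
    nu: float = 0.3

    def __post_init__(self) -> None:
        if len(self.g) != len(self.tau):
            raise ValueError("g and tau must have equal length")
        if any(t <= 0 for t in self.tau):
            raise ValueError(f"non-positive time constant in {self.tau}")
        if any(gi < 0 for gi in self.g):
            raise ValueError(f"negative Prony weight in {self.g}")
        s = sum(self.g)
        if not 0.0 < s < 1.0:
            raise ValueError(f"sum of Prony weights {s} outside (0, 1)")

    @property
    def g_inf(self) -> float:
        return 1.0 - sum(self.g)

    def relaxation(self, t: np.ndarray | float) -> np.ndarray | float:
        """Normalized relaxation function g(t)."""
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.g_inf)
        for gi, ti in zip(self.g, self.tau):
            out = out + gi * np.exp(-t / ti)
        return out


# Published two-term series for the initial-state (day 0) callus.
PUBLISHED_CALLUS_PRONY = PronyModel(g=(0.396, 0.542), tau=(10.775, 977.88))


@dataclass(frozen=True)
class RelaxationCurve:
    """A sampled relaxation-force curve after one distraction increment.

    ``day`` is the distraction day index, ``u`` the applied displacement
    increment (mm), ``t`` sample times (s) and ``force`` the traction force
    (N).  Forces should be positive and non-increasing in time.
    """

    day: int
    u: float
    t: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if t.shape != f.shape:
            raise ValueError("t and force must have equal shape")
        if np.any(t < 0):
            raise ValueError("negative sample times")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "force", f)

    @classmethod
    def from_csv(cls, path, day: int = 0, u: float = 1.0) -> "RelaxationCurve":
        try:
            data = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError:  # header row present
            data = np.loadtxt(path, delimiter=",", ndmin=2, skiprows=1)
        return cls(day=day, u=u, t=data[:, 0], force=data[:, 1])

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.t, self.force]), delimiter=",",
                   header="t_seconds,force_newtons", comments="")


def relaxation_force(j: int | float, u: float, t: np.ndarray | float):
    """Traction force F_j(t) (N) after a displacement increment ``u`` (mm).

    Empirical law for the in-vivo callus: three decaying exponential branches
    plus an equilibrium term, each amplified by a per-day growth factor; the
    whole force is proportional to the applied increment.  ``j`` is the
    distraction day, ``t`` the time in seconds since the increment.
    """
    if j < 0:
        raise ValueError(f"distraction day must be >= 0, got {j}")
    if u < 0:
        raise ValueError(f"displacement increment must be >= 0, got {u}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    a_eq, b_eq = _RELAX_EQUILIBRIUM
    out = np.full_like(t, a_eq * np.exp(b_eq * j))
    for a, b, tau0, btau in _RELAX_BRANCHES:
        tau = tau0 * np.exp(btau * j)
        out = out + a * np.exp(b * j) * np.exp(-t / tau)
    out = u * out
    return float(out) if out.ndim == 0 else out


def residual_force(j: int | float, peak: float) -> float:
    """Residual force (N) remaining in the callus long after a distraction step."""
    if peak < 0:
        raise ValueError(f"peak force must be >= 0, got {peak}")
    return RESIDUAL_FORCE_FRACTION * peak


def sample_relaxation_curve(j: int = 0, u: float = 1.0, n: int = 200,
                            t_end: float = 43200.0,
                            t_min: float = 0.1) -> RelaxationCurve:
    """Sample the empirical daily relaxation law on t=0 plus log-spaced times."""
    t = np.concatenate([[0.0], np.logspace(np.log10(t_min), np.log10(t_end), n - 1)])
    return RelaxationCurve(day=int(j), u=u, t=t, force=relaxation_force(j, u, t))


def fit_prony(curve: RelaxationCurve, n_terms: int = 2, *,
              pin_equilibrium: bool = False,
              nu: float = 0.3) -> tuple[PronyModel, float]:
    """Least-squares fit of a normalized ``n_terms``-term Prony series.

    The sampled forces are normalized by the peak value F(0) and
    g(t) = 1 - sum_i g_i (1 - exp(-t/tau_i)) is fitted by nonlinear least
    squares (time constants optimized in log space and returned sorted
    ascending).  With ``pin_equilibrium=True`` the long-time fraction
    ``1 - sum(g_i)`` is constrained to the last (largest-time) sample — the
    appropriate choice when the sampled hold is long enough that the slowest
    physical mode has fully decayed, so the plateau is observed rather than
    extrapolated.

    Returns the fitted model (``E_inst`` taken from F(0)/u against a unit
    reference, see :func:`calibrate_instantaneous_modulus` for a geometric
    calibration) and the RMS residual of the normalized fit.
    """
    t = np.asarray(curve.t, dtype=float)
    f = np.asarray(curve.force, dtype=float)
    if t.size < 2 * n_terms + 1:
        raise ValueError(
            f"need at least {2 * n_terms + 1} samples for a {n_terms}-term fit")
    if np.any(f <= 0):
        raise ValueError("relaxation forces must be positive")
    order = np.argsort(t)
    t, f = t[order], f[order]
    if t[0] != 0.0:
        raise ValueError("curve must include a t=0 (peak) sample")
    y = f / f[0]

    # Initial guess: equal weights, time constants log-spaced over the data.
    t_pos = t[t > 0]
    lt = np.linspace(np.log(max(t_pos[0], 1e-6) * 3), np.log(t_pos[-1] / 3), n_terms)
    y_end = y[-1]

    if pin_equilibrium:
        g_total = 1.0 - y_end

        def resid(p):
            gs = np.concatenate([p[: n_terms - 1], [g_total - np.sum(p[: n_terms - 1])]])
            taus = np.exp(p[n_terms - 1:])
            model = 1.0 - np.sum(gs[:, None] * (1 - np.exp(-t[None, :] / taus[:, None])), axis=0)
            return model - y

        p0 = np.concatenate([np.full(n_terms - 1, g_total / n_terms), lt])
        sol = least_squares(resid, p0, method="lm", max_nfev=20000)
        gs = np.concatenate([sol.x[: n_terms - 1],
                             [g_total - np.sum(sol.x[: n_terms - 1])]])
        taus = np.exp(sol.x[n_terms - 1:])
    else:
        def resid(p):
            gs = p[:n_terms]
            taus = np.exp(p[n_terms:])
            model = 1.0 - np.sum(gs[:, None] * (1 - np.exp(-t[None, :] / taus[:, None])), axis=0)
            return model - y

        p0 = np.concatenate([np.full(n_terms, (1.0 - y_end) / n_terms), lt])
        sol = least_squares(resid, p0, method="lm", max_nfev=20000)
        gs, taus = sol.x[:n_terms], np.exp(sol.x[n_terms:])

    if not sol.success:
        raise RuntimeError(
            f"Prony fit did not converge: {sol.message}; best iterate g={gs}, "
            f"tau={taus}, residual RMS={np.sqrt(np.mean(sol.fun ** 2)):.3e}")
    order = np.argsort(taus)
    gs, taus = gs[order], taus[order]
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    model = PronyModel(g=tuple(float(g) for g in gs),
                       tau=tuple(float(ti) for ti in taus), nu=nu)
    return model, rms


def fit_published_callus_prony(n_terms: int = 2, day: int = 0) -> tuple[PronyModel, float]:
    """Two-term Prony calibration of the day-``day`` empirical relaxation curve.

    Samples the daily relaxation law over the 12 h hold and fits with the
    equilibrium pinned to the observed end-of-hold plateau (the slowest
    branch, tau = 3690 s, has decayed by more than e^-11 at 43200 s).
    """
    curve = sample_relaxation_curve(j=day)
    return fit_prony(curve, n_terms, pin_equilibrium=True)


@dataclass(frozen=True)
class MaterialLibrary:
    """Per-tissue elastic constants (MPa, -) and the soft-callus Prony series.

    Default elastic constants follow the standard fracture-healing literature
    values for granulation/connective tissue, cartilage, woven and cortical
    bone; they must be ordered E_conn < E_cart < E_woven < E_cort.
    """

    E_conn: float = 3.0
    nu_conn: float = 0.3
    E_cart: float = 10.0
    nu_cart: float = 0.45
    E_woven: float = 4000.0
    nu_woven: float = 0.36
    E_cort: float = 20000.0
    nu_cort: float = 0.3
    callus_prony: PronyModel = field(default_factory=lambda: PUBLISHED_CALLUS_PRONY)

    def __post_init__(self) -> None:
        if not self.E_conn < self.E_cart < self.E_woven < self.E_cort:
            raise ValueError("tissue moduli must satisfy E_conn < E_cart < E_woven < E_cort")

    @property
    def moduli(self) -> np.ndarray:
        return np.array([self.E_conn, self.E_cart, self.E_woven, self.E_cort])

    @property
    def poissons(self) -> np.ndarray:
        return np.array([self.nu_conn, self.nu_cart, self.nu_woven, self.nu_cort])


def mixture_properties(state: TissueState, lib: MaterialLibrary
                       ) -> tuple[float, float, PronyModel]:
    """Element-level (E, nu, Prony) from a tissue mixture.

    The Young's modulus follows the cube-root mixture rule
    E = (sum_i c_i E_i^{1/3})^3 with volume fractions c_i; the Poisson ratio
    is the linear mixture.  Prony weights are scaled linearly toward a purely
    elastic response as the mineralized fraction (woven + cortical bone)
    approaches 100 %.
    """
    state.validate()
    E, nu, soft = mixture_properties_arrays(
        np.array([[state.c_conn, state.c_cart, state.c_bone, state.c_cort]]),
        lib)
    prony = lib.callus_prony
    g_scaled = tuple(gi * float(soft[0]) for gi in prony.g)
    if sum(g_scaled) <= 0.0:
        scaled = None  # fully mineralized: purely elastic response
    else:
        scaled = replace(prony, g=g_scaled, E_inst=float(E[0]), nu=float(nu[0]))
    return float(E[0]), float(nu[0]), scaled


def mixture_properties_arrays(conc: np.ndarray, lib: MaterialLibrary
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized mixture rule.

    ``conc`` has shape (n, 4) with columns (connective, cartilage, woven bone,
    cortical bone) in percent.  Returns (E, nu, soft_fraction) arrays where
    ``soft_fraction`` multiplies the callus Prony weights (1 for fully soft,
    0 for fully mineralized).
    """
    c = np.asarray(conc, dtype=float) / 100.0
    E = (c @ np.cbrt(lib.moduli)) ** 3
    nu = c @ lib.poissons
    soft = 1.0 - (c[:, 2] + c[:, 3])
    return E, nu, np.clip(soft, 0.0, 1.0)


def calibrate_instantaneous_modulus(gap: float = 1.0,
                                    inner_diameter: float = 12.0,
                                    outer_diameter: float = 16.0,
                                    day: int = 0) -> float:
    """Instantaneous callus modulus (MPa) matching the empirical peak stiffness.

    Chooses E so that the t=0 axial stiffness E*A/L of a uniform connective
    tissue column filling the annular gap equals the peak force per unit
    displacement F_j(0)/u of the daily relaxation law.  Documented calibration
    utility; the default material library instead uses literature elastic
    constants (the two conventions are both config-selectable).
    """
    area = np.pi * ((outer_diameter / 2) ** 2 - (inner_diameter / 2) ** 2)
    k = relaxation_force(day, 1.0, 0.0)  # N per mm of increment
    return float(k * gap / area)
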