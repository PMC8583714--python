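"""Fuzzy-logic mechano-regulation of tissue differentiation in the callus.

Each callus element carries seven state variables: two mechanical inputs
(dilatational strain epsilon and octahedral distortional strain gamma, both
in percent, taken at the peak of the most recent loading event) and five
biological ones (blood perfusion, cartilage and bone concentration, and the
Gaussian-kernel-weighted perfusion and bone concentration of the adjacent
elements).  A Mamdani-style rule base (min-conjunction, max-aggregation,
centroid defuzzification over symmetric output sets) maps these to daily
changes of perfusion, cartilage and bone, covering angiogenesis,
chondrogenesis, intramembranous and endochondral ossification, cartilage
calcification and tissue disruption.

The published rule sets this controller descends from are not printed in
full anywhere, so the default table below is reconstructed from the
quantitative strain windows the underlying studies report:

* favorable ossification/angiogenesis window: 0.01 < |eps| < 3.4 and
  gamma < 15 (all %), with gamma < 5 a "very low" sub-band that stimulates
  only weakly (very low distraction stimulus leads to premature, slow
  regeneration);
* chondrogenesis band: 15 <= gamma < 20;
* disruption: |eps| > 3.4 together with gamma > 20 (gamma > 30 "very high").

Trapezoidal memberships carry 10 % shoulders around each breakpoint.  The
whole table is a plain data structure and can be serialized / replaced from
a config file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import Mesh, REGION_CORTEX

logger = logging.getLogger(__name__)

__all__ = [
    "RegulationInput",
    "RegulationOutput",
    "RuleBase",
    "default_rule_base",
    "neighborhood_aggregate",
    "evaluate_rules",
    "apply_regulation",
    "bone_source_field",
    "perfusion_source_field",
]

# output class centers on the normalized rate axis [-1, 1]
_OUTPUT_CLASSES = {"negative": -1.0, "zero": 0.0, "low": 0.5, "high": 1.0}


@dataclass
class RegulationInput:
    """Per-element controller inputs (arrays or scalars, units %).

    ``eps_dil`` is signed (tension positive); the rules act on its magnitude,
    tensile and compressive states sharing the same window magnitudes.
    """

    eps_dil: np.ndarray
    gamma_dist: np.ndarray
    perfusion: np.ndarray
    c_cart: np.ndarray
    c_bone: np.ndarray
    neighbor_perfusion: np.ndarray
    neighbor_bone: np.ndarray

    def __post_init__(self) -> None:
        arrs = {k: np.atleast_1d(np.asarray(v, dtype=float))
                for k, v in self.__dict__.items()}
        n = max(a.size for a in arrs.values())
        for k, a in arrs.items():
            if a.size == 1 and n > 1:
                a = np.full(n, a[0])
            setattr(self, k, a)
        for k in ("perfusion", "c_cart", "c_bone",
                  "neighbor_perfusion", "neighbor_bone"):
            a = getattr(self, k)
            if np.any((a < -1e-9) | (a > 100 + 1e-9)):
                raise ValueError(f"{k} outside [0, 100]")


@dataclass
class RegulationOutput:
    """Signed daily rates (%/day) and the disruption flag, per element."""

    d_perfusion: np.ndarray
    d_cart: np.ndarray
    d_bone: np.ndarray
    destroyed: np.ndarray


def _trapezoid(x: np.ndarray, abcd: tuple[float, float, float, float]
               ) -> np.ndarray:
    a, b, c, d = abcd
    y = np.zeros_like(x, dtype=float)
    if b > a:
        y = np.where((x > a) & (x < b), (x - a) / (b - a), y)
    y = np.where((x >= b) & (x <= c), 1.0, y)
    if d > c:
        y = np.where((x > c) & (x < d), (d - x) / (d - c), y)
    return y


_INF = float("inf")


@dataclass
class RuleBase:
    """Membership breakpoints, linguistic rules and per-process maximum rates.

    ``memberships`` maps variable -> term -> trapezoid (a, b, c, d); a rule is
    (name, antecedent, consequent) where the antecedent maps variable -> term
    or list of alternative terms (OR within a variable, AND across variables)
    and the consequent maps output name -> class label, with the special
    output "destroyed" marking disruption rules.  Rates are %/day.
    """

    memberships: dict[str, dict[str, tuple[float, float, float, float]]]
    rules: list[tuple[str, dict[str, object], dict[str, str]]]
    d_perfusion_max: float = 10.0
    d_cart_max: float = 10.0
    d_bone_max: float = 10.0
    destruction_threshold: float = 0.5   # firing strength that triggers reset

    def __post_init__(self) -> None:
        for var, terms in self.memberships.items():
            for term, abcd in terms.items():
                a, b, c, d = abcd
                if not (a <= b <= c <= d):
                    raise ValueError(f"membership {var}.{term} not sorted: {abcd}")
        if min(self.d_perfusion_max, self.d_cart_max, self.d_bone_max) < 0:
            raise ValueError("maximum daily rates must be >= 0")

    def grade(self, var: str, term: str, x: np.ndarray) -> np.ndarray:
        return _trapezoid(np.asarray(x, dtype=float), self.memberships[var][term])

    def to_dict(self) -> dict:
        return {
            "memberships": {v: {t: list(tr) for t, tr in terms.items()}
                            for v, terms in self.memberships.items()},
            "rules": [{"name": n, "if": a, "then": c} for n, a, c in self.rules],
            "rates": {"d_perfusion_max": self.d_perfusion_max,
                      "d_cart_max": self.d_cart_max,
                      "d_bone_max": self.d_bone_max},
            "destruction_threshold": self.destruction_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleBase":
        return cls(
            memberships={v: {t: tuple(tr) for t, tr in terms.items()}
                         for v, terms in d["memberships"].items()},
            rules=[(r["name"], r["if"], r["then"]) for r in d["rules"]],
            d_perfusion_max=d["rates"]["d_perfusion_max"],
            d_cart_max=d["rates"]["d_cart_max"],
            d_bone_max=d["rates"]["d_bone_max"],
            destruction_threshold=d.get("destruction_threshold", 0.5),
        )


def default_rule_base(eps_low: float = 0.01, eps_high: float = 3.4,
                      gamma_very_low: float = 5.0, gamma_fav: float = 15.0,
                      gamma_destr: float = 20.0, gamma_very_high: float = 30.0,
                      shoulder: float = 0.10) -> RuleBase:
    """Reconstructed 12-rule controller built from the reported strain windows.

    Breakpoints are in percent strain; each carries a ``shoulder`` relative
    half-width (default 10 %).
    """
    def br(x: float) -> tuple[float, float]:
        return x * (1 - shoulder), x * (1 + shoulder)

    e_lo0, e_lo1 = br(eps_low)
    e_hi0, e_hi1 = br(eps_high)
    g_vl0, g_vl1 = br(gamma_very_low)
    g_f0, g_f1 = br(gamma_fav)
    g_d0, g_d1 = br(gamma_destr)
    g_vh0, g_vh1 = br(gamma_very_high)

    memberships = {
        "eps": {  # magnitude of the dilatational strain
            "negligible": (-_INF, -_INF, e_lo0, e_lo1),
            "moderate": (e_lo0, e_lo1, e_hi0, e_hi1),
            "high": (e_hi0, e_hi1, _INF, _INF),
        },
        "gamma": {
            "very_low": (-_INF, -_INF, g_vl0, g_vl1),
            "moderate": (g_vl0, g_vl1, g_f0, g_f1),
            "elevated": (g_f0, g_f1, g_d0, g_d1),
            "high": (g_d0, g_d1, _INF, _INF),
            "very_high": (g_vh0, g_vh1, _INF, _INF),
        },
        "perfusion": {
            "low": (-_INF, -_INF, 27.0, 33.0),
            "medium": (27.0, 33.0, 63.0, 77.0),
            "high": (63.0, 77.0, _INF, _INF),
        },
        "c_cart": {
            "low": (-_INF, -_INF, 9.0, 11.0),
            "present": (9.0, 11.0, _INF, _INF),
        },
        "c_bone": {
            "low": (-_INF, -_INF, 9.0, 11.0),
            "present": (9.0, 11.0, _INF, _INF),
        },
        # vessels and bone fronts grow in from vascularized / ossified
        # neighbors: "present" ramps up over the first 10 %
        "neighbor_perfusion": {
            "absent": (-_INF, -_INF, 0.0, 10.0),
            "present": (0.0, 10.0, _INF, _INF),
        },
        "neighbor_bone": {
            "absent": (-_INF, -_INF, 0.0, 10.0),
            "present": (0.0, 10.0, _INF, _INF),
        },
        # sign of the dilatational strain: distraction pulls (tensile),
        # the consolidation load squeezes (compressive)
        "sign": {
            "tensile": (0.0, e_lo1, _INF, _INF),
            "compressive": (-_INF, -_INF, -e_lo1, 0.0),
        },
    }

    rules = [
        # angiogenesis: favorable stimulus, vessels grow from perfused
        # tissue; high tensile dilatation tears capillaries, whereas the
        # intermittent compressive consolidation load does not gate on eps
        ("angiogenesis",
         {"eps": "moderate", "gamma": "moderate",
          "neighbor_perfusion": "present"},
         {"d_perfusion": "high"}),
        ("angiogenesis_weak_stimulus",
         {"eps": "moderate", "gamma": "very_low",
          "neighbor_perfusion": "present"},
         {"d_perfusion": "low"}),
        ("angiogenesis_compressive",
         {"sign": "compressive", "gamma": ["moderate", "elevated"],
          "neighbor_perfusion": "present"},
         {"d_perfusion": "high"}),
        ("angiogenesis_compressive_weak",
         {"sign": "compressive", "gamma": "very_low",
          "neighbor_perfusion": "present"},
         {"d_perfusion": "low"}),
        # intramembranous ossification in the favorable window, requiring
        # local vascularity and an advancing bone front
        ("intramembranous_ossification",
         {"eps": "moderate", "gamma": "moderate", "perfusion": "high",
          "neighbor_bone": "present"},
         {"d_bone": "high"}),
        ("intramembranous_weak_stimulus",
         {"eps": "moderate", "gamma": "very_low", "perfusion": "high",
          "neighbor_bone": "present"},
         {"d_bone": "low"}),
        # compressive ossification gates on the distortional stimulus: the
        # daily load squeezes the regenerate without tearing it
        ("intramembranous_compressive",
         {"sign": "compressive", "gamma": "moderate", "perfusion": "high",
          "neighbor_bone": "present"},
         {"d_bone": "high"}),
        ("intramembranous_compressive_weak",
         {"sign": "compressive", "gamma": "very_low", "perfusion": "high",
          "neighbor_bone": "present"},
         {"d_bone": "low"}),
        # chondrogenesis under elevated distortion (avascular route); under
        # compression it extends to arbitrarily high strain (fibrocartilage
        # instead of rupture)
        ("chondrogenesis",
         {"eps": "moderate", "gamma": "elevated"},
         {"d_cart": "high"}),
        ("chondrogenesis_high_eps",
         {"sign": "tensile", "eps": "high",
          "gamma": ["very_low", "moderate", "elevated"]},
         {"d_cart": "low"}),
        ("chondrogenesis_compressive",
         {"sign": "compressive", "gamma": ["elevated", "high", "very_high"]},
         {"d_cart": "high"}),
        # cartilage calcification / endochondral ossification once the
        # environment calms down and vessels arrive
        ("cartilage_calcification",
         {"c_cart": "present", "perfusion": "high",
          "gamma": ["very_low", "moderate", "elevated"]},
         {"d_bone": "high", "d_cart": "negative"}),
        # disruption: the stretch tears the regenerate once either invariant
        # leaves the differentiation window (under the low rate the
        # dilatational bound is passed until the gap reaches ~6 mm, under the
        # high rate until ~12 mm, reproducing the reported disruptive ranges)
        ("tissue_disruption_dilatational",
         {"sign": "tensile", "eps": "high"},
         {"destroyed": "high", "d_perfusion": "negative"}),
        ("tissue_disruption_distortional",
         {"sign": "tensile", "gamma": ["high", "very_high"]},
         {"destroyed": "high", "d_perfusion": "negative"}),
    ]
    return RuleBase(memberships=memberships, rules=rules)


def neighborhood_aggregate(mesh: Mesh, element_field: np.ndarray,
                           sigma: float) -> np.ndarray:
    """Gaussian-kernel-weighted mean of ``element_field`` over adjacent elements.

    For each element the field values of all *other* elements whose centroids
    lie within 3 sigma are averaged with weights exp(-d^2 / 2 sigma^2)
    (normalized); the element itself is excluded.  Elements outside the
    callus participate as sources only (the caller supplies their values,
    e.g. cortex perfusion = 100 %).  Elements with no neighbor in range get 0.
    """
    if sigma <= 0:
        raise ValueError("kernel width must be > 0")
    field_ = np.asarray(element_field, dtype=float)
    if field_.shape[0] != mesh.n_elements:
        raise ValueError("field not defined on every element")
    cen = mesh.centroids()
    tree = cKDTree(cen)
    pairs = tree.query_pairs(3.0 * sigma, output_type="ndarray")
    num = np.zeros(mesh.n_elements)
    den = np.zeros(mesh.n_elements)
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        d2 = ((cen[i] - cen[j]) ** 2).sum(axis=1)
        w = np.exp(-d2 / (2.0 * sigma ** 2))
        np.add.at(num, i, w * field_[j])
        np.add.at(den, i, w)
        np.add.at(num, j, w * field_[i])
        np.add.at(den, j, w)
    out = np.zeros(mesh.n_elements)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def evaluate_rules(inp: RegulationInput, rules: RuleBase) -> RegulationOutput:
    """Mamdani inference over the rule table (vectorized over elements).

    Antecedents combine by min (AND across variables, max over alternative
    terms of one variable); per output class the firing strengths aggregate
    by max; defuzzification is the centroid of the fired symmetric output
    sets, scaled by the per-process maximum daily rate.  Disruption fires
    the ``destroyed`` flag once its aggregated strength exceeds the
    configured threshold and dominates the other consequents.
    """
    values = {
        "eps": np.abs(inp.eps_dil),
        "sign": inp.eps_dil,
        "gamma": inp.gamma_dist,
        "perfusion": inp.perfusion,
        "c_cart": inp.c_cart,
        "c_bone": inp.c_bone,
        "neighbor_perfusion": inp.neighbor_perfusion,
        "neighbor_bone": inp.neighbor_bone,
    }
    n = values["eps"].size
    agg: dict[str, dict[str, np.ndarray]] = {
        out: {} for out in ("d_perfusion", "d_cart", "d_bone", "destroyed")}

    for name, antecedent, consequent in rules.rules:
        w = np.ones(n)
        for var, term in antecedent.items():
            terms = term if isinstance(term, (list, tuple)) else [term]
            grade = np.max([rules.grade(var, t, values[var]) for t in terms],
                           axis=0)
            w = np.minimum(w, grade)
        for out, cls in consequent.items():
            prev = agg[out].get(cls)
            agg[out][cls] = w if prev is None else np.maximum(prev, w)

    def defuzz(out: str, max_rate: float) -> np.ndarray:
        num = np.zeros(n)
        den = np.zeros(n)
        for cls, w in agg[out].items():
            num += w * _OUTPUT_CLASSES[cls]
            den += w
        rate = np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)
        return rate * max_rate

    w_destr = np.zeros(n)
    for w in agg["destroyed"].values():
        w_destr = np.maximum(w_destr, w)
    destroyed = w_destr >= rules.destruction_threshold

    d_perf = defuzz("d_perfusion", rules.d_perfusion_max)
    d_cart = defuzz("d_cart", rules.d_cart_max)
    d_bone = defuzz("d_bone", rules.d_bone_max)
    # disruption dominance: no anabolic output on a disrupted element
    d_perf = np.where(destroyed, np.minimum(d_perf, 0.0), d_perf)
    d_cart = np.where(destroyed, 0.0, d_cart)
    d_bone = np.where(destroyed, 0.0, d_bone)
    return RegulationOutput(d_perfusion=d_perf, d_cart=d_cart, d_bone=d_bone,
                            destroyed=destroyed)


def apply_regulation(conc: np.ndarray, perfusion: np.ndarray,
                     out: RegulationOutput, dt_days: float = 1.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Advance tissue concentrations and perfusion by one regulation step.

    ``conc`` is (n, 4) percent columns (connective, cartilage, woven bone,
    cortical); new bone is sourced from connective tissue (intramembranous
    route) or from cartilage when the calcification rule withdrew it
    (negative d_cart); cartilage is sourced from connective tissue.
    Disrupted elements reset to fully connective, unperfused tissue.
    Concentrations are clipped and renormalized to sum to 100.
    """
    c = np.asarray(conc, dtype=float).copy()
    perf = np.asarray(perfusion, dtype=float).copy()
    if np.any(np.abs(c.sum(axis=1) - 100.0) > 1e-6):
        raise ValueError("tissue concentrations must sum to 100")

    perf = np.clip(perf + out.d_perfusion * dt_days, 0.0, 100.0)
    cart = np.clip(c[:, 1] + out.d_cart * dt_days, 0.0, 100.0)
    bone = np.clip(c[:, 2] + out.d_bone * dt_days, 0.0, 100.0)
    cort = c[:, 3]
    conn = 100.0 - cart - bone - cort
    neg = conn < 0.0
    if np.any(neg):
        # growth exhausted the connective reservoir: scale back the increments
        over = -conn[neg]
        d_cart = cart[neg] - c[neg, 1]
        d_bone = bone[neg] - c[neg, 2]
        growth = np.maximum(d_cart, 0.0) + np.maximum(d_bone, 0.0)
        scale = np.where(growth > 0, 1.0 - over / np.maximum(growth, 1e-30), 1.0)
        scale = np.clip(scale, 0.0, 1.0)
        cart[neg] = c[neg, 1] + np.maximum(d_cart, 0.0) * scale \
            + np.minimum(d_cart, 0.0)
        bone[neg] = c[neg, 2] + np.maximum(d_bone, 0.0) * scale \
            + np.minimum(d_bone, 0.0)
        conn = 100.0 - cart - bone - cort
        conn = np.maximum(conn, 0.0)

    new = np.column_stack([conn, cart, bone, cort])
    new *= 100.0 / new.sum(axis=1, keepdims=True)

    dest = out.destroyed
    if np.any(dest):
        new[dest, 0] = 100.0 - new[dest, 3]
        new[dest, 1] = 0.0
        new[dest, 2] = 0.0
        perf[dest] = 0.0
    return new, perf


def bone_source_field(mesh: Mesh, conc: np.ndarray) -> np.ndarray:
    """Mineralized-tissue field used for the neighbor-bone aggregate.

    Woven plus cortical bone; the intact cortex (100 % cortical) seeds the
    bone front at the fragment ends.
    """
    return conc[:, 2] + conc[:, 3]


def perfusion_source_field(mesh: Mesh, perfusion: np.ndarray) -> np.ndarray:
    """Perfusion field with the cortex clamped to 100 % as a vessel source."""
    p = np.asarray(perfusion, dtype=float).copy()
    p[mesh.region == REGION_CORTEX] = 100.0
    return p
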