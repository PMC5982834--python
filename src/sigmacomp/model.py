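"""Steady states of the sigma-factor competition network.

Two model variants are solved:

* the **holoenzyme** variant — core polymerase (E), sigma70, sigma38, the
  anti-sigma factor Rsd and 6S RNA, coupled purely by reversible binding:

  .. code-block:: text

      E + sigma70      <-> E.sigma70         (K_E_sigma70)
      E + sigma38      <-> E.sigma38         (K_E_sigma38)
      Rsd + sigma70    <-> Rsd.sigma70       (K_Rsd)
      6S + E.sigma70   <-> 6S.E.sigma70      (K_6S)

* the **full** variant, which adds nonspecific chromosomal sites (one
  shared K_NS for E and both holoenzymes), cognate promoters (one shared
  K_EsigmaP), promoter clearance at rate ``c`` releasing sigma, and return
  of elongating polymerase to the free pool at rate ``e``:

  .. code-block:: text

      E        + DNA  <-> E.DNA              (K_NS)
      E.sigma  + DNA  <-> E.sigma.DNA        (K_NS)
      E.sigma  + P    <-> E.sigma.P          (K_EsigmaP)
      E.sigma.P  -c->  Ee + sigma + P
      Ee         -e->  E  (+ transcript)

The steady-state transcription flux per promoter class is ``e*[Ee]``,
equal to ``c*[E.sigma.P]`` by flux balance. Transcripts themselves are not
tracked as a species: with no decay they have no steady level, only a
steady production flux.

The primary solver exploits that, with every reversible reaction
equilibrated, each conservation relation is strictly monotone in one free
concentration, so the network reduces to nested scalar root brackets
(Brent's method) — free E outermost, free sigma70/sigma38 inner. The
independent route, :func:`ode_oracle`, integrates the mass-action kinetics
to stationarity and is used to cross-check the algebraic solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .parameters import ModelParameters

__all__ = [
    "SteadyState",
    "SteadyStateError",
    "solve_holoenzyme_model",
    "solve_full_model",
    "transcription_rates",
    "ode_oracle",
    "conservation_residuals",
]

_TINY = 1e-18  # molar floor used when normalizing residuals
_BRENT_KW = dict(xtol=1e-30, rtol=8.881784197001252e-16, maxiter=300)

HOLO_SPECIES = (
    "free_E",
    "free_sigma70",
    "free_sigma38",
    "free_Rsd",
    "free_6S",
    "E_sigma70",
    "E_sigma38",
    "Rsd_sigma70",
    "c6S_E_sigma70",
)
FULL_SPECIES = HOLO_SPECIES + (
    "free_DNA",
    "E_DNA",
    "E_sigma70_DNA",
    "E_sigma38_DNA",
    "free_P70",
    "free_P38",
    "E_sigma70_P70",
    "E_sigma38_P38",
    "Ee70",
    "Ee38",
)


class SteadyStateError(RuntimeError):
    """Raised when neither the root solver nor ODE integration converges."""


@dataclass(frozen=True)
class SteadyState:
    """Concentrations (molar) of every species at steady state.

    ``rate70``/``rate38`` (M/s) are the steady transcription fluxes
    ``e*[Ee70]`` / ``e*[Ee38]`` and are only set for the full variant.
    ``residual_norm`` is the largest conservation residual relative to the
    corresponding total.
    """

    variant: Literal["holoenzyme", "full"]
    method: Literal["root", "ode"]
    residual_norm: float
    free_E: float
    free_sigma70: float
    free_sigma38: float
    free_Rsd: float
    free_6S: float
    E_sigma70: float
    E_sigma38: float
    Rsd_sigma70: float
    c6S_E_sigma70: float
    free_DNA: float | None = None
    E_DNA: float | None = None
    E_sigma70_DNA: float | None = None
    E_sigma38_DNA: float | None = None
    free_P70: float | None = None
    free_P38: float | None = None
    E_sigma70_P70: float | None = None
    E_sigma38_P38: float | None = None
    Ee70: float | None = None
    Ee38: float | None = None
    rate70: float | None = None
    rate38: float | None = None

    @property
    def species_names(self) -> tuple[str, ...]:
        return FULL_SPECIES if self.variant == "full" else HOLO_SPECIES

    def species(self) -> dict[str, float]:
        """Species concentrations (M) as a flat dict."""
        return {name: getattr(self, name) for name in self.species_names}

    def as_record(self) -> dict[str, float | str]:
        rec: dict[str, float | str] = {"variant": self.variant, "method": self.method}
        rec.update(self.species())
        if self.variant == "full":
            rec["rate70"] = self.rate70
            rec["rate38"] = self.rate38
        rec["residual_norm"] = self.residual_norm
        return rec


def _require_positive_K(p: ModelParameters, names: tuple[str, ...]) -> None:
    for name in names:
        if getattr(p, name) <= 0:
            raise ValueError(
                f"{name} must be > 0 to solve the binding network (got "
                f"{getattr(p, name)!r}); a zero dissociation constant makes "
                "the equilibrium singular"
            )


def _rel(x: float, scale: float) -> float:
    return abs(x) / max(scale, _TINY)


# ---------------------------------------------------------------------------
# holoenzyme variant
# ---------------------------------------------------------------------------


def _holo_sigma70(E: float, t: dict[str, float], p: ModelParameters) -> float:
    """Free sigma70 satisfying sigma70 conservation at given free E."""
    s70t = t["sigma70_total"]
    if s70t == 0:
        return 0.0

    def g(s70: float) -> float:
        Es70 = E * s70 / p.K_E_sigma70
        rsd70 = t["Rsd_total"] * (s70 / p.K_Rsd) / (1 + s70 / p.K_Rsd)
        c6 = t["RNA6S_total"] * Es70 / (p.K_6S + Es70)
        return s70 + Es70 + rsd70 + c6 - s70t

    if g(0.0) == 0.0:
        return 0.0
    return brentq(g, 0.0, s70t, **_BRENT_KW)


def _holo_species(E: float, s70: float, t: dict[str, float], p: ModelParameters) -> dict[str, float]:
    Es70 = E * s70 / p.K_E_sigma70
    s38 = t["sigma38_total"] / (1 + E / p.K_E_sigma38)
    Es38 = E * s38 / p.K_E_sigma38
    rsd = t["Rsd_total"] / (1 + s70 / p.K_Rsd)
    rsd70 = rsd * s70 / p.K_Rsd
    x6 = t["RNA6S_total"] / (1 + Es70 / p.K_6S)
    c6 = x6 * Es70 / p.K_6S
    return {
        "free_E": E,
        "free_sigma70": s70,
        "free_sigma38": s38,
        "free_Rsd": rsd,
        "free_6S": x6,
        "E_sigma70": Es70,
        "E_sigma38": Es38,
        "Rsd_sigma70": rsd70,
        "c6S_E_sigma70": c6,
    }


def solve_holoenzyme_model(params: ModelParameters) -> SteadyState:
    """Steady state of the binding-only (no DNA, no promoter) variant.

    Returns the unique nonnegative solution of the four equilibrium
    relations together with the five conservation relations for E,
    sigma70, sigma38, Rsd and 6S RNA. DNA/promoter fields of ``params``
    are ignored.
    """
    _require_positive_K(params, ("K_E_sigma70", "K_E_sigma38", "K_Rsd", "K_6S"))
    t = params.totals_molar()
    Et = t["E_total"]

    def outer(E: float) -> float:
        s70 = _holo_sigma70(E, t, params)
        sp = _holo_species(E, s70, t, params)
        return sp["free_E"] + sp["E_sigma70"] + sp["E_sigma38"] + sp["c6S_E_sigma70"] - Et

    try:
        if Et == 0 or outer(0.0) == 0.0:
            E = 0.0
        else:
            E = brentq(outer, 0.0, Et, **_BRENT_KW)
        s70 = _holo_sigma70(E, t, params)
        sp = _holo_species(E, s70, t, params)
        res = _holo_residual_norm(sp, t)
        if res > 1e-10:
            raise SteadyStateError("root residual too large")
        return SteadyState(variant="holoenzyme", method="root", residual_norm=res, **sp)
    except (ValueError, SteadyStateError):
        # bracketing/round-off failure: fall back to integrating the kinetics
        state = ode_oracle(params, "holoenzyme")
        if state.residual_norm > 1e-8:
            raise SteadyStateError(
                f"holoenzyme steady state did not converge for parameters {params.to_dict()!r}"
            )
        return state


def _holo_residual_norm(sp: dict[str, float], t: dict[str, float]) -> float:
    res = [
        _rel(sp["free_E"] + sp["E_sigma70"] + sp["E_sigma38"] + sp["c6S_E_sigma70"] - t["E_total"], t["E_total"]),
        _rel(
            sp["free_sigma70"] + sp["E_sigma70"] + sp["Rsd_sigma70"] + sp["c6S_E_sigma70"] - t["sigma70_total"],
            t["sigma70_total"],
        ),
        _rel(sp["free_sigma38"] + sp["E_sigma38"] - t["sigma38_total"], t["sigma38_total"]),
        _rel(sp["free_Rsd"] + sp["Rsd_sigma70"] - t["Rsd_total"], t["Rsd_total"]),
        _rel(sp["free_6S"] + sp["c6S_E_sigma70"] - t["RNA6S_total"], t["RNA6S_total"]),
    ]
    return max(res)


# ---------------------------------------------------------------------------
# full variant (nonspecific DNA, promoters, clearance, elongation)
# ---------------------------------------------------------------------------


def _full_species(
    E: float, s70: float, s38: float, t: dict[str, float], p: ModelParameters
) -> dict[str, float]:
    Es70 = E * s70 / p.K_E_sigma70
    Es38 = E * s38 / p.K_E_sigma38
    rsd = t["Rsd_total"] / (1 + s70 / p.K_Rsd)
    rsd70 = rsd * s70 / p.K_Rsd
    x6 = t["RNA6S_total"] / (1 + Es70 / p.K_6S)
    c6 = x6 * Es70 / p.K_6S
    dna = t["DNA_total"] / (1 + (E + Es70 + Es38) / p.K_NS)
    P70 = t["P70_total"] / (1 + Es70 / p.K_EsigmaP)
    P38 = t["P38_total"] / (1 + Es38 / p.K_EsigmaP)
    E70P70 = P70 * Es70 / p.K_EsigmaP
    E38P38 = P38 * Es38 / p.K_EsigmaP
    ce = p.clearance_rate_c / p.elongation_escape_rate_e if p.elongation_escape_rate_e > 0 else 0.0
    return {
        "free_E": E,
        "free_sigma70": s70,
        "free_sigma38": s38,
        "free_Rsd": rsd,
        "free_6S": x6,
        "E_sigma70": Es70,
        "E_sigma38": Es38,
        "Rsd_sigma70": rsd70,
        "c6S_E_sigma70": c6,
        "free_DNA": dna,
        "E_DNA": E * dna / p.K_NS,
        "E_sigma70_DNA": Es70 * dna / p.K_NS,
        "E_sigma38_DNA": Es38 * dna / p.K_NS,
        "free_P70": P70,
        "free_P38": P38,
        "E_sigma70_P70": E70P70,
        "E_sigma38_P38": E38P38,
        "Ee70": ce * E70P70,
        "Ee38": ce * E38P38,
    }


def _full_sigma_residuals(sp: dict[str, float], t: dict[str, float]) -> tuple[float, float]:
    r70 = (
        sp["free_sigma70"]
        + sp["E_sigma70"]
        + sp["Rsd_sigma70"]
        + sp["c6S_E_sigma70"]
        + sp["E_sigma70_DNA"]
        + sp["E_sigma70_P70"]
        - t["sigma70_total"]
    )
    r38 = (
        sp["free_sigma38"]
        + sp["E_sigma38"]
        + sp["E_sigma38_DNA"]
        + sp["E_sigma38_P38"]
        - t["sigma38_total"]
    )
    return r70, r38


def _full_inner(E: float, t: dict[str, float], p: ModelParameters) -> tuple[float, float]:
    """Free sigma70 and sigma38 satisfying their conservations at fixed free E.

    The two scalar problems couple only weakly (through depletion of free
    nonspecific DNA), so alternating Brent solves converge in a few rounds.
    """
    s70t, s38t = t["sigma70_total"], t["sigma38_total"]
    s70, s38 = 0.0, 0.0
    for _ in range(200):
        s70_prev, s38_prev = s70, s38
        if s70t > 0:
            def g70(x: float) -> float:
                return _full_sigma_residuals(_full_species(E, x, s38, t, p), t)[0]

            s70 = 0.0 if g70(0.0) == 0.0 else brentq(g70, 0.0, s70t, **_BRENT_KW)
        if s38t > 0:
            def g38(x: float) -> float:
                return _full_sigma_residuals(_full_species(E, s70, x, t, p), t)[1]

            s38 = 0.0 if g38(0.0) == 0.0 else brentq(g38, 0.0, s38t, **_BRENT_KW)
        if (
            abs(s70 - s70_prev) <= 1e-14 * max(s70t, _TINY)
            and abs(s38 - s38_prev) <= 1e-14 * max(s38t, _TINY)
        ):
            break
    return s70, s38


def _full_residual_norm(sp: dict[str, float], t: dict[str, float]) -> float:
    r70, r38 = _full_sigma_residuals(sp, t)
    e_tot = (
        sp["free_E"]
        + sp["E_sigma70"]
        + sp["E_sigma38"]
        + sp["c6S_E_sigma70"]
        + sp["E_DNA"]
        + sp["E_sigma70_DNA"]
        + sp["E_sigma38_DNA"]
        + sp["E_sigma70_P70"]
        + sp["E_sigma38_P38"]
        + sp["Ee70"]
        + sp["Ee38"]
    )
    res = [
        _rel(e_tot - t["E_total"], t["E_total"]),
        _rel(r70, t["sigma70_total"]),
        _rel(r38, t["sigma38_total"]),
        _rel(sp["free_Rsd"] + sp["Rsd_sigma70"] - t["Rsd_total"], t["Rsd_total"]),
        _rel(sp["free_6S"] + sp["c6S_E_sigma70"] - t["RNA6S_total"], t["RNA6S_total"]),
        _rel(sp["free_DNA"] + sp["E_DNA"] + sp["E_sigma70_DNA"] + sp["E_sigma38_DNA"] - t["DNA_total"], t["DNA_total"]),
        _rel(sp["free_P70"] + sp["E_sigma70_P70"] - t["P70_total"], t["P70_total"]),
        _rel(sp["free_P38"] + sp["E_sigma38_P38"] - t["P38_total"], t["P38_total"]),
    ]
    return max(res)


def _finish_full(sp: dict[str, float], t: dict[str, float], p: ModelParameters, method: str) -> SteadyState:
    res = _full_residual_norm(sp, t)
    return SteadyState(
        variant="full",
        method=method,  # type: ignore[arg-type]
        residual_norm=res,
        rate70=p.elongation_escape_rate_e * sp["Ee70"],
        rate38=p.elongation_escape_rate_e * sp["Ee38"],
        **sp,
    )


def solve_full_model(params: ModelParameters) -> SteadyState:
    """Steady state of the full variant including DNA, promoters and flux.

    The reversible reactions are equilibrated; the clearance/elongation
    cycle fixes ``[Ee] = (c/e)*[E.sigma.P]`` so that the fluxes through
    promoter clearance and transcript completion balance. Transcription
    rates are ``rate70 = e*[Ee70]`` and ``rate38 = e*[Ee38]``.
    """
    _require_positive_K(
        params, ("K_E_sigma70", "K_E_sigma38", "K_Rsd", "K_6S", "K_NS", "K_EsigmaP")
    )
    if params.clearance_rate_c > 0 and params.elongation_escape_rate_e == 0:
        raise ValueError(
            "elongation_escape_rate_e must be > 0 when clearance_rate_c > 0: "
            "otherwise elongating polymerase accumulates without bound"
        )
    t = params.totals_molar()
    Et = t["E_total"]

    def outer(E: float) -> float:
        s70, s38 = _full_inner(E, t, params)
        sp = _full_species(E, s70, s38, t, params)
        return (
            sp["free_E"]
            + sp["E_sigma70"]
            + sp["E_sigma38"]
            + sp["c6S_E_sigma70"]
            + sp["E_DNA"]
            + sp["E_sigma70_DNA"]
            + sp["E_sigma38_DNA"]
            + sp["E_sigma70_P70"]
            + sp["E_sigma38_P38"]
            + sp["Ee70"]
            + sp["Ee38"]
            - Et
        )

    try:
        if Et == 0 or outer(0.0) == 0.0:
            E = 0.0
        else:
            E = brentq(outer, 0.0, Et, **_BRENT_KW)
        s70, s38 = _full_inner(E, t, params)
        sp = _full_species(E, s70, s38, t, params)
        state = _finish_full(sp, t, params, "root")
        if state.residual_norm > 1e-10:
            raise SteadyStateError("root residual too large")
        return state
    except (ValueError, SteadyStateError):
        state = ode_oracle(params, "full")
        if state.residual_norm > 1e-8:
            raise SteadyStateError(
                f"full-model steady state did not converge for parameters {params.to_dict()!r}"
            )
        return state


def transcription_rates(state: SteadyState) -> tuple[float, float]:
    """Steady transcription fluxes ``(e*[Ee70], e*[Ee38])`` in M/s."""
    if state.variant != "full":
        raise ValueError(
            "transcription rates are defined only for the full model variant "
            "(the holoenzyme variant has no promoters)"
        )
    return state.rate70, state.rate38


# ---------------------------------------------------------------------------
# independent ODE route
# ---------------------------------------------------------------------------

# index map for the full mass-action state vector
_IDX = {name: i for i, name in enumerate(FULL_SPECIES)}


def _mass_action_rhs(p: ModelParameters, variant: str, kon: float) -> Callable[[float, np.ndarray], np.ndarray]:
    i = _IDX
    bind = [
        # (A, B, AB, K)
        ("free_E", "free_sigma70", "E_sigma70", p.K_E_sigma70),
        ("free_E", "free_sigma38", "E_sigma38", p.K_E_sigma38),
        ("free_Rsd", "free_sigma70", "Rsd_sigma70", p.K_Rsd),
        ("free_6S", "E_sigma70", "c6S_E_sigma70", p.K_6S),
    ]
    if variant == "full":
        bind += [
            ("free_E", "free_DNA", "E_DNA", p.K_NS),
            ("E_sigma70", "free_DNA", "E_sigma70_DNA", p.K_NS),
            ("E_sigma38", "free_DNA", "E_sigma38_DNA", p.K_NS),
            ("E_sigma70", "free_P70", "E_sigma70_P70", p.K_EsigmaP),
            ("E_sigma38", "free_P38", "E_sigma38_P38", p.K_EsigmaP),
        ]
    bind_idx = [(i[a], i[b], i[ab], K) for a, b, ab, K in bind]
    c, e = p.clearance_rate_c, p.elongation_escape_rate_e
    full = variant == "full"

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        for ia, ib, iab, K in bind_idx:
            v = kon * (y[ia] * y[ib] - K * y[iab])
            dy[ia] -= v
            dy[ib] -= v
            dy[iab] += v
        if full:
            # clearance: E.sigma.P -> Ee + sigma + P
            v70 = c * y[i["E_sigma70_P70"]]
            dy[i["E_sigma70_P70"]] -= v70
            dy[i["Ee70"]] += v70
            dy[i["free_sigma70"]] += v70
            dy[i["free_P70"]] += v70
            v38 = c * y[i["E_sigma38_P38"]]
            dy[i["E_sigma38_P38"]] -= v38
            dy[i["Ee38"]] += v38
            dy[i["free_sigma38"]] += v38
            dy[i["free_P38"]] += v38
            # elongation escape: Ee -> E (+ transcript, not tracked)
            dy[i["Ee70"]] -= e * y[i["Ee70"]]
            dy[i["Ee38"]] -= e * y[i["Ee38"]]
            dy[i["free_E"]] += e * (y[i["Ee70"]] + y[i["Ee38"]])
        return dy

    return rhs


def ode_oracle(
    params: ModelParameters,
    variant: Literal["holoenzyme", "full"] = "holoenzyme",
    *,
    kon: float | None = None,
    stationarity_tol: float = 1e-10,
    max_time: float = 1e9,
) -> SteadyState:
    """Brute-force steady state by integrating the mass-action kinetics.

    On-rates are ``kon`` (M^-1 s^-1) for every reversible binding step and
    off-rates ``kon*K``; the equilibrium of the binding network depends on
    the K values only. For the full variant ``kon`` must be fast relative
    to promoter clearance, otherwise the clearance flux visibly perturbs
    the promoter-binding balance; the default (1e9, near diffusion limit)
    keeps that perturbation below ~1e-4 relative.

    Integration proceeds in expanding stages until
    ``max |dX/dt| / max(X, 1e-18 M) <= stationarity_tol`` (s^-1).
    """
    if variant not in ("holoenzyme", "full"):
        raise ValueError(f"unknown variant {variant!r}")
    if kon is None:
        kon = 1e6 if variant == "holoenzyme" else 1e9
    t = params.totals_molar()
    n = len(FULL_SPECIES) if variant == "full" else len(HOLO_SPECIES)
    y0 = np.zeros(n)
    y0[_IDX["free_E"]] = t["E_total"]
    y0[_IDX["free_sigma70"]] = t["sigma70_total"]
    y0[_IDX["free_sigma38"]] = t["sigma38_total"]
    y0[_IDX["free_Rsd"]] = t["Rsd_total"]
    y0[_IDX["free_6S"]] = t["RNA6S_total"]
    if variant == "full":
        y0[_IDX["free_DNA"]] = t["DNA_total"]
        y0[_IDX["free_P70"]] = t["P70_total"]
        y0[_IDX["free_P38"]] = t["P38_total"]
    if not y0.any():
        zeros = {name: 0.0 for name in (FULL_SPECIES if variant == "full" else HOLO_SPECIES)}
        if variant == "full":
            return SteadyState(variant="full", method="ode", residual_norm=0.0, rate70=0.0, rate38=0.0, **zeros)
        return SteadyState(variant="holoenzyme", method="ode", residual_norm=0.0, **zeros)

    rhs = _mass_action_rhs(params, variant, kon)
    t_end = 10.0 / kon / max(y0.max(), _TINY)  # a few fastest-association times
    t_end = max(t_end, 1e-6)
    y = y0
    while True:
        sol = solve_ivp(
            rhs, (0.0, t_end), y, method="BDF", rtol=1e-10, atol=1e-22 * max(y0.max(), 1.0)
        )
        if not sol.success:
            raise SteadyStateError(
                f"ODE integration failed for parameters {params.to_dict()!r}: {sol.message}"
            )
        y = sol.y[:, -1]
        dy = rhs(0.0, y)
        crit = np.abs(dy) / np.maximum(np.abs(y), _TINY)
        if crit.max() <= stationarity_tol:
            break
        if t_end >= max_time:
            raise SteadyStateError(
                f"ODE integration not stationary by t={max_time:g} s "
                f"(max relative derivative {crit.max():.3e} s^-1) for parameters "
                f"{params.to_dict()!r}"
            )
        t_end *= 10.0
    y = np.maximum(y, 0.0)
    names = FULL_SPECIES if variant == "full" else HOLO_SPECIES
    sp = {name: float(y[_IDX[name]]) for name in names}
    if variant == "full":
        return _finish_full(sp, t, params, "ode")
    return SteadyState(
        variant="holoenzyme", method="ode", residual_norm=_holo_residual_norm(sp, t), **sp
    )


def conservation_residuals(state: SteadyState, params: ModelParameters) -> dict[str, float]:
    """Relative conservation residual per conserved total (diagnostic)."""
    t = params.totals_molar()
    sp = state.species()
    if state.variant == "holoenzyme":
        sums = {
            "E_total": sp["free_E"] + sp["E_sigma70"] + sp["E_sigma38"] + sp["c6S_E_sigma70"],
            "sigma70_total": sp["free_sigma70"] + sp["E_sigma70"] + sp["Rsd_sigma70"] + sp["c6S_E_sigma70"],
            "sigma38_total": sp["free_sigma38"] + sp["E_sigma38"],
            "Rsd_total": sp["free_Rsd"] + sp["Rsd_sigma70"],
            "RNA6S_total": sp["free_6S"] + sp["c6S_E_sigma70"],
        }
    else:
        sums = {
            "E_total": sp["free_E"] + sp["E_sigma70"] + sp["E_sigma38"] + sp["c6S_E_sigma70"]
            + sp["E_DNA"] + sp["E_sigma70_DNA"] + sp["E_sigma38_DNA"]
            + sp["E_sigma70_P70"] + sp["E_sigma38_P38"] + sp["Ee70"] + sp["Ee38"],
            "sigma70_total": sp["free_sigma70"] + sp["E_sigma70"] + sp["Rsd_sigma70"]
            + sp["c6S_E_sigma70"] + sp["E_sigma70_DNA"] + sp["E_sigma70_P70"],
            "sigma38_total": sp["free_sigma38"] + sp["E_sigma38"] + sp["E_sigma38_DNA"] + sp["E_sigma38_P38"],
            "Rsd_total": sp["free_Rsd"] + sp["Rsd_sigma70"],
            "RNA6S_total": sp["free_6S"] + sp["c6S_E_sigma70"],
            "DNA_total": sp["free_DNA"] + sp["E_DNA"] + sp["E_sigma70_DNA"] + sp["E_sigma38_DNA"],
            "P70_total": sp["free_P70"] + sp["E_sigma70_P70"],
            "P38_total": sp["free_P38"] + sp["E_sigma38_P38"],
        }
    return {k: _rel(v - t[k], t[k]) for k, v in sums.items()}
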