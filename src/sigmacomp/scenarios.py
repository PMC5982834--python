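"""Knockout scenarios, parameter sweeps, threshold search and robustness scan.

A :class:`Scenario` perturbs a baseline parameter set by absolute overrides
and/or multiplicative factors. The built-in scenarios encode the simulated
knockouts:

``wt``
    unmodified baseline.
``rsd_zero`` / ``ssrS_zero``
    plain removal of Rsd / 6S RNA, nothing else changed.
``rsd_ko_sim``
    the Rsd knockout as observed: Rsd absent and 6S RNA up 2.3-fold
    (the deletion strain overexpresses 6S RNA in stationary phase).
``ssrS_ko_sim``
    the 6S RNA knockout as observed: 6S absent, Rsd and core polymerase
    halved, sigma38 up 50%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import SteadyState, SteadyStateError, solve_full_model, solve_holoenzyme_model
from .parameters import ModelParameters

__all__ = [
    "Scenario",
    "BUILTIN_SCENARIOS",
    "apply_scenario",
    "SweepResult",
    "sweep",
    "find_rsd_threshold",
    "robustness_scan",
    "MECHANISTIC_PARAMETERS",
]


@dataclass(frozen=True)
class Scenario:
    """Named perturbation of a baseline parameter set.

    ``overrides`` are applied first (absolute values), then ``multipliers``;
    a field may appear in only one of the two maps.
    """

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clash = set(self.overrides) & set(self.multipliers)
        if clash:
            raise ValueError(
                f"scenario {self.name!r}: fields {sorted(clash)} appear in both "
                "overrides and multipliers"
            )


BUILTIN_SCENARIOS: dict[str, Scenario] = {
    "wt": Scenario("wt"),
    "rsd_zero": Scenario("rsd_zero", overrides={"Rsd_total": 0.0}),
    "ssrS_zero": Scenario("ssrS_zero", overrides={"RNA6S_total": 0.0}),
    "rsd_ko_sim": Scenario(
        "rsd_ko_sim", overrides={"Rsd_total": 0.0}, multipliers={"RNA6S_total": 2.3}
    ),
    "ssrS_ko_sim": Scenario(
        "ssrS_ko_sim",
        overrides={"RNA6S_total": 0.0},
        multipliers={"Rsd_total": 0.5, "E_total": 0.5, "sigma38_total": 1.5},
    ),
}


def apply_scenario(params: ModelParameters, scenario: Scenario | str) -> ModelParameters:
    """Return a new parameter set with the scenario applied; input untouched."""
    if isinstance(scenario, str):
        try:
            scenario = BUILTIN_SCENARIOS[scenario]
        except KeyError:
            raise KeyError(
                f"unknown scenario {scenario!r}; built-ins: {sorted(BUILTIN_SCENARIOS)}"
            ) from None
    known = set(params.field_names())
    for fname in (*scenario.overrides, *scenario.multipliers):
        if fname not in known:
            raise KeyError(f"scenario {scenario.name!r} targets unknown field {fname!r}")
    changes = dict(scenario.overrides)
    for fname, factor in scenario.multipliers.items():
        base = changes.get(fname, getattr(params, fname))
        changes[fname] = base * factor
    return params.replace(**changes)


@dataclass(frozen=True)
class SweepResult:
    """Steady states along a grid of one swept total/constant."""

    swept_field: str
    grid: np.ndarray  # values in the field's native unit, strictly increasing
    states: tuple[SteadyState | None, ...]  # None where a point failed
    failures: tuple[str, ...] = ()

    def table(self) -> pd.DataFrame:
        rows = []
        for g, st in zip(self.grid, self.states):
            rec: dict[str, object] = {self.swept_field: g}
            if st is None:
                rec["converged"] = False
            else:
                rec["converged"] = True
                rec.update(st.as_record())
            rows.append(rec)
        return pd.DataFrame(rows)


def default_grid(upper: float, n: int = 200) -> np.ndarray:
    """Zero plus log-spaced points up to ``upper`` (native units)."""
    if upper <= 0:
        return np.array([0.0])
    return np.concatenate([[0.0], np.geomspace(upper / 10**3, upper, n - 1)])


def sweep(
    params: ModelParameters,
    swept_field: str,
    grid: Iterable[float],
    variant: Literal["holoenzyme", "full"] = "full",
) -> SweepResult:
    """Solve an independent steady state at each grid value of one field."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty sweep grid")
    if not np.all(np.isfinite(grid)) or np.any(grid < 0):
        raise ValueError("sweep grid must be finite and nonnegative")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    if swept_field not in params.field_names():
        raise KeyError(f"unknown parameter field {swept_field!r}")
    solver = solve_full_model if variant == "full" else solve_holoenzyme_model
    states: list[SteadyState | None] = []
    failures: list[str] = []
    for g in grid:
        try:
            states.append(solver(params.replace(**{swept_field: float(g)})))
        except (SteadyStateError, ValueError) as exc:
            states.append(None)
            failures.append(f"{swept_field}={g:g}: {exc}")
    return SweepResult(swept_field, grid, tuple(states), tuple(failures))


def find_rsd_threshold(params: ModelParameters, *, tol_uM: float = 0.01) -> float:
    """Total Rsd (uM) at which the 6S-RNA-knockout sigma38 rate equals wild-type.

    The wild-type sigma38 transcription rate is computed once from the
    unmodified parameters (full model). With 6S RNA removed, the rate is an
    increasing function of total Rsd; bisection on [0, 2x default Rsd]
    locates the crossing to within ``tol_uM``.
    """
    wt_rate38 = solve_full_model(params).rate38

    def f(rsd_uM: float) -> float:
        ko = params.replace(RNA6S_total=0.0, Rsd_total=rsd_uM)
        return solve_full_model(ko).rate38 - wt_rate38

    lo, hi = 0.0, 2.0 * params.Rsd_total
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise SteadyStateError(
            "no sign change in rate38(6S=0) - rate38(wt) over "
            f"[0, {hi:g}] uM Rsd; the parameter set is inconsistent with a "
            "threshold in that range"
        )
    while hi - lo > tol_uM:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm * flo <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


#: single parameters perturbed by the robustness scan: every mechanistic
#: total, dissociation constant and rate; cell geometry and the purely
#: documentary operon length are excluded.
MECHANISTIC_PARAMETERS: tuple[str, ...] = (
    "E_total",
    "sigma70_total",
    "sigma38_total",
    "Rsd_total",
    "RNA6S_total",
    "DNA_total_sites",
    "P70_count",
    "P38_count",
    "K_E_sigma70",
    "K_E_sigma38",
    "K_Rsd",
    "K_6S",
    "K_NS",
    "K_EsigmaP",
    "clearance_rate_c",
    "elongation_escape_rate_e",
)


def robustness_scan(params: ModelParameters, fold: float = 10.0) -> pd.DataFrame:
    """Can any single fold-change perturbation invert the 6S-knockout effect?

    For each mechanistic parameter, multiplied and divided by ``fold``, the
    plain 6S RNA knockout (6S total = 0, nothing else changed) is compared
    with its matched wild-type under the same perturbation. One row per
    perturbation records whether the knockout's sigma38 transcription rate
    drops below the matched wild-type rate — the experimentally observed
    direction, which the unperturbed model does not produce.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rows = []
    for name in MECHANISTIC_PARAMETERS:
        for factor in (fold, 1.0 / fold):
            base = getattr(params, name) * factor
            row: dict[str, object] = {
                "parameter": name,
                "factor": factor,
                "value": base,
                "converged": True,
                "rate38_wt": np.nan,
                "rate38_ssrS_zero": np.nan,
                "ko_below_wt": False,
            }
            try:
                perturbed = params.replace(**{name: base})
                wt = solve_full_model(perturbed)
                ko = solve_full_model(apply_scenario(perturbed, "ssrS_zero"))
                row["rate38_wt"] = wt.rate38
                row["rate38_ssrS_zero"] = ko.rate38
                row["ko_below_wt"] = bool(ko.rate38 < wt.rate38)
            except (SteadyStateError, ValueError) as exc:
                row["converged"] = False
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
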