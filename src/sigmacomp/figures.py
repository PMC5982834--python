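"""Drivers reproducing the model-prediction panels as tidy tables.

``replicate_sweep_panels`` regenerates the sweep and bar-chart datasets
behind the model figure: holoenzyme partitioning as total Rsd is swept
with and without 6S RNA, transcription rates as total 6S RNA is swept,
and the knockout-approximation bar scenarios.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import solve_full_model
from .parameters import ModelParameters
from .scenarios import apply_scenario, sweep

__all__ = ["replicate_sweep_panels", "PANEL_NAMES"]

PANEL_NAMES = ("B_i", "B_ii", "B_iii", "B_iv", "B_v", "C_i", "C_ii")


def _scenario_rates(params: ModelParameters, names: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for name in names:
        st = solve_full_model(apply_scenario(params, name))
        rows.append({"scenario": name, "rate70": st.rate70, "rate38": st.rate38})
    return pd.DataFrame(rows)


def replicate_sweep_panels(
    params: ModelParameters | None = None,
    *,
    n_grid: int = 81,
    rsd_max_uM: float = 20.0,
    rna6s_max_uM: float = 26.0,
) -> dict[str, pd.DataFrame]:
    """Panel datasets keyed by panel name.

    * ``B_i``   holoenzyme levels vs total Rsd, 6S RNA absent;
    * ``B_ii``  the same sweep with 6S RNA at its default level;
    * ``B_iii`` the 6S-holoenzyme complex along the 6S-present sweep;
    * ``B_iv``  free core polymerase and free sigma70 along that sweep;
    * ``B_v``   transcription-rate bars: wild-type, plain Rsd removal and
      the Rsd-knockout approximation (6S RNA up 2.3-fold);
    * ``C_i``   transcription rates vs total 6S RNA;
    * ``C_ii``  bars: wild-type, plain 6S removal and the 6S-knockout
      approximation (Rsd and E halved, sigma38 up 50%).
    """
    if params is None:
        params = ModelParameters()
    rsd_grid = np.linspace(0.0, rsd_max_uM, n_grid)
    x6_grid = np.linspace(0.0, rna6s_max_uM, n_grid)

    no6s = sweep(params.replace(RNA6S_total=0.0), "Rsd_total", rsd_grid, variant="holoenzyme")
    with6s = sweep(params, "Rsd_total", rsd_grid, variant="holoenzyme")
    t_no6s, t_with6s = no6s.table(), with6s.table()

    panels: dict[str, pd.DataFrame] = {}
    panels["B_i"] = t_no6s[["Rsd_total", "E_sigma70", "E_sigma38"]].copy()
    panels["B_ii"] = t_with6s[["Rsd_total", "E_sigma70", "E_sigma38"]].copy()
    panels["B_iii"] = t_with6s[["Rsd_total", "c6S_E_sigma70"]].copy()
    panels["B_iv"] = t_with6s[["Rsd_total", "free_E", "free_sigma70"]].copy()
    panels["B_v"] = _scenario_rates(params, ("wt", "rsd_zero", "rsd_ko_sim"))

    x6sweep = sweep(params, "RNA6S_total", x6_grid, variant="full")
    panels["C_i"] = x6sweep.table()[["RNA6S_total", "rate70", "rate38"]].copy()
    panels["C_ii"] = _scenario_rates(params, ("wt", "ssrS_zero", "ssrS_ko_sim"))
    return panels


def write_panels(panels: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, tab in panels.items():
        path = outdir / f"panel_{name}.tsv"
        tab.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
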