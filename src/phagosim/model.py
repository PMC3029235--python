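"""Model/Results front-end over the simulation engine.

``PhagocytosisModel`` packages a scenario (the target-specific effector
switchboard) with the constitutive parameters of the two-phase cytoplasm.
``fit()`` optionally calibrates the free mechanical scales against observed
(or synthetic-benchmark) population statistics and then runs the forward
simulation; the returned ``PhagocytosisResults`` carries the trajectory,
the extracted uptake metrics with their benchmark uncertainties, and a
``summary()`` table.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmarks import POPULATION_STATS
from .biphasic import ConstitutiveParams
from .errors import ConfigurationError
from .observables import ObservableSummary, compare_trace, summarize
from .scenarios import ScenarioConfig, Trajectory, make_scenario, run_simulation


class PhagocytosisModel:
    """Forward model of one engulfment scenario.

    Parameters
    ----------
    scenario : str or ScenarioConfig
        Named preset ("zymosan", "antibody", "fcgamma_no_attraction",
        "zymosan_full_contact_protrusion") or an explicit configuration.
    params : ConstitutiveParams, optional
        Material/kinetic parameters; defaults to the package calibration.
    targets : dict, optional
        Observed statistics to calibrate against, e.g.
        ``{"engulfment_time_s": 66.0}``.  Defaults to the published
        population means for the scenario.
    """

    def __init__(self, scenario="zymosan", params: ConstitutiveParams | None = None,
                 targets: dict | None = None):
        if isinstance(scenario, str):
            scenario = make_scenario(scenario)
        scenario.validate()
        self.scenario = scenario
        self.params = params or ConstitutiveParams()
        self.params.validate()
        if targets is None and scenario.name in POPULATION_STATS:
            st = POPULATION_STATS[scenario.name]
            targets = {
                "push_out_um": st["pushout_mean"],
                "engulfment_time_s": st["time_mean"],
                "max_inward_speed_nm_per_s": st["speed"],
            }
        self.targets = targets or {}

    @classmethod
    def from_config(cls, path) -> "PhagocytosisModel":
        from .io import load_config

        cfg, params = load_config(path)
        return cls(cfg, params)

    def simulate(self, **kwargs) -> Trajectory:
        return run_simulation(self.scenario, self.params, **kwargs)

    def fit(self, calibrate: str | None = None, max_iter: int = 6,
            rtol: float = 0.1) -> "PhagocytosisResults":
        """Run the model; optionally first calibrate one parameter.

        ``calibrate="viscosity"`` adjusts ``mu_network_0`` by a secant
        iteration until the simulated engulfment time matches the target
        within ``rtol``; ``calibrate=None`` (default) runs with the stored
        parameters.
        """
        history = []
        if calibrate is not None:
            if calibrate != "viscosity":
                raise ConfigurationError(f"unknown calibration mode {calibrate!r}")
            target_T = self.targets.get("engulfment_time_s")
            if target_T is None:
                raise ConfigurationError("no engulfment-time target to calibrate against")
            mu = self.params.mu_network_0
            for _ in range(max_iter):
                params = dataclasses.replace(self.params, mu_network_0=mu)
                traj = run_simulation(self.scenario, params)
                T = summarize(traj).engulfment_time
                history.append((mu, T))
                if T is not None and abs(T - target_T) <= rtol * target_T:
                    break
                # engulfment time grows roughly linearly with viscosity
                scale = (target_T / T) if T else 0.7
                mu *= float(np.clip(scale, 0.6, 1.6))
            self.params = dataclasses.replace(self.params, mu_network_0=mu)

        traj = run_simulation(self.scenario, self.params)
        return PhagocytosisResults(self, traj, calibration_history=history)


@dataclass
class PhagocytosisResults:
    """Trajectory, metrics and diagnostics of one fitted/simulated scenario."""

    model: PhagocytosisModel
    trajectory: Trajectory
    calibration_history: list = field(default_factory=list)

    def __post_init__(self):
        self.metrics: ObservableSummary = summarize(self.trajectory)

    def metric_frame(self) -> pd.DataFrame:
        st = POPULATION_STATS.get(self.model.scenario.name, {})
        rows = {
            "push_out_um": (
                self.metrics.push_out_distance,
                st.get("pushout_mean"), st.get("pushout_sd"),
            ),
            "engulfment_time_s": (
                self.metrics.engulfment_time,
                st.get("time_mean"), st.get("time_sd"),
            ),
            "max_inward_speed_nm_per_s": (
                self.metrics.max_inward_speed, st.get("speed"), None,
            ),
        }
        return pd.DataFrame(rows, index=["model", "observed_mean", "observed_sd"]).T

    def compare(self, bench) -> dict:
        return compare_trace(self.trajectory, bench)

    def summary(self) -> str:
        sc = self.model.scenario
        df = self.metric_frame()
        lines = [
            "Phagocytosis simulation results",
            "===============================",
            f"scenario: {sc.name}  (stimulus {sc.stimulus_scale:.2f}, "
            f"contact protrusion {sc.contact_protrusion_scale:.2f}, "
            f"attraction {'on' if sc.attraction_on else 'off'})",
            f"tension: {sc.tension_rest} -> {sc.tension_plateau} mN/m, "
            f"viscosity ramp x{sc.viscosity_ramp_factor:g}",
            f"steps: {self.trajectory.diagnostics.get('n_steps')}  "
            f"volume drift: {self.trajectory.volume_drift:.2e}",
            "",
            df.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        if self.calibration_history:
            lines.append("")
            lines.append("calibration (mu_network_0 -> engulfment time):")
            for mu, T in self.calibration_history:
                lines.append(f"  {mu:.3g} -> {T if T is None else round(T, 1)}")
        return "\n".join(lines)
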