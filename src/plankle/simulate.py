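"""Named moment-sweep protocols.

Three standard protocols are provided:

* ``sim1`` -- M_ext from -0.20 to +0.20 N*m in 51 steps;
* ``sim2`` -- M_ext from -5.00 to +5.00 N*m in 51 steps;
* ``sim3`` -- the sim2 sweep on a sensitivity-perturbed model in which
  1 mm is added to the y coordinate of the PTT attachment on the basis
  (TFS) side, slack length deliberately not recomputed.

Negative moments drive dorsiflexion, positive moments plantarflexion.
Each run yields the sweep table (CSV) and a JSON summary with the angular
ranges per direction, per-ligament peak/mean-absolute strains and peak
forces, and the peak contact force.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fixtures import perturb_attachment
from .statics import JointModel, SweepTable, sweep_moments

__all__ = ["SIMULATIONS", "moment_grid", "run_simulation"]

# name -> (moment range N*m, step count, PTT perturbation applied)
SIMULATIONS = {
    "sim1": (0.20, 51, False),
    "sim2": (5.00, 51, False),
    "sim3": (5.00, 51, True),
}

PTT_PERTURBATION_MM = (0.0, 1.0)


def moment_grid(moment_range_nm: float, steps: int) -> np.ndarray:
    """Symmetric grid from -range to +range (N*m), inclusive."""
    if not (moment_range_nm > 0 and steps >= 2):
        raise ValueError("need moment_range_nm > 0 and steps >= 2")
    return np.linspace(-moment_range_nm, moment_range_nm, int(steps))


def run_simulation(
    name: str,
    model: JointModel,
    out_dir=None,
    warm_start: bool = True,
) -> tuple[SweepTable, dict]:
    """Execute a named protocol; optionally write ``<name>.csv`` and
    ``<name>_summary.json`` under ``out_dir``."""
    if name not in SIMULATIONS:
        raise KeyError(f"unknown simulation {name!r}; choose from {sorted(SIMULATIONS)}")
    rng_nm, steps, perturb = SIMULATIONS[name]
    run_model = (
        perturb_attachment(model, "PTT", PTT_PERTURBATION_MM, side="basis")
        if perturb
        else model
    )
    table = sweep_moments(run_model, moment_grid(rng_nm, steps), warm_start=warm_start)
    summary = table.summary()
    summary["simulation"] = name
    summary["moment_range_nm"] = rng_nm
    summary["steps"] = steps
    summary["force_model"] = model.force_model
    summary["residual_norm_convention"] = model.solver.residual_norm
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"{name}.csv")
        (out_dir / f"{name}_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return table, summary
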